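"""Pairwise kinship and linkage-based pruning.

Kinship uses the KING-robust between-family estimator

    phi = (N_het,het - 2 N_opp_hom) / (N_het,i + N_het,j)

over autosomal biallelic SNVs, with sites missing in either sample skipped.
The third-degree exclusion threshold 0.0884 = 2^(-7/2) is the standard
boundary for this estimator.  LD pruning follows the sliding-window
pairwise-r^2 convention (window and step measured in variant counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypePanel, PanelError

#: 2^(-7/2): third-degree relative boundary for KING-robust kinship.
KING_THIRD_DEGREE = 0.0884


@dataclass
class KinshipResult:
    """Pairwise kinship matrix with the exclusion outcome."""

    phi: np.ndarray
    samples: list[str]
    excluded: list[str] = field(default_factory=list)
    threshold: float = KING_THIRD_DEGREE


def _autosomal_snv_mask(panel: GenotypePanel) -> np.ndarray:
    return panel.chromosome_set_mask("autosomes") & np.array(
        [v.is_snv for v in panel.variants], dtype=bool
    )


def king_kinship(panel: GenotypePanel, sample_i: str, sample_j: str) -> float:
    """KING-robust kinship between two samples (NaN if undefined)."""
    gi = panel.genotypes[:, panel.sample_index(sample_i)]
    gj = panel.genotypes[:, panel.sample_index(sample_j)]
    mask = _autosomal_snv_mask(panel) & (gi >= 0) & (gj >= 0)
    gi, gj = gi[mask], gj[mask]
    het_i = gi == 1
    het_j = gj == 1
    n_hh = int((het_i & het_j).sum())
    n_opp = int(((gi == 0) & (gj == 2)).sum() + ((gi == 2) & (gj == 0)).sum())
    denom = int(het_i.sum() + het_j.sum())
    if denom == 0:
        return float("nan")
    return (n_hh - 2.0 * n_opp) / denom


def kinship_matrix(panel: GenotypePanel) -> KinshipResult:
    """All-pairs KING-robust kinship (diagonal 0.5 by convention)."""
    mask = _autosomal_snv_mask(panel)
    g = panel.genotypes[mask].astype(np.int16)
    n = panel.n_samples
    phi = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = g[:, i], g[:, j]
            ok = (gi >= 0) & (gj >= 0)
            a, b = gi[ok], gj[ok]
            n_hh = int(((a == 1) & (b == 1)).sum())
            n_opp = int(((a == 0) & (b == 2)).sum() + ((a == 2) & (b == 0)).sum())
            denom = int((a == 1).sum() + (b == 1).sum())
            phi[i, j] = phi[j, i] = (
                (n_hh - 2.0 * n_opp) / denom if denom else np.nan
            )
    return KinshipResult(phi, list(panel.samples))


def prune_related(
    panel: GenotypePanel, threshold: float = KING_THIRD_DEGREE
) -> list[str]:
    """Greedy removal of related samples until no pair has phi >= threshold.

    While any pair remains at or above the threshold, the sample involved in
    the most such pairs is removed (ties broken toward the later sample in
    panel order).  Returns the retained sample list in panel order.
    """
    res = kinship_matrix(panel)
    phi = res.phi.copy()
    np.fill_diagonal(phi, 0.0)
    active = np.ones(panel.n_samples, dtype=bool)
    with np.errstate(invalid="ignore"):
        hot = np.nan_to_num(phi, nan=0.0) >= threshold
    while True:
        deg = (hot & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        worst = np.flatnonzero(deg == deg.max())[-1]  # later sample on ties
        active[worst] = False
    return [s for s, keep in zip(panel.samples, active) if keep]


def _pairwise_r2(g: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of genotype codes over shared sites."""
    a, b = g[i], g[j]
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) < 2:
        return 0.0
    va, vb = a.var(), b.var()
    if va == 0.0 or vb == 0.0:
        return 0.0
    c = np.corrcoef(a, b)[0, 1]
    return float(c * c)


def _window_r2_matrix(g: np.ndarray, idx: list[int]) -> np.ndarray:
    """r^2 between all variant pairs in one window (pairwise deletion)."""
    rows = g[idx]
    k = len(idx)
    if np.all(rows >= 0):
        x = rows.astype(float)
        sd = x.std(axis=1)
        ok = sd > 0.0
        r2 = np.zeros((k, k))
        if ok.sum() >= 2:
            c = np.corrcoef(x[ok])
            r2[np.ix_(ok, ok)] = c * c
        np.fill_diagonal(r2, 0.0)
        return r2
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = _pairwise_r2(g, idx[a], idx[b])
    return out


def ld_prune(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Sliding-window LD pruning; returns retained variant indices.

    Within each window of ``window`` variants (sliding by ``step``, per
    chromosome), pairs with r^2 > ``r2_max`` are resolved by removing the
    later variant in genomic order.  Zero-variance variants are retained.
    """
    if panel.n_samples < 2:
        raise PanelError("LD pruning requires >= 2 samples")
    removed: set[int] = set()
    chroms = panel.chrom_array
    g = panel.genotypes  # (variants, samples): g[i] is one variant's codes
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom).tolist()
        changed = True
        while changed:  # iterate to a fixpoint over the retained set
            changed = False
            active = [i for i in idx if i not in removed]
            for start in range(0, max(len(active) - 1, 1), step):
                local = active[start : start + window]
                r2 = _window_r2_matrix(g, local)
                # greedy: earlier variants evict later ones above threshold;
                # removing a variant leaves the other pairs' r^2 unchanged
                gone: set[int] = set()
                for a_pos in range(len(local)):
                    if a_pos in gone:
                        continue
                    for b_pos in range(a_pos + 1, len(local)):
                        if b_pos in gone:
                            continue
                        if r2[a_pos, b_pos] > r2_max:
                            gone.add(b_pos)
                            removed.add(local[b_pos])
                            changed = True
                if start + window >= len(active):
                    break
    return np.array(
        [i for i in range(panel.n_variants) if i not in removed], dtype=np.intp
    )
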