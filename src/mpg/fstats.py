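"""f4 and outgroup-f3 admixture statistics with block-jackknife errors.

Per site with population alternate-allele frequencies p:

    f4(A, B; C, D): (pA - pB)(pC - pD)
    f3(O; A, B):    (pO - pA)(pO - pB)

The genome-wide estimate is the unweighted mean over retained sites,
computed as a ratio of block sums so the same delete-one-block weighted
jackknife machinery yields the standard error and Z-score.  f4 is zero in
expectation for an unadmixed tree with A,B on one side and C,D on the other;
a large |Z| signals gene flow.  Outgroup-f3 measures shared drift of A and B
relative to an outgroup O: larger values mean a more recent common ancestor.

A single individual may stand as a "population"; its frequencies then take
values in {0, 0.5, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BlockEstimate, GenotypePanel, PanelError, block_jackknife_ratio, partition_blocks


@dataclass
class FStatResult:
    """An f-statistic with its jackknife uncertainty."""

    kind: str  # "f3" | "f4"
    populations: tuple[str, ...]
    block: BlockEstimate

    @property
    def estimate(self) -> float:
        return self.block.estimate

    @property
    def se(self) -> float:
        return self.block.se

    @property
    def z(self) -> float:
        return self.block.z


def _freqs(panel: GenotypePanel, pops: tuple[str, ...], variant_mask) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-pop frequencies and a mask of sites observed in all pops."""
    ps = []
    ok = None
    for pop in pops:
        idx = panel.sample_indices_in(pop)
        if len(idx) == 0:
            raise PanelError(f"unknown or empty population {pop!r}")
        alt, tot = panel.allele_counts(idx, variant_mask)
        good = tot > 0
        p = np.where(good, alt / np.maximum(tot, 1), np.nan)
        ps.append(p)
        ok = good if ok is None else (ok & good)
    return np.vstack(ps), ok


def _blockwise_mean(
    terms: np.ndarray,
    ok: np.ndarray,
    chroms: np.ndarray,
    block_size: int,
) -> BlockEstimate:
    blocks = partition_blocks(chroms, block_size, variant_mask=ok)
    num = np.array([terms[b].sum() for b in blocks])
    den = np.array([float(len(b)) for b in blocks])
    w = den.copy()
    return block_jackknife_ratio(num, den, w, block_size)


def f4(
    panel: GenotypePanel,
    a: str,
    b: str,
    c: str,
    d: str,
    block_size: int = 25_000,
    variant_mask: np.ndarray | None = None,
) -> FStatResult:
    """f4(A, B; C, D) with block-jackknife SE and Z."""
    if len({a, b, c, d}) != 4:
        raise PanelError("f4 requires four distinct populations")
    p, ok = _freqs(panel, (a, b, c, d), variant_mask)
    terms = (p[0] - p[1]) * (p[2] - p[3])
    chroms = panel.chrom_array
    if variant_mask is not None:
        chroms = chroms[variant_mask]
    est = _blockwise_mean(np.where(ok, terms, 0.0), ok, chroms, block_size)
    return FStatResult("f4", (a, b, c, d), est)


def f3_outgroup(
    panel: GenotypePanel,
    o: str,
    a: str,
    b: str,
    block_size: int = 25_000,
    variant_mask: np.ndarray | None = None,
) -> FStatResult:
    """Outgroup f3(O; A, B): shared drift of A and B relative to O."""
    if len({o, a, b}) != 3:
        raise PanelError("f3 requires three distinct populations")
    p, ok = _freqs(panel, (o, a, b), variant_mask)
    terms = (p[0] - p[1]) * (p[0] - p[2])
    chroms = panel.chrom_array
    if variant_mask is not None:
        chroms = chroms[variant_mask]
    est = _blockwise_mean(np.where(ok, terms, 0.0), ok, chroms, block_size)
    return FStatResult("f3", (o, a, b), est)
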