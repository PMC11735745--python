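"""Hudson FST, block-jackknife aggregation, population-specific outliers,
and the X/autosome drift-ratio Q statistic.

Per-site Hudson components for populations with alt frequencies p1, p2 and
observed allele counts n1, n2:

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)

Genome-wide FST is the ratio of averages sum(N)/sum(D) (never the average of
per-site ratios), with a delete-one-block weighted jackknife over contiguous
blocks of variants (25,000 by default) for the standard error.

The Q statistic compares the drift implied by autosomal and X-chromosome
FST: with d = -ln(1 - FST), Q = d_auto / d_X.  Under equal effective sizes
and migration for both sexes the X effective size is 3/4 of the autosomal
one, so Q is expected to be 0.75; smaller values indicate male-biased
migration.  Q is undefined when either FST lies outside (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BlockEstimate,
    GenotypePanel,
    PanelError,
    block_jackknife_ratio,
    partition_blocks,
)


@dataclass
class FstComponents:
    """Per-variant Hudson numerators/denominators with the inputs."""

    num: np.ndarray
    den: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    usable: np.ndarray  # n1, n2 >= 2 at the site
    n_skipped: int


@dataclass
class QResult:
    """Relative drift of autosomes versus the X chromosome."""

    fst_auto: float
    fst_x: float
    q: float
    defined: bool


def hudson_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> FstComponents:
    """Vectorised per-site Hudson numerator and denominator.

    Sites where either population has fewer than two observed alleles are
    flagged unusable and counted; their components are NaN.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise PanelError("allele frequency outside [0, 1]")
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    return FstComponents(
        num, den, p1, p2, n1, n2, usable, int((~usable).sum())
    )


def per_site_fst(components: FstComponents) -> np.ndarray:
    """Per-variant N/D where defined (NaN where D = 0 or unusable)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(components.den > 0, components.num / components.den, np.nan)


def pair_components(
    panel: GenotypePanel,
    pop_a: str,
    pop_b: str,
    variant_mask: np.ndarray | None = None,
) -> FstComponents:
    """Hudson components between two populations of a panel."""
    ia = panel.sample_indices_in(pop_a)
    ib = panel.sample_indices_in(pop_b)
    if len(ia) == 0 or len(ib) == 0:
        raise PanelError(f"empty population in pair ({pop_a}, {pop_b})")
    alt_a, tot_a = panel.allele_counts(ia, variant_mask)
    alt_b, tot_b = panel.allele_counts(ib, variant_mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(tot_a > 0, alt_a / np.maximum(tot_a, 1), 0.0)
        pb = np.where(tot_b > 0, alt_b / np.maximum(tot_b, 1), 0.0)
    return hudson_components(pa, tot_a, pb, tot_b)


def genomewide_fst(
    components: FstComponents,
    block_size: int = 25_000,
    chroms: np.ndarray | None = None,
) -> BlockEstimate:
    """Ratio-of-averages FST with delete-one-block jackknife SE.

    Blocks are contiguous runs of usable variants (never spanning
    chromosomes when ``chroms`` is given) weighted by their variant counts.
    """
    usable = components.usable & np.isfinite(components.num)
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        raise PanelError("no usable sites")
    if chroms is None:
        chroms = np.zeros(len(components.num), dtype=int)
    blocks = partition_blocks(np.asarray(chroms), block_size, variant_mask=usable)
    num_b = np.array([components.num[b].sum() for b in blocks])
    den_b = np.array([components.den[b].sum() for b in blocks])
    w = np.array([len(b) for b in blocks], dtype=float)
    return block_jackknife_ratio(num_b, den_b, w, block_size)


def pair_fst(
    panel: GenotypePanel,
    pop_a: str,
    pop_b: str,
    chromosome_set: str = "autosomes",
    block_size: int = 25_000,
) -> BlockEstimate:
    """Genome-wide Hudson FST between two populations on a chromosome set."""
    mask = panel.chromosome_set_mask(chromosome_set)
    comp = pair_components(panel, pop_a, pop_b, mask)
    return genomewide_fst(comp, block_size, panel.chrom_array[mask])


def population_specific_fst(
    panel: GenotypePanel,
    target_pop: str,
    top_fraction: float = 0.01,
    variant_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant FST of one population against the pooled remainder.

    Returns ``(values, designated)``: per-variant Hudson N/D (NaN where
    undefined) and a boolean mask of the top ``top_fraction`` upper tail.
    At least ``ceil(top_fraction * n_defined)`` variants are designated, and
    ties at the cutoff value are all included.
    """
    target = panel.sample_indices_in(target_pop)
    if len(target) == 0:
        raise PanelError(f"unknown or empty target population {target_pop!r}")
    background = np.array(
        [i for i in range(panel.n_samples) if i not in set(target.tolist())],
        dtype=np.intp,
    )
    if len(background) == 0:
        raise PanelError("empty background population")
    alt_t, tot_t = panel.allele_counts(target, variant_mask)
    alt_b, tot_b = panel.allele_counts(background, variant_mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        pt = np.where(tot_t > 0, alt_t / np.maximum(tot_t, 1), 0.0)
        pb = np.where(tot_b > 0, alt_b / np.maximum(tot_b, 1), 0.0)
    comp = hudson_components(pt, tot_t, pb, tot_b)
    values = per_site_fst(comp)
    defined = np.isfinite(values)
    designated = np.zeros(len(values), dtype=bool)
    n_def = int(defined.sum())
    if n_def:
        k = max(1, int(np.ceil(top_fraction * n_def)))
        cutoff = np.sort(values[defined])[-k]
        designated = defined & (values >= cutoff)
    return values, designated


def q_statistic(fst_auto: float, fst_x: float) -> QResult:
    """Drift ratio Q = ln(1 - FST_auto) / ln(1 - FST_X).

    Undefined (``defined=False``, q=NaN) when either FST lies outside (0, 1),
    where the log-drift transform has no meaning.
    """
    ok = 0.0 < fst_auto < 1.0 and 0.0 < fst_x < 1.0
    if not ok:
        return QResult(fst_auto, fst_x, float("nan"), False)
    q = float(np.log1p(-fst_auto) / np.log1p(-fst_x))
    return QResult(fst_auto, fst_x, q, True)
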