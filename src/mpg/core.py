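"""Shared data model: genotype panels, variant records, genome blocks.

The universal substrate of every analysis stage is the :class:`GenotypePanel`,
a site-by-individual matrix of diploid genotype codes

    0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
    -1 = missing,

together with variant metadata, a sample -> population mapping, and a ploidy
map (males are haploid on the non-pseudoautosomal X, where only codes
{0, 2, -1} are legal).  Phase is deliberately collapsed (0|1 == 0/1): no
statistic in this package is haplotype-aware.

Coordinates are 1-based inclusive internally (VCF convention); BED I/O
converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Chromosome labels treated as the X chromosome by default.
X_CHROMOSOMES = frozenset({"chrX", "X"})

#: Non-pseudoautosomal X interval used by default (1-based inclusive bp),
#: overridable in config.
X_NONPAR = ("chrX", 2_364_962, 151_635_290)

MISSING = -1


class PanelError(ValueError):
    """Raised on malformed panels or inconsistent configuration."""


@dataclass
class VariantRecord:
    """A single biallelic variant.

    ``info`` carries numeric call annotations (QD, QUAL, FS, MQ, MQRankSum,
    ReadPosRankSum, SOR, ExcessHet, ...) consumed by the hard filter.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    info: dict = field(default_factory=dict)

    @property
    def variant_class(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"


@dataclass
class GenotypePanel:
    """Site-by-individual genotype matrix with metadata.

    Parameters
    ----------
    variants
        Ordered variant records, sorted by (chromosome, position).
    samples
        Ordered sample identifiers (columns of ``genotypes``).
    populations
        Mapping sample -> population label; every sample appears exactly once.
    genotypes
        ``(n_variants, n_samples)`` int8 array of genotype codes.
    haploid_chroms
        Mapping sample -> set of chromosome labels on which that sample is
        haploid (e.g. males on the non-PAR X).  Absent samples are diploid
        everywhere.
    x_chromosomes
        Chromosome labels that count as X (everything else is autosomal).
    """

    variants: list[VariantRecord]
    samples: list[str]
    populations: dict[str, str]
    genotypes: np.ndarray
    haploid_chroms: dict[str, frozenset] = field(default_factory=dict)
    x_chromosomes: frozenset = X_CHROMOSOMES
    n_multiallelic_skipped: int = 0

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise PanelError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise PanelError(f"samples without population label: {missing_pop}")

    # ------------------------------------------------------------------ sizes
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # ------------------------------------------------------------- indexing
    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise PanelError(f"unknown sample {name!r}") from None

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    def population_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == population]

    def sample_indices_in(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] == population],
            dtype=np.intp,
        )

    # ------------------------------------------------------------ chromosomes
    @property
    def chrom_array(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def pos_array(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def is_x_variant(self) -> np.ndarray:
        """Boolean per-variant mask of X-chromosome variants."""
        xset = self.x_chromosomes
        return np.array([v.chrom in xset for v in self.variants], dtype=bool)

    def chromosome_set_mask(self, chromosome_set: str) -> np.ndarray:
        """Mask for ``'autosomes'`` or ``'X'``."""
        isx = self.is_x_variant()
        if chromosome_set == "autosomes":
            return ~isx
        if chromosome_set == "X":
            return isx
        raise PanelError(f"unknown chromosome set {chromosome_set!r}")

    def ploidy_of(self, sample: str, chrom: str) -> int:
        return 1 if chrom in self.haploid_chroms.get(sample, ()) else 2

    def ploidy_matrix(self) -> np.ndarray:
        """``(n_variants, n_samples)`` int8 matrix of per-entry ploidies."""
        ploidy = np.full((self.n_variants, self.n_samples), 2, dtype=np.int8)
        chroms = self.chrom_array
        for j, s in enumerate(self.samples):
            hap = self.haploid_chroms.get(s)
            if hap:
                ploidy[np.isin(chroms, list(hap)), j] = 1
        return ploidy

    # ----------------------------------------------------------- frequencies
    def allele_counts(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele and total-allele counts per variant over a sample set.

        Missing genotypes contribute no alleles.  Haploid entries contribute
        one allele (code 2 -> one alt allele).
        """
        g = self.genotypes
        ploidy = self.ploidy_matrix()
        if sample_idx is not None:
            g = g[:, np.asarray(sample_idx, dtype=np.intp)]
            ploidy = ploidy[:, np.asarray(sample_idx, dtype=np.intp)]
        if variant_mask is not None:
            g = g[variant_mask]
            ploidy = ploidy[variant_mask]
        observed = g != MISSING
        tot = np.where(observed, ploidy, 0).sum(axis=1).astype(float)
        alt = np.where(observed, g * ploidy / 2.0, 0.0).sum(axis=1)
        return alt, tot

    def alt_freq(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-variant alternate-allele frequency (NaN where no alleles observed)."""
        alt, tot = self.allele_counts(sample_idx, variant_mask)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    # -------------------------------------------------------------- subsetting
    def subset(
        self,
        variant_idx: np.ndarray | Sequence[int] | None = None,
        sample_names: Sequence[str] | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given variants and/or samples."""
        vi = (
            np.arange(self.n_variants)
            if variant_idx is None
            else np.asarray(variant_idx)
        )
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        if sample_names is None:
            sample_names = list(self.samples)
        si = np.array([self.sample_index(s) for s in sample_names], dtype=np.intp)
        return GenotypePanel(
            variants=[self.variants[i] for i in vi],
            samples=list(sample_names),
            populations={s: self.populations[s] for s in sample_names},
            genotypes=self.genotypes[np.ix_(vi, si)],
            haploid_chroms={
                s: self.haploid_chroms[s]
                for s in sample_names
                if s in self.haploid_chroms
            },
            x_chromosomes=self.x_chromosomes,
        )

    def add_samples(
        self,
        names: Sequence[str],
        pops: Mapping[str, str],
        genotypes: np.ndarray,
        haploid_chroms: Mapping[str, Iterable[str]] | None = None,
    ) -> "GenotypePanel":
        """Return a new panel with extra sample columns appended."""
        hap = dict(self.haploid_chroms)
        for s, chroms in (haploid_chroms or {}).items():
            hap[s] = frozenset(chroms)
        return GenotypePanel(
            variants=list(self.variants),
            samples=list(self.samples) + list(names),
            populations={**self.populations, **dict(pops)},
            genotypes=np.hstack([self.genotypes, np.asarray(genotypes, dtype=np.int8)]),
            haploid_chroms=hap,
            x_chromosomes=self.x_chromosomes,
        )

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        """Check the structural invariants; raise :class:`PanelError` on failure."""
        codes = np.unique(self.genotypes)
        bad = set(codes.tolist()) - {-1, 0, 1, 2}
        if bad:
            raise PanelError(f"illegal genotype codes {sorted(bad)}")
        ploidy = self.ploidy_matrix()
        if np.any((ploidy == 1) & (self.genotypes == 1)):
            raise PanelError("haploid entry carries a heterozygous code")
        key = [(v.chrom, v.pos) for v in self.variants]
        # sorted within chromosome; chromosomes grouped contiguously
        chrom_first = {}
        prev = None
        for chrom, pos in key:
            if chrom != (prev[0] if prev else None):
                if chrom in chrom_first:
                    raise PanelError(f"chromosome {chrom} not contiguous")
                chrom_first[chrom] = pos
            elif pos < prev[1]:
                raise PanelError(f"variants unsorted at {chrom}:{pos}")
            prev = (chrom, pos)
        for v in self.variants:
            if not v.ref or not v.alt:
                raise PanelError("empty allele string")


@dataclass
class BlockEstimate:
    """A genome-wide ratio statistic with jackknife uncertainty.

    ``estimate`` always equals ``sum(per_block_numerators) /
    sum(per_block_denominators)`` (the ratio-of-averages convention); ``se``
    is a delete-one-block weighted jackknife standard error and ``z`` is
    ``estimate / se``.  ``se`` and ``z`` are NaN when fewer than two blocks
    are available.
    """

    estimate: float
    se: float
    z: float
    n_blocks: int
    block_size: int
    per_block_numerators: np.ndarray
    per_block_denominators: np.ndarray
    per_block_weights: np.ndarray

    @property
    def se_available(self) -> bool:
        return np.isfinite(self.se)


@dataclass(frozen=True)
class PopulationPair:
    """An ordered pair of distinct populations on a chromosome set."""

    pop_a: str
    pop_b: str
    chromosome_set: str = "autosomes"

    def __post_init__(self) -> None:
        if self.pop_a == self.pop_b:
            raise PanelError("population pair must name two distinct populations")
        if self.chromosome_set not in ("autosomes", "X"):
            raise PanelError(f"unknown chromosome set {self.chromosome_set!r}")


def partition_blocks(
    panel_or_chroms: "GenotypePanel | np.ndarray",
    block_size: int,
    variant_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Partition variant indices into contiguous blocks of ``block_size``.

    Blocks never span chromosomes; the final block on each chromosome may be
    smaller.  The returned arrays hold indices into the *original* variant
    order and form a partition of the retained set.
    """
    if block_size < 1:
        raise PanelError("block_size must be >= 1")
    chroms = (
        panel_or_chroms.chrom_array
        if isinstance(panel_or_chroms, GenotypePanel)
        else np.asarray(panel_or_chroms)
    )
    idx = np.arange(len(chroms))
    if variant_mask is not None:
        idx = idx[variant_mask]
    blocks: list[np.ndarray] = []
    start = 0
    while start < len(idx):
        chrom = chroms[idx[start]]
        # extent of current chromosome within the retained index list
        stop = start
        while stop < len(idx) and chroms[idx[stop]] == chrom:
            stop += 1
        for b in range(start, stop, block_size):
            blocks.append(idx[b : min(b + block_size, stop)])
        start = stop
    return blocks


def block_jackknife_ratio(
    numerators: np.ndarray,
    denominators: np.ndarray,
    weights: np.ndarray | None = None,
    block_size: int = 0,
) -> BlockEstimate:
    """Ratio-of-sums estimate with a delete-one-block weighted jackknife SE.

    ``numerators[j]`` / ``denominators[j]`` are block totals; ``weights[j]``
    is the block's variant count (defaults to equal weights).  The weighted
    delete-one jackknife (Busing's formula) reduces to the ordinary
    delete-one jackknife when all weights are equal.
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    g = len(num)
    if g == 0 or den.sum() == 0:
        raise PanelError("no usable blocks (zero denominator)")
    w = np.ones(g) if weights is None else np.asarray(weights, dtype=float)
    theta = num.sum() / den.sum()
    if g < 2:
        return BlockEstimate(theta, np.nan, np.nan, g, block_size, num, den, w)
    theta_j = (num.sum() - num) / (den.sum() - den)
    n = w.sum()
    h = n / w
    theta_dot = g * theta - np.sum((1.0 - w / n) * theta_j)
    tau = h * theta - (h - 1.0) * theta_j
    var = np.sum((tau - theta_dot) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = theta / se if se > 0 else np.nan
    return BlockEstimate(float(theta), se, z, g, block_size, num, den, w)
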