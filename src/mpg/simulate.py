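"""Synthetic structured-population genotype panels with known truth.

The generator emulates a panel of diverged populations plus outgroup
individuals.  Allele frequencies start from an ancestral density on (0, 1)
and evolve down a population tree by hierarchical Balding--Nichols draws:
along a branch with drift amount ``F = 1 - exp(-t / (2N))``,

    p_child ~ Beta(p (1-F)/F, (1-p) (1-F)/F),

which preserves the mean and adds variance ``F p (1-p)``.  Admixture events
mix leaf frequencies as ``p_target <- (1-alpha) p_target + alpha p_source``.
X-chromosome sites use the drift implied by an effective size ``N * x_factor``
(default 3/4, the neutral expectation with equal sex-specific parameters),
males are haploid on X.  Genotypes are drawn under Hardy--Weinberg within
each population; sites are unlinked (optionally a fraction of sites is
duplicated as perfectly correlated "tag pairs" to exercise LD pruning).

The reference allele is the ancestral allele, so an outgroup individual
homozygous for the reference carries no derived allele -- matching the
outgroup polarization logic of the downstream loss-of-function analysis.

Every stochastic operation takes an explicit seed, and the
:class:`SimTruth` record carries the ground truth (per-branch drift,
expected pairwise Hudson FST, pedigree, planted autozygous tracts and
loss-of-function sites) that downstream acceptance tests check against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GenotypePanel, PanelError, VariantRecord


# --------------------------------------------------------------------- config
@dataclass
class PopNode:
    """A node of the population tree.

    ``t`` (generations) and ``N`` (diploid effective size) set the branch
    drift ``F = 1 - exp(-t/(2N))`` leading *into* this node; ``drift`` may
    specify F directly instead.  Leaves are sampled populations.
    """

    name: str
    children: list["PopNode"] = field(default_factory=list)
    t: float = 0.0
    N: float = 10_000.0
    drift: float | None = None

    def branch_drift(self, x_factor: float = 1.0) -> float:
        if self.drift is not None:
            f = self.drift
            # F specified directly: rescale through the implied t/(2N)
            return 1.0 - (1.0 - f) ** (1.0 / x_factor) if f < 1.0 else 1.0
        if self.t == 0:
            return 0.0
        return 1.0 - np.exp(-self.t / (2.0 * self.N * x_factor))

    def leaves(self) -> list["PopNode"]:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class AdmixtureEvent:
    """One-shot admixture: target frequencies pulled toward the source."""

    source: str
    target: str
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise PanelError("admixture fraction must lie in [0, 1]")


@dataclass
class DemographyConfig:
    """Parameters of one simulated panel.

    Defaults reflect macaque-scale values: mutation rate 6.5e-9 per site per
    generation and an 11-year generation time (reporting only -- sites are
    generated directly at frequency level), and an X/autosome effective-size
    ratio of 0.75.
    """

    tree: PopNode
    n_individuals: dict[str, int]
    n_sites_autosome: int = 10_000
    n_sites_x: int = 0
    x_factor: float = 0.75
    admixture: list[AdmixtureEvent] = field(default_factory=list)
    site_spacing: int = 1_000
    n_autosomes: int = 1
    ancestral_beta: tuple[float, float] = (0.2, 0.2)
    ancestral_trunc: tuple[float, float] = (0.05, 0.95)
    indel_fraction: float = 0.0
    tag_pair_fraction: float = 0.0
    sex_by_sample: dict[str, str] = field(default_factory=dict)
    mutation_rate: float = 6.5e-9
    generation_time: float = 11.0

    def __post_init__(self) -> None:
        if not 0.0 < self.x_factor <= 1.0:
            raise PanelError("x_factor must lie in (0, 1]")
        for pop, n in self.n_individuals.items():
            if n < 1:
                raise PanelError(f"population {pop} needs >= 1 individual")


def two_population_config(
    drift: float | None = None,
    t: float = 2_000.0,
    N: float = 10_000.0,
    n_individuals: int = 20,
    n_sites_autosome: int = 50_000,
    n_sites_x: int = 0,
    x_factor: float = 0.75,
    pops: tuple[str, str] = ("A", "B"),
    **kw,
) -> DemographyConfig:
    """Two populations splitting from a common ancestor with equal branches."""
    a, b = pops
    tree = PopNode(
        "root",
        [PopNode(a, t=t, N=N, drift=drift), PopNode(b, t=t, N=N, drift=drift)],
    )
    return DemographyConfig(
        tree=tree,
        n_individuals={a: n_individuals, b: n_individuals},
        n_sites_autosome=n_sites_autosome,
        n_sites_x=n_sites_x,
        x_factor=x_factor,
        **kw,
    )


def quartet_config(
    drift: float = 0.05,
    n_individuals: int = 10,
    n_sites_autosome: int = 25_000,
    admixture: Sequence[AdmixtureEvent] = (),
    n_autosomes: int = 20,
    **kw,
) -> DemographyConfig:
    """Symmetric two-deep tree ((A,B),(C,D)) with equal branch drift.

    Sites are spread over ``n_autosomes`` chromosomes so block-jackknife
    estimates have several blocks even at large block sizes.
    """
    tree = PopNode(
        "root",
        [
            PopNode(
                "AB",
                [PopNode("A", drift=drift), PopNode("B", drift=drift)],
                drift=drift,
            ),
            PopNode(
                "CD",
                [PopNode("C", drift=drift), PopNode("D", drift=drift)],
                drift=drift,
            ),
        ],
    )
    return DemographyConfig(
        tree=tree,
        n_individuals={p: n_individuals for p in "ABCD"},
        n_sites_autosome=n_sites_autosome,
        admixture=list(admixture),
        n_autosomes=n_autosomes,
        **kw,
    )


# ---------------------------------------------------------------------- truth
@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    branch_drift: dict[str, float] = field(default_factory=dict)
    branch_drift_x: dict[str, float] = field(default_factory=dict)
    expected_fst: dict[tuple[str, str, str], float] = field(default_factory=dict)
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)
    planted_roh: list[tuple[str, str, int, int]] = field(default_factory=list)
    planted_lof: list[tuple[int, str, str]] = field(default_factory=list)
    admixture: list[AdmixtureEvent] = field(default_factory=list)
    leaf_freqs: dict[str, np.ndarray] = field(default_factory=dict)

    def expected_pair_fst(self, pop_a: str, pop_b: str, chromosome_set: str = "autosomes") -> float:
        key = (min(pop_a, pop_b), max(pop_a, pop_b), chromosome_set)
        return self.expected_fst[key]


def _path_drifts(tree: PopNode, x_factor: float) -> dict[tuple[str, str], float]:
    """Compounded drift along the two paths from each pair's MRCA.

    Returns the expected genome-wide Hudson FST for each unordered leaf pair:
    the *mean* of the two path drifts ``1 - prod(1 - F_i)`` below the MRCA,
    which is what the ratio-of-averages estimator converges to under this
    generative model.
    """

    def walk(node: PopNode) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
        if not node.children:
            return {node.name: 0.0}, {}
        below: list[dict[str, float]] = []
        pair_fst: dict[tuple[str, str], float] = {}
        for child in node.children:
            survive, pairs = walk(child)
            f_branch = child.branch_drift(x_factor)
            # compound the child's branch into every leaf path below it
            compounded = {
                leaf: 1.0 - (1.0 - f_branch) * (1.0 - f)
                for leaf, f in survive.items()
            }
            below.append(compounded)
            pair_fst.update(pairs)
        for da, db in itertools.combinations(below, 2):
            for la, fa in da.items():
                for lb, fb in db.items():
                    key = (min(la, lb), max(la, lb))
                    pair_fst[key] = 0.5 * (fa + fb)
        merged = {k: v for d in below for k, v in d.items()}
        return merged, pair_fst

    _, pairs = walk(tree)
    return pairs


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """One Balding--Nichols drift step; fixed sites stay fixed."""
    if f <= 0.0:
        return p.copy()
    if f >= 1.0:
        return (rng.random(p.shape) < p).astype(float)
    out = p.copy()
    seg = (p > 0.0) & (p < 1.0)
    scale = (1.0 - f) / f
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def _leaf_frequencies(
    rng: np.random.Generator,
    config: DemographyConfig,
    n_sites: int,
    x_factor: float,
) -> dict[str, np.ndarray]:
    a, b = config.ancestral_beta
    lo, hi = config.ancestral_trunc
    p0 = lo + (hi - lo) * rng.beta(a, b, size=n_sites)

    freqs: dict[str, np.ndarray] = {}

    def walk(node: PopNode, p: np.ndarray) -> None:
        if not node.children:
            freqs[node.name] = p
            return
        for child in node.children:
            f = child.branch_drift(x_factor)
            walk(child, _balding_nichols(rng, p, f))

    walk(config.tree, p0)
    for ev in config.admixture:
        if ev.source not in freqs or ev.target not in freqs:
            raise PanelError(f"admixture names unknown population: {ev}")
        freqs[ev.target] = (1.0 - ev.alpha) * freqs[ev.target] + ev.alpha * freqs[ev.source]
    return freqs


def _assign_sexes(config: DemographyConfig) -> dict[str, str]:
    sexes: dict[str, str] = {}
    for pop, n in config.n_individuals.items():
        for i in range(n):
            name = f"{pop}_{i:02d}"
            sexes[name] = config.sex_by_sample.get(name, "F" if i % 2 == 0 else "M")
    return sexes


def simulate_panel(
    config: DemographyConfig, seed: int
) -> tuple[GenotypePanel, SimTruth]:
    """Simulate a genotype panel with its ground truth.

    Autosomal sites are spread over ``n_autosomes`` chromosomes named
    ``chr1..``; X sites live on ``chrX`` where male samples are haploid.
    """
    rng = np.random.default_rng(seed)
    leaves = [lf.name for lf in config.tree.leaves()]
    for pop in config.n_individuals:
        if pop not in leaves:
            raise PanelError(f"population {pop} is not a leaf of the tree")
    pops = [p for p in leaves if p in config.n_individuals]
    sexes = _assign_sexes(config)
    samples = list(sexes)
    populations = {s: s.rsplit("_", 1)[0] for s in samples}

    truth = SimTruth(admixture=list(config.admixture))

    def record_drift(node: PopNode) -> None:
        for child in node.children:
            truth.branch_drift[child.name] = child.branch_drift(1.0)
            truth.branch_drift_x[child.name] = child.branch_drift(config.x_factor)
            record_drift(child)

    record_drift(config.tree)
    for (la, lb), fst in _path_drifts(config.tree, 1.0).items():
        truth.expected_fst[(la, lb, "autosomes")] = fst
    for (la, lb), fst in _path_drifts(config.tree, config.x_factor).items():
        truth.expected_fst[(la, lb, "X")] = fst

    variants: list[VariantRecord] = []
    geno_rows: list[np.ndarray] = []
    freq_rows: dict[str, list[np.ndarray]] = {p: [] for p in pops}

    def emit_sites(chrom: str, n_sites: int, freqs: dict[str, np.ndarray], haploid_males: bool) -> None:
        if n_sites == 0:
            return
        g = np.empty((n_sites, len(samples)), dtype=np.int8)
        for j, s in enumerate(samples):
            p = freqs[populations[s]]
            if haploid_males and sexes[s] == "M":
                g[:, j] = 2 * rng.binomial(1, p)
            else:
                g[:, j] = rng.binomial(2, p)
        n_indel = rng.binomial(n_sites, config.indel_fraction) if config.indel_fraction else 0
        indel_idx = set(rng.choice(n_sites, size=n_indel, replace=False).tolist()) if n_indel else set()
        n_tag = int(round(config.tag_pair_fraction * n_sites))
        tag_idx = set(rng.choice(n_sites, size=n_tag, replace=False).tolist()) if n_tag else set()
        pos = 1
        for i in range(n_sites):
            ref, alt = ("A", "AT") if i in indel_idx else ("A", "G")
            variants.append(VariantRecord(chrom, pos, ref, alt))
            geno_rows.append(g[i])
            for p in pops:
                freq_rows[p].append(freqs[p][i])
            if i in tag_idx:  # perfectly correlated duplicate right next door
                variants.append(VariantRecord(chrom, pos + 1, "A", "G"))
                geno_rows.append(g[i])
                for p in pops:
                    freq_rows[p].append(freqs[p][i])
            pos += config.site_spacing

    per_chrom = np.array_split(np.arange(config.n_sites_autosome), config.n_autosomes)
    auto_freqs = _leaf_frequencies(rng, config, config.n_sites_autosome, 1.0)
    offset = 0
    for c, idx in enumerate(per_chrom, start=1):
        chunk = {p: auto_freqs[p][offset : offset + len(idx)] for p in pops}
        emit_sites(f"chr{c}", len(idx), chunk, haploid_males=False)
        offset += len(idx)
    if config.n_sites_x:
        x_freqs = _leaf_frequencies(rng, config, config.n_sites_x, config.x_factor)
        emit_sites("chrX", config.n_sites_x, x_freqs, haploid_males=True)

    haploid = {
        s: frozenset({"chrX"}) for s in samples if sexes[s] == "M"
    } if config.n_sites_x else {}
    panel = GenotypePanel(
        variants=variants,
        samples=samples,
        populations=populations,
        genotypes=np.vstack(geno_rows) if geno_rows else np.empty((0, len(samples)), dtype=np.int8),
        haploid_chroms=haploid,
    )
    truth.leaf_freqs = {p: np.array(freq_rows[p]) for p in pops}
    return panel, truth


# ------------------------------------------------------------------ relatives
def spawn_relatives(
    panel: GenotypePanel,
    pedigree_spec: Iterable[tuple],
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[GenotypePanel, SimTruth]:
    """Add offspring by independent Mendelian transmission per site.

    ``pedigree_spec`` holds ``(child, parent1, parent2)`` tuples (optionally a
    4th element, the child's sex, defaulting to ``"F"``).  Sites are treated
    as unlinked.  A missing parent genotype yields a missing child genotype.
    """
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else SimTruth()
    new_names: list[str] = []
    new_pops: dict[str, str] = {}
    new_cols: list[np.ndarray] = []
    new_hap: dict[str, frozenset] = {}
    chroms = panel.chrom_array
    isx = panel.is_x_variant()

    def transmit(parent: str, child_sex: str) -> np.ndarray:
        j = panel.sample_index(parent)
        g = panel.genotypes[:, j].astype(float)
        hap_parent = np.array(
            [panel.ploidy_of(parent, c) == 1 for c in chroms], dtype=bool
        )
        allele = np.where(
            hap_parent, g / 2.0, rng.binomial(1, np.clip(g / 2.0, 0, 1))
        )
        allele[g < 0] = np.nan
        return allele

    for spec in pedigree_spec:
        child, p1, p2, *rest = spec
        sex = rest[0] if rest else "F"
        for parent in (p1, p2):
            if parent not in panel.samples:
                raise PanelError(f"parent {parent} not in panel")
        a1 = transmit(p1, sex)
        a2 = transmit(p2, sex)
        g_child = a1 + a2
        if sex == "M":
            # haploid X: keep only the maternally transmitted allele
            g_child = np.where(isx, 2 * a1, g_child)
            new_hap[child] = frozenset({"chrX"})
        col = np.where(np.isnan(g_child), -1, g_child).astype(np.int8)
        new_names.append(child)
        new_pops[child] = panel.populations[p1]
        new_cols.append(col[:, None])
        truth.pedigree.append((child, p1, p2))
    out = panel.add_samples(
        new_names, new_pops, np.hstack(new_cols), new_hap
    )
    return out, truth


# ----------------------------------------------------------------------- ROH
def plant_roh(
    panel: GenotypePanel,
    sample: str,
    interval: tuple[str, int, int],
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[GenotypePanel, SimTruth]:
    """Make a sample autozygous across an interval.

    Within ``interval = (chrom, start, end)`` (1-based inclusive) the
    sample's genotypes are replaced by homozygotes drawn from its
    population's empirical allele frequency -- as if both haplotypes
    descended from one recent ancestor.
    """
    chrom, start, end = interval
    truth = truth if truth is not None else SimTruth()
    for (s, c, a, b) in truth.planted_roh:
        if s == sample and c == chrom and not (end < a or start > b):
            raise PanelError("planted ROH overlaps an existing planted segment")
    if end < start:
        return panel, truth
    rng = np.random.default_rng(seed)
    pos = panel.pos_array
    in_iv = (panel.chrom_array == chrom) & (pos >= start) & (pos <= end)
    j = panel.sample_index(sample)
    pop_idx = panel.sample_indices_in(panel.populations[sample])
    freqs = panel.alt_freq(sample_idx=pop_idx)
    geno = panel.genotypes.copy()
    idx = np.flatnonzero(in_iv)
    p = np.nan_to_num(freqs[idx], nan=0.0)
    geno[idx, j] = 2 * rng.binomial(1, p)
    out = GenotypePanel(
        variants=list(panel.variants),
        samples=list(panel.samples),
        populations=dict(panel.populations),
        genotypes=geno,
        haploid_chroms=dict(panel.haploid_chroms),
        x_chromosomes=panel.x_chromosomes,
    )
    truth.planted_roh.append((sample, chrom, start, end))
    return out, truth


# --------------------------------------------------------------- consequences
LOF_CLASSES_SNV = ("stop_gained", "splice_acceptor", "splice_donor")
NON_LOF_CLASSES = ("missense", "synonymous")


def assign_consequences(
    panel: GenotypePanel,
    gene_intervals: Sequence[tuple[str, int, int, str]],
    lof_fraction: float,
    seed: int,
    truth: SimTruth | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Emulate per-variant consequence annotation.

    Each in-gene variant receives a consequence class; a fraction
    ``lof_fraction`` get a loss-of-function class (indels -> frameshift,
    SNVs -> premature stop or splice disruption), the rest missense or
    synonymous.  Variants outside genes are intergenic.  Returns a
    :class:`~pandas.DataFrame` with columns ``variant_index, chrom, pos,
    consequence, gene_id`` and records planted LoF sites in the truth.
    """
    if not 0.0 <= lof_fraction <= 1.0:
        raise PanelError("lof_fraction must lie in [0, 1]")
    for (c1, s1, e1, _), (c2, s2, e2, _) in itertools.combinations(gene_intervals, 2):
        if c1 == c2 and not (e1 < s2 or e2 < s1):
            raise PanelError("gene intervals overlap")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else SimTruth()
    rows = []
    for i, v in enumerate(panel.variants):
        gene = None
        for (c, s, e, gid) in gene_intervals:
            if v.chrom == c and s <= v.pos <= e:
                gene = gid
                break
        if gene is None:
            rows.append((i, v.chrom, v.pos, "intergenic", None))
            continue
        if rng.random() < lof_fraction:
            if v.variant_class == "indel":
                csq = "frameshift"
            else:
                csq = LOF_CLASSES_SNV[rng.integers(len(LOF_CLASSES_SNV))]
            truth.planted_lof.append((i, gene, csq))
        else:
            csq = NON_LOF_CLASSES[rng.integers(len(NON_LOF_CLASSES))]
        rows.append((i, v.chrom, v.pos, csq, gene))
    table = pd.DataFrame(
        rows, columns=["variant_index", "chrom", "pos", "consequence", "gene_id"]
    )
    return table, truth


# ---------------------------------------------------------------------- depth
def simulate_depth(
    panel: GenotypePanel,
    mean_depth: float,
    dispersion: float,
    seed: int,
    odd_site_fraction: float = 0.0,
) -> np.ndarray:
    """Negative-binomial per-site per-sample sequencing depths.

    ``dispersion`` is the negative-binomial size parameter; ``inf`` gives
    the Poisson limit.  A fraction ``odd_site_fraction`` of sites is drawn
    with doubled or halved mean depth to create inaccessible tails.
    """
    if mean_depth <= 0:
        raise PanelError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    n, m = panel.n_variants, panel.n_samples
    if n == 0:
        return np.empty((0, m), dtype=np.int64)
    means = np.full(n, float(mean_depth))
    if odd_site_fraction > 0:
        n_odd = int(round(odd_site_fraction * n))
        odd = rng.choice(n, size=n_odd, replace=False)
        factor = rng.choice([0.5, 2.0], size=n_odd)
        means[odd] *= factor
    mu = means[:, None] * np.ones((1, m))
    if np.isinf(dispersion):
        return rng.poisson(mu).astype(np.int64)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p).astype(np.int64)
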