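# Methods

This document records the statistical definitions, the generative model used
for validation, parameter defaults with their rationale, and known
limitations.

## 1. Data model

Genotypes are stored as an `int8` matrix of alternate-allele dosages
(0/1/2, −1 = missing) over biallelic variants; phase is not retained.
Chromosomes are partitioned into autosomes and X; within the X, the
non-pseudoautosomal region (non-PAR, default interval
chrX:2,364,962–151,635,290) is haploid in males, whose calls there take
codes {0, 2} and contribute a single allele to frequency counts.
Multiallelic records are skipped on VCF input (counted and logged).
Site annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, SOR, ExcessHet,
and the QUAL column) are carried per variant for hard filtering.

## 2. Estimators

### Hudson F<sub>ST</sub>

Per site with sample frequencies p₁, p₂ from n₁, n₂ observed alleles:

```
N = (p₁ − p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
D = p₁(1−p₂) + p₂(1−p₁)
```

Sites with n < 2 alleles in either population are skipped (the unbiased
within-population heterozygosity is undefined). The genome-wide estimate is
the **ratio of sums** ΣN/ΣD, not the mean of ratios, which keeps the
estimator unbiased under varying information content per site.

### Block jackknife

Standard errors come from a weighted delete-one-block jackknife
(Busing-style): with g blocks of m_j variants, n = Σm_j, h_j = n/m_j,

```
τ_j = h_j θ̂ − (h_j − 1) θ̂_(−j)
θ̇  = g θ̂ − Σ_j (1 − m_j/n) θ̂_(−j)
var = (1/g) Σ_j (τ_j − θ̇)² / (h_j − 1)
```

which reduces to the ordinary delete-one jackknife for equal block sizes.
Blocks are contiguous runs of retained variants and **never span
chromosome boundaries**; the default block size is 25,000 variants.

### Q statistic

`Q = ln(1 − F_auto)/ln(1 − F_X)` compares compounded drift on autosomes vs
the X. It is reported as undefined outside the domain
F_auto ∈ [0, 1), F_X ∈ (0, 1). Under sex-symmetric demography the X
effective size is 3/4 of the autosomal one and Q = 0.75 exactly (see §3).

### f-statistics

`f4(A,B;C,D) = E[(p_A−p_B)(p_C−p_D)]` and
`f3(O;A,B) = E[(p_O−p_A)(p_O−p_B)]`, estimated as the mean over sites
observed in all populations, computed as a ratio of block sums (numerator:
block sums of per-site terms; denominator: block site counts) so the same
jackknife machinery yields SE and Z. A single individual may stand in for a
population. f4 satisfies exact antisymmetry and the cyclic identity
`f4(A,B;C,D) + f4(A,C;D,B) + f4(A,D;B,C) = 0` (tested to 1e−12).

### Heterozygosity, π

Individual heterozygosity is the count of het calls divided by the number of
accessible sites. Nucleotide diversity π uses the unbiased per-site estimator
`2 p (1−p) · n/(n−1)` on pooled allele counts, averaged over accessible
sites.

### Runs of homozygosity

A two-state HMM (states: Hardy–Weinberg, autozygous) over per-site het/hom
calls. Emissions: `P(het | HW) = 2p(1−p)(1−ε) + ε′` with site frequency p,
`P(het | AZ) = ε_AZ` (defaults ε = ε′ = ε_AZ = 1e−3). Transitions follow a
two-state continuous-time chain with per-bp rates HW→AZ 6.6e−9 and
AZ→HW 5.0e−9, scaled by the physical distance between adjacent sites, so
sparse regions are less sticky. Segments are Viterbi runs of the AZ state
from first to last AZ site; segment quality is
`−10·log10(1 − mean posterior)` capped at 99. The default filter keeps
segments with quality ≥ 30 **and** length ≥ 100 kb.

**Edge limitation.** The mean-posterior quality is intrinsically bounded by
the segment's edge sites: the posterior decays over a few sites at each
boundary, so a perfectly recovered ~500-site segment still accumulates a
fixed posterior deficit at its edges and its quality scales roughly like
`−10·log10(c/n_sites)`. Very confident but site-sparse segments can
therefore fall below quality 30. Recovery (overlap with a true tract) is
validated at the segmentation level, and the filter's boundary behaviour is
validated on constructed segments.

### Kinship and pruning

KING-robust: `φ = (N_het,het − 2 N_opp,hom)/(N_het,i + N_het,j)` over
autosomal biallelic SNVs with pairwise deletion of missing calls; undefined
(NaN) when neither sample has a het. Pruning removes, while any pair is at
or above 0.0884 (= 2^(−7/2), the third-degree boundary), the sample in the
most such pairs, ties broken toward the later sample, guaranteeing no
remaining pair at or above the threshold.

### LD pruning

Sliding windows of 50 variants, step 5, per chromosome; within a window any
pair with genotype r² > 0.5 drops the later variant. Windows are re-scanned
over the retained set to a fixpoint, so the invariant "no retained pair
within a window exceeds the threshold" holds after pruning. Zero-variance
variants are retained. Note that rare variants can show chance r² = 1
through shared singleton carriers; pruning such sites is correct behaviour,
not an artifact.

### Genotype distance and trees

Per-site distance: identical homozygotes 0, opposite homozygotes 1, and 0.5
whenever either individual is het (two heterozygotes share one allele on
average). Pair distance is the mean over sites non-missing in both
individuals; `n_sites_used` is exposed to detect imbalance. Neighbor joining
is the Saitou–Nei algorithm with the standard Q-criterion, deterministic
first-pair tie-breaking, and negative branch lengths clamped to zero with
the excess transferred to the sibling branch. Exports: PHYLIP square
distances, NEXUS DISTANCES block, newick.

### Loss-of-function bookkeeping

A variant is species-specific derived when **every** outgroup individual is
unambiguously homozygous reference (no het, no missing). LoF classes:
frameshift, stop_gained, splice_acceptor, splice_donor. Species-specific LoF
variants split into fixed (all focal samples hom-alt, no missingness) vs
segregating; per-individual burdens count homozygous segregating LoF (split
SNV/indel) and distinct genes carrying any LoF allele.

### Site filters

- **Mappability**: brute-force (k=30, e=2) — the score at a position is
  1/(number of genome windows within Hamming distance 2 of its 30-mer);
  the filter retains score-1 sites only.
- **Accessibility**: per-site summed depth across samples must lie in
  [mode/2, 2·mode], the mode taken as the smallest tied argmax of the
  depth histogram.
- **Hard filters**: SNVs fail on QD < 2, QUAL < 30, SOR > 3, FS > 60,
  MQ < 40, MQRankSum < −12.5, ReadPosRankSum < −8, ExcessHet > 30; indels on
  QD < 2, QUAL < 30, FS > 200, ReadPosRankSum < −20, ExcessHet > 30.
  Missing annotations do not fail a site. The rule engine accepts arbitrary
  `(key, comparator, threshold)` triples.

## 3. The simulator and its ground truth

Allele frequencies start from a truncated Beta(0.2, 0.2) ancestral density
on [0.05, 0.95] and evolve down a population tree by hierarchical
Balding–Nichols draws: along a branch with drift `F = 1 − exp(−t/(2N))`,

```
p_child ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
```

preserving the mean and adding variance `F·p(1−p)`. X sites use the drift
implied by `N·x_factor` (equivalently `F_X = 1 − (1−F)^(1/x_factor)`);
males are haploid on X. Genotypes are Hardy–Weinberg within populations;
sites are unlinked except for optional perfectly-correlated "tag pairs" used
to exercise LD pruning. One-shot admixture mixes leaf frequencies
(`p_target ← (1−α)p_target + α p_source`). Relatives are created by
Mendelian transmission from existing parents; autozygous tracts are planted
by drawing homozygous genotypes from population frequencies within an
interval; consequence annotations are assigned per gene interval with a
configurable LoF fraction. Read depths are negative-binomial.

**Expected F<sub>ST</sub> (derivation).** For two leaves a, b with MRCA m,
let F_a, F_b be the compounded drifts along the paths m→a and m→b
(`1−F_path = Π(1−F_branch)`). Under Balding–Nichols,
`E[p(1−p)] = p₀(1−p₀)(1−F_path)`, and substituting into Hudson's N and D and
averaging over sites gives

```
E[ΣN/ΣD] = (F_a + F_b) / 2
```

— the *mean* of the two path drifts (not their compounded product). The
simulator's truth record stores this value; at desk scale the Monte-Carlo
estimate matches it well within jackknife error. A corollary is that for a
symmetric split the expected Q is exactly
`ln(1−F)/ln(1−F_X) = x_factor`, making the Q acceptance target analytic.

**What the generator emulates / does not.** It emulates tree-structured
drift, sex-linked effective-size differences, admixture pulses, Mendelian
relatives, ROH tracts, and annotation plumbing. It does **not** model
linkage (beyond tag pairs), recombination, mutation-rate heterogeneity,
selection, or sequencing error; `mutation_rate` (6.5e−9/site/generation) and
`generation_time` (11 years) are carried for reporting only.

## 4. Parameter defaults and rationale

| Parameter | Default | Rationale |
| --- | --- | --- |
| block size | 25,000 variants | large enough to absorb local LD in real data; blocks never span chromosomes |
| quartet sims `n_autosomes` | 20 | guarantees ≥ 20 jackknife blocks even at the default block size (blocks cannot span chromosomes) |
| x_factor | 0.75 | neutral X/autosome effective-size ratio with equal sex parameters |
| KING cutoff | 0.0884 | 2^(−7/2), third-degree boundary |
| LD window/step/r² | 50 / 5 / 0.5 | standard sliding-window convention |
| ROH rates | 6.6e−9, 5.0e−9 per bp | transition scale giving ~100-kb-scale expected segment lengths |
| ROH filter | quality ≥ 30, length ≥ 100 kb | suppresses short chance runs of homozygosity |
| mappability | k=30, e=2 | 30-mer uniqueness allowing 2 mismatches |
| accessibility band | [mode/2, 2·mode] | excludes collapsed repeats (high) and poorly covered sites (low) |

## 5. Numerical and reproducibility choices

- All stochastic entry points take explicit integer seeds; the pipeline
  derives per-stage seeds from one root seed with `numpy.random.SeedSequence`
  and records them (reduced mod 2³¹) in `manifest.json` with output hashes.
- Forward–backward uses per-site scaling; Viterbi works in log space. Both
  are validated against exhaustive path enumeration.
- Jackknife, FST, f-statistics and distances are validated against
  independent brute-force re-implementations in the test suite.
- Newick branch lengths are written with 6 significant digits.

## 6. Limitations

- Unlinked-sites simulation understates block-jackknife utility; on real
  data blocks matter because of LD, here they mainly partition noise.
- ROH quality is edge-limited (see §2); comparisons across cohorts should
  use the same site density.
- The brute-force mappability scorer is quadratic in genome length and
  intended for kb-scale validation sequences, not whole genomes.
- Population-specific outlier F<sub>ST</sub> designates the top tail by rank
  (ties included), which is a screening device, not a significance test.
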