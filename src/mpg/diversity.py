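"""Individual heterozygosity, panel nucleotide diversity, and an HMM-based
runs-of-homozygosity caller.

Heterozygosity per individual is het sites / accessible sites -- the
nucleotide difference per base pair between an individual's two autosomes.
Panel diversity is the unbiased per-site expected heterozygosity summed over
variant sites and divided by the accessible-site total.

ROH are called with a two-state HMM over a sample's variant sites: state HW
(outbred, Hardy--Weinberg emission of hets at rate ~2p(1-p)) versus AZ
(autozygous, hets only through error).  Transition probabilities scale with
the base-pair distance between consecutive sites as a two-state Markov jump
process.  The Viterbi path defines segments (first to last AZ site); segment
quality is a Phred-scaled complement of the mean forward--backward posterior
of AZ over the segment.  Segments below Phred 30 or shorter than 100 kb are
filtered out by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypePanel, PanelError


@dataclass
class ROHSegment:
    """A contiguous autozygous interval (1-based inclusive)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_sites: int
    quality: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise PanelError("ROH segment with end < start")


@dataclass
class ROHParams:
    """HMM parameters.

    ``hw_to_az`` / ``az_to_hw`` are per-base-pair transition rates;
    ``eps`` deflates the Hardy--Weinberg het emission, ``eps_het`` adds a
    genotyping-error floor to it, and ``eps_az`` is the het emission inside
    autozygous tracts.  ``max_quality`` caps the Phred-scaled segment
    confidence.
    """

    hw_to_az: float = 6.6e-9
    az_to_hw: float = 5.0e-9
    eps: float = 1e-3
    eps_het: float = 1e-3
    eps_az: float = 1e-3
    max_quality: float = 99.0


def individual_heterozygosity(
    panel: GenotypePanel, accessible_site_total: int
) -> dict[str, float]:
    """Per-sample heterozygosity: autosomal het calls / accessible sites."""
    if accessible_site_total <= 0:
        raise PanelError("accessible_site_total must be positive")
    auto = panel.chromosome_set_mask("autosomes")
    het = (panel.genotypes[auto] == 1).sum(axis=0)
    return {
        s: float(het[j]) / accessible_site_total
        for j, s in enumerate(panel.samples)
    }


def panel_pi(panel: GenotypePanel, accessible_site_total: int) -> float:
    """Nucleotide diversity: sum of unbiased per-site heterozygosity
    ``2 p (1-p) n/(n-1)`` over accessible sites (autosomes)."""
    if accessible_site_total <= 0:
        raise PanelError("accessible_site_total must be positive")
    if panel.n_samples < 2:
        raise PanelError("panel_pi requires >= 2 samples")
    auto = panel.chromosome_set_mask("autosomes")
    alt, tot = panel.allele_counts(variant_mask=auto)
    ok = tot >= 2
    p = alt[ok] / tot[ok]
    n = tot[ok]
    per_site = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(per_site.sum() / accessible_site_total)


def _hmm_inputs(
    het: np.ndarray, pos: np.ndarray, freqs: np.ndarray, params: ROHParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site emission matrix (n, 2 states) and transition matrices (n-1, 2, 2)."""
    p = freqs
    if np.any((p < 0) | (p > 1)):
        raise PanelError("allele frequency outside [0, 1]")
    p_het_hw = np.clip(2 * p * (1 - p) * (1 - params.eps) + params.eps_het, 1e-12, 1 - 1e-12)
    p_het_az = np.clip(np.full_like(p, params.eps_az), 1e-12, 1 - 1e-12)
    emit = np.empty((len(p), 2))
    emit[:, 0] = np.where(het, p_het_hw, 1 - p_het_hw)
    emit[:, 1] = np.where(het, p_het_az, 1 - p_het_az)

    a, b = params.hw_to_az, params.az_to_hw
    d = np.diff(pos).astype(float)
    if np.any(d < 0):
        raise PanelError("sites are not sorted by position")
    rate = a + b
    decay = np.exp(-rate * d)
    pi_az = a / rate
    trans = np.empty((len(d), 2, 2))
    trans[:, 0, 1] = pi_az * (1 - decay)
    trans[:, 0, 0] = 1 - trans[:, 0, 1]
    trans[:, 1, 0] = (1 - pi_az) * (1 - decay)
    trans[:, 1, 1] = 1 - trans[:, 1, 0]
    return emit, trans


def viterbi_path(
    het: np.ndarray, pos: np.ndarray, freqs: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Most probable HW(0)/AZ(1) state path for one chromosome of one sample."""
    emit, trans = _hmm_inputs(het, pos, freqs, params)
    n = len(het)
    a = params.hw_to_az / (params.hw_to_az + params.az_to_hw)
    log_start = np.log(np.array([1 - a, a]))
    score = log_start + np.log(emit[0])
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        lt = np.log(trans[t - 1])
        cand = score[:, None] + lt  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], [0, 1]] + np.log(emit[t])
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def posterior_az(
    het: np.ndarray, pos: np.ndarray, freqs: np.ndarray, params: ROHParams
) -> np.ndarray:
    """Forward--backward posterior probability of the AZ state per site."""
    emit, trans = _hmm_inputs(het, pos, freqs, params)
    n = len(het)
    a = params.hw_to_az / (params.hw_to_az + params.az_to_hw)
    start = np.array([1 - a, a])
    fwd = np.empty((n, 2))
    scale = np.empty(n)
    fwd[0] = start * emit[0]
    scale[0] = fwd[0].sum()
    fwd[0] /= scale[0]
    for t in range(1, n):
        fwd[t] = (fwd[t - 1] @ trans[t - 1]) * emit[t]
        scale[t] = fwd[t].sum()
        fwd[t] /= scale[t]
    bwd = np.empty((n, 2))
    bwd[-1] = 1.0
    for t in range(n - 2, -1, -1):
        bwd[t] = trans[t] @ (emit[t + 1] * bwd[t + 1])
        bwd[t] /= bwd[t].sum()
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 1]


def roh_call(
    panel: GenotypePanel,
    sample: str,
    allele_freqs: np.ndarray | None = None,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Call autozygous segments for one sample on autosomes.

    ``allele_freqs`` gives per-variant alternate-allele frequencies aligned
    with ``panel.variants`` (defaults to panel-wide frequencies).  Sites with
    a missing genotype in the sample are skipped.  Consecutive Viterbi-AZ
    sites merge into segments spanning first to last AZ site; quality is
    ``-10 log10(1 - mean posterior)`` capped at ``params.max_quality``.
    """
    params = params or ROHParams()
    if allele_freqs is None:
        allele_freqs = panel.alt_freq()
    j = panel.sample_index(sample)
    g = panel.genotypes[:, j]
    chroms = panel.chrom_array
    pos = panel.pos_array
    auto = panel.chromosome_set_mask("autosomes")
    segments: list[ROHSegment] = []
    for chrom in dict.fromkeys(chroms[auto]):
        use = np.flatnonzero((chroms == chrom) & (g >= 0) & ~np.isnan(allele_freqs))
        if len(use) == 0:
            continue
        het = (g[use] == 1).astype(bool)
        p = allele_freqs[use]
        cpos = pos[use]
        path = viterbi_path(het, cpos, p, params)
        post = posterior_az(het, cpos, p, params)
        i = 0
        while i < len(path):
            if path[i] == 1:
                k = i
                while k + 1 < len(path) and path[k + 1] == 1:
                    k += 1
                mean_post = float(post[i : k + 1].mean())
                qual = min(
                    -10.0 * np.log10(max(1.0 - mean_post, 1e-300)),
                    params.max_quality,
                )
                segments.append(
                    ROHSegment(
                        sample=sample,
                        chrom=chrom,
                        start=int(cpos[i]),
                        end=int(cpos[k]),
                        n_sites=k - i + 1,
                        quality=float(qual),
                    )
                )
                i = k + 1
            else:
                i += 1
    return segments


def roh_filter(
    segments: list[ROHSegment],
    min_quality: float = 30.0,
    min_length: int = 100_000,
) -> list[ROHSegment]:
    """Keep segments with quality >= 30 and length >= 100 kb (boundaries kept)."""
    return [
        s for s in segments if s.quality >= min_quality and s.length >= min_length
    ]
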