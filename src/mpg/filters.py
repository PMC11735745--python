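"""Site-level filters: k-mer mappability, coverage-mode accessibility,
and expression-style hard filters.

The three filters mirror a standard short-read variant-calling workflow:

* **Mappability** -- a position passes when the k-mer starting there is
  unique in the genome even allowing ``e`` mismatches (the "(30, 2)
  mappability score of 1" rule).  The score at a position is the reciprocal
  of the number of k-mers within Hamming distance ``e``; computed by brute
  force, intended for small synthetic genomes.
* **Accessibility** -- summed read depth across all individuals must fall
  within half to twice the mode of the depth distribution.
* **Hard filters** -- GATK-style threshold expressions over per-variant
  annotations (QD, QUAL, FS, ...), with separate rule sets for SNVs and
  indels.  A variant fails if any rule fires on a *present* annotation;
  absent annotations never remove a site.

All three commute: the retained set is independent of application order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GenotypePanel, PanelError

log = logging.getLogger(__name__)

#: SNV hard-filter rules of a standard GATK-style workflow.
DEFAULT_SNV_RULES = (
    ("QD", "<", 2.0),
    ("QUAL", "<", 30.0),
    ("SOR", ">", 3.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
    ("ExcessHet", ">", 30.0),
)

#: Indel hard-filter rules.
DEFAULT_INDEL_RULES = (
    ("QD", "<", 2.0),
    ("QUAL", "<", 30.0),
    ("FS", ">", 200.0),
    ("ReadPosRankSum", "<", -20.0),
    ("ExcessHet", ">", 30.0),
)

_COMPARATORS = {
    "<": lambda x, t: x < t,
    ">": lambda x, t: x > t,
    "<=": lambda x, t: x <= t,
    ">=": lambda x, t: x >= t,
}


@dataclass
class SiteMask:
    """Per-variant retention flags with per-filter removal counts."""

    retained: np.ndarray
    removed_by: dict[str, int] = field(default_factory=dict)
    accessible_site_total: int | None = None
    annotation_missing: int = 0

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def intersect(self, other: "SiteMask") -> "SiteMask":
        merged = dict(self.removed_by)
        for k, v in other.removed_by.items():
            merged[k] = merged.get(k, 0) + v
        return SiteMask(
            self.retained & other.retained,
            merged,
            self.accessible_site_total or other.accessible_site_total,
            self.annotation_missing + other.annotation_missing,
        )


def mappability_scores(sequence: str, k: int, e: int) -> np.ndarray:
    """Brute-force (k, e)-mappability score for every valid start position.

    The score at position i is ``1 / m`` where ``m`` counts the positions on
    the forward strand of ``sequence`` whose k-mer lies within Hamming
    distance ``e`` of the k-mer at i (the k-mer itself included, so scores
    lie in (0, 1] and equal 1 iff unique).  Callers wanting strand-aware
    behaviour may concatenate the reverse complement themselves.
    """
    if k < 1 or e < 0:
        raise PanelError("require k >= 1 and e >= 0")
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=float)
    kmers = np.lib.stride_tricks.sliding_window_view(seq, k)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        dists = (kmers != kmers[i]).sum(axis=1)
        scores[i] = 1.0 / int((dists <= e).sum())
    return scores


def mappability_mask(
    panel: GenotypePanel,
    sequences: dict[str, str],
    k: int = 30,
    e: int = 2,
) -> SiteMask:
    """Retain variants whose (k, e)-mappability score at the site is 1."""
    per_chrom = {c: mappability_scores(s, k, e) for c, s in sequences.items()}
    retained = np.ones(panel.n_variants, dtype=bool)
    removed = 0
    for i, v in enumerate(panel.variants):
        scores = per_chrom.get(v.chrom)
        j = v.pos - 1
        if scores is None or j >= len(scores) or scores[j] < 1.0:
            retained[i] = False
            removed += 1
    return SiteMask(retained, {"mappability": removed})


def accessibility_mask(
    depth_matrix: np.ndarray,
) -> tuple[int, float, float, np.ndarray]:
    """Coverage-mode accessibility band.

    Total depth per site is summed across samples; the mode of the summed
    distribution (ties broken toward the smaller depth) defines the
    inclusive accessible band ``[mode/2, 2*mode]``.

    Returns ``(mode, low_bound, high_bound, retained)``.
    """
    depth = np.asarray(depth_matrix)
    if depth.size == 0:
        raise PanelError("empty depth matrix")
    if np.any(depth < 0):
        raise PanelError("negative depths")
    total = depth.sum(axis=1)
    counts = np.bincount(total.astype(np.int64))
    mode = int(np.argmax(counts))  # argmax returns the first (smallest) tie
    if mode == 0:
        log.warning("depth mode is 0; accessibility band is degenerate")
    low, high = mode / 2.0, 2.0 * mode
    retained = (total >= low) & (total <= high)
    return mode, low, high, retained


def accessibility_site_mask(depth_matrix: np.ndarray) -> SiteMask:
    mode, low, high, retained = accessibility_mask(depth_matrix)
    mask = SiteMask(retained, {"accessibility": int((~retained).sum())})
    mask.accessible_site_total = int(retained.sum())
    return mask


Rule = tuple[str, str, float]


def hard_filter(
    panel: GenotypePanel,
    snv_rules: Sequence[Rule] = DEFAULT_SNV_RULES,
    indel_rules: Sequence[Rule] = DEFAULT_INDEL_RULES,
) -> SiteMask:
    """Apply threshold rules to per-variant annotations.

    A variant is removed if ANY rule of its class (SNV / indel) fires on an
    annotation present in its ``info``.  Absent annotations never fire; such
    variants are retained and counted in ``annotation_missing``.
    """
    for key, op, _ in list(snv_rules) + list(indel_rules):
        if op not in _COMPARATORS:
            raise PanelError(f"unknown comparator {op!r} in rule for {key}")
    retained = np.ones(panel.n_variants, dtype=bool)
    removed = 0
    n_missing = 0
    for i, v in enumerate(panel.variants):
        rules = snv_rules if v.is_snv else indel_rules
        any_missing = False
        for key, op, thr in rules:
            val = v.info.get(key)
            if val is None:
                any_missing = True
                continue
            if _COMPARATORS[op](val, thr):
                retained[i] = False
                break
        if retained[i] and any_missing:
            n_missing += 1
    removed = int((~retained).sum())
    if n_missing:
        log.info("%d variants retained with missing annotations", n_missing)
    return SiteMask(retained, {"hard_filter": removed}, annotation_missing=n_missing)
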