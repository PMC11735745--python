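"""Outgroup-polarized loss-of-function variant bookkeeping.

A variant is *species-specific derived* when every outgroup individual is
unambiguously homozygous for the reference (ancestral) allele -- no
heterozygotes and no missing calls among the outgroups.  The alternate
allele is then treated as derived in the focal species.  Loss-of-function
classes are frameshifts, premature stop codons, and splice acceptor/donor
disruptions.  Species-specific LoF variants partition into those *fixed*
in all focal samples (every sample hom-alt, no missingness) and those still
segregating; per-individual burdens count homozygous segregating LoF
variants (split SNV / indel) and the distinct genes carrying at least one
LoF allele (het or hom, fixed or segregating).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypePanel, PanelError

log = logging.getLogger(__name__)

#: Consequence classes counted as loss-of-function by default.
DEFAULT_LOF_CLASSES = frozenset(
    {"frameshift", "stop_gained", "splice_acceptor", "splice_donor"}
)

KNOWN_CLASSES = DEFAULT_LOF_CLASSES | {
    "missense",
    "synonymous",
    "intergenic",
    "splice_region",
}


@dataclass
class LofSummary:
    """Per-sample and panel-level LoF burden counts."""

    per_sample_hom_snv: dict[str, int]
    per_sample_hom_indel: dict[str, int]
    per_sample_gene_burden: dict[str, int]
    fixed_lof_snv: int
    fixed_lof_indel: int
    affected_genes: list[str]
    mean_hom_snv: float = field(init=False)
    mean_hom_indel: float = field(init=False)
    mean_gene_burden: float = field(init=False)

    def __post_init__(self) -> None:
        def mean(d: dict[str, int]) -> float:
            return float(np.mean(list(d.values()))) if d else 0.0

        self.mean_hom_snv = mean(self.per_sample_hom_snv)
        self.mean_hom_indel = mean(self.per_sample_hom_indel)
        self.mean_gene_burden = mean(self.per_sample_gene_burden)


def polarize_species_specific(
    panel: GenotypePanel, outgroup_samples: Sequence[str]
) -> np.ndarray:
    """Mask of sites where the alt allele is derived and focal-specific.

    True iff EVERY outgroup sample is homozygous reference with no
    missingness ("unambiguously") -- a haploid outgroup call of the
    reference allele also qualifies.
    """
    if not outgroup_samples:
        raise PanelError("outgroup sample list is empty")
    idx = np.array([panel.sample_index(s) for s in outgroup_samples], dtype=np.intp)
    g = panel.genotypes[:, idx]
    return np.all(g == 0, axis=1)


def classify_lof(
    consequences: pd.DataFrame,
    lof_classes: frozenset = DEFAULT_LOF_CLASSES,
) -> pd.DataFrame:
    """Rows of the consequence table whose class is loss-of-function.

    Unknown class labels are warned about and treated as non-LoF.  Every
    returned row carries a gene identifier.
    """
    unknown = set(consequences["consequence"]) - KNOWN_CLASSES - lof_classes
    if unknown:
        log.warning("unknown consequence classes treated as non-LoF: %s", sorted(unknown))
    out = consequences[consequences["consequence"].isin(lof_classes)]
    if out["gene_id"].isna().any():
        raise PanelError("LoF-classified variant without gene identifier")
    return out


def partition_fixed(
    panel: GenotypePanel,
    focal_samples: Sequence[str],
    variant_set: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Split variant indices into (fixed, segregating) among focal samples.

    Fixed: every focal sample hom-alt with no missingness (haploid code 2
    counts as hom-alt).
    """
    if not focal_samples:
        raise PanelError("focal sample list is empty")
    variant_set = np.asarray(variant_set)
    if variant_set.dtype == bool:
        variant_set = np.flatnonzero(variant_set)
    idx = np.array([panel.sample_index(s) for s in focal_samples], dtype=np.intp)
    g = panel.genotypes[np.ix_(variant_set, idx)]
    fixed_mask = np.all(g == 2, axis=1)
    return variant_set[fixed_mask], variant_set[~fixed_mask]


def lof_burden(
    panel: GenotypePanel,
    lof_table: pd.DataFrame,
    focal_samples: Sequence[str],
    species_specific: np.ndarray,
) -> LofSummary:
    """Per-individual burden of species-specific LoF variants.

    ``lof_table`` is the output of :func:`classify_lof` (variant_index and
    gene_id columns); only rows passing the ``species_specific`` mask count.
    Homozygous counts cover *segregating* variants split by SNV/indel; gene
    burden counts distinct genes with any LoF allele (het or hom), fixed
    variants included.
    """
    ss = np.asarray(species_specific, dtype=bool)
    rows = lof_table[lof_table["variant_index"].map(lambda i: bool(ss[i]))]
    vidx = rows["variant_index"].to_numpy()
    genes = rows["gene_id"].to_numpy()
    fixed, segregating = partition_fixed(panel, focal_samples, vidx)
    seg_set = set(segregating.tolist())
    is_snv = np.array([panel.variants[i].is_snv for i in vidx], dtype=bool)

    hom_snv: dict[str, int] = {}
    hom_indel: dict[str, int] = {}
    gene_burden: dict[str, int] = {}
    for s in focal_samples:
        j = panel.sample_index(s)
        g = panel.genotypes[vidx, j]
        seg_mask = np.array([i in seg_set for i in vidx], dtype=bool)
        hom = g == 2
        hom_snv[s] = int((hom & seg_mask & is_snv).sum())
        hom_indel[s] = int((hom & seg_mask & ~is_snv).sum())
        carrier = (g == 1) | (g == 2)
        gene_burden[s] = len(set(genes[carrier].tolist()))

    fixed_set = set(fixed.tolist())
    fixed_rows = np.array([i in fixed_set for i in vidx], dtype=bool)
    affected = sorted(set(genes.tolist()))
    return LofSummary(
        per_sample_hom_snv=hom_snv,
        per_sample_hom_indel=hom_indel,
        per_sample_gene_burden=gene_burden,
        fixed_lof_snv=int((fixed_rows & is_snv).sum()),
        fixed_lof_indel=int((fixed_rows & ~is_snv).sum()),
        affected_genes=affected,
    )
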