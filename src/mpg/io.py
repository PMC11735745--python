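"""VCF and BED input/output.

Reading goes through :mod:`cyvcf2` (plain or bgzipped VCF); writing emits a
minimal VCF 4.2 with a GT field per sample.  Genotypes are collapsed to the
0/1/2/-1 code convention of :class:`mpg.core.GenotypePanel`; phase is
discarded.  Multiallelic records are skipped and counted.  Haploid calls
(males on non-PAR X) are written as single-allele GT and restored as haploid
on reading.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .core import (
    MISSING,
    GenotypePanel,
    PanelError,
    VariantRecord,
    X_CHROMOSOMES,
)

log = logging.getLogger(__name__)

#: INFO keys round-tripped as numeric call annotations.
INFO_KEYS = (
    "QD",
    "FS",
    "MQ",
    "MQRankSum",
    "ReadPosRankSum",
    "SOR",
    "ExcessHet",
)


class VcfFormatError(ValueError):
    """Raised on structurally invalid VCF input."""


def read_vcf(
    path: str,
    sample_population_map: Mapping[str, str],
    ploidy_rules: Mapping[str, Sequence[str]] | None = None,
    x_chromosomes: frozenset = X_CHROMOSOMES,
) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Parameters
    ----------
    path
        Plain or bgzipped VCF with GT fields.
    sample_population_map
        Sample -> population label; every VCF sample must be present.
    ploidy_rules
        Mapping sample -> chromosome labels on which the sample is haploid
        (e.g. ``{"male1": ["chrX"]}``).  Single-allele GT calls additionally
        mark (sample, chromosome) pairs as haploid.

    Raises
    ------
    VcfFormatError
        If the VCF lacks GT data.
    PanelError
        If a VCF sample is absent from ``sample_population_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in sample_population_map]
    if missing:
        raise PanelError(f"samples absent from population map: {missing}")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    haploid: dict[str, set] = {}
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        info: dict = {}
        if v.QUAL is not None:
            info["QUAL"] = float(v.QUAL)
        for key in INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        variants.append(VariantRecord(v.CHROM, v.POS, v.REF, v.ALT[0], info))
        row = np.empty(len(samples), dtype=np.int8)
        gts = v.genotypes
        if gts is None:
            raise VcfFormatError(f"record {v.CHROM}:{v.POS} has no GT data")
        for j, g in enumerate(gts):
            alleles = g[:-1]  # last element is the phased flag
            alleles = [a for a in alleles if a >= -1]
            if len(alleles) == 1:
                a = alleles[0]
                row[j] = MISSING if a < 0 else 2 * a
                haploid.setdefault(samples[j], set()).add(v.CHROM)
            else:
                if any(a < 0 for a in alleles):
                    row[j] = MISSING
                else:
                    row[j] = sum(alleles)
        rows.append(row)
    if n_multi:
        log.info("skipped %d multiallelic records", n_multi)

    for sample, chroms in (ploidy_rules or {}).items():
        haploid.setdefault(sample, set()).update(chroms)

    geno = (
        np.vstack(rows)
        if rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypePanel(
        variants=variants,
        samples=samples,
        populations={s: sample_population_map[s] for s in samples},
        genotypes=geno,
        haploid_chroms={s: frozenset(c) for s, c in haploid.items()},
        x_chromosomes=x_chromosomes,
        n_multiallelic_skipped=n_multi,
    )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_CODE_HAP = {0: "0", 2: "1", MISSING: "."}


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write a panel as minimal VCF 4.2 (GT only; QUAL column preserved)."""
    chrom_order: dict[str, None] = {}
    for v in panel.variants:
        chrom_order.setdefault(v.chrom, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for key in INFO_KEYS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for i, var in enumerate(panel.variants):
            qual = var.info.get("QUAL")
            qual_s = "." if qual is None else f"{qual:g}"
            info_items = [
                f"{k}={var.info[k]:g}" for k in INFO_KEYS if k in var.info
            ]
            info_s = ";".join(info_items) if info_items else "."
            fields = [
                var.chrom,
                str(var.pos),
                ".",
                var.ref,
                var.alt,
                qual_s,
                ".",
                info_s,
                "GT",
            ]
            for j, s in enumerate(panel.samples):
                g = int(panel.genotypes[i, j])
                if panel.ploidy_of(s, var.chrom) == 1:
                    fields.append(_GT_CODE_HAP[g])
                else:
                    fields.append(_GT_CODE[g])
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read a BED file into 1-based inclusive (chrom, start, end) intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def write_bed(
    intervals: Sequence[tuple], path: str, extra_cols: Sequence[Sequence] | None = None
) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for k, (chrom, start, end, *rest) in enumerate(intervals):
            row = [chrom, str(start - 1), str(end)] + [str(x) for x in rest]
            if extra_cols is not None:
                row += [str(x) for x in extra_cols[k]]
            fh.write("\t".join(row) + "\n")
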