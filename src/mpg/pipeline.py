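"""End-to-end orchestration: simulate or load a panel, then chain the
analysis stages and write tidy tables plus a reproducibility manifest.

All randomness flows from one root seed, split per stage with
:class:`numpy.random.SeedSequence`; the per-stage seeds are recorded in the
manifest so a run is reproducible from its manifest alone.  Tables are
tab-separated with a comment header carrying the manifest hash.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import os
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import GenotypePanel, PanelError
from .distance import export, genotype_distance, neighbor_joining
from .diversity import individual_heterozygosity, panel_pi, roh_call, roh_filter
from .fst import pair_fst, population_specific_fst, q_statistic
from .fstats import f3_outgroup, f4
from .io import read_vcf, write_vcf
from .relatedness import KING_THIRD_DEGREE, kinship_matrix, ld_prune, prune_related
from .simulate import (
    DemographyConfig,
    PopNode,
    assign_consequences,
    simulate_panel,
)

STAGES = (
    "heterozygosity",
    "roh",
    "kinship",
    "ldprune",
    "fst",
    "q",
    "popfst",
    "fstats",
    "distance",
)


def _stage_seeds(root_seed: int, names: tuple[str, ...]) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for n, c in zip(names, children)
    }


def _tree_from_dict(d: dict) -> PopNode:
    return PopNode(
        name=d["name"],
        children=[_tree_from_dict(c) for c in d.get("children", [])],
        t=d.get("t", 0.0),
        N=d.get("N", 10_000.0),
        drift=d.get("drift"),
    )


def demography_from_config(cfg: dict) -> DemographyConfig:
    """Build a :class:`DemographyConfig` from a plain (YAML-ready) dict."""
    kw = {k: v for k, v in cfg.items() if k not in ("tree", "admixture")}
    from .simulate import AdmixtureEvent

    return DemographyConfig(
        tree=_tree_from_dict(cfg["tree"]),
        admixture=[AdmixtureEvent(**a) for a in cfg.get("admixture", [])],
        **kw,
    )


def _write_table(df: pd.DataFrame, path: str, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest={manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _file_hash(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def fst_table(
    panel: GenotypePanel,
    pops: list[str],
    block_size: int,
) -> pd.DataFrame:
    """Square pairwise-FST table: upper-right triangle autosomes,
    lower-left triangle X, entries "estimate (se)"."""
    has_x = bool(panel.is_x_variant().any())
    table = pd.DataFrame("...", index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        est = pair_fst(panel, a, b, "autosomes", block_size)
        table.loc[a, b] = f"{est.estimate:.3f} ({est.se:.3f})"
        if has_x:
            estx = pair_fst(panel, a, b, "X", block_size)
            table.loc[b, a] = f"{estx.estimate:.3f} ({estx.se:.3f})"
    return table.reset_index(names="population")


def run_pipeline(config: dict, out_dir: str) -> dict[str, Any]:
    """Run the configured stages; returns the manifest (also written as JSON).

    ``config`` keys: ``seed`` (root seed), ``panel`` (either ``{"vcf": path,
    "populations": {...}}`` or ``{"simulate": <demography dict>}``),
    ``stages`` (subset of the stage names; default all), plus optional
    stage parameters (``block_size``, ``accessible_site_total``,
    ``outgroup_population``, ``f4_quartets``, ``f3_triples``, ...).
    """
    os.makedirs(out_dir, exist_ok=True)
    root_seed = int(config.get("seed", 0))
    seeds = _stage_seeds(root_seed, ("simulate",) + STAGES)
    stages = list(config.get("stages", STAGES))
    block_size = int(config.get("block_size", 25_000))

    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config,
        "root_seed": root_seed,
        "stage_seeds": seeds,
        "counts": {},
        "outputs": {},
    }
    manifest_hash = hashlib.sha256(
        json.dumps({"config": config, "seed": root_seed}, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    panel_cfg = config["panel"]
    truth = None
    if "simulate" in panel_cfg:
        demog = demography_from_config(panel_cfg["simulate"])
        panel, truth = simulate_panel(demog, seeds["simulate"])
        write_vcf(panel, os.path.join(out_dir, "panel.vcf"))
    else:
        panel = read_vcf(
            panel_cfg["vcf"],
            panel_cfg["populations"],
            panel_cfg.get("ploidy_rules"),
        )
    manifest["counts"]["n_variants"] = panel.n_variants
    manifest["counts"]["n_samples"] = panel.n_samples

    outgroup_pop = config.get("outgroup_population")
    focal_samples = [
        s for s in panel.samples if panel.populations[s] != outgroup_pop
    ]
    focal_pops = [p for p in panel.population_labels() if p != outgroup_pop]
    accessible = int(
        config.get(
            "accessible_site_total",
            panel.chromosome_set_mask("autosomes").sum(),
        )
    )

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        _write_table(df, path, manifest_hash)
        manifest["outputs"][name] = _file_hash(path)

    if "kinship" in stages:
        kin = kinship_matrix(panel)
        retained = prune_related(panel, config.get("king_cutoff", KING_THIRD_DEGREE))
        kin_df = pd.DataFrame(kin.phi, index=panel.samples, columns=panel.samples)
        emit("kinship.tsv", kin_df.reset_index(names="sample"))
        emit("retained_samples.tsv", pd.DataFrame({"sample": retained}))
        manifest["counts"]["n_related_removed"] = panel.n_samples - len(retained)
        panel = panel.subset(sample_names=retained)
        focal_samples = [s for s in focal_samples if s in retained]

    if "ldprune" in stages:
        kept = ld_prune(panel, **config.get("ldprune", {}))
        manifest["counts"]["n_ld_pruned"] = panel.n_variants - len(kept)

    if "heterozygosity" in stages:
        het = individual_heterozygosity(panel, accessible)
        pi = panel_pi(panel, accessible)
        df = pd.DataFrame(
            {
                "sample": list(het),
                "population": [panel.populations[s] for s in het],
                "heterozygosity": list(het.values()),
            }
        )
        emit("heterozygosity.tsv", df)
        manifest["counts"]["panel_pi"] = pi

    if "roh" in stages:
        rows = []
        freqs = panel.alt_freq()
        for s in panel.samples:
            for seg in roh_filter(
                roh_call(panel, s, freqs),
                config.get("roh_min_quality", 30.0),
                config.get("roh_min_length", 100_000),
            ):
                rows.append(
                    (seg.sample, seg.chrom, seg.start, seg.end, seg.n_sites, seg.quality)
                )
        emit(
            "roh.tsv",
            pd.DataFrame(
                rows,
                columns=["sample", "chrom", "start", "end", "n_sites", "quality"],
            ),
        )

    if "fst" in stages:
        emit("fst_table.tsv", fst_table(panel, focal_pops, block_size))

    if "q" in stages:
        if not panel.is_x_variant().any():
            raise PanelError("Q statistic requested but panel has no X variants")
        rows = []
        for a, b in itertools.combinations(focal_pops, 2):
            fa = pair_fst(panel, a, b, "autosomes", block_size).estimate
            fx = pair_fst(panel, a, b, "X", block_size).estimate
            qr = q_statistic(fa, fx)
            rows.append((a, b, fa, fx, qr.q, qr.defined))
        emit(
            "q_table.tsv",
            pd.DataFrame(
                rows,
                columns=["pop_a", "pop_b", "fst_auto", "fst_x", "q", "defined"],
            ),
        )

    if "popfst" in stages:
        lof_genes: dict[int, str] = {}
        ss_mask = None
        csq = None
        if truth is not None and config.get("popfst_lof", True):
            genes = config.get(
                "gene_intervals",
                [("chr1", 1, 10**9, "gene1")],
            )
            csq, _ = assign_consequences(
                panel,
                [tuple(g) for g in genes],
                config.get("lof_fraction", 0.05),
                seeds["popfst"],
            )
        rows = []
        for popn in focal_pops:
            sub = panel.subset(
                sample_names=[
                    s for s in panel.samples if panel.populations[s] != outgroup_pop
                ]
            )
            values, designated = population_specific_fst(
                sub, popn, config.get("top_fraction", 0.01)
            )
            for i in np.flatnonzero(designated):
                v = sub.variants[i]
                csq_label = (
                    csq.loc[csq["variant_index"] == i, "consequence"].iloc[0]
                    if csq is not None
                    else ""
                )
                rows.append((popn, v.chrom, v.pos, values[i], csq_label))
        emit(
            "population_specific_fst.tsv",
            pd.DataFrame(
                rows, columns=["population", "chrom", "pos", "fst", "consequence"]
            ),
        )

    if "fstats" in stages:
        rows = []
        for quartet in config.get("f4_quartets", []):
            r = f4(panel, *quartet, block_size=block_size)
            rows.append(("f4", ",".join(quartet), r.estimate, r.se, r.z))
        for triple in config.get("f3_triples", []):
            r = f3_outgroup(panel, *triple, block_size=block_size)
            rows.append(("f3", ",".join(triple), r.estimate, r.se, r.z))
        emit(
            "fstats.tsv",
            pd.DataFrame(rows, columns=["kind", "populations", "estimate", "se", "z"]),
        )

    if "distance" in stages:
        dm = genotype_distance(panel)
        export(dm, os.path.join(out_dir, "dist.phy"), "phylip")
        export(dm, os.path.join(out_dir, "dist.nex"), "nexus")
        manifest["outputs"]["dist.phy"] = _file_hash(os.path.join(out_dir, "dist.phy"))
        manifest["outputs"]["dist.nex"] = _file_hash(os.path.join(out_dir, "dist.nex"))
        if panel.n_samples >= 3:
            tree = neighbor_joining(dm)
            export(tree, os.path.join(out_dir, "tree.nwk"), "newick")
            manifest["outputs"]["tree.nwk"] = _file_hash(
                os.path.join(out_dir, "tree.nwk")
            )

    manifest["manifest_hash"] = manifest_hash
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
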