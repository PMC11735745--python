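import numpy as np
import pytest

from mpg.core import GenotypePanel, VariantRecord


def make_panel(
    genotypes,
    chroms=None,
    positions=None,
    samples=None,
    populations=None,
    haploid_chroms=None,
    refs=None,
    alts=None,
    infos=None,
):
    """Small hand-built panel for unit tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samp = g.shape
    chroms = chroms or ["chr1"] * n_var
    positions = positions or list(range(1, n_var + 1))
    samples = samples or [f"s{j}" for j in range(n_samp)]
    populations = populations or {s: "P" for s in samples}
    refs = refs or ["A"] * n_var
    alts = alts or ["G"] * n_var
    infos = infos or [{} for _ in range(n_var)]
    variants = [
        VariantRecord(c, p, r, a, dict(i))
        for c, p, r, a, i in zip(chroms, positions, refs, alts, infos)
    ]
    return GenotypePanel(
        variants=variants,
        samples=list(samples),
        populations=dict(populations),
        genotypes=g,
        haploid_chroms={k: frozenset(v) for k, v in (haploid_chroms or {}).items()},
    )


@pytest.fixture
def toy_panel():
    return make_panel(
        [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 0, 0]],
        populations={"s0": "A", "s1": "A", "s2": "B"},
    )
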