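"""Genotype distances, neighbor-joining trees, and matrix/tree exports."""

import numpy as np
import pytest

from mpg.core import PanelError
from mpg.distance import (
    DistanceMatrix,
    export,
    genotype_distance,
    neighbor_joining,
    read_phylip,
    write_phylip,
)
from mpg.simulate import simulate_panel, two_population_config

from conftest import make_panel


class TestGenotypeDistance:
    @pytest.mark.parametrize(
        "gi,gj,expected",
        [
            (0, 0, 0.0),
            (2, 2, 0.0),
            (0, 2, 1.0),
            (2, 0, 1.0),
            (0, 1, 0.5),
            (1, 0, 0.5),
            (2, 1, 0.5),
            (1, 2, 0.5),
            (1, 1, 0.5),  # two heterozygotes share one allele on average
        ],
    )
    def test_per_site_values(self, gi, gj, expected):
        panel = make_panel([[gi, gj]])
        dm = genotype_distance(panel)
        assert dm.matrix[0, 1] == expected

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(121)
        g = rng.choice([-1, 0, 1, 2], size=(300, 5), p=[0.1, 0.35, 0.25, 0.3])
        panel = make_panel(g.astype(np.int8), positions=list(range(1, 301)))
        dm = genotype_distance(panel)
        lookup = {
            (0, 0): 0.0, (2, 2): 0.0, (0, 2): 1.0, (2, 0): 1.0,
            (0, 1): 0.5, (1, 0): 0.5, (1, 2): 0.5, (2, 1): 0.5, (1, 1): 0.5,
        }
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert dm.matrix[i, j] == 0.0
                    continue
                vals = [
                    lookup[(a, b)]
                    for a, b in zip(g[:, i], g[:, j])
                    if a >= 0 and b >= 0
                ]
                assert dm.matrix[i, j] == pytest.approx(np.mean(vals))
                assert dm.n_sites_used[i, j] == len(vals)

    def test_duplicate_sample_distance_zero(self):
        rng = np.random.default_rng(122)
        g = rng.integers(0, 3, size=(100, 1)).astype(np.int8)
        panel = make_panel(
            np.hstack([g, g, rng.integers(0, 3, size=(100, 1)).astype(np.int8)]),
            positions=list(range(1, 101)),
        )
        dm = genotype_distance(panel)
        # identical genotype vectors: only het sites contribute 0.5 each
        het_frac = (g[:, 0] == 1).mean()
        assert dm.matrix[0, 1] == pytest.approx(0.5 * het_frac)

    def test_polymorphic_only_rescales(self):
        g = np.zeros((10, 2), dtype=np.int8)
        g[0] = [0, 2]  # one polymorphic site, distance 1
        panel = make_panel(g, positions=list(range(1, 11)))
        assert genotype_distance(panel).matrix[0, 1] == pytest.approx(0.1)
        assert genotype_distance(panel, polymorphic_only=True).matrix[
            0, 1
        ] == pytest.approx(1.0)

    def test_no_shared_sites_undefined(self):
        panel = make_panel([[0, -1], [-1, 2]])
        dm = genotype_distance(panel)
        assert dm.undefined_pairs() == [("s0", "s1")]
        with pytest.raises(PanelError, match="undefined"):
            neighbor_joining(
                DistanceMatrix(
                    np.array([[0.0, np.nan], [np.nan, 0.0]]),
                    ["a", "b"],
                    np.zeros((2, 2), dtype=np.int64),
                )
            )


def _dm(matrix, labels):
    m = np.asarray(matrix, dtype=float)
    return DistanceMatrix(m, list(labels), np.zeros(m.shape, dtype=np.int64))


def _patristic(newick, labels):
    """Leaf-to-leaf path lengths from a newick string (via dendropy)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = [[0, 4, 6], [4, 0, 8], [6, 8, 0]]
        nwk = neighbor_joining(_dm(d, ["a", "b", "c"]))
        p = _patristic(nwk, ["a", "b", "c"])
        np.testing.assert_allclose(p, np.array(d, dtype=float), atol=1e-9)

    def test_additive_five_taxon_exact_recovery(self):
        # distances generated from a known tree are recovered exactly
        #      ((a:2,b:3):1,(c:4,d:1):2,e:6)
        branch = {
            "a": [2, 1], "b": [3, 1], "c": [4, 2], "d": [1, 2], "e": [6],
        }
        labels = list("abcde")
        d = np.zeros((5, 5))
        # path lengths on that tree, written out by hand
        paths = {
            ("a", "b"): 5, ("a", "c"): 9, ("a", "d"): 6, ("a", "e"): 9,
            ("b", "c"): 10, ("b", "d"): 7, ("b", "e"): 10,
            ("c", "d"): 5, ("c", "e"): 12, ("d", "e"): 9,
        }
        for (x, y), v in paths.items():
            i, j = labels.index(x), labels.index(y)
            d[i, j] = d[j, i] = v
        nwk = neighbor_joining(_dm(d, labels))
        p = _patristic(nwk, labels)
        np.testing.assert_allclose(p, d, atol=1e-9)

    def test_matches_skbio_on_random_additive_matrix(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(123)
        # random positive additive-ish matrix from random points
        pts = rng.random((6, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(6)]
        ours = _patristic(neighbor_joining(_dm(d, labels)), labels)
        ref_tree = skbio_nj(SkbioDM(d, ids=labels))
        ref = np.zeros((6, 6))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    ref[i, j] = ref_tree.find(a).distance(ref_tree.find(b))
        # identical topology and branch lengths up to the 6-significant-digit
        # branch-length formatting of the newick output
        np.testing.assert_allclose(ours, ref, atol=1e-5)

    def test_label_permutation_same_patristic(self):
        rng = np.random.default_rng(124)
        pts = rng.random((7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(7)]
        p1 = _patristic(neighbor_joining(_dm(d, labels)), labels)
        perm = rng.permutation(7)
        p2 = _patristic(
            neighbor_joining(_dm(d[np.ix_(perm, perm)], [labels[k] for k in perm])),
            labels,
        )
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_populations_cluster_together(self):
        import dendropy

        cfg = two_population_config(t=3000, n_individuals=5, n_sites_autosome=5_000)
        panel, _ = simulate_panel(cfg, 125)
        nwk = neighbor_joining(genotype_distance(panel, polymorphic_only=True))
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        tree.encode_bipartitions()
        taxa = tree.taxon_namespace
        a_set = frozenset(t for t in taxa if t.label.startswith("A"))
        # some bipartition splits exactly A vs B
        split = dendropy.Bipartition
        found = any(
            frozenset(bp.leafset_taxa(taxa)) in (a_set, frozenset(taxa) - a_set)
            for bp in tree.bipartition_encoding
        )
        assert found

    def test_too_few_taxa(self):
        with pytest.raises(PanelError):
            neighbor_joining(_dm([[0.0, 1.0], [1.0, 0.0]], ["a", "b"]))


class TestExport:
    def test_phylip_round_trip(self, tmp_path):
        rng = np.random.default_rng(126)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        dm = _dm(m, ["w", "x", "y", "z"])
        p = tmp_path / "d.phy"
        write_phylip(dm, str(p))
        back = read_phylip(str(p))
        assert back.samples == dm.samples
        np.testing.assert_allclose(back.matrix, dm.matrix, atol=1e-8)

    def test_nexus_has_header_and_taxa(self, tmp_path):
        dm = _dm([[0, 1], [1, 0]], ["x", "y"])
        p = tmp_path / "d.nex"
        export(dm, str(p), "nexus")
        text = p.read_text()
        assert text.startswith("#NEXUS")
        assert "'x'" in text and "ntax=2" in text

    def test_newick_export_parses(self, tmp_path):
        import dendropy

        nwk = neighbor_joining(_dm([[0, 4, 6], [4, 0, 8], [6, 8, 0]], ["a", "b", "c"]))
        p = tmp_path / "t.nwk"
        export(nwk, str(p), "newick")
        tree = dendropy.Tree.get(path=str(p), schema="newick")
        assert {t.label for t in tree.taxon_namespace} == {"a", "b", "c"}

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(PanelError, match="format"):
            export("(a,b);", str(tmp_path / "x"), "svg")

    def test_export_bit_stable(self, tmp_path):
        dm = _dm([[0, 0.123456789], [0.123456789, 0]], ["a", "b"])
        p1, p2 = tmp_path / "1.phy", tmp_path / "2.phy"
        export(dm, str(p1), "phylip")
        export(dm, str(p2), "phylip")
        assert p1.read_bytes() == p2.read_bytes()
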