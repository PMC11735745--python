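"""Generator correctness: drift model, Mendelian offspring, planted
autozygosity, consequence labels, and depth simulation."""

import numpy as np
import pytest

from mpg.core import PanelError
from mpg.lof import classify_lof
from mpg.relatedness import king_kinship
from mpg.simulate import (
    AdmixtureEvent,
    DemographyConfig,
    PopNode,
    assign_consequences,
    plant_roh,
    quartet_config,
    simulate_panel,
    simulate_depth,
    spawn_relatives,
    two_population_config,
)


class TestSimulatePanel:
    def test_zero_drift_gives_identical_frequencies(self):
        cfg = two_population_config(t=0, n_individuals=5, n_sites_autosome=500)
        panel, truth = simulate_panel(cfg, 0)
        np.testing.assert_allclose(
            truth.leaf_freqs["A"], truth.leaf_freqs["B"]
        )
        assert truth.expected_pair_fst("A", "B") == 0.0

    def test_single_population_panel_shape(self):
        cfg = DemographyConfig(
            tree=PopNode("root", [PopNode("A", t=0)]),
            n_individuals={"A": 1},
            n_sites_autosome=100,
        )
        panel, _ = simulate_panel(cfg, 1)
        panel.validate()
        assert panel.n_variants == 100
        assert panel.n_samples == 1
        assert all(len(v.ref) == 1 and len(v.alt) == 1 for v in panel.variants)

    def test_balding_nichols_mean_preserving(self):
        # across many sites the child frequency's mean equals the parent's
        cfg = two_population_config(
            drift=0.2, n_individuals=2, n_sites_autosome=20_000
        )
        panel, truth = simulate_panel(cfg, 11)
        rng = np.random.default_rng(11)
        # reconstruct the ancestral draw exactly as the generator does
        lo, hi = cfg.ancestral_trunc
        a, b = cfg.ancestral_beta
        p0 = lo + (hi - lo) * rng.beta(a, b, size=cfg.n_sites_autosome)
        for pop in ("A", "B"):
            diff = truth.leaf_freqs[pop] - p0
            se = diff.std() / np.sqrt(len(diff))
            assert abs(diff.mean()) < 3 * se

    def test_x_drift_exceeds_autosomal(self):
        cfg = two_population_config(
            t=2000, N=10_000, n_individuals=10,
            n_sites_autosome=5_000, n_sites_x=5_000, x_factor=0.75,
        )
        _, truth = simulate_panel(cfg, 3)
        assert truth.expected_pair_fst("A", "B", "X") > truth.expected_pair_fst(
            "A", "B", "autosomes"
        )

    def test_males_haploid_on_x(self):
        cfg = two_population_config(
            t=100, n_individuals=4, n_sites_autosome=50, n_sites_x=50
        )
        panel, _ = simulate_panel(cfg, 5)
        panel.validate()
        isx = panel.is_x_variant()
        assert isx.sum() == 50
        males = [s for s in panel.samples if panel.ploidy_of(s, "chrX") == 1]
        assert len(males) == 4  # half of the 8 individuals
        for s in males:
            j = panel.sample_index(s)
            assert not np.any(panel.genotypes[isx, j] == 1)

    def test_hudson_truth_matches_montecarlo_oracle(self):
        """Brute-force Monte Carlo over the generative model agrees with the
        stored expected FST for two populations with branch drift 0.1."""
        F = 0.1
        rng = np.random.default_rng(99)
        n_sites = 200_000
        lo, hi = 0.05, 0.95
        p0 = lo + (hi - lo) * rng.beta(0.2, 0.2, n_sites)
        scale = (1 - F) / F
        p1 = rng.beta(p0 * scale, (1 - p0) * scale)
        p2 = rng.beta(p0 * scale, (1 - p0) * scale)
        # population (not sample) frequencies: Hudson numerator without
        # finite-sample correction
        num = (p1 - p2) ** 2
        den = p1 * (1 - p2) + p2 * (1 - p1)
        mc_fst = num.sum() / den.sum()
        cfg = two_population_config(drift=F, n_individuals=2, n_sites_autosome=10)
        _, truth = simulate_panel(cfg, 0)
        assert truth.expected_pair_fst("A", "B") == pytest.approx(F, abs=1e-12)
        assert mc_fst == pytest.approx(F, abs=0.005)

    def test_admixture_pulls_frequencies(self):
        cfg = quartet_config(
            drift=0.1, n_individuals=2, n_sites_autosome=5_000,
            admixture=[AdmixtureEvent("A", "C", 0.5)],
        )
        _, truth = simulate_panel(cfg, 7)
        cfg0 = quartet_config(drift=0.1, n_individuals=2, n_sites_autosome=5_000)
        _, truth0 = simulate_panel(cfg0, 7)
        d_adm = np.abs(truth.leaf_freqs["C"] - truth.leaf_freqs["A"]).mean()
        d_null = np.abs(truth0.leaf_freqs["C"] - truth0.leaf_freqs["A"]).mean()
        assert d_adm < d_null

    def test_tag_pairs_duplicate_genotypes(self):
        cfg = two_population_config(
            t=100, n_individuals=3, n_sites_autosome=100, tag_pair_fraction=0.2
        )
        panel, _ = simulate_panel(cfg, 1)
        assert panel.n_variants == 120
        g = panel.genotypes
        pos = panel.pos_array
        dup = np.flatnonzero(np.diff(pos) == 1)
        assert len(dup) == 20
        for i in dup:
            assert np.array_equal(g[i], g[i + 1])


class TestSpawnRelatives:
    def test_forced_transmission(self):
        from conftest import make_panel

        panel = make_panel([[2, 2], [0, 2]], populations={"s0": "A", "s1": "A"})
        out, truth = spawn_relatives(panel, [("kid", "s0", "s1")], 0)
        j = out.sample_index("kid")
        assert out.genotypes[0, j] == 2  # both parents hom-alt
        assert out.genotypes[1, j] == 1  # hom-ref x hom-alt
        assert truth.pedigree == [("kid", "s0", "s1")]

    def test_missing_parent_rejected(self, toy_panel):
        with pytest.raises(PanelError, match="not in panel"):
            spawn_relatives(toy_panel, [("kid", "s0", "nope")], 0)

    def test_parent_offspring_king_kinship(self):
        cfg = two_population_config(t=2000, n_individuals=3, n_sites_autosome=15_000)
        panel, _ = simulate_panel(cfg, 21)
        out, _ = spawn_relatives(panel, [("kid", "A_00", "A_01")], 22)
        phi = king_kinship(out, "kid", "A_00")
        # brute-force resampling oracle of the KING expectation
        rng = np.random.default_rng(23)
        g1 = panel.genotypes[:, panel.sample_index("A_00")].astype(float)
        g2 = panel.genotypes[:, panel.sample_index("A_01")].astype(float)
        kid = rng.binomial(1, g1 / 2) + rng.binomial(1, g2 / 2)
        n_hh = ((kid == 1) & (g1 == 1)).sum()
        n_opp = (((kid == 0) & (g1 == 2)) | ((kid == 2) & (g1 == 0))).sum()
        phi_bf = (n_hh - 2 * n_opp) / ((kid == 1).sum() + (g1 == 1).sum())
        assert phi == pytest.approx(0.25, abs=0.03)
        assert phi == pytest.approx(phi_bf, abs=0.03)


class TestPlantRoh:
    def test_no_hets_inside_interval(self):
        cfg = two_population_config(t=100, n_individuals=5, n_sites_autosome=2_000)
        panel, truth = simulate_panel(cfg, 31)
        panel, truth = plant_roh(panel, "A_00", ("chr1", 1, 500_000), 32, truth)
        j = panel.sample_index("A_00")
        inside = panel.pos_array <= 500_000
        assert not np.any(panel.genotypes[inside, j] == 1)
        assert truth.planted_roh == [("A_00", "chr1", 1, 500_000)]

    def test_empty_interval_unchanged(self, toy_panel):
        out, _ = plant_roh(toy_panel, "s0", ("chr1", 10, 5), 0)
        assert np.array_equal(out.genotypes, toy_panel.genotypes)

    def test_overlap_rejected(self):
        cfg = two_population_config(t=100, n_individuals=3, n_sites_autosome=100)
        panel, truth = simulate_panel(cfg, 1)
        panel, truth = plant_roh(panel, "A_00", ("chr1", 1, 1000), 2, truth)
        with pytest.raises(PanelError, match="overlap"):
            plant_roh(panel, "A_00", ("chr1", 500, 2000), 3, truth)

    def test_outside_het_rate_matches_hwe(self):
        cfg = two_population_config(t=10, N=10_000, n_individuals=20, n_sites_autosome=20_000)
        panel, truth = simulate_panel(cfg, 41)
        panel, truth = plant_roh(panel, "A_00", ("chr1", 1, 1_000_000), 42, truth)
        j = panel.sample_index("A_00")
        outside = panel.pos_array > 1_000_000
        p = truth.leaf_freqs["A"][outside]
        expected = (2 * p * (1 - p)).mean()
        observed = (panel.genotypes[outside, j] == 1).mean()
        se = np.sqrt(expected * (1 - expected) / outside.sum())
        assert abs(observed - expected) < 4 * se


class TestConsequences:
    def test_lof_fraction_extremes(self):
        cfg = two_population_config(t=100, n_individuals=2, n_sites_autosome=200)
        panel, _ = simulate_panel(cfg, 1)
        genes = [("chr1", 1, 10**9, "g1")]
        tab_none, truth_none = assign_consequences(panel, genes, 0.0, 2)
        assert len(classify_lof(tab_none)) == 0
        assert truth_none.planted_lof == []
        tab_all, truth_all = assign_consequences(panel, genes, 1.0, 2)
        assert len(classify_lof(tab_all)) == panel.n_variants
        assert len(truth_all.planted_lof) == panel.n_variants

    def test_planted_truth_equals_classify_output(self):
        cfg = two_population_config(
            t=100, n_individuals=2, n_sites_autosome=500, indel_fraction=0.3
        )
        panel, _ = simulate_panel(cfg, 5)
        genes = [("chr1", 1, 200_000, "g1"), ("chr1", 300_000, 10**9, "g2")]
        table, truth = assign_consequences(panel, genes, 0.3, 6)
        lof = classify_lof(table)
        assert sorted(lof["variant_index"]) == sorted(i for i, _, _ in truth.planted_lof)
        # indels never get SNV-only LoF classes and vice versa
        for i, gene, csq in truth.planted_lof:
            if panel.variants[i].variant_class == "indel":
                assert csq == "frameshift"
            else:
                assert csq in ("stop_gained", "splice_acceptor", "splice_donor")

    def test_invalid_fraction(self, toy_panel):
        with pytest.raises(PanelError):
            assign_consequences(toy_panel, [], 1.5, 0)


class TestDepth:
    def test_poisson_limit_mean(self, toy_panel):
        d = simulate_depth(toy_panel, 30.0, np.inf, 0)
        se = np.sqrt(30.0 / d.size)
        assert abs(d.mean() - 30.0) < 3 * se

    def test_summed_mode_near_expectation(self):
        from conftest import make_panel

        panel = make_panel(np.zeros((5_000, 4), dtype=np.int8),
                           positions=list(range(1, 5_001)))
        d = simulate_depth(panel, 40.0, 50.0, 1)
        total = d.sum(axis=1)
        mode = np.bincount(total).argmax()
        assert abs(mode - 160) < 15

    def test_zero_sites(self):
        from conftest import make_panel

        panel = make_panel(np.empty((0, 2), dtype=np.int8))
        assert simulate_depth(panel, 30.0, 10.0, 0).shape == (0, 2)

    def test_odd_sites_create_tails(self, toy_panel):
        d = simulate_depth(toy_panel, 100.0, np.inf, 3, odd_site_fraction=0.5)
        assert d.shape == (4, 3)
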