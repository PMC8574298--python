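import itertools

import networkx as nx
import numpy as np
import pytest

from interbench.network_io import Interactome
from interbench.synthetic_data import SyntheticSpec, gen_network, plant_complex
from interbench.topology import (
    PowerLawFit,
    ba_reference,
    bootstrap_gof,
    centralities,
    classify_scale_freeness,
    compare_alternatives,
    fit_power_law,
    global_measures,
    hub_overlap_null,
    hubs,
    sample_discrete_powerlaw,
)

from conftest import make_net


class TestCentralities:
    def test_star_closed_forms(self, star4):
        df = centralities(star4)
        assert df.loc["c", "degree"] == 3
        assert df.loc["c", "betweenness"] == 3  # the three leaf pairs
        assert df.loc["c", "closeness"] == pytest.approx(1.0)
        assert df.loc["x", "closeness"] == pytest.approx(3 / 5)

    def test_triangle_symmetry_all_measures(self, triangle):
        df = centralities(triangle)
        for col in df.columns:
            assert df[col].nunique() == 1

    def test_path_middle_gene_leads_degree_and_closeness(self, path5):
        df = centralities(path5, measures=("degree", "closeness"))
        assert df["closeness"].idxmax() == "C"
        assert df.loc["C", "degree"] == df["degree"].max()

    def test_disconnected_errors(self):
        net = make_net("t", [("A", "B"), ("X", "Y")])
        with pytest.raises(ValueError, match="connected"):
            centralities(net)

    def test_measure_subset_and_order(self, triangle):
        df = centralities(triangle, measures=("closeness", "degree"))
        assert list(df.columns) == ["closeness", "degree"]

    def test_spectral_positive_and_star_center_dominates(self, star4):
        df = centralities(star4, measures=("spectral",))
        assert (df["spectral"] >= 0).all()
        assert df.loc["c", "spectral"] == df["spectral"].max()


class TestGlobalMeasures:
    def test_path3(self):
        net = make_net("p3", [("A", "B"), ("B", "C")])
        gm = global_measures(net)
        assert gm.diameter == 2
        assert gm.mean_distance == pytest.approx(4 / 3)
        assert gm.transitivity == 0.0

    def test_triangle(self, triangle):
        gm = global_measures(triangle)
        assert (gm.diameter, gm.mean_distance, gm.transitivity) == (1, 1.0, 1.0)

    def test_4clique(self):
        net = make_net("k4", list(itertools.combinations("ABCD", 2)))
        gm = global_measures(net)
        assert gm.diameter == 1
        assert gm.transitivity == 1.0

    def test_mean_distance_bounded_by_diameter(self, ba_small):
        gm = global_measures(ba_small)
        assert gm.mean_distance <= gm.diameter


class TestBAReference:
    def test_matches_gene_count_and_reproducible(self, ba_small):
        ref1 = ba_reference(ba_small, n_instances=3, seed=5)
        ref2 = ba_reference(ba_small, n_instances=3, seed=5)
        assert all(r.n_genes == ba_small.n_genes for r in ref1)
        assert ref1 == ref2

    def test_ba_less_clustered_than_planted_cliques(self):
        base = gen_network(SyntheticSpec(n_genes=300, n_edges=450, model="er", rng_seed=3))
        clumped = base.copy("clumped")
        for i in range(14):
            clumped, _ = plant_complex(clumped, 8, 1.0, rng_seed=100 + i,
                                       set_id=f"cl{i}")
        ba_trans = np.mean([g.transitivity for g in ba_reference(clumped, 3, seed=1)])
        assert global_measures(clumped).transitivity > ba_trans

    def test_bad_instance_count_errors(self, ba_small):
        with pytest.raises(ValueError):
            ba_reference(ba_small, 0, seed=0)


class TestHubs:
    def test_right_tail_definition(self, ba_small):
        hs = hubs(ba_small, percentile=2.0)
        # at least the nominal count, every non-hub strictly below the cut
        assert len(hs.genes) >= 0.02 * ba_small.n_genes
        non_hub_max = max(
            ba_small.degree(g) for g in ba_small.genes - set(hs.genes)
        )
        assert non_hub_max < hs.degree_threshold
        assert all(ba_small.degree(g) >= hs.degree_threshold for g in hs.genes)

    def test_all_equal_degrees_degenerate(self, triangle):
        hs = hubs(triangle, percentile=2.0)
        assert hs.genes == frozenset("ABC")

    def test_ties_at_cutoff_included(self):
        # two genes of degree 3, many of degree 1: ties straddling the cut survive
        net = make_net("t", [("h1", f"a{i}") for i in range(3)]
                       + [("h2", f"b{i}") for i in range(3)])
        hs = hubs(net, percentile=20.0)
        assert {"h1", "h2"} <= hs.genes
        assert all(net.degree(g) >= hs.degree_threshold for g in hs.genes)

    def test_invalid_percentile(self, triangle):
        with pytest.raises(ValueError):
            hubs(triangle, percentile=0)


class TestHubOverlapNull:
    def test_shared_universe_mean_matches_hypergeometric(self):
        uni = {f"G{i:04d}" for i in range(1000)}
        h1 = {f"G{i:04d}" for i in range(20)}
        h2 = {f"G{i:04d}" for i in range(10, 30)}
        null = hub_overlap_null([h1, h2], [uni, uni], n_perm=5000, seed=2)
        assert null.null_mean[1] == pytest.approx(20 * 20 / 1000, abs=0.07)

    def test_disjoint_universes_share_nothing(self):
        u1 = {f"A{i}" for i in range(50)}
        u2 = {f"B{i}" for i in range(50)}
        null = hub_overlap_null([set(list(u1)[:5]), set(list(u2)[:5])],
                                [u1, u2], n_perm=200, seed=0)
        assert null.null_counts[:, 1].max() == 0

    def test_seed_reproducibility(self):
        uni = {f"G{i}" for i in range(100)}
        h = [set(list(uni)[:10]), set(list(uni)[5:15])]
        a = hub_overlap_null(h, [uni, uni], n_perm=100, seed=9)
        b = hub_overlap_null(h, [uni, uni], n_perm=100, seed=9)
        assert np.array_equal(a.null_counts, b.null_counts)

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            hub_overlap_null([{"A"}], [{"A", "B"}])


class TestPowerLawFit:
    def test_known_exponent_recovery(self):
        rng = np.random.default_rng(0)
        degs = sample_discrete_powerlaw(2.5, 1, 10000, rng)
        fit = fit_power_law(degs)
        assert fit.alpha == pytest.approx(2.5, abs=0.1)

    def test_onset_cannot_precede_support_minimum(self):
        rng = np.random.default_rng(1)
        degs = sample_discrete_powerlaw(2.5, 1, 10000, rng)
        truncated = degs[degs >= 5]
        fit = fit_power_law(truncated)
        assert fit.k_min >= 5

    def test_constant_sequence_errors(self):
        with pytest.raises(ValueError):
            fit_power_law([4] * 100)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            fit_power_law([1, 2, 3])

    def test_fit_invariant_to_permutation(self):
        rng = np.random.default_rng(2)
        degs = sample_discrete_powerlaw(2.2, 2, 2000, rng)
        f1 = fit_power_law(degs)
        f2 = fit_power_law(rng.permutation(degs))
        assert f1 == f2

    def test_estimator_attributes(self):
        rng = np.random.default_rng(3)
        est = PowerLawFit().fit(sample_discrete_powerlaw(2.5, 1, 5000, rng))
        assert est.n_tail_ <= 5000
        assert est.ks_stat_ >= 0


class TestBootstrapGof:
    def test_calibrated_on_true_power_law(self):
        rng = np.random.default_rng(10)
        degs = sample_discrete_powerlaw(2.5, 1, 5000, rng)
        fit = fit_power_law(degs)
        p = bootstrap_gof(degs, fit, n_boot=100, seed=10)
        assert p >= 0.1  # typical seeded run; p is ~ uniform under the null

    def test_rejects_geometric_with_full_range_fit(self):
        rng = np.random.default_rng(11)
        degs = rng.geometric(0.05, 10000)
        fit = fit_power_law(degs, k_min=1)  # whole-range fit: blatantly wrong model
        p = bootstrap_gof(degs, fit, n_boot=50, seed=11, k_min=1)
        assert p < 0.1

    def test_zero_boot_errors(self):
        rng = np.random.default_rng(12)
        degs = sample_discrete_powerlaw(2.5, 1, 1000, rng)
        fit = fit_power_law(degs)
        with pytest.raises(ValueError):
            bootstrap_gof(degs, fit, n_boot=0)


class TestCompareAlternatives:
    def test_power_law_tail_beats_both(self):
        rng = np.random.default_rng(20)
        tail = sample_discrete_powerlaw(2.5, 1, 5000, rng)
        assert compare_alternatives(tail, 1) == (True, True)

    def test_geometric_tail_prefers_exponential(self):
        rng = np.random.default_rng(21)
        tail = rng.geometric(0.1, 5000)
        better_exp, _ = compare_alternatives(tail, 1)
        assert better_exp is False

    def test_tiny_tail_errors(self):
        with pytest.raises(ValueError):
            compare_alternatives([3, 4, 5, 6, 7], 3)


class TestClassification:
    @pytest.mark.parametrize(
        "p_ok,tail_ok,alpha_ok,beats_both",
        list(itertools.product([False, True], repeat=4)),
    )
    def test_truth_table(self, p_ok, tail_ok, alpha_ok, beats_both):
        """Exhaustive 16-cell check of the none/weak/medium/strong rule."""
        p = 0.5 if p_ok else 0.05
        n_tail = 300 if tail_ok else 150
        alpha = 2.5 if alpha_ok else 3.4
        level = classify_scale_freeness(p, n_tail, alpha, beats_both, beats_both)
        if not (p_ok and tail_ok):
            assert level == "none"
        elif alpha_ok and beats_both:
            assert level == "strong"
        elif alpha_ok or beats_both:
            assert level == "medium"
        else:
            assert level == "weak"

    def test_spec_cells(self):
        assert classify_scale_freeness(0.05, 300, 2.5, True, True) == "none"
        assert classify_scale_freeness(0.5, 300, 2.5, True, True) == "strong"
        assert classify_scale_freeness(0.5, 300, 3.4, True, True) == "medium"

    def test_gate_is_strict_below_point_one(self):
        assert classify_scale_freeness(0.1, 300, 3.5, False, False) == "weak"
        assert classify_scale_freeness(0.0999, 300, 2.5, True, True) == "none"

    def test_mixed_alternative_comparison_is_not_enough(self):
        # beating only one of the two alternatives does not satisfy medium (b)
        assert classify_scale_freeness(0.5, 300, 3.4, True, False) == "weak"


class TestCentralityRankAgreement:
    def test_degree_betweenness_closeness_positively_correlated_on_ba(self, ba_small):
        from scipy.stats import spearmanr

        df = centralities(ba_small, measures=("degree", "betweenness", "closeness"))
        for a, b in itertools.combinations(df.columns, 2):
            rho, _ = spearmanr(df[a], df[b])
            assert rho > 0
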