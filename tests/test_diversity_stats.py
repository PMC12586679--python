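"""Faith's PD, composite diversity, Mantel tests, correlations, regression."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from pbinkit.diversity_stats import (
    between_module_alpha_correlation,
    diversity_records,
    faith_pd,
    hostrange_prevalence,
    mantel,
    mantel_statistic,
    regress_richness,
    within_module_alpha_correlation,
    within_module_diversity,
)
from pbinkit.profiles import DistanceMatrix


@pytest.fixture
def four_tip_tree():
    # ((A:1,B:2):0.5,(C:1,D:3):0.25); total branch length 7.75
    return dendropy.Tree.get(
        data="((A:1,B:2):0.5,(C:1,D:3):0.25);", schema="newick"
    )


class TestFaithPd:
    def test_all_tips_gives_total_branch_length(self, four_tip_tree):
        assert faith_pd(four_tip_tree, ["A", "B", "C", "D"]) == pytest.approx(7.75)

    def test_single_tip_is_root_path(self, four_tip_tree):
        assert faith_pd(four_tip_tree, ["A"]) == pytest.approx(1.5)
        assert faith_pd(four_tip_tree, ["D"]) == pytest.approx(3.25)

    def test_subset_matches_edge_enumeration_oracle(self, four_tip_tree):
        # {A, C}: edges A(1), A-clade stem (0.5), C(1), C-clade stem (0.25)
        assert faith_pd(four_tip_tree, ["A", "C"]) == pytest.approx(2.75)
        # oracle: brute force over edges
        tree = four_tip_tree
        present = {"A", "C"}
        total = 0.0
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            below = {l.taxon.label for l in node.leaf_iter()}
            if below & present:
                total += node.edge.length
        assert faith_pd(tree, ["A", "C"]) == pytest.approx(total)

    def test_empty_set_is_zero(self, four_tip_tree):
        assert faith_pd(four_tip_tree, []) == 0.0

    def test_monotone_in_tip_additions(self, four_tip_tree):
        tips = ["A", "B", "C", "D"]
        prev = 0.0
        for i in range(1, 5):
            cur = faith_pd(four_tip_tree, tips[:i])
            assert cur >= prev
            prev = cur

    def test_unknown_tip_rejected(self, four_tip_tree):
        with pytest.raises(ValueError):
            faith_pd(four_tip_tree, ["Z"])

    def test_unit_branch_lengths_count_branches(self):
        tree = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")
        assert faith_pd(tree, ["A", "B", "C", "D"]) == pytest.approx(6.0)


class TestWithinModuleDiversity:
    def _inputs(self, four_tip_tree):
        presence_b = pd.DataFrame(
            [[1, 1, 0, 0]], index=["s1"], columns=["A", "B", "C", "D"]
        )
        presence_v = pd.DataFrame([[1, 1, 0]], index=["s1"], columns=["v1", "v2", "v3"])
        return presence_b, presence_v

    def test_composite_is_product(self, four_tip_tree):
        pb, pv = self._inputs(four_tip_tree)
        rec = within_module_diversity(
            "s1", 1, ["A", "B"], ["v1", "v2", "v3"], pb, pv,
            {("s1", "A"): 0.01, ("s1", "B"): 0.03}, four_tip_tree,
        )
        assert rec["mean_pi"] == pytest.approx(0.02)
        assert rec["composite"] == pytest.approx(rec["pd"] * 0.02)
        assert rec["viral_richness"] == 2

    def test_zero_pi_zeroes_composite(self, four_tip_tree):
        pb, pv = self._inputs(four_tip_tree)
        rec = within_module_diversity(
            "s1", 1, ["A", "B"], [], pb, pv,
            {("s1", "A"): 0.0, ("s1", "B"): 0.0}, four_tip_tree,
        )
        assert rec["composite"] == 0.0 and rec["pd"] > 0

    def test_missing_pi_excluded_and_flagged(self, four_tip_tree):
        pb, pv = self._inputs(four_tip_tree)
        rec = within_module_diversity(
            "s1", 1, ["A", "B"], [], pb, pv,
            {("s1", "A"): 0.04}, four_tip_tree,
        )
        assert rec["mean_pi"] == pytest.approx(0.04)
        assert rec["n_pi_missing"] == 1

    def test_absent_module_returns_none(self, four_tip_tree):
        pb, pv = self._inputs(four_tip_tree)
        assert (
            within_module_diversity("s1", 2, ["C", "D"], [], pb, pv, {}, four_tip_tree)
            is None
        )


def _dm(arr, labels, metric="m"):
    return DistanceMatrix(pd.DataFrame(arr, index=labels, columns=labels), metric)


class TestMantel:
    def _random_dm(self, rng, n, labels=None):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return _dm(a, labels or [f"s{i}" for i in range(n)])

    def test_identical_matrices_statistic_one(self):
        rng = np.random.default_rng(0)
        d = self._random_dm(rng, 8)
        res = mantel(d, d, n_permutations=199, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        d1 = self._random_dm(rng, 8)
        d2 = _dm(np.sqrt(d1.data.to_numpy()), d1.labels)
        assert mantel_statistic(d1, d2) == pytest.approx(1.0)

    def test_label_alignment_not_order(self):
        rng = np.random.default_rng(2)
        d1 = self._random_dm(rng, 6)
        perm = list(reversed(d1.labels))
        d2 = _dm(d1.data.loc[perm, perm].to_numpy(), perm)
        assert mantel_statistic(d1, d2) == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(3)
        d = self._random_dm(rng, 3)
        with pytest.raises(ValueError):
            mantel(d, d)

    def test_type_one_error_calibrated(self):
        # independent random matrices: rejection rate ~ alpha
        rng = np.random.default_rng(4)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            d1 = self._random_dm(rng, 12)
            d2 = self._random_dm(rng, 12)
            res = mantel(d1, d2, n_permutations=99, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestAlphaCorrelations:
    def _records(self, rng, n_modules=4, n_samples=20, noise=0.0):
        rows = []
        for m in range(1, n_modules + 1):
            for s in range(n_samples):
                comp = m + rng.normal(0, noise)
                rows.append(
                    {
                        "sample_id": f"s{s}",
                        "module_id": m,
                        "pd": 1.0,
                        "mean_pi": comp,
                        "composite": comp,
                        "viral_richness": 2 * m + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_proportional_planted_diversities_correlate(self):
        rng = np.random.default_rng(0)
        out = between_module_alpha_correlation(self._records(rng, noise=0.01))
        assert out["r"] == pytest.approx(1.0, abs=1e-3)

    def test_two_modules_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError):
            between_module_alpha_correlation(self._records(rng, n_modules=2))

    def test_within_module_monotone_gives_rho_one(self):
        recs = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "module_id": 1,
                "pd": 1.0,
                "mean_pi": np.arange(10.0),
                "composite": np.arange(10.0),
                "viral_richness": np.arange(10.0) ** 2,  # monotone transform
            }
        )
        out = within_module_alpha_correlation(recs, 1)
        assert out["rho"] == pytest.approx(1.0)

    def test_ties_use_midranks(self):
        richness = np.array([1, 1, 2, 2, 3, 3, 4, 5])
        comp = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        recs = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "module_id": 1,
                "pd": 1.0,
                "mean_pi": comp,
                "composite": comp,
                "viral_richness": richness,
            }
        )
        out = within_module_alpha_correlation(recs, 1)
        # naive midrank oracle: pearson correlation of midranks
        r1 = scipy.stats.rankdata(comp)
        r2 = scipy.stats.rankdata(richness)
        expect = np.corrcoef(r1, r2)[0, 1]
        assert out["rho"] == pytest.approx(expect)

    def test_zero_variance_rejected(self):
        recs = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "module_id": 1,
                "pd": 1.0,
                "mean_pi": 0.5,
                "composite": 0.5,
                "viral_richness": np.arange(6),
            }
        )
        with pytest.raises(ValueError):
            within_module_alpha_correlation(recs, 1)


class TestRegressRichness:
    def _records(self, pd_vals, pi_vals, richness):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(richness))],
                "module_id": 1,
                "pd": pd_vals,
                "mean_pi": pi_vals,
                "composite": np.asarray(pd_vals) * np.asarray(pi_vals),
                "viral_richness": richness,
            }
        )

    def test_noise_free_slopes_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pdv = rng.uniform(1, 5, 30)
        piv = rng.uniform(0.001, 0.05, 30)
        rich = 2 + 5.0 * piv + 0.0 * pdv
        res = regress_richness(self._records(pdv, piv, rich))
        assert res.slope("mean_pi") == pytest.approx(5.0, abs=1e-6)
        assert res.slope("pd") == pytest.approx(0.0, abs=1e-6)
        assert res.slope("intercept") == pytest.approx(2.0, abs=1e-6)

    def test_matches_ols_without_outliers(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        pdv = rng.uniform(1, 5, 49)
        piv = rng.uniform(0.001, 0.05, 49)
        # no-outlier limit: Huber downweighting vanishes with the noise scale
        rich = 1 + 3 * pdv + 40 * piv + rng.normal(0, 1e-8, 49)
        res = regress_richness(self._records(pdv, piv, rich))
        X = sm.add_constant(np.column_stack([pdv, piv]))
        ols = sm.OLS(rich, X).fit()
        assert np.allclose(res.table["slope"].to_numpy(), ols.params, atol=1e-6)

    def test_slope_recovery_with_gaussian_noise(self):
        rng = np.random.default_rng(2)
        slopes = []
        for _ in range(20):
            pdv = rng.uniform(1, 5, 49)
            piv = rng.uniform(0.01, 0.05, 49)
            rich = 1 + 2 * pdv + 100 * piv + rng.normal(0, 1, 49)
            res = regress_richness(self._records(pdv, piv, rich))
            slopes.append(res.slope("mean_pi"))
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 100) < 4 * se

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(3)
        piv = rng.uniform(0.01, 0.05, 20)
        with pytest.raises(ValueError):
            regress_richness(self._records(np.ones(20), piv, piv * 2))

    def test_wald_z_is_slope_over_se(self):
        rng = np.random.default_rng(4)
        pdv = rng.uniform(1, 5, 30)
        piv = rng.uniform(0.01, 0.05, 30)
        rich = 1 + 2 * pdv + 50 * piv + rng.normal(0, 0.5, 30)
        res = regress_richness(self._records(pdv, piv, rich))
        t = res.table
        assert np.allclose(t["z"], t["slope"] / t["se"])


class TestHostrangePrevalence:
    def test_nested_generator_susceptibility_gives_positive_rho(self, demo_run):
        hr = demo_run["stats"]["hostrange"]
        assert (hr["rho"].dropna() > 0).all()

    def test_identical_host_ranges_undefined(self):
        from pbinkit.pbin import BipartiteNetwork

        net = BipartiteNetwork(
            ["b1", "b2"], ["v1", "v2", "v3"], np.ones((2, 3), dtype=int)
        )
        presence = pd.DataFrame(
            [[1, 0, 1], [1, 1, 0]], index=["s1", "s2"], columns=["v1", "v2", "v3"]
        )
        out = hostrange_prevalence(
            net, presence, {"v1": 1, "v2": 1, "v3": 1}, {"b1": 1, "b2": 1}
        )
        assert np.isnan(out.loc[0, "rho"])

    def test_small_module_skipped(self):
        from pbinkit.pbin import BipartiteNetwork

        net = BipartiteNetwork(["b1"], ["v1", "v2"], np.array([[1, 1]]))
        presence = pd.DataFrame([[1, 1]], index=["s1"], columns=["v1", "v2"])
        out = hostrange_prevalence(net, presence, {"v1": 1, "v2": 1}, {"b1": 1})
        assert out.empty
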