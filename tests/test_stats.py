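"""Spearman machinery, FDR, cluster permutation FWE, partial and dependent tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tractofluency.cohort import generate_scalar_profiles
from tractofluency.stats import (
    StatsConfig,
    along_tract_correlation,
    cluster_permutation_fwe,
    dependent_corr_z,
    mean_tract_correlations,
    partial_spearman,
    spearman_rho,
)


class TestSpearmanRho:
    def test_monotone_increasing_is_one(self):
        out = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert out["rho"] == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        out = spearman_rho([1, 2, 3], [5, 0, -5])
        assert out["rho"] == pytest.approx(-1.0)

    def test_five_point_example_is_point_eight(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1,0), sum d^2 = 4
        out = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert out["rho"] == pytest.approx(0.8)

    def test_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        base = spearman_rho(x, y)
        warped = spearman_rho(np.exp(x), y**3)
        assert warped["rho"] == pytest.approx(base["rho"])
        assert warped["p"] == pytest.approx(base["p"])

    def test_reversing_one_input_flips_sign(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = spearman_rho(x, y)["rho"]
        b = spearman_rho(x, -y)["rho"]
        assert b == pytest.approx(-a)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_one_sided_halves_the_aligned_p(self, rng):
        x = np.arange(20.0)
        y = x + rng.normal(0, 5, 20)
        two = spearman_rho(x, y, tail="two_sided")
        one = spearman_rho(x, y, tail="one_sided")
        assert one["p"] == pytest.approx(two["p"] / 2)


class TestMeanTractCorrelations:
    def _table(self, n=20, n_tracts=3, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"S{i:03d}" for i in range(n)]
        means = pd.DataFrame(
            rng.normal(size=(n, n_tracts)), index=ids,
            columns=[f"T{j}" for j in range(n_tracts)],
        )
        behavior = pd.Series(rng.normal(size=n), index=ids)
        return means, behavior

    def test_single_tract_bh_reduces_to_raw_threshold(self):
        rng = np.random.default_rng(3)
        ids = [f"S{i:03d}" for i in range(30)]
        x = rng.normal(size=30)
        means = pd.DataFrame({"T0": x}, index=ids)
        behavior = pd.Series(x + rng.normal(0, 0.5, 30), index=ids)
        out = mean_tract_correlations(means, behavior, fdr_q=0.05)
        assert out.loc[0, "p"] < 0.01
        assert bool(out.loc[0, "fdr_reject"])

    def test_bh_step_up_matches_enumeration_oracle(self):
        # oracle: largest k with p_(k) <= k*q/m; reject the k smallest
        pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.09, 0.2, 0.6, 0.9])
        q, m = 0.05, len(pvals)
        order = np.argsort(pvals)
        k = max((i + 1 for i in range(m) if pvals[order][i] <= (i + 1) * q / m), default=0)
        expected = np.zeros(m, dtype=bool)
        expected[order[:k]] = True
        assert expected.sum() == 2

        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        np.testing.assert_array_equal(reject, expected)

    def test_null_tracts_rarely_rejected(self):
        means, behavior = self._table(n=45, n_tracts=8, seed=5)
        out = mean_tract_correlations(means, behavior)
        assert len(out) == 8
        assert out["fdr_reject"].sum() == 0

    def test_subject_mismatch_rejected_listing_ids(self):
        means, behavior = self._table()
        behavior = behavior.rename(index={"S000": "S999"})
        with pytest.raises(ValueError, match="S999"):
            mean_tract_correlations(means, behavior)

    def test_alignment_by_subject_id_not_order(self):
        means, behavior = self._table(seed=7)
        shuffled = behavior.sample(frac=1.0, random_state=0)
        a = mean_tract_correlations(means, behavior)
        b = mean_tract_correlations(means, shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestAlongTractCorrelation:
    def test_node_equal_to_behavior_has_rho_one(self, rng):
        prof = rng.normal(size=(30, 10))
        beh = rng.normal(size=30)
        prof[:, 4] = beh
        rho, p = along_tract_correlation(prof, beh)
        assert rho[4] == pytest.approx(1.0)
        assert p[4] < 1e-10

    def test_matches_scipy_node_by_node(self, rng):
        prof = rng.normal(size=(25, 8))
        beh = rng.normal(size=25)
        rho, p = along_tract_correlation(prof, beh)
        for k in range(8):
            ref = sps.spearmanr(prof[:, k], beh)
            assert rho[k] == pytest.approx(ref.statistic, abs=1e-12)
            assert p[k] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_consistent_row_permutation_leaves_output_unchanged(self, rng):
        prof = rng.normal(size=(20, 6))
        beh = rng.normal(size=20)
        perm = rng.permutation(20)
        rho0, p0 = along_tract_correlation(prof, beh)
        rho1, p1 = along_tract_correlation(prof[perm], beh[perm])
        np.testing.assert_allclose(rho1, rho0, atol=1e-12)
        np.testing.assert_allclose(p1, p0, atol=1e-12)

    def test_constant_node_degenerate_not_fatal(self, rng):
        prof = rng.normal(size=(15, 5))
        prof[:, 2] = 3.3
        with pytest.warns(UserWarning, match="constant node"):
            rho, p = along_tract_correlation(prof, rng.normal(size=15))
        assert rho[2] == 0.0 and p[2] == 1.0

    def test_null_rejection_rate_near_alpha(self, rng):
        hits = total = 0
        for _ in range(150):
            prof = rng.normal(size=(45, 30))
            beh = rng.normal(size=45)
            _, p = along_tract_correlation(prof, beh)
            hits += (p < 0.05).sum()
            total += 30
        assert 0.03 < hits / total < 0.07


class TestClusterPermutationFwe:
    def test_no_suprathreshold_nodes_means_no_clusters(self):
        # every node carries the same interleaved column, nearly uncorrelated
        # with the behavior, so all observed node p-values sit above alpha
        col = np.array([1.0, 10, 2, 9, 3, 8, 4, 7, 5, 6])
        beh = np.arange(10.0)
        prof = np.tile(col[:, None], (1, 12))
        result = cluster_permutation_fwe(prof, beh, StatsConfig(n_permutations=200, seed=1))
        assert (result.node_p >= 0.05).all()
        assert result.clusters == []

    def test_deterministic_given_seed(self, rng):
        prof = rng.normal(size=(30, 20))
        beh = rng.normal(size=30)
        cfg = StatsConfig(n_permutations=300, seed=11)
        a = cluster_permutation_fwe(prof, beh, cfg)
        b = cluster_permutation_fwe(prof, beh, cfg)
        assert a.critical_cluster_size == b.critical_cluster_size
        assert a.clusters == b.clusters
        np.testing.assert_array_equal(a.node_p, b.node_p)

    def test_embedded_cluster_detected(self):
        from tractofluency.cohort import embed_effect

        rng = np.random.default_rng(2)
        prof = generate_scalar_profiles(45, np.full(30, 0.45), 0.03, 0.04, seed=3)
        beh = rng.normal(size=45)
        prof = embed_effect(prof, beh, (17, 22), 0.75)
        result = cluster_permutation_fwe(prof, beh, StatsConfig(n_permutations=500, seed=4),
                                         tract="MCP_R", metric="MD")
        overlapping = [c for c in result.clusters if c[0] <= 22 and c[1] >= 17]
        assert overlapping, "strong embedded effect should produce a cluster in its window"
        assert overlapping[0][2] > 0.5

    def test_clusters_are_maximal_suprathreshold_runs(self, rng):
        prof = rng.normal(size=(40, 30))
        beh = rng.normal(size=40)
        result = cluster_permutation_fwe(prof, beh, StatsConfig(n_permutations=200, seed=5))
        sig = result.node_p < 0.05
        for start, end, _ in result.clusters:
            assert sig[start - 1 : end].all()
            if start > 1:
                assert not sig[start - 2]
            if end < 30:
                assert not sig[end]
            assert (end - start + 1) > result.critical_cluster_size

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            cluster_permutation_fwe(rng.normal(size=(10, 5)), np.ones(10))


class TestPartialSpearman:
    def test_identical_variables_have_partial_rho_one(self, rng):
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        out = partial_spearman(x, x.copy(), z)
        assert out["rho"] == pytest.approx(1.0)

    def test_controlling_for_the_cause_kills_the_correlation(self, rng):
        n = 2000
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        out = partial_spearman(x, z + rng.normal(0, 0.05, n), z)
        assert abs(out["rho"]) < 3 / np.sqrt(n) * 2

    def test_hand_built_sextet_matches_rank_formula(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 6.0])
        z = np.array([1.0, 4.0, 1.5, 9.0, 2.0, 6.5])
        rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
        r_xy = np.corrcoef(rx, ry)[0, 1]
        r_xz = np.corrcoef(rx, rz)[0, 1]
        r_yz = np.corrcoef(ry, rz)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        out = partial_spearman(x, y, z)
        assert out["rho"] == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=45)
        y = 0.5 * x + rng.normal(size=45)
        z = 0.3 * x + rng.normal(size=45)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        out = partial_spearman(x, y, z)
        assert out["rho"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert out["p"] == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_degenerate_conditioning_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="degenerate"):
            partial_spearman(x, np.array([2.0, 1.0, 5.0, 3.0, 4.0]), x * 2)


class TestDependentCorrZ:
    def test_equal_correlations_give_zero_z(self):
        out = dependent_corr_z(0.4, 0.4, 0.3, 45, tail="two_sided")
        assert out["Z"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_antisymmetric_in_the_compared_correlations(self):
        a = dependent_corr_z(0.46, 0.15, 0.60, 45)
        b = dependent_corr_z(0.15, 0.46, 0.60, 45)
        assert b["Z"] == pytest.approx(-a["Z"])

    def test_one_sided_p_for_z_2396(self):
        # Phi(-2.396) ~ 0.0083 — below the 0.009 level this statistic pairs with
        p = float(sps.norm.sf(2.396))
        assert p == pytest.approx(0.00829, abs=2e-4)
        assert p < 0.009

    def test_fixed_inputs_match_direct_formula_evaluation(self):
        r_xy, r_xz, r_yz, n = 0.46, 0.15, 0.60, 45
        rbar2 = (r_xy**2 + r_xz**2) / 2
        f = min(1.0, (1 - r_yz) / (2 * (1 - rbar2)))
        h = (1 - f * rbar2) / (1 - rbar2)
        expected = (np.arctanh(r_xy) - np.arctanh(r_xz)) * np.sqrt(
            (n - 3) / (2 * (1 - r_yz) * h)
        )
        out = dependent_corr_z(r_xy, r_xz, r_yz, n)
        assert out["Z"] == pytest.approx(expected, abs=1e-12)
        assert out["p"] == pytest.approx(float(sps.norm.sf(expected)), rel=1e-9)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            dependent_corr_z(0.3, 0.2, 0.1, 3)

    def test_boundary_correlations_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            dependent_corr_z(1.0, 0.2, 0.1, 20)


class TestStatsConfig:
    @pytest.mark.parametrize("kwargs", [
        {"node_alpha": 0.0},
        {"fwe_alpha": 1.0},
        {"n_permutations": 50},
        {"tail": "lefty"},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StatsConfig(**kwargs)
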