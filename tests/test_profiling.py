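"""Equidistant resampling, bundle core, node profiles, FA/MD formulas."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tractofluency.bundles import Bundle
from tractofluency.cohort import generate_bundle
from tractofluency.profiling import (
    TractProfile,
    compute_core,
    fa_md_from_eigenvalues,
    resample_streamline,
    tract_profile,
)


class TestResampleStreamline:
    def test_straight_segment_gives_integer_nodes(self):
        sl = np.array([(0.0, 0.0, 0.0), (0.0, 0.0, 29.0)])
        out = resample_streamline(sl, 30)
        np.testing.assert_allclose(out[:, 2], np.arange(30), atol=1e-12)
        np.testing.assert_allclose(out[:, :2], 0.0, atol=1e-12)

    def test_right_angle_midpoint_at_corner(self):
        sl = np.array([(0.0, 0.0, 0.0), (10.0, 0.0, 0.0), (10.0, 10.0, 0.0)])
        out = resample_streamline(sl, 3)
        np.testing.assert_allclose(out[1], (10.0, 0.0, 0.0), atol=1e-12)

    def test_endpoints_preserved_exactly(self):
        sl = np.array([(1.0, 2.0, 3.0), (4.0, 6.0, 3.0), (0.0, 9.0, 1.0)])
        out = resample_streamline(sl, 7)
        np.testing.assert_array_equal(out[0], sl[0])
        np.testing.assert_array_equal(out[-1], sl[-1])

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50)
            ),
            min_size=2,
            max_size=12,
            unique=True,
        ),
        st.integers(2, 40),
    )
    def test_internode_distances_equal(self, points, n_nodes):
        sl = np.asarray(points, dtype=float)
        if np.linalg.norm(np.diff(sl, axis=0), axis=1).sum() < 1e-6:
            return
        out = resample_streamline(sl, n_nodes)
        # arc-length spacing between consecutive nodes measured along the
        # original polyline is uniform; chord distances are only equal when
        # the polyline is straight, so check cumulative arc positions instead
        seg = np.linalg.norm(np.diff(sl, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        arc_positions = []
        for p in out:
            d = np.linalg.norm(sl - p, axis=1)
            # locate p on the polyline by projecting onto each segment
            best = None
            for i in range(len(sl) - 1):
                v = sl[i + 1] - sl[i]
                L = np.linalg.norm(v)
                if L == 0:
                    continue
                t = np.clip(np.dot(p - sl[i], v) / L**2, 0.0, 1.0)
                proj = sl[i] + t * v
                dist = np.linalg.norm(p - proj)
                if best is None or dist < best[0]:
                    best = (dist, cum[i] + t * L)
            arc_positions.append(best[1])
        spacing = np.diff(arc_positions)
        assert np.allclose(spacing, spacing[0], rtol=1e-6, atol=1e-6)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="single-point"):
            resample_streamline(np.array([(0.0, 0.0, 0.0)]), 5)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="zero arc length"):
            resample_streamline(np.zeros((3, 3)), 5)


class TestComputeCore:
    def test_mirror_streamlines_have_axis_core(self):
        a = np.column_stack([np.full(10, 3.0), np.zeros(10), np.arange(10.0)])
        b = a.copy()
        b[:, 0] *= -1
        core, cov = compute_core([a, b])
        np.testing.assert_allclose(core[:, 0], 0.0, atol=1e-12)
        assert cov.shape == (10, 3, 3)

    def test_single_streamline_core_is_itself_with_zero_spread(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        core, cov = compute_core([a])
        np.testing.assert_array_equal(core, a)
        np.testing.assert_array_equal(cov, 0.0)

    def test_jittered_copies_recover_centerline(self):
        center = np.array([(0.0, 0.0, 0.0), (0.0, 0.0, 100.0)])
        bundle = generate_bundle(center, 100, jitter_sd=1.0, seed=9, n_points=30)
        core, _ = compute_core(list(bundle.streamlines))
        se = 1.0 / np.sqrt(100)
        assert np.abs(core[:, :2]).max() < 3 * se * 2  # smooth offsets correlate nodes

    def test_inconsistent_node_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            compute_core([np.zeros((5, 3)), np.zeros((6, 3))])


def straight_bundle(values, n_points=30, spread=1.0):
    """Parallel straight streamlines at graded x offsets carrying given scalars."""
    sls, fa = [], []
    for i, v in enumerate(values):
        x = spread * (i - (len(values) - 1) / 2)
        z = np.linspace(0.0, 29.0, n_points)
        sls.append(np.column_stack([np.full(n_points, x), np.zeros(n_points), z]))
        fa.append(np.full(n_points, v))
    return Bundle(sls, name="toy", scalars={"FA": fa})


class TestTractProfile:
    def test_constant_scalar_bundle_profiles_flat(self):
        profile = tract_profile(straight_bundle([0.5, 0.5, 0.5]), "FA", n_nodes=30,
                                weighting="uniform")
        np.testing.assert_allclose(profile.node_values, 0.5, atol=1e-12)
        assert profile.tract_mean == pytest.approx(0.5)

    def test_uniform_weighting_averages_streamlines(self):
        profile = tract_profile(straight_bundle([0.4, 0.6]), "FA", weighting="uniform")
        np.testing.assert_allclose(profile.node_values, 0.5, atol=1e-12)

    def test_gaussian_weighting_discounts_far_outlier(self):
        # 10 streamlines define a tight core (value 0.5); one sits far away
        # (value 0.9) and is down-weighted to irrelevance
        rng = np.random.default_rng(0)
        values = [0.5] * 10 + [0.9]
        bundle = straight_bundle(values, spread=0.0)
        for i, sl in enumerate(bundle.streamlines[:10]):
            sl[:, 0] = rng.normal(0, 0.3, size=len(sl))
        bundle.streamlines[10][:, 0] = 30.0
        profile = tract_profile(bundle, "FA", weighting="gaussian_distance")
        assert np.abs(profile.node_values - 0.5).max() < 1e-3

    def test_gaussian_weights_match_direct_formula(self):
        rng = np.random.default_rng(1)
        offsets = rng.normal(0, 1.0, size=6)
        values = rng.uniform(0.3, 0.7, size=6)
        bundle = straight_bundle(values, spread=0.0)
        for sl, dx in zip(bundle.streamlines, offsets):
            sl[:, 0] = dx
        profile = tract_profile(bundle, "FA", weighting="gaussian_distance")
        # independent evaluation: 1-D offsets -> Mahalanobis reduces to
        # |dx - mean| / sd at every node (ridge-regularized covariance)
        mean, var = offsets.mean(), offsets.var(ddof=1)
        ridge = max(1e-6, 1e-6 * var / 3)
        d2 = (offsets - mean) ** 2 / (var + ridge)
        w = np.exp(-0.5 * d2)
        expected = (w * values).sum() / w.sum()
        np.testing.assert_allclose(profile.node_values, expected, atol=1e-9)

    def test_reversing_streamlines_reverses_profile(self):
        rng = np.random.default_rng(2)
        bundle = straight_bundle(rng.uniform(0.3, 0.7, 5))
        ramp = np.linspace(0.2, 0.8, 30)
        bundle.scalars["FA"] = [ramp + 0.01 * i for i in range(5)]
        fwd = tract_profile(bundle, "FA", weighting="uniform")
        rev = Bundle(
            [s[::-1] for s in bundle.streamlines],
            scalars={"FA": [v[::-1] for v in bundle.scalars["FA"]]},
        )
        bwd = tract_profile(rev, "FA", weighting="uniform")
        np.testing.assert_allclose(bwd.node_values, fwd.node_values[::-1], atol=1e-12)

    def test_callable_sampler_used_at_node_coordinates(self):
        bundle = straight_bundle([0.0, 0.0])
        profile = tract_profile(bundle, lambda pts: pts[:, 2] / 29.0, n_nodes=30,
                                weighting="uniform", metric="ramp")
        np.testing.assert_allclose(profile.node_values, np.linspace(0, 1, 30), atol=1e-9)

    def test_empty_bundle_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tract_profile(Bundle([]), "FA")

    def test_non_finite_sampler_values_rejected_naming_nodes(self):
        bundle = straight_bundle([0.5])

        def bad(pts):
            v = np.ones(len(pts))
            v[3] = np.nan
            return v

        with pytest.raises(ValueError, match="nodes \\[4\\]"):
            tract_profile(bundle, bad, n_nodes=30)

    def test_profile_recovers_planted_node_curve_as_jitter_vanishes(self):
        curve = 0.4 + 0.1 * np.sin(np.pi * np.linspace(0, 1, 30))
        center = np.array([(0.0, 0.0, 0.0), (0.0, 0.0, 100.0)])
        errors = []
        for jitter in (2.0, 0.1):
            bundle = generate_bundle(center, 30, jitter_sd=jitter, seed=3, n_points=30)
            rng = np.random.default_rng(4)
            bundle.scalars["FA"] = [
                curve + rng.normal(0, 0.2 * jitter, 30) for _ in range(30)
            ]
            prof = tract_profile(bundle, "FA", weighting="uniform")
            errors.append(np.sqrt(np.mean((prof.node_values - curve) ** 2)))
        assert errors[1] < errors[0]
        assert errors[1] < 0.01


class TestFaMdFromEigenvalues:
    @pytest.mark.parametrize(
        "eigs, fa, md",
        [
            ((1.0, 1.0, 1.0), 0.0, 1.0),
            ((1.0, 0.0, 0.0), 1.0, 1.0 / 3.0),
            ((1.7e-3, 0.3e-3, 0.2e-3), 0.8359, 7.333e-4),
        ],
    )
    def test_worked_examples(self, eigs, fa, md):
        out = fa_md_from_eigenvalues(*eigs)
        assert out["FA"] == pytest.approx(fa, abs=5e-4)
        assert out["MD"] == pytest.approx(md, rel=1e-3)

    def test_zero_tensor_is_isotropic_by_convention(self):
        out = fa_md_from_eigenvalues(0.0, 0.0, 0.0)
        assert out == {"FA": 0.0, "MD": 0.0}

    @given(
        st.tuples(st.floats(1e-6, 5e-3), st.floats(1e-6, 5e-3), st.floats(1e-6, 5e-3)),
        st.floats(0.1, 10.0),
    )
    def test_fa_scale_invariant_md_linear(self, eigs, c):
        base = fa_md_from_eigenvalues(*eigs)
        scaled = fa_md_from_eigenvalues(*(c * e for e in eigs))
        assert scaled["FA"] == pytest.approx(base["FA"], rel=1e-9, abs=1e-12)
        assert scaled["MD"] == pytest.approx(c * base["MD"], rel=1e-9)
        assert 0.0 <= base["FA"] <= 1.0

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fa_md_from_eigenvalues(1.0, -0.1, 0.0)


class TestTractProfileContainer:
    def test_tract_mean_is_node_mean_and_frame_is_one_based(self):
        prof = TractProfile("S001", "FAT_L", "FA", np.linspace(0.3, 0.6, 30))
        assert prof.tract_mean == pytest.approx(np.linspace(0.3, 0.6, 30).mean())
        frame = prof.to_frame()
        assert frame.node.min() == 1 and frame.node.max() == 30
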