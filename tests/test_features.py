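"""Movement-feature formulas: tilt angles, deviations, rates, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionfis import features
from motionfis.features import (
    DegenerateVectorError,
    diff_rate,
    extract_features,
    gradient,
    relative_vector,
    tilt_angle,
    tilt_between,
    to_set1,
    to_set2,
    window_std,
)
from motionfis.imu_signals import calibrate, window_means
from motionfis.synthetic import ActivityScript, MotionProfile, simulate_session

vec3 = st.lists(
    st.floats(-5, 5, allow_nan=False, allow_infinity=False), min_size=3, max_size=3
).map(np.array)
nonzero3 = vec3.filter(lambda v: np.linalg.norm(v) > 1e-3)


class TestElementaryFeatures:
    @pytest.mark.parametrize(
        "v,v0,expected",
        [
            ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), (0.0, 0.0, 0.0)),
            ((1.0, 0.0, 0.0), (0.0, 0.0, 1.0), (1.0, 0.0, -1.0)),
        ],
    )
    def test_relative_vector(self, v, v0, expected):
        np.testing.assert_allclose(relative_vector(np.array(v), np.array(v0)), expected)

    @pytest.mark.parametrize(
        "gi,g0,deg",
        [
            ((1, 0, 0), (1, 0, 0), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((1, 1, 0), (1, 0, 0), 45.0),
            ((-1, 0, 0), (1, 0, 0), 180.0),
        ],
    )
    def test_tilt_angle_closed_forms(self, gi, g0, deg):
        assert tilt_angle(np.array(gi, float), np.array(g0, float)) == pytest.approx(deg)

    def test_tilt_between_matches_tilt_angle(self):
        assert tilt_between(np.array([1.0, 0, 0]), np.array([1.0, 1, 0])) == pytest.approx(45.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateVectorError):
            tilt_angle(np.zeros(3), np.array([1.0, 0, 0]))

    @settings(deadline=None)
    @given(nonzero3, nonzero3)
    def test_tilt_symmetric_and_scale_invariant(self, a, b):
        t1 = tilt_angle(a, b)
        assert t1 == pytest.approx(tilt_angle(b, a), abs=1e-9)
        # arccos is ill-conditioned near 0/180 deg, hence the loose tolerance
        assert t1 == pytest.approx(tilt_angle(3.7 * a, b), abs=1e-3)
        assert 0.0 <= t1 <= 180.0

    @pytest.mark.parametrize(
        "vals,expected", [([5.0] * 8, 0.0), ([0.0, 2.0], 1.0)]
    )
    def test_window_std_closed_forms(self, vals, expected):
        assert window_std(vals) == pytest.approx(expected)

    def test_window_std_equals_population_formula_on_gaussian_sample(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 0.1, 50)
        mu = sum(x) / len(x)
        brute = (sum((xi - mu) ** 2 for xi in x) / len(x)) ** 0.5
        assert window_std(x) == pytest.approx(brute, rel=1e-12)

    @settings(deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40))
    def test_window_std_property_vs_brute_force(self, vals):
        mu = sum(vals) / len(vals)
        brute = (sum((v - mu) ** 2 for v in vals) / len(vals)) ** 0.5
        assert window_std(vals) == pytest.approx(brute, abs=1e-9)

    def test_window_std_empty_rejected(self):
        with pytest.raises(ValueError):
            window_std([])

    @pytest.mark.parametrize(
        "Vi,V0,expected",
        [((1.0, 2, 3), (1.0, 2, 3), 0.0), ((2.0, 4, 6), (1.0, 2, 3), 1.0)],
    )
    def test_diff_rate_closed_forms(self, Vi, V0, expected):
        assert diff_rate(np.array(Vi), np.array(V0)) == pytest.approx(expected)

    def test_diff_rate_zero_baseline_rejected(self):
        with pytest.raises(DegenerateVectorError):
            diff_rate(np.ones(3), np.zeros(3))

    @settings(deadline=None)
    @given(vec3, nonzero3, st.floats(0.1, 3.1))
    def test_diff_rate_rotation_invariant(self, vi, v0, angle):
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        assert diff_rate(R @ vi, R @ v0) == pytest.approx(diff_rate(vi, v0), rel=1e-6, abs=1e-9)

    @pytest.mark.parametrize(
        "xi,xprev,dt,expected", [(1.0, 1.0, 1.0, 0.0), (1.2, 1.0, 1.0, 0.2)]
    )
    def test_gradient_arithmetic(self, xi, xprev, dt, expected):
        assert gradient(xi, xprev, dt) == pytest.approx(expected)

    def test_gradient_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            gradient(1.0, 0.0, 0.0)


class TestFrameExtraction:
    @pytest.fixture
    def stand_frames(self):
        sess = simulate_session(
            ActivityScript((("stand", 5.0),)),
            {"stand": MotionProfile(0.0, 0.0, 1e-12, 1e-12, 1e-12)},
            seed=0,
        )
        cc = calibrate(sess.chest, 2)
        ct = calibrate(sess.thigh, 2)
        return extract_features(
            window_means(sess.chest), window_means(sess.thigh), cc, ct
        )

    def test_stand_only_session_all_features_quiet(self, stand_frames):
        for f in stand_frames:
            assert f.theta_A == pytest.approx(0.0, abs=1e-5)
            assert f.theta_B == pytest.approx(0.0, abs=1e-5)
            np.testing.assert_allclose(f.sigma_gA, 0.0, atol=1e-9)
            if f.has_gradients:
                np.testing.assert_allclose(f.gamma_gA, 0.0, atol=1e-9)

    def test_first_frame_gradients_missing(self, stand_frames):
        assert not stand_frames[0].has_gradients
        assert all(f.has_gradients for f in stand_frames[1:])

    def test_static_gravity_magnitude_is_one_g(self, stand_frames):
        # static windows: |mean acceleration| should be the 1 g gravity vector
        for f in stand_frames:
            assert np.linalg.norm(f.gAR + np.array([1.0, 0.0, 0.0])) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_rotated_thigh_reads_ninety_degrees(self):
        prof = {
            "stand": MotionProfile(0.0, 0.0, 1e-12, 1e-12, 1e-12),
            "sit": MotionProfile(0.0, 90.0, 1e-12, 1e-12, 1e-12),
        }
        sess = simulate_session(
            ActivityScript((("stand", 3.0), ("sit", 5.0)), gap_s=1.0), prof, seed=0
        )
        cc = calibrate(sess.chest, 2)
        ct = calibrate(sess.thigh, 2)
        frames = extract_features(
            window_means(sess.chest), window_means(sess.thigh), cc, ct
        )
        labels = sess.window_labels()
        sit_thetas = [f.theta_B for f, l in zip(frames, labels) if l == "sit"]
        assert sit_thetas
        np.testing.assert_allclose(sit_thetas, 90.0, atol=0.01)

    def test_mismatched_window_counts_rejected(self, stand_frames):
        sess = simulate_session(ActivityScript((("stand", 5.0),)), seed=1)
        cc = calibrate(sess.chest, 2)
        with pytest.raises(ValueError, match="differ"):
            extract_features(
                window_means(sess.chest), window_means(sess.thigh)[:-1], cc, cc
            )


class TestSetProjections:
    def _frame(self, **over):
        base = dict(
            window_index=1, t_mid=1.5, theta_A=4.76, theta_B=86.0, theta_AB=81.0,
            gAR=np.array([0.01, 0, 0]), gBR=np.array([0.02, 0, 0]),
            omegaAR=np.array([1.0, 0, 0]), omegaBR=np.array([2.0, 0, 0]),
            sigma_gA=np.array([0.0114, 0.01, 0.01]), sigma_gB=np.array([0.02, 0.01, 0.01]),
            sigma_wA=np.array([1.0, 1, 1]), sigma_wB=np.array([2.0, 1, 1]),
            nu_gAR=0.001, nu_gBR=0.002,
            gamma_gA=np.array([0.001, 0, 0]), gamma_gB=np.array([-0.000588, 0, 0]),
            gamma_wA=np.array([-5.11, 0, 0]), gamma_wB=np.array([1.0, 0, 0]),
        )
        base.update(over)
        return features.FeatureFrame(**base)

    def test_set2_projection_reproduces_published_vector(self):
        # dynamic features are taken as absolute values
        v = to_set2(self._frame())
        np.testing.assert_allclose(v, [4.76, 86.0, 5.11, 0.000588, 0.0114])

    def test_set1_projection_picks_the_right_components(self):
        v = to_set1(self._frame())
        np.testing.assert_allclose(v, [4.76, 86.0, 2.0, 0.02, 0.02])

    def test_set2_without_gradients_raises_and_matrix_skips(self):
        f0 = self._frame(window_index=0, gamma_gA=np.full(3, np.nan),
                         gamma_gB=np.full(3, np.nan), gamma_wA=np.full(3, np.nan),
                         gamma_wB=np.full(3, np.nan))
        with pytest.raises(ValueError, match="gradients"):
            to_set2(f0)
        X, kept = features.feature_matrix([f0, self._frame()], 2)
        assert X.shape == (1, 5)
        assert kept == [1]

    def test_dataframe_export_has_one_row_per_window(self):
        df = features.frames_to_dataframe([self._frame(), self._frame(window_index=2)])
        assert len(df) == 2
        assert "sigma_gAx" in df.columns and "gamma_wAx" in df.columns
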