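"""Sugeno system: grid init, forward pass, hybrid training, index bands."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motionfis import anfis, diagnostics
from motionfis.anfis import (
    GaussianMF,
    SugenoModel,
    TrainingConfig,
    classify_index,
    evaluate,
    forward,
    forward_batch,
    hybrid_train,
    init_grid,
    label_training_data,
    rule_weights,
)
from motionfis.synthetic import make_training_set


def enumeration_forward(model, x):
    """Explicit 27-term oracle: loop every MF combination."""
    num = den = 0.0
    r = 0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                w = (
                    model.mfs[0][i](x[0])
                    * model.mfs[1][j](x[1])
                    * model.mfs[2][k](x[2])
                )
                num += w * model.consequents[r]
                den += w
                r += 1
    return num / den


def random_model(seed):
    rng = np.random.default_rng(seed)
    mfs = [
        [GaussianMF(rng.uniform(0.2, 0.6), mu) for mu in (0.0, 1.0, 2.0)]
        for _ in range(3)
    ]
    return SugenoModel(mfs=mfs, consequents=rng.uniform(1.0, 4.0, 27))


class TestInitialization:
    def test_walk_band_constants_spaced_by_one_thirteenth(self):
        m = init_grid()
        walk = m.consequents[:13]
        np.testing.assert_allclose(np.diff(walk), 1.0 / 13.0)
        assert round(float(np.diff(walk)[0]), 4) == 0.0769
        assert walk[-1] == pytest.approx(2.0)

    def test_twenty_seven_consequents_last_at_uncertain_center(self):
        m = init_grid()
        assert m.consequents.shape == (27,)
        assert m.consequents[-1] == 2.5
        run = m.consequents[13:26]
        np.testing.assert_allclose(np.diff(run), 1.0 / 13.0)
        assert run[-1] == pytest.approx(4.0)

    def test_gaussians_centered_on_the_canonical_grid(self):
        m = init_grid()
        for row in m.mfs:
            assert [mf.mu for mf in row] == [0.0, 1.0, 2.0]
            assert all(mf.sigma == pytest.approx(0.3397) for mf in row)
            assert all(mf(mf.mu) == pytest.approx(1.0) for mf in row)

    def test_custom_range_scales_centers_and_width(self):
        m = init_grid([(0.0, 2.0), (0.0, 4.0), (1.0, 3.0)])
        assert [mf.mu for mf in m.mfs[1]] == [0.0, 2.0, 4.0]
        assert m.mfs[1][0].sigma == pytest.approx(2 * 0.3397)
        assert [mf.mu for mf in m.mfs[2]] == [1.0, 2.0, 3.0]

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            init_grid([(0.0, 0.0), (0.0, 2.0), (0.0, 2.0)])


class TestForward:
    def test_constant_consequents_give_constant_output(self):
        m = init_grid()
        m.consequents = np.full(27, 1.7)
        for x in ([0.1, 0.5, 1.9], [1.0, 1.0, 1.0]):
            assert forward(m, x) == pytest.approx(1.7)

    def test_grid_point_dominated_by_its_rule(self):
        m = random_model(0)
        for row in m.mfs:  # sharpen to make rule (0,0,0) dominant
            for mf in row:
                mf.sigma = 0.05
        assert forward(m, [0.0, 0.0, 0.0]) == pytest.approx(m.consequents[0], abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_explicit_enumeration_oracle(self, seed):
        m = random_model(seed)
        rng = np.random.default_rng(100 + seed)
        for x in rng.uniform(0.0, 2.0, (5, 3)):
            assert forward(m, x) == pytest.approx(enumeration_forward(m, x), rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 2), min_size=3, max_size=3))
    def test_output_is_convex_combination_of_consequents(self, x):
        m = random_model(9)
        y = forward(m, np.array(x))
        assert m.consequents.min() - 1e-9 <= y <= m.consequents.max() + 1e-9

    def test_normalized_strengths_sum_to_one(self):
        m = random_model(4)
        X = np.random.default_rng(5).uniform(0, 2, (20, 3))
        W = rule_weights(m, X)
        np.testing.assert_allclose(W.sum(axis=1) / W.sum(axis=1), 1.0, atol=1e-12)
        Wn = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(Wn.sum(axis=1), 1.0, atol=1e-12)

    def test_vanishing_weights_raise(self):
        m = random_model(6)
        for row in m.mfs:
            for mf in row:
                mf.sigma = 1e-3
        with pytest.raises(FloatingPointError):
            forward(m, [0.5, 0.5, 0.5])


class TestTraining:
    def test_ls_only_epoch_equals_normal_equations_oracle(self):
        X, _, y = make_training_set(200, seed=8)
        m = init_grid()
        trace = hybrid_train(m, X, y, TrainingConfig(epochs=1, step_size=0.0))
        W = rule_weights(m, X)
        Wn = W / W.sum(axis=1, keepdims=True)
        c_ls, *_ = np.linalg.lstsq(Wn, y, rcond=None)
        cond = np.linalg.cond(Wn)
        if cond <= 1e8:
            np.testing.assert_allclose(trace.model.consequents, c_ls, atol=1e-8)
        pred = Wn @ trace.model.consequents
        assert trace.rmse[0] == pytest.approx(float(np.sqrt(np.mean((pred - y) ** 2))))

    def test_ls_step_never_increases_rmse_at_fixed_antecedents(self):
        X, _, y = make_training_set(150, seed=9)
        m = init_grid()
        W = rule_weights(m, X)
        Wn = W / W.sum(axis=1, keepdims=True)
        rmse_before = float(np.sqrt(np.mean((Wn @ m.consequents - y) ** 2)))
        trace = hybrid_train(m, X, y, TrainingConfig(epochs=1, step_size=0.0))
        assert trace.rmse[0] <= rmse_before + 1e-12

    def test_recovers_forward_behavior_of_a_known_model(self):
        rng = np.random.default_rng(5)
        true = init_grid()
        true.consequents = rng.uniform(1.0, 4.0, 27)
        X = rng.uniform(0.0, 2.0, (200, 3))
        y = forward_batch(true, X) + rng.normal(0.0, 0.05, 200)
        trace = hybrid_train(init_grid(), X, y, TrainingConfig(epochs=40))
        assert trace.rmse[-1] <= 0.1
        grid = np.array(list(itertools.product(np.linspace(0, 2, 5), repeat=3)))
        err = np.abs(forward_batch(trace.model, grid) - forward_batch(true, grid))
        assert err.max() <= 0.15

    def test_forty_epoch_walk_run_training_reduces_rmse(self):
        X, _, y = make_training_set(187, seed=1)
        trace = hybrid_train(init_grid(), X, y, TrainingConfig(epochs=40, seed=1))
        assert len(trace.rmse) == 40
        assert trace.rmse[-1] < trace.rmse[0]

    def test_training_does_not_mutate_input_model(self):
        X, _, y = make_training_set(60, seed=3)
        m = init_grid()
        before = anfis.to_json(m)
        hybrid_train(m, X, y, TrainingConfig(epochs=2))
        assert anfis.to_json(m) == before


class TestIndexBands:
    @pytest.mark.parametrize(
        "value,band",
        [
            (1.61, "walk"),
            (3.31, "run"),
            (2.5, "uncertain"),
            (1.0, "walk"),
            (2.0, "walk"),
            (3.0, "run"),
            (4.0, "run"),
            (0.4, "out_of_range"),
            (4.7, "out_of_range"),
        ],
    )
    def test_band_assignment(self, value, band):
        assert classify_index(value).band == band

    def test_labels_drawn_within_their_bands_and_reproducible(self):
        labels = ["walk"] * 20 + ["run"] * 20
        t1 = label_training_data(labels, seed=7)
        t2 = label_training_data(labels, seed=7)
        np.testing.assert_array_equal(t1, t2)
        assert np.all((t1[:20] >= 1.0) & (t1[:20] <= 2.0))
        assert np.all((t1[20:] >= 3.0) & (t1[20:] <= 4.0))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="walk or run"):
            label_training_data(["stand"], seed=0)


class TestEvaluation:
    def test_separable_set_reaches_full_rate_excluding_uncertain(self):
        m = init_grid()
        # consequents so that rule (0,0,0) -> walk band, (1,1,1)/(2,2,2) -> run
        c = np.full(27, 2.5)
        c[0] = 1.5
        c[13 * 1] = 3.5  # rule (1,1,1) index 9+3+1 = 13
        c[26] = 3.5  # rule (2,2,2)
        m.consequents = c
        X = np.array([[0.05, 0.05, 0.05], [1.0, 1.0, 1.0], [1.95, 1.95, 1.95]])
        rep = evaluate(m, X, ["walk", "run", "run"])
        assert rep.rate_excluding == {"run": 100.0, "walk": 100.0}

    def test_report_counts_and_uncertain_column(self):
        m = init_grid()
        m.consequents = np.full(27, 2.5)  # everything lands uncertain
        X = np.random.default_rng(0).uniform(0, 2, (6, 3))
        rep = evaluate(m, X, ["walk"] * 3 + ["run"] * 3)
        assert rep.total == {"run": 3, "walk": 3}
        assert rep.uncertain == {"run": 3, "walk": 3}
        assert rep.rate_including == {"run": 0.0, "walk": 0.0}
        assert rep.rate_excluding == {"run": None, "walk": None}
        assert rep.rmse_excluding is None


class TestSerializationAndDiagnostics:
    def test_model_round_trip(self, tmp_path):
        m = random_model(11)
        p = tmp_path / "sugeno.json"
        anfis.save(m, p)
        m2 = anfis.load(p)
        x = [0.3, 1.2, 0.8]
        assert forward(m2, x) == pytest.approx(forward(m, x))
        assert m2.rule_order == m.rule_order

    def test_ordering_diagnostic_reports_all_six_candidates(self):
        results = diagnostics.evaluate_orderings()
        assert len(results) == 6
        for r in results.values():
            assert len(r["outputs"]) == 2
            assert all(np.isfinite(r["outputs"]))
        text = diagnostics.format_report(results)
        assert "ordering" in text and "order_123" in text
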