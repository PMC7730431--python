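"""Fuzzy-inference engine: oracle agreement, training behavior, persistence."""

import json

import numpy as np
import pytest

from broncholoc.anfis import (
    AnfisModel,
    FuzzyRule,
    TriangularMF,
    evaluate,
    evaluate_batch,
    load_model,
    save_model,
    train,
)


# ---------------------------------------------------------------------------
# independent dense-grid Mamdani/COG oracle (pure loops, no shared code path)
# ---------------------------------------------------------------------------

def tri(x, l, p, r):
    if x < l or x > r:
        return 0.0
    if x == p:
        return 1.0
    if x < p:
        return (x - l) / (p - l) if p > l else 1.0
    return (r - x) / (r - p) if r > p else 1.0


def mamdani_oracle(model, x, grid_points=1001):
    lo, hi = model.output_domain
    ys = [lo + (hi - lo) * i / (grid_points - 1) for i in range(grid_points)]
    agg = [0.0] * grid_points
    for rule in model.rules:
        w = rule.weight
        for inp, mf_idx in rule.antecedent:
            mf = model.input_mfs[inp][mf_idx]
            w = min(w, tri(x[inp], mf.left, mf.peak, mf.right))
        out = model.output_mfs[rule.consequent]
        for i, y in enumerate(ys):
            agg[i] = max(agg[i], min(w, tri(y, out.left, out.peak, out.right)))
    area = sum(agg)
    if area == 0:
        return 0.5 * (lo + hi)
    return sum(a * y for a, y in zip(agg, ys)) / area


def simple_ramp_model():
    """1-input model: low->low-out, high->high-out on [0,1]."""
    return AnfisModel(
        1,
        [[TriangularMF(0, 0, 1), TriangularMF(0, 1, 1)]],
        [FuzzyRule(((0, 0),), 0), FuzzyRule(((0, 1),), 1)],
        [TriangularMF(0, 0, 1), TriangularMF(0, 1, 1)],
    )


class TestTriangularMF:
    def test_membership_shape(self):
        mf = TriangularMF(0.0, 0.5, 1.0)
        assert mf(0.5) == 1.0
        assert mf(-0.1) == 0.0 and mf(1.1) == 0.0
        xs = np.linspace(-1, 2, 301)
        vals = mf(xs)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            TriangularMF(1.0, 0.5, 2.0)


class TestEvaluate:
    def test_single_always_firing_rule_returns_peak_of_symmetric_output(self):
        model = AnfisModel(
            1,
            [[TriangularMF(-1e9, 0.0, 1e9)]],  # fires fully everywhere near 0
            [FuzzyRule(((0, 0),), 0)],
            [TriangularMF(0.0, 0.5, 1.0)],
        )
        assert evaluate(model, [0.0]) == pytest.approx(0.5, abs=1e-9)

    def test_ramp_model_matches_bruteforce_oracle_on_grid(self):
        model = simple_ramp_model()
        for x in [0.0, 0.25, 0.5, 0.75, 1.0]:
            assert evaluate(model, [x]) == pytest.approx(
                mamdani_oracle(model, [x]), abs=1e-9
            )

    def test_randomized_small_models_match_oracle(self, rng):
        for trial in range(10):
            n_inputs = int(rng.integers(1, 4))
            n_mfs = int(rng.integers(1, 4))
            model = AnfisModel.default(
                n_inputs, n_mfs, [(-1.0, 1.0)] * n_inputs, output_domain=(0.0, 2.0)
            )
            for _ in range(5):
                x = rng.uniform(-1.2, 1.2, n_inputs)
                got = evaluate(model, x)
                want = mamdani_oracle(model, list(x))
                assert got == pytest.approx(want, abs=2e-3)
                lo = min(m.left for m in model.output_mfs)
                hi = max(m.right for m in model.output_mfs)
                assert lo - 1e-9 <= got <= hi + 1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(simple_ramp_model(), [0.1, 0.2])

    def test_zero_activation_returns_midpoint_with_warning(self):
        model = AnfisModel(
            1,
            [[TriangularMF(0.0, 0.1, 0.2)]],
            [FuzzyRule(((0, 0),), 0)],
            [TriangularMF(0, 0.5, 1)],
            output_domain=(0.0, 1.0),
        )
        with pytest.warns(RuntimeWarning):
            out = evaluate(model, [5.0])
        assert out == 0.5

    def test_two_input_surface_bounded_and_finite(self):
        model = AnfisModel.default(2, 3, [(0, 1), (0, 1)])
        xs = np.linspace(0, 1, 9)
        grid = np.array([[evaluate(model, [a, b]) for a in xs] for b in xs])
        assert np.all(np.isfinite(grid))
        assert grid.min() >= 0.0 and grid.max() <= 1.0


class TestTrain:
    def test_self_consistent_samples_keep_rmse_near_zero(self, rng):
        model = simple_ramp_model()
        X = rng.uniform(0, 1, 30)
        samples = [([x], evaluate(model, [x])) for x in X]
        trained = train(model, samples, epochs=3, seed=0)
        pred = evaluate_batch(trained, np.array(X)[:, None])
        target = np.array([s[1] for s in samples])
        initial = np.sqrt(np.mean((evaluate_batch(model, np.array(X)[:, None]) - target) ** 2))
        final = np.sqrt(np.mean((pred - target) ** 2))
        assert final <= initial + 1e-12
        assert final < 0.05

    def test_clamp_function_reaches_low_rmse(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-0.5, 1.5, 200)
        y = np.clip(X, 0.0, 1.0)
        model = AnfisModel.default(1, 2, [(-0.5, 1.5)])
        trained = train(model, list(zip(X[:, None], y)), epochs=100, learning_rate=0.05, seed=7)
        rmse = np.sqrt(np.mean((evaluate_batch(trained, X[:, None]) - y) ** 2))
        assert rmse < 0.1

    def test_constant_target_learned_within_tolerance(self, rng):
        c = 0.3
        X = rng.uniform(0, 1, 100)
        model = AnfisModel.default(1, 2, [(0.0, 1.0)])
        trained = train(model, [([x], c) for x in X], epochs=40, seed=3)
        grid = np.linspace(0, 1, 21)[:, None]
        assert np.all(np.abs(evaluate_batch(trained, grid) - c) < 0.05)

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(0, 1, 50)
        y = X**2
        model = AnfisModel.default(1, 3, [(0.0, 1.0)])
        t1 = train(model, list(zip(X[:, None], y)), epochs=5, seed=11)
        t2 = train(model, list(zip(X[:, None], y)), epochs=5, seed=11)
        probe = np.linspace(0, 1, 17)[:, None]
        assert np.array_equal(evaluate_batch(t1, probe), evaluate_batch(t2, probe))

    def test_empty_or_nonfinite_samples_rejected(self):
        model = simple_ramp_model()
        with pytest.raises(ValueError):
            train(model, [], epochs=1, seed=0)
        with pytest.raises(ValueError):
            train(model, [([np.nan], 0.5)], epochs=1, seed=0)


class TestPersistence:
    def test_roundtrip_evaluates_identically(self, tmp_path, rng):
        model = AnfisModel.default(2, 3, [(0, 1), (0, 1)])
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        X = rng.uniform(0, 1, (100, 2))
        assert np.array_equal(evaluate_batch(model, X), evaluate_batch(loaded, X))

    def test_invariant_violation_in_file_rejected(self, tmp_path):
        model = simple_ramp_model()
        path = tmp_path / "model.json"
        save_model(model, path)
        data = json.loads(path.read_text())
        data["input_mfs"][0][0] = [0.9, 0.5, 1.0]  # left > peak
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="left <= peak <= right"):
            load_model(path)

    def test_truncated_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "model.json"
        save_model(simple_ramp_model(), path)
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ValueError, match="malformed"):
            load_model(path)
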