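"""Network-layer closed forms, scalar-loop oracle, gradient checks,
structure learning and training contracts."""

import numpy as np
import pytest

from emg2kin.rfnn import (
    LearningConfig,
    RecurrentFuzzyRegression,
    RfnnParams,
    ZeroActivationError,
    defuzzify,
    forward_sequence,
    fuzzify,
    grad_step,
    gradients,
    recurrent_update,
    rule_strength,
    sample_loss,
    structure_adapt,
    structure_init,
)


def random_params(seed, n_in=None, n_rules=None, n_out=None):
    r = np.random.default_rng(seed)
    n_in = n_in or int(r.integers(2, 5))
    n_rules = n_rules or int(r.integers(2, 6))
    n_out = n_out or int(r.integers(1, 4))
    return RfnnParams(
        centers=r.uniform(0, 1, (n_in, n_rules)),
        widths=r.uniform(0.3, 1.0, (n_in, n_rules)),
        lambdas=r.uniform(0.05, 0.95, n_rules),
        weights=r.uniform(0, 1, (n_rules, n_out)),
        x_min=np.zeros(n_in), x_range=np.ones(n_in),
        y_min=np.zeros(n_out), y_range=np.ones(n_out),
    )


class TestLayers:
    def test_membership_peak_and_one_sigma(self):
        p = random_params(0)
        x = p.centers[:, 0].copy()
        a2 = fuzzify(x, p.centers, p.widths)
        np.testing.assert_allclose(a2[:, 0], 1.0)
        a2 = fuzzify(x + p.widths[:, 0], p.centers, p.widths)
        np.testing.assert_allclose(a2[:, 0], np.exp(-1.0), rtol=1e-12)

    def test_fuzzify_matches_scalar_loop(self):
        p = random_params(1)
        r = np.random.default_rng(5)
        x = r.uniform(0, 1, p.n_inputs)
        a2 = fuzzify(x, p.centers, p.widths)
        for i in range(p.n_inputs):
            for j in range(p.n_rules):
                expected = np.exp(
                    -((x[i] - p.centers[i, j]) ** 2) / p.widths[i, j] ** 2
                )
                assert abs(a2[i, j] - expected) < 1e-15

    def test_rule_strength_product(self):
        a2 = np.array([[0.5], [0.5]])
        np.testing.assert_allclose(rule_strength(a2), [0.25])
        np.testing.assert_allclose(rule_strength(np.ones((4, 3))), 1.0)

    def test_rule_strength_monotone(self):
        r = np.random.default_rng(2)
        a2 = r.uniform(0.1, 1.0, (5, 4))
        s = rule_strength(a2)
        a2b = a2.copy()
        a2b[2, 1] *= 0.5
        assert rule_strength(a2b)[1] <= s[1]

    @pytest.mark.parametrize(
        "lam,s,u_prev,expected",
        [(1.0, 0.4, 0.8, 0.4), (0.0, 0.4, 0.8, 0.8), (0.5, 0.4, 0.8, 0.6)],
    )
    def test_recurrent_update_arithmetic(self, lam, s, u_prev, expected):
        u = recurrent_update(
            np.array([s]), np.array([u_prev]), np.array([lam])
        )
        assert u[0] == pytest.approx(expected)

    def test_recurrent_update_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            recurrent_update(np.array([0.5]), np.array([0.5]), np.array([1.5]))

    def test_defuzzify_uniform_and_onehot(self):
        w = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        np.testing.assert_allclose(
            defuzzify(np.ones(3), w), w.mean(axis=0)
        )
        np.testing.assert_allclose(defuzzify(np.array([0.0, 1.0, 0.0]), w), w[1])

    def test_defuzzify_convex_combination_bounds(self):
        r = np.random.default_rng(3)
        for _ in range(20):
            w = r.uniform(-2, 2, (6, 2))
            u = r.uniform(0.01, 1, 6)
            y = defuzzify(u, w)
            assert np.all(y >= w.min(axis=0) - 1e-12)
            assert np.all(y <= w.max(axis=0) + 1e-12)

    def test_defuzzify_zero_activation_signalled(self):
        with pytest.raises(ZeroActivationError):
            defuzzify(np.zeros(3), np.ones((3, 1)))


class TestForwardSequence:
    def test_memoryless_limit_permutes_with_inputs(self):
        p = random_params(4)
        p.lambdas[:] = 1.0
        r = np.random.default_rng(6)
        X = r.uniform(0, 1, (10, p.n_inputs))
        perm = r.permutation(10)
        Y = forward_sequence(p, X)
        Yp = forward_sequence(p, X[perm])
        np.testing.assert_allclose(Yp, Y[perm], atol=1e-12)

    def test_matches_pure_scalar_loop_oracle(self):
        p = random_params(7)
        r = np.random.default_rng(8)
        T = 20
        X = r.uniform(0, 1, (T, p.n_inputs))
        Y = forward_sequence(p, X)
        # independent four-nested-loop implementation
        u_state = [0.0] * p.n_rules
        for t in range(T):
            s_list = []
            for j in range(p.n_rules):
                prod = 1.0
                for i in range(p.n_inputs):
                    prod *= np.exp(
                        -((X[t, i] - p.centers[i, j]) ** 2)
                        / p.widths[i, j] ** 2
                    )
                s_list.append(prod)
            u_new = [
                p.lambdas[j] * s_list[j] + (1 - p.lambdas[j]) * u_state[j]
                for j in range(p.n_rules)
            ]
            total = sum(u_new)
            for o in range(p.n_outputs):
                num = sum(u_new[j] * p.weights[j, o] for j in range(p.n_rules))
                assert abs(Y[t, o] - num / total) < 1e-12
            u_state = u_new

    def test_constant_input_converges_to_memoryless_answer(self):
        p = random_params(9)
        p.lambdas[:] = 0.3
        r = np.random.default_rng(10)
        x = r.uniform(0, 1, p.n_inputs)
        X = np.tile(x, (200, 1))
        Y = forward_sequence(p, X)
        p2 = p.copy()
        p2.lambdas[:] = 1.0
        fixed = forward_sequence(p2, x[None, :])[0]
        np.testing.assert_allclose(Y[-1], fixed, atol=1e-10)


class TestGradients:
    def test_zero_error_means_zero_gradient(self):
        p = random_params(11)
        r = np.random.default_rng(12)
        u_prev = r.uniform(0, 1, p.n_rules)
        x = r.uniform(0, 1, p.n_inputs)
        y, = [None]
        from emg2kin.rfnn import _forward_step

        y, _ = _forward_step(p, u_prev, x)
        g, _ = gradients(p, u_prev, x, y)
        for arr in g.values():
            np.testing.assert_allclose(arr, 0.0, atol=1e-14)

    def test_all_partials_match_central_finite_differences(self):
        h = 1e-6
        for case in range(100):
            p = random_params(100 + case)
            r = np.random.default_rng(200 + case)
            u_prev = r.uniform(0, 1, p.n_rules)
            x = r.uniform(0, 1, p.n_inputs)
            yt = r.uniform(0, 1, p.n_outputs)
            g, _ = gradients(p, u_prev, x, yt)
            for name in ("centers", "widths", "lambdas", "weights"):
                arr = getattr(p, name)
                it = np.nditer(arr, flags=["multi_index"])
                for _ in it:
                    idx = it.multi_index
                    orig = arr[idx]
                    arr[idx] = orig + h
                    lp = sample_loss(p, u_prev, x, yt)
                    arr[idx] = orig - h
                    lm = sample_loss(p, u_prev, x, yt)
                    arr[idx] = orig
                    fd = (lp - lm) / (2 * h)
                    an = g[name][idx]
                    # rel 1e-5 with an absolute floor at the FD noise level
                    assert abs(an - fd) <= 1e-5 * max(abs(an), abs(fd)) + 1e-10

    def test_small_step_does_not_increase_loss(self):
        for case in range(10):
            p = random_params(300 + case)
            r = np.random.default_rng(400 + case)
            u_prev = r.uniform(0, 1, p.n_rules)
            x = r.uniform(0, 1, p.n_inputs)
            yt = r.uniform(0, 1, p.n_outputs)
            before = sample_loss(p, u_prev, x, yt)
            tiny = LearningConfig(
                lr_center=1e-4, lr_width=1e-4, lr_lambda=1e-4, lr_weight=1e-4
            )
            grad_step(p, u_prev, x, yt, tiny)
            after = sample_loss(p, u_prev, x, yt)
            assert after <= before + 1e-12

    def test_constraints_preserved_by_updates(self):
        p = random_params(13)
        r = np.random.default_rng(14)
        cfg = LearningConfig(lr_lambda=10.0, lr_width=10.0)  # violent steps
        u_prev = r.uniform(0, 1, p.n_rules)
        for _ in range(50):
            x = r.uniform(0, 1, p.n_inputs)
            yt = r.uniform(0, 1, p.n_outputs)
            cache = grad_step(p, u_prev, x, yt, cfg)
            u_prev = cache["u"]
            assert np.all((p.lambdas >= 0) & (p.lambdas <= 1))
            assert np.all(p.widths >= p.sigma_min)


class TestStructure:
    def test_kmeans_recovers_separated_clouds(self):
        r = np.random.default_rng(15)
        a = r.normal([0.2, 0.2], 0.02, (50, 2))
        b = r.normal([0.8, 0.8], 0.02, (50, 2))
        X = np.vstack([a, b])
        Y = np.vstack([np.zeros((50, 1)), np.ones((50, 1))])
        p = structure_init(X, Y, n_rules=2, seed=0)
        got = np.sort(p.centers[0])
        true = np.sort(
            [(0.2 - X[:, 0].min()) / np.ptp(X[:, 0]),
             (0.8 - X[:, 0].min()) / np.ptp(X[:, 0])]
        )
        assert np.all(np.abs(got - true) < 0.05)

    def test_single_rule_degenerate_case(self):
        r = np.random.default_rng(16)
        X = r.uniform(0, 1, (30, 3))
        Y = r.uniform(0, 1, (30, 2))
        p = structure_init(X, Y, n_rules=1, seed=0)
        np.testing.assert_allclose(
            p.centers[:, 0], p.normalize_x(X).mean(axis=0), atol=1e-12
        )
        np.testing.assert_allclose(
            p.weights[0], p.normalize_y(Y).mean(axis=0), atol=1e-12
        )

    def test_widths_respect_floor(self):
        X = np.tile([0.5, 0.5], (20, 1)) + np.random.default_rng(17).normal(
            0, 1e-9, (20, 2)
        )
        Y = np.zeros((20, 1))
        p = structure_init(X, Y, n_rules=2, seed=0)
        assert np.all(p.widths >= p.sigma_min)

    def test_too_many_rules_rejected(self):
        with pytest.raises(ValueError):
            structure_init(np.zeros((3, 2)), np.zeros((3, 1)), n_rules=5)

    def test_adapt_adds_rule_far_from_centers(self):
        p = random_params(18, n_in=3, n_rules=2)
        p.centers[:] = 0.1
        p.widths[:] = 0.05
        n0 = p.n_rules
        added = structure_adapt(
            p, np.full(3, 0.9), np.array([0.5] * p.n_outputs), 0.1
        )
        assert added and p.n_rules == n0 + 1
        np.testing.assert_allclose(p.centers[:, -1], 0.9)

    def test_adapt_noop_at_existing_center(self):
        p = random_params(19, n_in=3, n_rules=2)
        n0 = p.n_rules
        added = structure_adapt(
            p, p.centers[:, 0].copy(), np.zeros(p.n_outputs), 0.1
        )
        assert not added and p.n_rules == n0

    def test_unfired_rule_pruned_after_epoch(self):
        r = np.random.default_rng(20)
        X = r.uniform(0.4, 0.6, (60, 2))
        Y = r.uniform(0, 1, (60, 1))
        cfg = LearningConfig(n_rules=2, epochs=1, seed=0)
        model = RecurrentFuzzyRegression(Y, X)
        params = structure_init(X, Y, 2, 0)
        # graft an unreachable rule far outside the data
        params.centers = np.column_stack([params.centers, [50.0, 50.0]])
        params.widths = np.column_stack([params.widths, [0.01, 0.01]])
        params.lambdas = np.append(params.lambdas, 0.5)
        params.weights = np.vstack([params.weights, [0.5]])
        # run one training epoch manually through fit on the grafted params:
        # simplest check is via the public fit with the same data — the
        # unreachable rule cannot arise there, so check the prune mechanics
        # directly instead
        from emg2kin.rfnn import fuzzify, rule_strength

        fire = np.zeros(params.n_rules)
        for x in params.normalize_x(X):
            fire += rule_strength(fuzzify(x, params.centers, params.widths))
        assert fire[-1] / len(X) < cfg.prune_threshold  # would be pruned


class TestFit:
    def test_constant_target_learned(self):
        r = np.random.default_rng(21)
        X = r.uniform(0, 1, (200, 2))
        Y = np.full((200, 2), 3.7)
        res = RecurrentFuzzyRegression(Y, X).fit(
            LearningConfig(n_rules=3, epochs=10, seed=0)
        )
        np.testing.assert_allclose(res.predict(X), 3.7, atol=1e-6)
        assert res.final_loss < 1e-3

    def test_same_seed_identical_parameters(self):
        r = np.random.default_rng(22)
        X = r.uniform(0, 1, (150, 3))
        Y = np.column_stack([X.sum(axis=1), X[:, 0]])
        cfg = LearningConfig(n_rules=4, epochs=5, seed=3)
        a = RecurrentFuzzyRegression(Y, X).fit(cfg)
        b = RecurrentFuzzyRegression(Y, X).fit(cfg)
        np.testing.assert_array_equal(a.params.centers, b.params.centers)
        np.testing.assert_array_equal(a.params.weights, b.params.weights)
        assert a.loss_history == b.loss_history

    def test_loss_history_and_summary(self):
        r = np.random.default_rng(23)
        X = r.uniform(0, 1, (100, 2))
        Y = X[:, :1] ** 2
        res = RecurrentFuzzyRegression(Y, X).fit(
            LearningConfig(n_rules=3, epochs=8, seed=0)
        )
        assert len(res.loss_history) == 8
        assert res.loss_history[-1] <= res.loss_history[0]
        text = res.summary().as_text()
        assert "No. rules" in text

    def test_roundtrip_serialization(self, tmp_path):
        r = np.random.default_rng(24)
        X = r.uniform(0, 1, (80, 2))
        Y = X[:, :1]
        res = RecurrentFuzzyRegression(Y, X).fit(
            LearningConfig(n_rules=3, epochs=3, seed=0)
        )
        path = tmp_path / "model.json"
        res.save(path)
        restored = RfnnParams.from_json(path)
        np.testing.assert_allclose(
            forward_sequence(restored, X), res.predict(X), atol=1e-12
        )

    def test_from_dataframe_sequences(self):
        import pandas as pd

        r = np.random.default_rng(25)
        df = pd.DataFrame(
            {
                "f1": r.uniform(0, 1, 60),
                "y": r.uniform(0, 1, 60),
                "seg": np.repeat([0, 1, 2], 20),
            }
        )
        model = RecurrentFuzzyRegression.from_dataframe(
            df, ["y"], ["f1"], sequence_col="seg"
        )
        assert len(model.exog) == 3 and model.exog[0].shape == (20, 1)
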