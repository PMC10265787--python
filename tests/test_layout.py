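"""Robust regression: incidence structure, Huber IRLS, two-step fit."""

import numpy as np
import pytest
from scipy.optimize import minimize

from regap.layout import (
    HuberLayoutModel,
    RobustConfig,
    build_problem,
    huber_irls,
    huber_rho,
    huber_weight,
    objective,
    ols_fit,
    two_step_fit,
)
from regap.overlap import OverlapObservation
from regap.util import round_half_away


def _obs(i, j, y, w=1.0):
    return OverlapObservation(i=i, j=j, y=float(y), weight=w)


from regap.simulate import simulate_overlap_graph as random_instance  # noqa: E402


def convex_oracle(problem, cfg):
    """Minimize the Huber objective directly with a generic convex optimizer."""
    X = problem.X.toarray()
    Y = problem.Y
    W0 = problem.W0
    (a_idx, a_val) = problem.anchors[0]

    def fun(beta):
        r = Y - X @ beta
        return float(np.sum(W0 * huber_rho(r, cfg.c)))

    def grad(beta):
        r = Y - X @ beta
        psi = np.clip(r, -cfg.c, cfg.c)
        return -(X.T @ (W0 * psi))

    n = problem.n
    # eliminate the anchored coordinate: optimize the shift-free reduced system
    free = [k for k in range(n) if k != a_idx]
    B = np.zeros((n, len(free)))
    for c, k in enumerate(free):
        B[k, c] = 1.0
    base = np.zeros(n)
    base[a_idx] = a_val
    res = minimize(lambda z: fun(base + B @ z), np.zeros(len(free)),
                   jac=lambda z: B.T @ grad(base + B @ z),
                   method="L-BFGS-B", options={"maxiter": 2000, "ftol": 1e-15,
                                               "gtol": 1e-12})
    return base + B @ res.x


class TestProblemStructure:
    def test_single_observation_incidence(self):
        p = build_problem([_obs(0, 1, 5)], 2, priors=[0.0, 5.0])
        assert p.X.toarray().tolist() == [[-1.0, 1.0]]
        assert len(p.components) == 1
        assert p.anchors == [(0, 0.0)]  # smallest-prior member anchored at its prior

    def test_every_row_has_minus_one_plus_one(self):
        obs, _ = random_instance(12, 30, 0.1, seed=1)
        p = build_problem(obs, 12)
        X = p.X.toarray()
        for row in X:
            nz = row[row != 0]
            assert sorted(nz.tolist()) == [-1.0, 1.0]

    def test_component_rank_matches_dense_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(10):
            n = int(rng.integers(4, 15))
            m = int(rng.integers(2, 25))
            obs = []
            for _ in range(m):
                i, j = rng.choice(n, size=2, replace=False)
                obs.append(_obs(int(i), int(j), float(rng.normal(0, 10))))
            p = build_problem(obs, n)
            X = p.X.toarray()
            for members in p.components:
                rows = [k for k, o in enumerate(p.observations)
                        if o.i in members and o.j in members]
                block = X[np.ix_(rows, members)] if rows else np.zeros((0, len(members)))
                assert np.linalg.matrix_rank(block) == len(members) - 1 or len(members) == 1

    def test_anchor_row_restores_full_column_rank(self):
        obs, _ = random_instance(8, 12, 0.0, seed=2)
        p = build_problem(obs, 8)
        from regap.layout import _augmented

        Xa, _ = _augmented(p, p.anchors)
        assert np.linalg.matrix_rank(Xa.toarray()) == 8

    def test_pseudo_anchor_preferred_over_prior(self):
        p = build_problem([_obs(0, 1, 5)], 2, priors=[3.0, 8.0], pseudo_anchors={1: 100.0})
        assert p.anchors == [(1, 100.0)]

    def test_duplicate_observations_kept(self):
        p = build_problem([_obs(0, 1, 5), _obs(0, 1, 5)], 2)
        assert p.m == 2


class TestHuberForms:
    def test_weight_closed_form_at_69(self):
        assert huber_weight(np.array([69.0]), 2.0)[0] == pytest.approx(2.0 / 69.0)

    def test_weight_is_one_inside(self):
        assert huber_weight(np.array([1.5, -2.0, 0.0]), 2.0).tolist() == [1.0, 1.0, 1.0]

    def test_loss_continuous_at_knot(self):
        c = 2.0
        assert huber_rho(np.array([c]), c)[0] == pytest.approx(c * c / 2.0)
        assert huber_rho(np.array([c - 1e-9]), c)[0] == pytest.approx(c * c / 2.0, abs=1e-6)
        assert huber_rho(np.array([c + 1e-9]), c)[0] == pytest.approx(c * c / 2.0, abs=1e-6)

    def test_objective_zero_at_exact_fit(self):
        p = build_problem([_obs(0, 1, 5)], 2)
        assert objective(p, np.array([0.0, 5.0]), RobustConfig()) == 0.0


class TestHuberIRLS:
    def test_single_chain_trivial_fit(self):
        p = build_problem([_obs(0, 1, 5)], 2, priors=[0.0, 5.0], pseudo_anchors={0: 0.0})
        r = huber_irls(p)
        assert np.allclose(r.beta, [0, 5], atol=1e-8)
        assert np.allclose(r.residuals, 0, atol=1e-8)
        assert r.iterations == 1
        assert r.converged

    def test_matches_convex_minimizer(self):
        cfg = RobustConfig(alpha=1e-6, max_iter=500)
        for seed in range(8):
            obs, truth = random_instance(12, 40, 0.2, seed=seed)
            p = build_problem(obs, 12, priors=truth, pseudo_anchors={0: 0.0})
            r = huber_irls(p, cfg)
            ref = convex_oracle(p, cfg)
            assert np.max(np.abs(r.beta - ref)) < 1e-4

    def test_objective_nonincreasing_every_iteration(self):
        for seed in range(5):
            obs, truth = random_instance(15, 50, 0.25, seed=100 + seed)
            p = build_problem(obs, 15, priors=truth, pseudo_anchors={0: 0.0})
            r = huber_irls(p, RobustConfig(alpha=1e-6, max_iter=300))
            path = np.array(r.objective_path)
            assert np.all(np.diff(path) <= 1e-7 * np.maximum(path[:-1], 1.0))

    def test_descent_from_ols_start(self):
        cfg = RobustConfig(alpha=1e-6, max_iter=300)
        for seed in range(5):
            obs, truth = random_instance(10, 35, 0.3, seed=200 + seed)
            p = build_problem(obs, 10, priors=truth, pseudo_anchors={0: 0.0})
            r = huber_irls(p, cfg)
            assert objective(p, r.beta, cfg) <= objective(p, ols_fit(p), cfg) + 1e-9


class TestTwoStepFit:
    def test_noiseless_instance_recovered_exactly(self):
        obs, truth = random_instance(10, 30, 0.0, seed=3)
        obs = [o for o in obs if float(o.y).is_integer() or True]
        # rebuild without measurement noise
        obs = [_obs(o.i, o.j, truth[o.j] - truth[o.i]) for o in obs]
        p = build_problem(obs, 10, priors=truth, pseudo_anchors={0: 0.0})
        fit = two_step_fit(p)
        assert np.array_equal(fit.beta, truth.astype(int))
        assert fit.outliers.sum() == 0

    def test_gross_false_overlap_is_trimmed(self):
        truth = np.arange(8) * 10.0
        obs = []
        for lag in (1, 2):
            for i in range(8 - lag):
                obs.append(_obs(i, i + lag, truth[i + lag] - truth[i]))
        obs.append(_obs(1, 5, truth[5] - truth[1] + 69.0))  # repeat-unit confusion
        p = build_problem(obs, 8, priors=truth, pseudo_anchors={0: 0.0})
        fit = two_step_fit(p)
        assert np.array_equal(fit.beta, truth.astype(int))
        assert fit.outliers.sum() == 1
        assert abs(fit.residuals[fit.outlier_indices[0]]) == pytest.approx(69.0, abs=1e-6)
        kept = fit.residuals[~fit.outliers]
        assert np.allclose(kept, 0.0, atol=1e-6)

    def test_trimming_can_split_into_two_layouts(self):
        # two clusters joined only by a pair of grossly disagreeing bridges:
        # neither can be satisfied, both get residuals > r_o and are trimmed
        truth = np.array([0.0, 10.0, 20.0, 300.0, 310.0, 320.0])
        obs = [_obs(0, 1, 10), _obs(1, 2, 10), _obs(0, 2, 20),
               _obs(3, 4, 10), _obs(4, 5, 10), _obs(3, 5, 20),
               _obs(2, 3, 280 + 75.0), _obs(2, 3, 280 - 75.0)]
        p = build_problem(obs, 6, priors=truth, pseudo_anchors={0: 0.0})
        fit = two_step_fit(p)
        assert len(fit.components_final) == 2
        for members in fit.components_final:
            rel = fit.beta[members] - fit.beta[members[0]]
            expect = truth[members] - truth[members[0]]
            assert np.array_equal(rel, expect.astype(int))

    def test_singleton_component_sits_at_prior(self):
        p = build_problem([_obs(0, 1, 7)], 3, priors=[0.0, 7.0, 42.0])
        fit = two_step_fit(p)
        assert fit.beta[2] == 42

    def test_anchor_shift_equivariance(self):
        obs, truth = random_instance(9, 25, 0.2, seed=5)
        p0 = build_problem(obs, 9, priors=truth, pseudo_anchors={0: 0.0})
        p1 = build_problem(obs, 9, priors=truth, pseudo_anchors={0: 1000.0})
        f0 = two_step_fit(p0)
        f1 = two_step_fit(p1)
        assert np.array_equal(f1.beta - 1000, f0.beta)

    def test_bounded_influence_of_one_outlier(self):
        """Doubling an already-gross outlier barely moves the M-estimate."""
        cfg = RobustConfig(alpha=1e-6, max_iter=300)
        obs, truth = random_instance(10, 30, 0.0, seed=6)
        base = [_obs(o.i, o.j, truth[o.j] - truth[o.i]) for o in obs]
        out1 = base + [_obs(0, 5, truth[5] - truth[0] + 80.0)]
        out2 = base + [_obs(0, 5, truth[5] - truth[0] + 160.0)]
        b1 = huber_irls(build_problem(out1, 10, priors=truth, pseudo_anchors={0: 0.0}), cfg).beta
        b2 = huber_irls(build_problem(out2, 10, priors=truth, pseudo_anchors={0: 0.0}), cfg).beta
        assert np.max(np.abs(b2 - b1)) < RobustConfig().alpha

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(np.array([0.5, -0.5, 1.49, -1.5, 2.5])).tolist() == [1, -1, 1, -2, 3]


class TestModelSurface:
    def test_fit_returns_results_with_summary(self):
        obs, truth = random_instance(8, 20, 0.1, seed=8)
        model = HuberLayoutModel(obs, 8, priors=truth, pseudo_anchors={0: 0.0})
        res = model.fit()
        assert res.params.shape == (8,)
        assert res.resid.shape == (20,)
        s = res.summary()
        assert "observations:    20" in s
        assert "huber c=2.0" in s

    def test_ols_method_ignores_outliers(self):
        truth = np.arange(6) * 10.0
        obs = ([_obs(i, i + 1, 10.0) for i in range(5)]
               + [_obs(i, i + 2, 20.0) for i in range(4)]
               + [_obs(0, 5, 50.0 + 69.0)])
        model = HuberLayoutModel(obs, 6, priors=truth, pseudo_anchors={0: 0.0})
        ols = model.fit(method="ols")
        two = model.fit()
        assert np.array_equal(two.params, truth.astype(int))
        assert np.max(np.abs(ols.params - truth)) > 5

    def test_bse_available_for_small_systems(self):
        obs, truth = random_instance(8, 25, 0.0, seed=10)
        res = HuberLayoutModel(obs, 8, priors=truth, pseudo_anchors={0: 0.0}).fit()
        bse = res.bse()
        assert bse is not None and bse.shape == (8,)
        assert np.all(bse >= 0)
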