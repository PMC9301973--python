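"""Cox engine: oracle equivalence, exact derivatives, lasso KKT, CV."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from lvshape import _coxlib

from conftest import survival_toy


def brute_force_partial_lik(beta, X, time, event):
    """Direct product-form Cox partial likelihood (no ties), evaluated
    independently of the package implementation."""
    beta = np.atleast_1d(beta)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            num = np.exp(X[i] @ beta)
            den = sum(np.exp(X[j] @ beta) for j in risk)
            ll += np.log(num / den)
    return ll


@pytest.fixture(scope="module")
def toy6():
    X = np.array([[0.5], [-1.2], [0.3], [2.0], [-0.7], [1.1]])
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1])
    return X, time, event


class TestPartialLoglik:
    def test_null_closed_form(self, toy6):
        X, time, event = toy6
        # beta = 0, no ties: sum over events of -log(risk-set size)
        expected = sum(
            -np.log((time >= time[i]).sum()) for i in range(6) if event[i]
        )
        assert _coxlib.partial_loglik([0.0], X, time, event) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_brute_force_product(self, toy6):
        X, time, event = toy6
        for b in (-0.8, 0.0, 0.4, 1.5):
            assert _coxlib.partial_loglik([b], X, time, event) == pytest.approx(
                brute_force_partial_lik(b, X, time, event), abs=1e-10
            )

    def test_late_censored_subject_joins_all_risk_sets(self, toy6):
        X, time, event = toy6
        X2 = np.vstack([X, [[0.9]]])
        time2 = np.append(time, 10.0)
        event2 = np.append(event, 0)
        for b in (-0.5, 0.7):
            assert _coxlib.partial_loglik([b], X2, time2, event2) == pytest.approx(
                brute_force_partial_lik(b, X2, time2, event2), abs=1e-10
            )

    def test_no_events_rejected(self, toy6):
        X, time, _ = toy6
        with pytest.raises(ValueError, match="no events"):
            _coxlib.partial_loglik([0.0], X, time, np.zeros(6, dtype=int))

    def test_efron_ties_match_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        X, time, event = survival_toy(seed=5, n=60, beta=[0.5] + [0] * 9)
        time = np.ceil(time)  # coarse times => heavy ties
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(10)])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(df, "T", "E")
        ours = _coxlib.partial_loglik(cph.params_.values, X, time, event)
        assert ours == pytest.approx(cph.log_likelihood_, rel=1e-9)


class TestDerivatives:
    def test_gradient_matches_numeric(self):
        X, time, event = survival_toy(seed=1, n=40, p=3)
        time = np.ceil(time)
        beta = np.array([0.3, -0.2, 0.5])
        _, grad = _coxlib.loglik_grad(beta, X, time, event)
        for j in range(3):
            d = np.zeros(3)
            d[j] = 1e-6
            num = (
                _coxlib.partial_loglik(beta + d, X, time, event)
                - _coxlib.partial_loglik(beta - d, X, time, event)
            ) / 2e-6
            assert grad[j] == pytest.approx(num, abs=1e-6)

    def test_hessian_matches_numeric(self):
        X, time, event = survival_toy(seed=2, n=40, p=3)
        time = np.ceil(time)
        beta = np.array([0.1, 0.4, -0.3])
        _, _, hess = _coxlib.loglik_grad_hess(beta, X, time, event)
        for j in range(3):
            d = np.zeros(3)
            d[j] = 1e-5
            _, gp = _coxlib.loglik_grad(beta + d, X, time, event)
            _, gm = _coxlib.loglik_grad(beta - d, X, time, event)
            assert np.allclose(hess[:, j], (gp - gm) / 2e-5, atol=1e-6)

    def test_weighted_counting_process_gradient(self):
        rng = np.random.default_rng(3)
        n = 30
        X = rng.normal(size=(n, 2))
        start = rng.uniform(0, 1, n)
        stop = start + rng.uniform(0.5, 5, n)
        event = rng.binomial(1, 0.5, n)
        event[0] = 1
        w = rng.uniform(0.5, 2, n)
        beta = np.array([0.2, -0.4])
        _, grad = _coxlib.loglik_grad(beta, X, stop, event, start=start, weights=w)
        for j in range(2):
            d = np.zeros(2)
            d[j] = 1e-6
            num = (
                _coxlib.partial_loglik(beta + d, X, stop, event, start, w)
                - _coxlib.partial_loglik(beta - d, X, stop, event, start, w)
            ) / 2e-6
            assert grad[j] == pytest.approx(num, abs=1e-6)


class TestNewton:
    def test_matches_brute_force_maximiser(self, toy6):
        X, time, event = toy6
        res = _coxlib.newton_fit(X, time, event)
        opt = minimize_scalar(
            lambda b: -brute_force_partial_lik(b, X, time, event),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.beta[0] == pytest.approx(opt.x, abs=1e-4)

    def test_multivariate_brute_force_8_subjects(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 2))
        time = np.arange(1.0, 9.0)
        event = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        res = _coxlib.newton_fit(X, time, event)
        opt = minimize(
            lambda b: -brute_force_partial_lik(b, X, time, event),
            x0=[0.0, 0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12},
        )
        assert np.allclose(res.beta, opt.x, atol=1e-4)

    def test_loglik_nondecreasing_over_iterations(self):
        X, time, event = survival_toy(seed=6, n=80, beta=[1.0] + [0] * 9)
        lls = []
        for k in (1, 2, 3, 5, 10):
            r = _coxlib.newton_fit(X, time, event, max_iter=k)
            lls.append(r.loglik)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        X, time, event = survival_toy(seed=7, n=150, beta=[0.4, -0.6] + [0] * 8)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(10)])
        df["T"], df["E"] = time, event
        cph = CoxPHFitter().fit(df, "T", "E")
        res = _coxlib.newton_fit(X, time, event)
        assert np.allclose(res.beta, cph.params_.values, atol=1e-5)
        assert np.allclose(res.se, cph.standard_errors_.values, atol=1e-5)

    def test_separation_flagged(self):
        # perfectly separating covariate => monotone likelihood
        time = np.arange(1.0, 11.0)
        event = np.ones(10, dtype=int)
        X = np.argsort(np.argsort(time))[:, None].astype(float)  # x orders time
        res = _coxlib.newton_fit(X, time, event)
        assert res.flagged
        assert np.abs(res.beta).max() <= 20.0


class TestLassoPath:
    def test_beta_zero_at_lambda_max(self):
        X, time, event = survival_toy(seed=8, n=100, beta=[0.8] + [0] * 9)
        lmax = _coxlib.lambda_max(X, time, event)
        beta, ok = _coxlib.lasso_fit(X, time, event, lmax * 1.0001)
        assert ok and np.all(beta == 0)
        beta2, _ = _coxlib.lasso_fit(X, time, event, lmax * 0.95)
        assert np.any(beta2 != 0)

    def test_lambda_zero_matches_newton(self):
        X, time, event = survival_toy(seed=9, n=120, beta=[0.5, -0.5] + [0] * 8)
        newton = _coxlib.newton_fit(X, time, event)
        beta, _ = _coxlib.lasso_fit(X, time, event, 1e-9)
        assert np.allclose(beta, newton.beta, atol=1e-4)

    def test_planted_mode_enters_first(self):
        X, time, event = survival_toy(seed=10, n=250, beta=[0, 0, 1.0] + [0] * 7)
        lams, betas, _ = _coxlib.lasso_path(X, time, event, n_lambda=40)
        order = np.argsort(-lams)
        for i in order:
            active = np.nonzero(betas[i])[0]
            if len(active):
                assert active.tolist() == [2]
                break

    def test_kkt_on_every_path_point(self):
        X, time, event = survival_toy(seed=11, n=150, beta=[0.6, 0, -0.6] + [0] * 7)
        lams, betas, flags = _coxlib.lasso_path(X, time, event, n_lambda=50)
        assert flags.all()
        for lam, beta in zip(lams, betas):
            assert _coxlib.kkt_violation(beta, lam, X, time, event) < 1e-6

    def test_path_deterministic(self):
        X, time, event = survival_toy(seed=12, n=100, beta=[0.5] + [0] * 9)
        a = _coxlib.lasso_path(X, time, event, n_lambda=20)
        b = _coxlib.lasso_path(X, time, event, n_lambda=20)
        assert np.array_equal(a[1], b[1])


class TestCrossValidation:
    def test_fold_label_permutation_invariant(self):
        X, time, event = survival_toy(seed=13, n=120, beta=[0.6] + [0] * 9)
        lams = _coxlib.default_lambda_grid(
            _coxlib.lambda_max(X, time, event), n_lambda=10
        )
        cv1, folds, _ = _coxlib.cv_partial_loglik(X, time, event, lams,
                                                  n_folds=5, seed=0)
        # renaming fold labels must not change the curve
        perm = np.array([3, 0, 4, 1, 2])
        cv2, _, _ = _coxlib.cv_partial_loglik(X, time, event, lams, n_folds=5,
                                              seed=0, folds=perm[folds])
        assert np.allclose(cv1, cv2, atol=1e-9)

    def test_every_fold_has_events(self):
        event = np.array([1] * 10 + [0] * 90)
        folds = _coxlib.stratified_event_folds(event, 5, seed=0)
        for f in range(5):
            assert event[folds == f].sum() >= 1

    def test_too_few_events_errors(self):
        event = np.array([1, 1] + [0] * 50)
        with pytest.raises(ValueError, match="folds"):
            _coxlib.stratified_event_folds(event, 5, seed=0)

    def test_signal_recovery_small(self):
        # smoke-scale version of the acceptance recovery property
        from lvshape import lvas

        hits = 0
        for s in range(5):
            X, time, event = survival_toy(
                seed=100 + s, n=300, beta=[0, 0, 0, 0, 0.7, -0.7, 0, 0, 0, 0.7]
            )
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            lams = _coxlib.default_lambda_grid(
                _coxlib.lambda_max(Xs, time, event), n_lambda=50
            )
            lam, _, _ = lvas.cv_select(Xs, time, event, n_folds=10, seed=s,
                                       lambda_grid=lams)
            beta, _ = _coxlib.lasso_fit(Xs, time, event, lam)
            if {4, 5, 9} <= set(np.nonzero(beta)[0]):
                hits += 1
        assert hits >= 4
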