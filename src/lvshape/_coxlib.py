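"""Cox partial-likelihood engine shared by the score-learning and
survival-analysis modules.

Supports counting-process episodes (start, stop], case weights, Efron
tie handling, exact gradients, a Newton maximiser with step-halving, a
lasso coordinate-descent path with warm starts, and the
Verweij-van Houwelingen cross-validated partial log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_inputs(X, stop, event, start=None, weights=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(stop)
    if X.shape[0] != n:
        X = X.T if X.shape[1] == n else X
    start = np.zeros(n) if start is None else np.asarray(start, dtype=float)
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if np.any(stop <= start):
        raise ValueError("episode stop times must exceed start times")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    if event.sum() == 0:
        raise ValueError("no events in the data; Cox likelihood undefined")
    return X, stop, event, start, weights


def _event_blocks(stop, event, start):
    """Per unique event time: (time, event-row indices, risk-set mask)."""
    times = np.unique(stop[event == 1])
    blocks = []
    for t in times:
        d_idx = np.nonzero((stop == t) & (event == 1))[0]
        at_risk = (start < t) & (stop >= t)
        blocks.append((t, d_idx, at_risk))
    return blocks


def eta_derivatives(eta, stop, event, start, weights, cache=None):
    """Efron partial log-likelihood and its exact first derivative plus a
    positive diagonal curvature per subject linear predictor.

    Uses an O(n log n) vectorised path when there is no delayed entry
    (all episode starts at 0), which covers every lasso / CV call.
    """
    if cache is not None or np.all(start == 0):
        return _eta_derivatives_fast(eta, stop, event, weights, cache=cache)
    r = weights * np.exp(eta)
    n = len(eta)
    ll = 0.0
    a_acc = np.zeros(n)  # sum over event times of (W/m) sum_l 1/denom for risk members
    b_diag = np.zeros(n)  # squared-term accumulator for the curvature
    g = weights * event * 1.0
    for _, d_idx, at_risk in _event_blocks(stop, event, start):
        m = len(d_idx)
        W = weights[d_idx].sum()
        S0 = r[at_risk].sum()
        D0 = r[d_idx].sum()
        f = np.arange(m) / m
        denom = S0 - f * D0
        ll += float((weights[d_idx] * eta[d_idx]).sum() - (W / m) * np.log(denom).sum())
        inv = 1.0 / denom
        a = (W / m) * inv.sum()
        b = (W / m) * (f * inv).sum()
        a2 = (W / m) * (inv**2).sum()
        # cross terms for tied members: (1 - f)^2 instead of 1
        c2 = (W / m) * (((1 - f) * inv) ** 2).sum()
        a_acc[at_risk] += a
        a_acc[d_idx] -= b  # tied members see (1 - f) in place of 1
        b_diag[at_risk] += a2
        b_diag[d_idx] += c2 - a2
    g = g - r * a_acc
    v = r * a_acc - r**2 * b_diag
    v = np.clip(v, 1e-12, None)
    return ll, g, v


class _FastCache:
    """Sort/group structure of one right-censored dataset, reused across
    the many likelihood evaluations of a lasso path."""

    def __init__(self, stop, event, weights):
        self.order = np.argsort(stop, kind="stable")
        stop_s = stop[self.order]
        event_s = event[self.order]
        self.w_s = weights[self.order]
        self.ev_pos = np.nonzero(event_s == 1)[0]
        t_ev = stop_s[self.ev_pos]
        self.uniq, counts = np.unique(t_ev, return_counts=True)
        self.row_of = np.searchsorted(stop_s, self.uniq, side="left")
        self.n_uniq = len(self.uniq)
        self.seg = np.repeat(np.arange(self.n_uniq), counts)
        m = counts.astype(float)
        offsets = np.concatenate([[0], np.cumsum(counts)])[:-1]
        self.f = (np.arange(len(self.seg)) - offsets[self.seg]) / m[self.seg]
        self.m = m
        self.W = np.bincount(self.seg, weights=self.w_s[self.ev_pos],
                             minlength=self.n_uniq)
        self.k = np.searchsorted(self.uniq, stop, side="right")
        self.ev_all = np.nonzero(event == 1)[0]
        self.tie_group = np.searchsorted(self.uniq, stop[self.ev_all])
        self.w_ev = self.w_s[self.ev_pos]


def _eta_derivatives_fast(eta, stop, event, weights, cache=None):
    """Vectorised Efron derivatives for right-censored data (start = 0)."""
    c = cache or _FastCache(stop, event, weights)
    r = weights * np.exp(eta)
    r_s = r[c.order]
    # suffix sums of risk over sorted stop: S0 at threshold t = sum r[stop >= t]
    suffix = np.concatenate([np.cumsum(r_s[::-1])[::-1], [0.0]])
    S0 = suffix[c.row_of]
    D0 = np.bincount(c.seg, weights=r_s[c.ev_pos], minlength=c.n_uniq)
    denom = S0[c.seg] - c.f * D0[c.seg]
    inv = 1.0 / denom
    wm = (c.W / c.m)[c.seg]

    ll = float((c.w_ev * eta[c.order][c.ev_pos]).sum() - (wm * np.log(denom)).sum())

    a_t = np.bincount(c.seg, weights=wm * inv, minlength=c.n_uniq)
    b_t = np.bincount(c.seg, weights=wm * c.f * inv, minlength=c.n_uniq)
    a2_t = np.bincount(c.seg, weights=wm * inv**2, minlength=c.n_uniq)
    c2_t = np.bincount(c.seg, weights=wm * ((1 - c.f) * inv) ** 2, minlength=c.n_uniq)

    # subject i is in the risk set of every event time <= stop_i
    a_acc = np.concatenate([[0.0], np.cumsum(a_t)])[c.k]
    b_diag = np.concatenate([[0.0], np.cumsum(a2_t)])[c.k]
    # tied members see (1 - f) in place of 1
    a_acc[c.ev_all] -= b_t[c.tie_group]
    b_diag[c.ev_all] += c2_t[c.tie_group] - a2_t[c.tie_group]

    g = weights * event - r * a_acc
    v = np.clip(r * a_acc - r**2 * b_diag, 1e-12, None)
    return ll, g, v


def partial_loglik(beta, X, stop, event, start=None, weights=None) -> float:
    X, stop, event, start, weights = _as_inputs(X, stop, event, start, weights)
    eta = X @ np.asarray(beta, dtype=float)
    ll, _, _ = eta_derivatives(eta, stop, event, start, weights)
    return ll


def loglik_grad(beta, X, stop, event, start=None, weights=None):
    X, stop, event, start, weights = _as_inputs(X, stop, event, start, weights)
    eta = X @ np.asarray(beta, dtype=float)
    ll, g, _ = eta_derivatives(eta, stop, event, start, weights)
    return ll, X.T @ g


def loglik_grad_hess(beta, X, stop, event, start=None, weights=None):
    """Exact Efron log-likelihood, gradient and Hessian."""
    X, stop, event, start, weights = _as_inputs(X, stop, event, start, weights)
    beta = np.asarray(beta, dtype=float)
    eta = X @ beta
    r = weights * np.exp(eta)
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for _, d_idx, at_risk in _event_blocks(stop, event, start):
        m = len(d_idx)
        W = weights[d_idx].sum()
        rR = r[at_risk]
        xR = X[at_risk]
        S0 = rR.sum()
        S1 = rR @ xR
        S2 = xR.T @ (rR[:, None] * xR)
        rD = r[d_idx]
        xD = X[d_idx]
        D0 = rD.sum()
        D1 = rD @ xD
        D2 = xD.T @ (rD[:, None] * xD)
        ll += float((weights[d_idx] * eta[d_idx]).sum())
        grad += weights[d_idx] @ xD
        for l in range(m):
            f = l / m
            denom = S0 - f * D0
            mu = (S1 - f * D1) / denom
            ll -= (W / m) * np.log(denom)
            grad -= (W / m) * mu
            hess -= (W / m) * ((S2 - f * D2) / denom - np.outer(mu, mu))
    return ll, grad, hess


@dataclass
class NewtonResult:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    flagged: bool  # monotone likelihood / separation suspected
    iterations: int
    cov: np.ndarray


def newton_fit(
    X,
    stop,
    event,
    start=None,
    weights=None,
    init=None,
    max_iter=100,
    tol=1e-9,
    beta_cap=20.0,
) -> NewtonResult:
    """Maximum partial likelihood by Newton-Raphson with step-halving;
    the log-likelihood is non-decreasing over accepted iterations."""
    Xa, stopa, eventa, starta, wa = _as_inputs(X, stop, event, start, weights)
    p = Xa.shape[1]
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, hess = loglik_grad_hess(beta, Xa, stopa, eventa, starta, wa)
    flagged = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            delta = -np.linalg.pinv(hess) @ grad
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new, grad_new, hess_new = loglik_grad_hess(
                cand, Xa, stopa, eventa, starta, wa
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            break
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > beta_cap:
            flagged = True
            beta = np.clip(beta, -beta_cap, beta_cap)
            ll, grad, hess = loglik_grad_hess(beta, Xa, stopa, eventa, starta, wa)
            break
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return NewtonResult(
        beta=beta, se=se, loglik=ll, converged=converged, flagged=flagged,
        iterations=it, cov=cov,
    )


# ---------------------------------------------------------------------------
# lasso path by cyclic coordinate descent on the local quadratic model
# ---------------------------------------------------------------------------

def _soft(x, lam):
    return np.sign(x) * max(abs(x) - lam, 0.0)


def lasso_fit(
    X, stop, event, lam, start=None, weights=None, init=None,
    max_outer=200, outer_tol=1e-7, max_inner=200, inner_tol=1e-9,
    _cache=None,
):
    """One penalised fit: maximise (1/N) loglik - lam * ||beta||_1.

    Proximal-Newton with a diagonal curvature working model; returns
    (beta, converged).
    """
    Xa, stopa, eventa, starta, wa = _as_inputs(X, stop, event, start, weights)
    n, p = Xa.shape
    if _cache is None and np.all(starta == 0):
        _cache = _FastCache(stopa, eventa, wa)
    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    for _ in range(max_outer):
        eta = Xa @ beta
        _, g, v = eta_derivatives(eta, stopa, eventa, starta, wa, cache=_cache)
        res = g / v  # working residual z - eta
        b = beta.copy()
        Vx = v[:, None] * Xa
        denom = (Vx * Xa).sum(axis=0) / n

        def sweep(active):
            nonlocal res
            max_step = 0.0
            for j in active:
                if denom[j] <= 0:
                    continue
                num = Vx[:, j] @ res / n + denom[j] * b[j]
                new = _soft(num, lam) / denom[j]
                if new != b[j]:
                    res_delta = new - b[j]
                    res -= Xa[:, j] * res_delta
                    max_step = max(max_step, abs(res_delta))
                    b[j] = new
            return max_step

        sweep(range(p))
        for _ in range(max_inner):  # active-set iterations, then full check
            active = np.nonzero(b)[0]
            if len(active) == 0 or sweep(active) < inner_tol:
                if sweep(range(p)) < inner_tol:
                    break
        change = np.max(np.abs(b - beta))
        beta = b
        if change < outer_tol:
            break
    else:
        beta[np.abs(beta) < 1e-10] = 0.0
        return beta, False
    # float-noise cleanup: at lam = lambda_max the soft threshold sits at
    # exact equality and can leave O(1e-17) residue
    beta[np.abs(beta) < 1e-10] = 0.0
    return beta, True


def lambda_max(X, stop, event, start=None, weights=None) -> float:
    """Smallest penalty at which beta = 0 is optimal (KKT threshold on
    the null-model gradient)."""
    Xa, stopa, eventa, starta, wa = _as_inputs(X, stop, event, start, weights)
    _, grad = loglik_grad(np.zeros(Xa.shape[1]), Xa, stopa, eventa, starta, wa)
    return float(np.max(np.abs(grad)) / Xa.shape[0])


def default_lambda_grid(lmax: float, n_lambda: int = 100, lmin_ratio: float = 1e-3):
    return np.geomspace(lmax, lmax * lmin_ratio, n_lambda)


def lasso_path(
    X, stop, event, lambdas=None, start=None, weights=None,
    n_lambda=100, lmin_ratio=1e-3,
):
    """Warm-started coordinate-descent path along decreasing lambda.

    Returns (lambdas, betas (L, p), converged flags).  Deterministic.
    """
    Xa, stopa, eventa, starta, wa = _as_inputs(X, stop, event, start, weights)
    if lambdas is None:
        lambdas = default_lambda_grid(
            lambda_max(Xa, stopa, eventa, starta, wa), n_lambda, lmin_ratio
        )
    lambdas = np.asarray(lambdas, dtype=float)
    order = np.argsort(-lambdas)
    betas = np.zeros((len(lambdas), Xa.shape[1]))
    flags = np.zeros(len(lambdas), dtype=bool)
    beta = np.zeros(Xa.shape[1])
    cache = _FastCache(stopa, eventa, wa) if np.all(starta == 0) else None
    for i in order:
        beta, ok = lasso_fit(
            Xa, stopa, eventa, lambdas[i], start=starta, weights=wa, init=beta,
            _cache=cache,
        )
        betas[i] = beta
        flags[i] = ok
    return lambdas, betas, flags


def kkt_violation(beta, lam, X, stop, event, start=None, weights=None) -> float:
    """Maximum violation of the lasso KKT conditions at (beta, lam):
    |g_j|/N <= lam for zero coefficients, g_j/N = lam * sign(beta_j)
    for active ones."""
    Xa, stopa, eventa, starta, wa = _as_inputs(X, stop, event, start, weights)
    _, grad = loglik_grad(beta, Xa, stopa, eventa, starta, wa)
    g = grad / Xa.shape[0]
    viol = 0.0
    for j, b in enumerate(np.asarray(beta, dtype=float)):
        if b == 0:
            viol = max(viol, abs(g[j]) - lam)
        else:
            viol = max(viol, abs(g[j] - lam * np.sign(b)))
    return viol


def stratified_event_folds(event, n_folds, seed, max_attempts=5):
    """Fold labels with events spread across folds; refolds with a new
    seed when a fold ends up event-free, erroring after max_attempts."""
    event = np.asarray(event, dtype=int)
    n = len(event)
    for attempt in range(max_attempts):
        rng = np.random.default_rng(seed + attempt)
        folds = np.empty(n, dtype=int)
        for group in (np.nonzero(event == 1)[0], np.nonzero(event == 0)[0]):
            perm = rng.permutation(group)
            folds[perm] = np.arange(len(perm)) % n_folds
        if all((event[folds == f] == 1).any() for f in range(n_folds)):
            return folds
    raise ValueError(
        f"could not build {n_folds} folds with at least one event each "
        f"after {max_attempts} attempts"
    )


def cv_partial_loglik(
    X, stop, event, lambdas, n_folds=10, seed=0, start=None, weights=None,
    folds=None,
):
    """Verweij-van Houwelingen cross-validated partial log-likelihood:
    CV(lam) = sum_k [ ll_full(beta_-k) - ll_train_k(beta_-k) ].

    A fixed fold assignment can be passed via ``folds`` (labels 0..K-1);
    the curve depends only on the partition, not on the label names.
    Returns (cv_values, fold_labels, per_fold_contributions).
    """
    Xa, stopa, eventa, starta, wa = _as_inputs(X, stop, event, start, weights)
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3")
    if folds is None:
        folds = stratified_event_folds(eventa, n_folds, seed)
    else:
        folds = np.asarray(folds, dtype=int)
        n_folds = folds.max() + 1
    lambdas = np.asarray(lambdas, dtype=float)
    per_fold = np.zeros((n_folds, len(lambdas)))
    for f in range(n_folds):
        tr = folds != f
        _, betas, _ = lasso_path(
            Xa[tr], stopa[tr], eventa[tr], lambdas,
            start=starta[tr], weights=wa[tr],
        )
        for i, beta in enumerate(betas):
            ll_full = partial_loglik(beta, Xa, stopa, eventa, starta, wa)
            ll_train = partial_loglik(
                beta, Xa[tr], stopa[tr], eventa[tr], starta[tr], wa[tr]
            )
            per_fold[f, i] = ll_full - ll_train
    return per_fold.sum(axis=0), folds, per_fold
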