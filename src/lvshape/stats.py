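"""Downstream survival statistics: Cox regressions (including
counting-process time-varying device covariates), univariate screening,
generalized propensity scores with stabilized inverse-probability
weights, chained-equation multiple imputation with Rubin pooling, and
descriptive two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingRegressor

from . import _coxlib
from .io import CohortTable

Z95 = 1.959963984540054


@dataclass
class SurvivalFit:
    """Cox regression result; CI = exp(coef +/- 1.96 se), HR = exp(coef)."""

    summary: pd.DataFrame  # coef, se, hr, ci_lower, ci_upper, p per covariate
    loglik: float
    n: int
    n_events: int
    tie_method: str = "efron"
    flagged: bool = False

    def coef(self, name: str) -> float:
        return float(self.summary.loc[name, "coef"])

    def hr(self, name: str) -> float:
        return float(self.summary.loc[name, "hr"])


def _summary_frame(names, beta, se):
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    with np.errstate(over="ignore"):
        return pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_lower": np.exp(beta - Z95 * se),
                "ci_upper": np.exp(beta + Z95 * se),
                "p": 2.0 * sps.norm.sf(np.abs(z)),
            },
            index=list(names),
        )


def _as_frame(cohort) -> pd.DataFrame:
    return cohort.data if isinstance(cohort, CohortTable) else cohort


def expand_time_varying(
    df: pd.DataFrame, time_varying: list[tuple[str, str]]
) -> pd.DataFrame:
    """Counting-process expansion: one episode per interval between
    device implant times; each device indicator switches 0 -> 1 at its
    implant time and is absorbing.  Total follow-up per patient is
    conserved, and the event lands on the final episode."""
    rows = []
    for idx, row in df.iterrows():
        follow = row["follow_up_years"]
        cuts = sorted(
            {
                float(row[tcol])
                for _, tcol in time_varying
                if pd.notna(row[tcol]) and 0.0 < float(row[tcol]) < follow
            }
        )
        bounds = [0.0] + cuts + [follow]
        for a, b in zip(bounds[:-1], bounds[1:]):
            ep = row.to_dict()
            ep["start"] = a
            ep["stop"] = b
            ep["episode_event"] = int(row["event"]) if b == follow else 0
            for name, tcol in time_varying:
                t = row[tcol]
                ep[name] = int(pd.notna(t) and float(t) <= a + 1e-12)
            ep["patient"] = idx
            rows.append(ep)
    return pd.DataFrame(rows)


def cox_fit(
    cohort,
    covariates: list[str],
    time_varying: list[tuple[str, str]] | None = None,
    weights: np.ndarray | None = None,
) -> SurvivalFit:
    """Newton-Raphson maximum partial likelihood (Efron ties).

    ``time_varying`` maps new covariate names to implant-time columns,
    e.g. ``[("icd", "icd_time_years")]``; episodes are split at implant
    times so the indicator switches 0 -> 1.  Monotone likelihood is
    flagged and the offending coefficient capped.
    """
    df = _as_frame(cohort)
    if time_varying:
        w = None
        if weights is not None:
            df = df.copy()
            df["_w"] = np.asarray(weights, dtype=float)
        ep = expand_time_varying(df, time_varying)
        names = list(covariates) + [name for name, _ in time_varying]
        X = ep[names].to_numpy(dtype=float)
        res = _coxlib.newton_fit(
            X,
            ep["stop"].to_numpy(),
            ep["episode_event"].to_numpy(),
            start=ep["start"].to_numpy(),
            weights=ep["_w"].to_numpy() if weights is not None else None,
        )
        n_events = int(df["event"].sum())
    else:
        names = list(covariates)
        X = df[names].to_numpy(dtype=float)
        res = _coxlib.newton_fit(
            X,
            df["follow_up_years"].to_numpy(),
            df["event"].to_numpy(dtype=int),
            weights=weights,
        )
        n_events = int(df["event"].sum())
    return SurvivalFit(
        summary=_summary_frame(names, res.beta, res.se),
        loglik=res.loglik,
        n=len(df),
        n_events=n_events,
        flagged=res.flagged,
    )


def univariate_screen(
    cohort,
    candidate_vars: list[str],
    p_threshold: float = 0.25,
    forced: tuple[str, ...] = ("age", "sex"),
) -> list[str]:
    """Variables for the propensity model: any column with missing data
    is excluded first, the rest are kept iff the univariate Cox p-value
    is below the threshold; ``forced`` columns are always included."""
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    df = _as_frame(cohort)
    selected = [v for v in forced if v in df.columns]
    for var in candidate_vars:
        if var in selected:
            continue
        col = df[var]
        if col.isna().any():
            continue
        if col.nunique() < 2:
            continue
        fit = cox_fit(df, [var])
        if fit.summary.loc[var, "p"] < p_threshold:
            selected.append(var)
    return selected


# ---------------------------------------------------------------------------
# generalized propensity score for a continuous exposure
# ---------------------------------------------------------------------------

@dataclass
class PropensityResult:
    weights: np.ndarray  # stabilized, truncated
    covariates: list[str]
    balance: pd.DataFrame  # unweighted/weighted Pearson r per covariate
    residual_sd: float
    truncation: tuple[float, float] = (0.01, 0.99)
    model: object = field(default=None, repr=False)


def _weighted_pearson(x, y, w):
    w = np.asarray(w, dtype=float)
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def propensity_continuous(
    exposure: np.ndarray,
    covariates: pd.DataFrame,
    truncate: tuple[float, float] = (0.01, 0.99),
    random_state: int = 0,
) -> PropensityResult:
    """Stabilized generalized-propensity weights for a continuous
    exposure: a tree-ensemble regression of exposure on covariates with
    a Gaussian residual density,
    w_i = f_marginal(e_i) / f(e_i | X_i), truncated to percentile
    bounds.  The stand-in estimator is deliberately conservative
    (shallow trees, slow learning) so weights stay near 1 when the
    covariates carry no information.
    """
    e = np.asarray(exposure, dtype=float)
    X = covariates.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("propensity covariates must be complete (post-screen)")
    model = GradientBoostingRegressor(
        n_estimators=300,
        max_depth=2,
        learning_rate=0.05,
        min_samples_leaf=50,
        random_state=random_state,
    )
    # out-of-fold conditional means: keeps the residual density honest
    # (in-sample fits understate sigma and inflate weights under the null)
    from sklearn.model_selection import KFold, cross_val_predict

    cv = KFold(n_splits=5, shuffle=True, random_state=random_state)
    fitted = cross_val_predict(model, X, e, cv=cv)
    model.fit(X, e)
    resid = e - fitted
    sd_cond = float(resid.std(ddof=1))
    if sd_cond < 1e-4 * max(e.std(), 1e-12):
        raise ValueError("exposure is fully determined by covariates")
    sd_marg = float(e.std(ddof=1))
    dens_cond = sps.norm.pdf(e, loc=fitted, scale=sd_cond)
    dens_marg = sps.norm.pdf(e, loc=e.mean(), scale=sd_marg)
    w = dens_marg / dens_cond
    lo, hi = np.quantile(w, truncate)
    w = np.clip(w, lo, hi)

    balance = pd.DataFrame(
        {
            "unweighted_r": [
                np.corrcoef(X[:, j], e)[0, 1] for j in range(X.shape[1])
            ],
            "weighted_r": [
                _weighted_pearson(X[:, j], e, w) for j in range(X.shape[1])
            ],
        },
        index=list(covariates.columns),
    )
    return PropensityResult(
        weights=w,
        covariates=list(covariates.columns),
        balance=balance,
        residual_sd=sd_cond,
        truncation=truncate,
        model=model,
    )


def adjusted_association(
    cohort,
    exposure: np.ndarray,
    weights: np.ndarray | None = None,
    propensity_score: np.ndarray | None = None,
    exposure_name: str = "lvas_quartile",
) -> dict[str, SurvivalFit]:
    """Confounding-controlled exposure-outcome association: (a) a Cox
    fit weighted by stabilized IPW weights, and (b) a sensitivity fit
    with the propensity score entered as a covariate."""
    df = _as_frame(cohort).copy()
    df[exposure_name] = np.asarray(exposure, dtype=float)
    out: dict[str, SurvivalFit] = {}
    if weights is not None:
        if np.any(np.asarray(weights) <= 0):
            raise ValueError("IPW weights must be positive")
        out["ipw"] = cox_fit(df, [exposure_name], weights=np.asarray(weights))
    if propensity_score is not None:
        df["_ps"] = np.asarray(propensity_score, dtype=float)
        out["covariate_adjusted"] = cox_fit(df, [exposure_name, "_ps"])
    if not out:
        out["unadjusted"] = cox_fit(df, [exposure_name])
    return out


# ---------------------------------------------------------------------------
# multiple imputation by chained equations
# ---------------------------------------------------------------------------

def _pmm_impute(y_obs, yhat_obs, yhat_mis, rng, k=5):
    """Predictive mean matching: donor drawn from the k observed rows
    with the closest fitted values."""
    out = np.empty(len(yhat_mis))
    for i, val in enumerate(yhat_mis):
        nearest = np.argsort(np.abs(yhat_obs - val))[:k]
        out[i] = y_obs[np.asarray(nearest)[rng.integers(len(nearest))]]
    return out


def mice_impute(
    cohort,
    m: int = 10,
    n_cycles: int = 10,
    seed: int = 0,
    cox_covariates: list[str] | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame | None]:
    """Chained-equation multiple imputation (predictive mean matching
    for continuous columns, logistic draws for binary ones) followed by
    per-imputation Cox fits pooled by Rubin's rules.

    Returns (completed data frames, pooled summary or None when no
    ``cox_covariates`` are requested).
    """
    from sklearn.linear_model import LinearRegression, LogisticRegression

    if m < 2:
        raise ValueError("m must be >= 2")
    df = _as_frame(cohort)
    miss_cols = [c for c in df.columns if df[c].isna().any()]
    for c in miss_cols:
        if df[c].isna().all():
            raise ValueError(f"column '{c}' is fully missing; cannot impute")
    pred_cols = [
        c
        for c in df.columns
        if c not in miss_cols
        and c not in ("icd_time_years", "crt_time_years")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    completed: list[pd.DataFrame] = []
    rng = np.random.default_rng(seed)
    for _ in range(m):
        work = df.copy()
        for c in miss_cols:  # initial fill: observed mean / mode
            obs = work[c].dropna()
            fill = obs.mean() if obs.nunique() > 2 else obs.mode().iloc[0]
            work[c] = work[c].fillna(fill)
        if not miss_cols:
            completed.append(work)
            continue
        for _ in range(n_cycles):
            for c in miss_cols:
                mis = df[c].isna().to_numpy()
                others = [x for x in miss_cols if x != c]
                Xp = work[pred_cols + others].to_numpy(dtype=float)
                y = work[c].to_numpy(dtype=float)
                y_obs = df.loc[~mis, c].to_numpy(dtype=float)
                binary = df[c].dropna().nunique() <= 2
                if binary:
                    if len(np.unique(y_obs)) < 2:
                        work.loc[mis, c] = y_obs[0]
                        continue
                    clf = LogisticRegression(max_iter=200)
                    clf.fit(Xp[~mis], y[~mis].astype(int))
                    p = clf.predict_proba(Xp[mis])[:, 1]
                    vals = np.unique(y_obs)
                    draw = (rng.random(mis.sum()) < p).astype(int)
                    work.loc[mis, c] = vals.max() * draw + vals.min() * (1 - draw)
                else:
                    reg = LinearRegression().fit(Xp[~mis], y[~mis])
                    yhat = reg.predict(Xp)
                    work.loc[mis, c] = _pmm_impute(
                        y_obs, yhat[~mis], yhat[mis], rng
                    )
        completed.append(work)

    pooled = None
    if cox_covariates:
        fits = [cox_fit(w, cox_covariates) for w in completed]
        coefs = np.array([f.summary["coef"].to_numpy() for f in fits])
        variances = np.array([f.summary["se"].to_numpy() ** 2 for f in fits])
        point = coefs.mean(axis=0)
        within = variances.mean(axis=0)
        between = coefs.var(axis=0, ddof=1) if m > 1 else np.zeros_like(point)
        total = within + (1.0 + 1.0 / m) * between
        pooled = _summary_frame(cox_covariates, point, np.sqrt(total))
    return completed, pooled


# ---------------------------------------------------------------------------
# descriptive group comparisons
# ---------------------------------------------------------------------------

def group_compare(
    cohort, group_col: str, variables: list[str] | None = None
) -> pd.DataFrame:
    """Two-group table: Mann-Whitney (normal approximation,
    tie-corrected, continuity-corrected) for continuous variables and
    chi-square contingency tests (Yates on 2x2) for categorical ones,
    using all available data per variable."""
    df = _as_frame(cohort)
    groups = df[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"'{group_col}' must define exactly 2 groups, got {groups}")
    g0, g1 = sorted(groups)
    if (df[group_col] == g0).sum() == 0 or (df[group_col] == g1).sum() == 0:
        raise ValueError("one of the groups is empty")
    if variables is None:
        variables = [c for c in df.columns if c != group_col]
    rows = []
    for var in variables:
        sub = df[[var, group_col]].dropna()
        x0 = sub.loc[sub[group_col] == g0, var]
        x1 = sub.loc[sub[group_col] == g1, var]
        categorical = sub[var].nunique() <= 5 and (
            sub[var].round() == sub[var]
        ).all()
        if categorical:
            table = pd.crosstab(sub[var], sub[group_col])
            stat, p, _, _ = sps.chi2_contingency(table.to_numpy())
            test = "chi2"
        else:
            stat, p = sps.mannwhitneyu(
                x0, x1, alternative="two-sided", method="asymptotic"
            )
            test = "mann-whitney"
        rows.append({"variable": var, "test": test, "statistic": stat, "p": p})
    return pd.DataFrame(rows).set_index("variable")


def yates_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square test of a 2x2 count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(stat), float(p)


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Proportion as a percentage rounded to the given decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)
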