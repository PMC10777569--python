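"""Survival endpoints for score subgroups.

Kaplan-Meier curves with Greenwood variance, the two-group log-rank test,
Cox proportional-hazards models (Newton-Raphson on the Breslow partial
likelihood), and the hazard-ratio-vs-score curve from a natural-cubic-spline
Cox model referenced at the median score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


def _validate(surv: pd.DataFrame, time_col="time", event_col="event"):
    t = surv[time_col].to_numpy(dtype=float)
    e = surv[event_col].to_numpy()
    if np.isnan(t).any() or (t <= 0).any():
        raise ValueError("times must be positive and non-missing")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event must be 0/1")
    return t, e.astype(int)


def km_estimate(surv: pd.DataFrame, by: str = "group", time_col="time", event_col="event"):
    """Product-limit estimate per group with Greenwood variance.

    Returns ``{group: DataFrame(time, survival, greenwood_var, ci_lower,
    ci_upper)}``.
    """
    t, e = _validate(surv, time_col, event_col)
    out = {}
    for g, sub in surv.groupby(by, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        table = kmf.event_table
        d, n = table["observed"].to_numpy(float), table["at_risk"].to_numpy(float)
        s = np.cumprod(np.where(n > 0, 1.0 - d / n, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = np.where((n - d) > 0, d / (n * (n - d)), 0.0)
        greenwood = s**2 * np.cumsum(inc)
        ci = kmf.confidence_interval_survival_function_
        df = pd.DataFrame(
            {
                "time": table.index.to_numpy(float),
                "survival": s,
                "greenwood_var": greenwood,
                "ci_lower": ci.iloc[:, 0].to_numpy(),
                "ci_upper": ci.iloc[:, 1].to_numpy(),
            }
        )
        df = df[table.removed.to_numpy() > 0]  # drop the synthetic t=0 row
        out[g] = df.reset_index(drop=True)
    return out


def logrank_test(surv: pd.DataFrame, by: str = "group", time_col="time", event_col="event"):
    """Two-group log-rank test; returns ``(chi2, p)``."""
    t, e = _validate(surv, time_col, event_col)
    groups = pd.unique(surv[by])
    if len(groups) != 2:
        raise ValueError("log-rank test requires exactly 2 groups")
    if e.sum() < 1:
        raise ValueError("no events: log-rank variance is zero")
    a = surv[surv[by] == groups[0]]
    b = surv[surv[by] == groups[1]]
    res = _ll_logrank(
        a[time_col], b[time_col], event_observed_A=a[event_col], event_observed_B=b[event_col]
    )
    return float(res.test_statistic), float(res.p_value)


class ConvergenceError(RuntimeError):
    pass


def _breslow_neg_loglik_grad_hess(beta, X, t, e):
    """Breslow partial likelihood pieces; observations sorted by time desc."""
    eta = X @ beta
    w = np.exp(eta)
    # cumulative risk-set sums: with times sorted descending, the risk set of
    # subject i is subjects 0..i plus any later subject with an equal time
    S0 = np.cumsum(w)
    S1 = np.cumsum(w[:, None] * X, axis=0)
    S2 = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
    # extend to ties: use the last index sharing the same time
    last = np.searchsorted(-t, -t, side="right") - 1
    S0, S1, S2 = S0[last], S1[last], S2[last]
    ev = e == 1
    loglik = float(eta[ev].sum() - np.log(S0[ev]).sum())
    xbar = S1[ev] / S0[ev, None]
    grad = X[ev].sum(axis=0) - xbar.sum(axis=0)
    hess = -(
        (S2[ev] / S0[ev, None, None]).sum(axis=0)
        - (xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    )
    return loglik, grad, hess


def cox_ph(
    surv: pd.DataFrame,
    covariates,
    time_col="time",
    event_col="event",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Cox proportional hazards by Newton-Raphson on the Breslow likelihood.

    ``covariates`` are numeric column names entering jointly (univariate =
    one name). Returns one row per covariate with ``coef``, ``hr``,
    ``ci_lower``, ``ci_upper`` (95% Wald), ``p``. Monotone likelihood
    (separation) and non-convergence raise :class:`ConvergenceError`.
    """
    covariates = [covariates] if isinstance(covariates, str) else list(covariates)
    t, e = _validate(surv, time_col, event_col)
    if e.sum() < len(covariates) + 1:
        raise ValueError("too few events for the number of covariates")
    X = surv[covariates].to_numpy(dtype=float)
    order = np.argsort(-t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    Xc = Xs - Xs.mean(axis=0)  # centering stabilizes Newton steps

    beta = np.zeros(len(covariates))
    for _ in range(max_iter):
        ll, grad, hess = _breslow_neg_loglik_grad_hess(beta, Xc, ts, es)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError("singular Hessian in Cox fit") from err
        beta = beta - step
        if np.abs(beta).max() > 20:
            raise ConvergenceError("monotone likelihood (perfect separation?)")
        if np.abs(step).max() < tol:
            break
    else:
        raise ConvergenceError("Cox Newton-Raphson did not converge")

    _, _, hess = _breslow_neg_loglik_grad_hess(beta, Xc, ts, es)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    zcrit = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "covariate": covariates,
            "coef": beta,
            "hr": np.exp(beta),
            "ci_lower": np.exp(beta - zcrit * se),
            "ci_upper": np.exp(beta + zcrit * se),
            "p": p,
        }
    )


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept): K knots -> K-1 columns."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(k):
        num = np.maximum(x - knots[k], 0) ** 3 - np.maximum(x - knots[-1], 0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def hr_score_curve(
    surv: pd.DataFrame,
    score_col: str = "score",
    df: int = 4,
    n_grid: int = 100,
    time_col="time",
    event_col="event",
) -> pd.DataFrame:
    """ln HR as a smooth function of a continuous score, 0 at the median.

    Fits a Cox model on a natural-cubic-spline basis of the score (``df``
    columns, knots at score quantiles) and evaluates the log hazard ratio
    relative to the median score on a grid, with pointwise 95% Wald bands.
    """
    scores = surv[score_col].to_numpy(dtype=float)
    uniq = np.unique(scores)
    if df >= len(uniq):
        raise ValueError(f"df={df} requires more than {df} distinct scores")
    knots = np.quantile(uniq, np.linspace(0, 1, df + 1))
    knots = np.unique(knots)
    if len(knots) < 3:
        raise ValueError("degenerate score distribution")

    basis_cols = [f"_ns{i}" for i in range(natural_spline_basis(scores[:2], knots).shape[1])]
    fit_df = surv[[time_col, event_col]].copy()
    B = natural_spline_basis(scores, knots)
    for i, c in enumerate(basis_cols):
        fit_df[c] = B[:, i]
    fit = cox_ph(fit_df, basis_cols, time_col=time_col, event_col=event_col)
    beta = fit.coef.to_numpy()

    # covariance of beta from the fitted model (recompute at solution)
    t, e = _validate(surv, time_col, event_col)
    order = np.argsort(-t, kind="stable")
    Bc = B - B.mean(axis=0)
    _, _, hess = _breslow_neg_loglik_grad_hess(beta, Bc[order], t[order], e[order])
    cov = np.linalg.inv(-hess)

    med = float(np.median(scores))
    grid = np.linspace(scores.min(), scores.max(), n_grid)
    grid = np.unique(np.append(grid, med))  # reference point always on the grid
    D = natural_spline_basis(grid, knots) - natural_spline_basis(np.full(len(grid), med), knots)
    ln_hr = D @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, cov, D))
    zcrit = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "score": grid,
            "ln_hr": ln_hr,
            "ci_lower": ln_hr - zcrit * se,
            "ci_upper": ln_hr + zcrit * se,
        }
    )
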