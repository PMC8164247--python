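"""Survival integration: per-gene Cox proportional hazards and log-rank tests.

The Cox model here is univariate (one gene's normalized expression at a
time), fitted by Newton-Raphson on the Breslow partial likelihood with
step-halving, reporting the log hazard ratio, its standard error and the
Wald p-value.  The k-group log-rank test uses the standard
observed-minus-expected chi-square over risk sets with the hypergeometric
variance; at ties, events precede censorings in the risk-set bookkeeping
(both remain at risk at their own time).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, ExpressionState, SurvivalTable

logger = logging.getLogger("resistscreen")

#: |beta| beyond this is treated as separation / non-identifiability.
BETA_BOUND = 20.0


def _breslow_quantities(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood, gradient and information at beta (Breslow ties).

    Arrays must be sorted by descending time so risk sets are cumulative
    prefixes.
    """
    eta = beta * x
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    # index of the last subject with time >= t_i (risk set for t_i)
    # with descending sort, subjects 0..i have time >= time[i]; extend
    # through ties so all subjects with equal time are in the risk set
    n = len(x)
    risk_end = np.empty(n, dtype=int)
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        risk_end[i] = j
    ev = event == 1
    idx = risk_end[ev]
    loglik = float(np.sum(eta[ev]) - np.sum(np.log(s0[idx])))
    grad = float(np.sum(x[ev]) - np.sum(s1[idx] / s0[idx]))
    info = float(np.sum(s2[idx] / s0[idx] - (s1[idx] / s0[idx]) ** 2))
    return loglik, grad, info


def cox_univariate(
    x,
    time,
    event,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> dict:
    """Fit a one-covariate Cox PH model (Breslow ties, Newton with step-halving).

    Returns a dict with beta_hat, hr, se, p_value, n_used, converged and a
    note ('zero variance', 'separation', 'no convergence' when degenerate).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        return dict(beta_hat=np.nan, hr=np.nan, se=np.nan, p_value=np.nan,
                    n_used=len(x), converged=False, note="zero variance")
    order = np.argsort(-time, kind="mergesort")
    x, time, event = x[order], time[order], event[order]
    beta = 0.0
    loglik, grad, info = _breslow_quantities(beta, x, time, event)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _breslow_quantities(new_beta, x, time, event)
        halvings = 0
        # tolerate fp-level likelihood noise near the optimum
        ll_slack = 1e-10 * max(1.0, abs(loglik))
        while new_ll < loglik - ll_slack and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _breslow_quantities(new_beta, x, time, event)
            halvings += 1
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(grad) < tol or abs(step) < 1e-12 * max(1.0, abs(beta)):
            converged = True
            break
    if abs(beta) > BETA_BOUND:
        return dict(beta_hat=np.nan, hr=np.nan, se=np.nan, p_value=np.nan,
                    n_used=len(x), converged=False, note="separation")
    if not converged:
        return dict(beta_hat=np.nan, hr=np.nan, se=np.nan, p_value=np.nan,
                    n_used=len(x), converged=False, note="no convergence")
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return dict(beta_hat=float(beta), hr=float(np.exp(beta)), se=se,
                p_value=p, n_used=len(x), converged=True, note="")


def cox_score_test(x, time, event) -> tuple[float, float]:
    """Cox score (Rao) test at beta = 0: chi-square = U(0)^2 / I(0), df = 1."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="mergesort")
    _, grad, info = _breslow_quantities(0.0, x[order], time[order], event[order])
    chi2 = grad * grad / info
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def cox_per_gene(expr: ExpressionMatrix, surv: SurvivalTable) -> pd.DataFrame:
    """Univariate Cox PH of each gene's normalized expression vs overall survival."""
    if expr.state == ExpressionState.raw_counts:
        raise ValueError("cox_per_gene expects normalized (or z-scored) expression")
    st = surv.table.set_index("sample_id")
    shared = expr.samples.intersection(st.index)
    if len(shared) == 0:
        raise ValueError("no samples shared between expression and survival")
    st = st.loc[shared]
    if st["event"].sum() < 2:
        raise ValueError("need at least 2 events among shared samples")
    time = st["time"].to_numpy(dtype=float)
    event = st["event"].to_numpy(dtype=int)
    vals = expr.values[shared]
    rows = []
    for gene in vals.index:
        res = cox_univariate(vals.loc[gene].to_numpy(), time, event)
        res["gene"] = gene
        rows.append(res)
    out = pd.DataFrame(rows)[
        ["gene", "beta_hat", "hr", "se", "p_value", "n_used", "converged", "note"]
    ]
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        logger.info("cox_per_gene: %d/%d genes not fitted (%s)", n_bad, len(out),
                    out.loc[~out["converged"], "note"].value_counts().to_dict())
    return out


def logrank_test(groups: pd.Series, surv: SurvivalTable) -> dict:
    """K-group log-rank test of survival differences.

    ``groups`` maps sample_id -> group label.  Returns chi_square, df,
    p_value and the per-group at-risk / event counts.
    """
    st = surv.table.set_index("sample_id")
    shared = groups.index.intersection(st.index)
    g = groups.loc[shared]
    labels = sorted(g.unique())
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    gidx = g.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    time = st.loc[shared, "time"].to_numpy(dtype=float)
    event = st.loc[shared, "event"].to_numpy(dtype=int)

    obs_minus_exp = np.zeros(k)
    cov = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int(((time == t) & (event == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[(time == t) & (event == 1)], minlength=k).astype(float)
        obs_minus_exp += d_g - d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
            cov += v
    v_sub = cov[: k - 1, : k - 1]
    u = obs_minus_exp[: k - 1]
    if np.allclose(u, 0):
        chi2 = 0.0
    else:
        chi2 = float(u @ np.linalg.solve(v_sub, u))
    p = float(stats.chi2.sf(chi2, df=k - 1)) if chi2 > 0 else 1.0
    events = {lab: int(event[(gidx == i)].sum()) for i, lab in enumerate(labels)}
    n_per = {lab: int((gidx == i).sum()) for i, lab in enumerate(labels)}
    return dict(chi_square=chi2, df=k - 1, p_value=p, groups=labels,
                events_per_group=events, n_per_group=n_per)
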