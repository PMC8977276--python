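"""Censored-survival statistics used throughout the toolkit.

Kaplan–Meier estimation, the k-sample log-rank test and Harrell's
concordance index are delegated to lifelines.  The Cox
proportional-hazards fit is implemented here directly because the search
stages need Breslow tie handling (the convention of the statistical
software the composite-signature methodology was developed with) and a
lean array interface that is cheap to call tens of thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index as _lifelines_cindex
from lifelines.utils import median_survival_times
from scipy import stats as sps


class DegenerateDesignError(ValueError):
    """Raised when a Cox design matrix has a constant or collinear column."""


class SurvivalDataError(ValueError):
    """Raised for invalid survival inputs (empty data, bad event codes...)."""


# --------------------------------------------------------------------------
# survival outcome container (scikit-survival compatible structured array)
# --------------------------------------------------------------------------

def as_survival(time, event) -> np.ndarray:
    """Pack times and event indicators into a structured outcome array.

    The dtype (``event`` bool, ``time`` float) matches the convention of
    scikit-survival, so the estimators in this package compose with
    sklearn model-selection utilities that pass ``y`` around opaquely.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    _validate_time_event(time, event)
    y = np.empty(time.shape[0], dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = event.astype(bool)
    y["time"] = time
    return y


def unpack_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(time, event)`` float/int arrays from a structured outcome."""
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        if not {"event", "time"} <= names:
            raise SurvivalDataError(
                f"structured outcome must have fields 'event' and 'time', got {sorted(names)}"
            )
        return np.asarray(y["time"], dtype=float), np.asarray(y["event"], dtype=int)
    y = np.asarray(y)
    if y.ndim == 2 and y.shape[1] == 2:
        return y[:, 0].astype(float), y[:, 1].astype(int)
    raise SurvivalDataError("outcome must be a structured (event, time) array or an (n, 2) array")


def _validate_time_event(time: np.ndarray, event: np.ndarray) -> None:
    if time.size == 0:
        raise SurvivalDataError("empty survival data")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise SurvivalDataError("survival times must be finite and strictly positive")
    ev = np.asarray(event, dtype=float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise SurvivalDataError("event indicator must be binary (0/1)")


# --------------------------------------------------------------------------
# Kaplan–Meier
# --------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``median`` is the earliest observed time at which the estimated
    survival drops to 0.5 or below; it is ``None`` when the curve never
    reaches 0.5 (the situation in which a median survival cannot be
    calculated).
    """

    event_times: np.ndarray          # distinct observed times, increasing
    survival: np.ndarray             # S(t) at each time
    at_risk: np.ndarray
    events: np.ndarray
    variance: np.ndarray             # Greenwood variance of S(t)
    median: float | None
    median_ci: tuple[float | None, float | None] | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "variance": self.variance,
            }
        )


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimate with Greenwood variance.

    The median confidence interval is derived from the log-log (exponential
    Greenwood) confidence band of the curve, the usual Brookmeyer–Crowley
    style construction.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _validate_time_event(time, event)

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    d = table["observed"].to_numpy(dtype=float)
    n_at_risk = table["at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)

    # Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    variance = surv**2 * np.cumsum(terms)

    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    median_ci: tuple[float | None, float | None] | None = None
    if median is not None:
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        median_ci = (lo if np.isfinite(lo) else None, hi if np.isfinite(hi) else None)

    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=n_at_risk,
        events=d,
        variance=variance,
        median=median,
        median_ci=median_ci,
    )


def reverse_km_followup(time, event) -> float | None:
    """Median follow-up by the reverse Kaplan–Meier method.

    Censoring is treated as the event of interest and death as censoring;
    the median of that flipped curve estimates the median follow-up time.
    Returns ``None`` when it is undefined (e.g. every patient died).
    """
    event = np.asarray(event, dtype=int)
    return km_estimate(time, 1 - event).median


# --------------------------------------------------------------------------
# log-rank
# --------------------------------------------------------------------------

@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p: float


def logrank(time, event, group) -> LogrankResult:
    """k-sample log-rank test; df = k - 1."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    _validate_time_event(time, event)
    labels = np.unique(group)
    if labels.size < 2:
        raise SurvivalDataError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(time, group, event)
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=int(labels.size - 1),
        p=float(res.p_value),
    )


# --------------------------------------------------------------------------
# concordance
# --------------------------------------------------------------------------

def concordance(risk_score, time, event) -> float:
    """Harrell's c-index of a risk score against censored outcomes.

    Higher risk is expected to pair with shorter survival; tied risk
    scores in comparable pairs count one half.
    """
    risk_score = np.asarray(risk_score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if risk_score.shape[0] != time.shape[0]:
        raise SurvivalDataError("risk score and outcome lengths differ")
    if event.sum() == 0:
        raise SurvivalDataError("no comparable pairs: every observation is censored")
    # lifelines orients scores as 'higher predicts longer survival'
    return float(_lifelines_cindex(time, -risk_score, event))


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``coef`` are the log hazard ratios; ``hr`` = exp(coef) with Wald 95%
    confidence limits; ``wald`` = (coef/se)^2 with one df each.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    wald: np.ndarray
    p: np.ndarray
    hr: np.ndarray
    hr_ci: np.ndarray                # (p, 2) lower/upper
    log_partial_likelihood: float
    concordance: float
    converged: bool
    covariance: np.ndarray = field(repr=False, default=None)
    n: int = 0
    n_events: int = 0

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef

    def summary_dict(self) -> dict:
        return {
            "covariates": [
                {
                    "name": nm,
                    "coef": float(b),
                    "se": float(s),
                    "wald": float(w),
                    "p": float(pv),
                    "hr": float(h),
                    "hr_ci": [float(lo), float(hi)],
                }
                for nm, b, s, w, pv, h, (lo, hi) in zip(
                    self.names, self.coef, self.se, self.wald, self.p, self.hr, self.hr_ci
                )
            ],
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "concordance": float(self.concordance),
            "converged": bool(self.converged),
            "n": int(self.n),
            "n_events": int(self.n_events),
        }


def _cox_loglik(beta, data, ties):
    """Breslow/Efron partial log-likelihood with gradient and Hessian.

    ``data`` carries the time-sorted design and tied-event blocks
    (see _prepare_cox).
    """
    Xs, event_blocks = data
    eta = Xs @ beta
    w = np.exp(eta)
    n, p = Xs.shape

    # suffix sums over the (ascending-time) risk sets
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    XX = Xs[:, :, None] * Xs[:, None, :]
    S2 = np.cumsum((w[:, None, None] * XX)[::-1], axis=0)[::-1]

    firsts, d_counts, ev_idx = event_blocks
    ll = float(eta[ev_idx].sum())
    grad = Xs[ev_idx].sum(axis=0)
    hess = np.zeros((p, p))
    if ties == "breslow":
        s0 = S0[firsts]                                  # (B,)
        u = S1[firsts] / s0[:, None]                     # (B, p)
        ll -= float((d_counts * np.log(s0)).sum())
        grad -= (d_counts[:, None] * u).sum(axis=0)
        hess -= np.einsum("b,bij->ij", d_counts, S2[firsts] / s0[:, None, None])
        hess += np.einsum("b,bi,bj->ij", d_counts, u, u)
    else:  # efron
        start = 0
        for f, d in zip(firsts, d_counts):
            idx = ev_idx[start:start + int(d)]
            start += int(d)
            wD = float(w[idx].sum())
            s1D = (w[idx, None] * Xs[idx]).sum(axis=0)
            s2D = (w[idx, None, None] * XX[idx]).sum(axis=0)
            for ell in range(int(d)):
                frac = ell / d
                s0 = S0[f] - frac * wD
                s1 = S1[f] - frac * s1D
                s2 = S2[f] - frac * s2D
                ll -= np.log(s0)
                grad -= s1 / s0
                hess -= s2 / s0 - np.outer(s1 / s0, s1 / s0)
    return ll, grad, hess


def _prepare_cox(X, time, event):
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    # group tied event times; the risk set of an event time starts at the
    # first index carrying a time >= that value
    ev_times = ts[es == 1]
    uniq, d_counts = np.unique(ev_times, return_counts=True)
    firsts = np.searchsorted(ts, uniq, side="left")
    ev_idx = np.flatnonzero(es == 1)   # grouped by time since ts is sorted
    return (Xs, (firsts, d_counts.astype(float), ev_idx)), order


def cox_fit(
    time,
    event,
    X,
    names: list[str] | None = None,
    ties: str = "breslow",
    tol: float = 1e-9,
    max_iter: int = 100,
    compute_concordance: bool = True,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    Maximises the partial likelihood (Breslow tie approximation by
    default, Efron optional) with step-halving whenever a full Newton
    step would decrease the likelihood.  Convergence is declared when the
    largest coefficient update falls below ``tol``.

    Raises
    ------
    DegenerateDesignError
        if a covariate column is constant or the design is exactly
        collinear.
    SurvivalDataError
        if there is no event or the inputs are malformed.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    _validate_time_event(time, event)
    n, p = X.shape
    if n != time.shape[0]:
        raise SurvivalDataError("design matrix and outcome lengths differ")
    if event.sum() == 0:
        raise SurvivalDataError("Cox fit requires at least one event")
    if np.any(~np.isfinite(X)):
        raise SurvivalDataError("design matrix contains non-finite values (missing scores?)")
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    ptp = X.max(axis=0) - X.min(axis=0)
    if np.any(ptp == 0):
        bad = [names[i] for i in np.flatnonzero(ptp == 0)]
        raise DegenerateDesignError(f"degenerate design: constant column(s) {bad}")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise DegenerateDesignError("degenerate design: exactly collinear columns")

    data, _ = _prepare_cox(X, time, event)
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, data, ties)
    converged = False
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guard above
            raise DegenerateDesignError("singular information matrix") from exc
        step = 1.0
        for _half in range(40):
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _cox_loglik(cand, data, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            break
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Cox fit did not converge within the iteration cap", RuntimeWarning)

    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("singular information matrix at optimum") from exc
    se = np.sqrt(np.diag(cov))
    wald = (beta / se) ** 2
    pvals = sps.chi2.sf(wald, df=1)
    z = sps.norm.ppf(0.975)
    hr = np.exp(beta)
    hr_ci = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
    cidx = concordance(X @ beta, time, event) if compute_concordance else float("nan")

    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        wald=wald,
        p=pvals,
        hr=hr,
        hr_ci=hr_ci,
        log_partial_likelihood=float(ll),
        concordance=cidx,
        converged=converged,
        covariance=cov,
        n=n,
        n_events=int(event.sum()),
    )
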