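"""Semi-parametric Cox proportional-hazards core.

Breslow-ties partial likelihood with analytic gradient and Hessian,
Newton-Raphson fitting with step-halving, Breslow baseline cumulative
hazard, and linear-predictor / landmark absolute-risk prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "AbsoluteRisk",
    "ConvergenceError",
    "neg_log_partial_likelihood",
    "breslow_baseline",
    "fit_cox",
    "predict_risk_score",
    "predict_absolute_risk",
]


class ConvergenceError(RuntimeError):
    """Raised when Newton iterations fail to converge.

    Carries the iteration trace (per-iteration log-likelihood values).
    """

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients plus Breslow baseline step function."""

    beta: np.ndarray
    baseline_times: np.ndarray  # jump times of H0 (distinct event times)
    baseline_cumhaz: np.ndarray  # H0 at each jump time, nondecreasing
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan
    # training-fold standardisation, applied transparently at predict time
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def cumhaz_at(self, t: float) -> float:
        """Right-continuous step-function evaluation of H0; H0(0) = 0."""
        if self.baseline_times.size == 0:
            return 0.0
        idx = np.searchsorted(self.baseline_times, t, side="right")
        if idx == 0:
            return 0.0
        return float(self.baseline_cumhaz[idx - 1])


@dataclass
class AbsoluteRisk:
    """Per-patient event probability 1 - S(t*|x) at a landmark horizon."""

    horizon: float
    risk: np.ndarray = field(default_factory=lambda: np.empty(0))


def _prepare(X: np.ndarray, time: np.ndarray, event: np.ndarray):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("predictor matrix contains non-finite values")
    if event.sum() == 0:
        raise ValueError("no events in outcome; partial likelihood undefined")
    # sort descending by time so risk sets are cumulative prefixes;
    # stable sort keeps determinism under ties
    order = np.argsort(-time, kind="stable")
    return X[order], time[order], event[order], order


def neg_log_partial_likelihood(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    beta: np.ndarray,
    compute_hessian: bool = True,
):
    """Breslow-ties negative log partial likelihood with derivatives.

    Returns ``(value, gradient)`` or ``(value, gradient, hessian)``.
    The value is convex in ``beta``; the Hessian is PSD.
    """
    Xs, ts, ds, _ = _prepare(X, time, event)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = Xs @ beta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    # numerically safe exp: subtract max (cancels in every ratio and in the
    # value up to an additive constant we restore explicitly)
    m = eta.max()
    w = np.exp(eta - m)
    s0 = np.cumsum(w)  # S0 over descending times = risk-set sums
    s1 = np.cumsum(w[:, None] * Xs, axis=0)

    # tie groups: with descending order the risk set at time t is the prefix
    # ending at the LAST index carrying that time
    n = ts.size
    boundary = np.r_[ts[1:] != ts[:-1], True]  # True at last member of group
    bidx = np.flatnonzero(boundary)
    last_of_group = bidx[np.searchsorted(bidx, np.arange(n), side="left")]

    ev = ds == 1
    idx = last_of_group[ev]
    log_s0 = np.log(s0[idx]) + m
    value = float(-(eta[ev] - log_s0).sum())
    xbar = s1[idx] / s0[idx, None]
    grad = -(Xs[ev] - xbar).sum(axis=0)
    if not compute_hessian:
        return value, grad
    # Hessian: sum over events of (S2/S0 - (S1/S0)(S1/S0)^T)
    p = Xs.shape[1]
    s2 = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    H = np.zeros((p, p))
    H += (s2[idx] / s0[idx, None, None]).sum(axis=0)
    H -= np.einsum("ij,ik->jk", xbar, xbar)
    return value, grad, H


def breslow_baseline(X, time, event, beta):
    """Breslow cumulative baseline hazard step function at event times.

    H0(t) = sum over event times t_i <= t of d_i / sum_{j in R(t_i)} exp(x_j beta).
    """
    Xs, ts, ds, _ = _prepare(X, time, event)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = Xs @ beta
    m = eta.max()
    w = np.exp(eta - m)
    s0 = np.cumsum(w) * np.exp(m)
    # distinct times descending; event counts and risk-set totals per time
    times_desc = []
    incr = []
    i, n = 0, ts.size
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        d = ds[i : j + 1].sum()
        if d > 0:
            times_desc.append(ts[i])
            incr.append(d / s0[j])
        i = j + 1
    times = np.array(times_desc[::-1])
    cumhaz = np.cumsum(np.array(incr[::-1]))
    return times, cumhaz


def fit_cox(
    X,
    time,
    event,
    tol: float = 1e-8,
    max_iter: int = 50,
    l2: float = 0.0,
    beta_init: np.ndarray | None = None,
) -> CoxFit:
    """Newton-Raphson Cox fit with step-halving and Breslow baseline.

    ``l2`` adds a small ridge penalty (used as a fallback for collinear
    designs). Monotone-likelihood separation is reported as an explicit
    error when coefficients diverge.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    p = X.shape[1]
    if l2 == 0 and np.any(X.std(axis=0) == 0):
        # a ridge fit tolerates constant columns (coefficient pinned at 0)
        raise ValueError("constant predictor column; drop it before fitting")
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, float).copy()
    trace: list[float] = []
    val, grad, H = neg_log_partial_likelihood(X, time, event, beta)
    val += 0.5 * l2 * beta @ beta
    grad = grad + l2 * beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Hp = H + l2 * np.eye(p)
        try:
            step = np.linalg.solve(Hp, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hp, grad, rcond=None)[0]
        # step-halving on likelihood decrease
        alpha = 1.0
        for _ in range(30):
            beta_new = beta - alpha * step
            try:
                val_new, grad_new, H_new = neg_log_partial_likelihood(
                    X, time, event, beta_new
                )
            except (ValueError, FloatingPointError, OverflowError):
                alpha *= 0.5
                continue
            val_new += 0.5 * l2 * beta_new @ beta_new
            if np.isfinite(val_new) and val_new <= val + 1e-12:
                break
            alpha *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed at iteration {it}", trace
            )
        beta, val, H = beta_new, val_new, H_new
        grad = grad_new + l2 * beta
        trace.append(-val)
        eta = X @ beta
        if np.max(np.abs(beta)) > 100 or (eta.max() - eta.min()) > 60:
            raise ConvergenceError(
                "coefficients diverging: monotone likelihood / separation "
                "detected",
                trace,
            )
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations "
            f"(gradient max-norm {np.max(np.abs(grad)):.3e})",
            trace,
        )
    bt, bh = breslow_baseline(X, time, event, beta)
    return CoxFit(
        beta=beta,
        baseline_times=bt,
        baseline_cumhaz=bh,
        converged=True,
        n_iter=it,
        loglik=-val,
    )


def _apply_standardisation(fit: CoxFit, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if fit.center is not None:
        X = (X - fit.center) / fit.scale
    return X


def predict_risk_score(fit: CoxFit, X) -> np.ndarray:
    """Linear predictor x'beta per patient (relative log-hazard)."""
    X = _apply_standardisation(fit, X)
    if X.shape[1] != fit.beta.size:
        raise ValueError(
            f"dimension mismatch: X has {X.shape[1]} columns, fit has "
            f"{fit.beta.size} coefficients"
        )
    return X @ fit.beta


def predict_absolute_risk(fit: CoxFit, X, t_star: float = 1.5) -> AbsoluteRisk:
    """Landmark absolute risk 1 - exp(-H0(t*) exp(x'beta)).

    Beyond the last baseline jump the hazard is held at its last value
    (constant extrapolation) with a logged warning.
    """
    if t_star <= 0:
        raise ValueError("t_star must be positive")
    eta = predict_risk_score(fit, X)
    if fit.baseline_times.size and t_star > fit.baseline_times[-1]:
        logger.warning(
            "t_star=%.3g beyond last observed event time %.3g; using last "
            "baseline value",
            t_star,
            fit.baseline_times[-1],
        )
    H0 = fit.cumhaz_at(t_star)
    risk = 1.0 - np.exp(-H0 * np.exp(eta))
    return AbsoluteRisk(horizon=t_star, risk=risk)
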