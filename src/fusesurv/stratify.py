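"""Outcome-guided three-group risk stratification.

Two cutoffs on the absolute-risk scale are searched over a central
quantile grid by maximising the K-sample log-rank statistic, subject to
minimum group-size and monotone event-rate constraints; fold-specific
cutoffs are averaged and applied to out-of-fold risks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .metrics import km_fit

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffPair",
    "RiskStratification",
    "logrank_chisq",
    "candidate_cutoffs",
    "search_cutoffs",
    "fold_averaged_stratification",
    "group_summary",
    "assign_groups",
]

GROUP_ORDER = ["low", "medium", "high"]


@dataclass
class CutoffPair:
    cutoff_1: float
    cutoff_2: float
    per_fold: list = field(default_factory=list)

    def __post_init__(self):
        if not self.cutoff_1 < self.cutoff_2:
            raise ValueError("cutoffs must satisfy cutoff_1 < cutoff_2")


@dataclass
class RiskStratification:
    groups: np.ndarray  # per-patient label in {low, medium, high}
    cutoffs: CutoffPair
    summary: pd.DataFrame
    logrank: float
    degenerate: bool = False


def logrank_chisq(groups, time, event) -> float:
    """K-sample log-rank chi-square statistic (df = K - 1).

    At each distinct event time the observed minus hypergeometric-expected
    event counts per group accumulate into O; the statistic is O' V^-1 O
    over the first K-1 groups. Invariant under group relabelling.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    labels = np.unique(groups)
    K = labels.size
    if K < 2:
        raise ValueError("log-rank needs at least 2 groups")
    g_idx = np.searchsorted(labels, groups)
    n = time.size
    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], g_idx[order]
    onehot = np.zeros((n, K))
    onehot[np.arange(n), g_s] = 1.0
    # at-risk counts per group just before each unique time (suffix sums)
    suffix = np.cumsum(onehot[::-1], axis=0)[::-1]
    starts = np.flatnonzero(np.r_[True, t_s[1:] != t_s[:-1]])
    ends = np.r_[starts[1:], n] - 1
    n_g_mat = suffix[starts]  # (U, K)
    # events per group within each tie block (segment sums)
    cum = np.cumsum(onehot * e_s[:, None], axis=0)
    d_g_mat = cum[ends].copy()
    d_g_mat[1:] -= cum[ends[:-1]]
    d_t = d_g_mat.sum(axis=1)
    keep = d_t > 0
    n_g_mat, d_g_mat, d_t = n_g_mat[keep], d_g_mat[keep], d_t[keep]
    n_t = n_g_mat.sum(axis=1)
    frac = n_g_mat / n_t[:, None]
    O = d_g_mat.sum(axis=0)
    E = (d_t[:, None] * frac).sum(axis=0)
    mult = np.where(n_t > 1, d_t * (n_t - d_t) / np.maximum(n_t - 1, 1), 0.0)
    V = np.diag((mult[:, None] * frac).sum(axis=0)) - frac.T @ (
        mult[:, None] * frac
    )
    z = (O - E)[: K - 1]
    Vr = V[: K - 1, : K - 1]
    try:
        stat = float(z @ np.linalg.solve(Vr, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vr) @ z)
    return stat


def candidate_cutoffs(scores, search_range=(0.15, 0.85), step=0.025):
    """All ordered pairs from a quantile grid over the central score range."""
    scores = np.asarray(scores, float)
    lo, hi = search_range
    qs = np.arange(lo, hi + 1e-12, step)
    pts = np.unique(np.quantile(scores, qs))
    if pts.size < 2:
        raise ValueError(
            "fewer than 2 distinct quantile grid points (degenerate scores)"
        )
    return [CutoffPair(float(a), float(b)) for a, b in combinations(pts, 2)]


def assign_groups(scores, c1: float, c2: float) -> np.ndarray:
    scores = np.asarray(scores, float)
    out = np.where(scores <= c1, "low", np.where(scores <= c2, "medium", "high"))
    return out


def search_cutoffs(
    scores,
    time,
    event,
    min_fraction: float = 0.15,
    search_range=(0.15, 0.85),
    step: float = 0.025,
    require_monotone: bool = True,
) -> CutoffPair:
    """Log-rank-maximising cutoff pair under group-size and monotone
    event-rate constraints; ties broken toward the tercile quantiles."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = scores.size
    if 3 * min_fraction > 1.0:
        raise ValueError(
            f"min_fraction={min_fraction} infeasible: 3 groups need "
            f"3*min_fraction <= 1"
        )
    cands = candidate_cutoffs(scores, search_range, step)
    terciles = np.quantile(scores, [1 / 3, 2 / 3])

    def scan(check_monotone):
        best = None
        best_stat = -np.inf
        best_dist = np.inf
        size_fail = mono_fail = 0
        for cp in cands:
            g = assign_groups(scores, cp.cutoff_1, cp.cutoff_2)
            counts = [int((g == k).sum()) for k in GROUP_ORDER]
            if min(counts) < min_fraction * n:
                size_fail += 1
                continue
            rates = [event[g == k].mean() for k in GROUP_ORDER]
            if check_monotone and not (rates[0] <= rates[1] <= rates[2]):
                mono_fail += 1
                continue
            stat = logrank_chisq(g, time, event)
            dist = abs(cp.cutoff_1 - terciles[0]) + abs(cp.cutoff_2 - terciles[1])
            if stat > best_stat + 1e-12 or (
                abs(stat - best_stat) <= 1e-12 and dist < best_dist
            ):
                best, best_stat, best_dist = cp, stat, dist
        return best, size_fail, mono_fail

    best, n_size_fail, n_mono_fail = scan(require_monotone)
    if best is None and require_monotone and n_mono_fail > 0:
        # monotone ordering is a preference, not a hard constraint: with
        # weak separation every size-feasible pair can fail it
        logger.warning(
            "no cutoff pair with monotone event rates; relaxing the "
            "monotonicity requirement"
        )
        best, n_size_fail, n_mono_fail = scan(False)
    if best is None:
        raise ValueError(
            "no feasible cutoff pair: "
            f"{n_size_fail} candidates violated the minimum group size, "
            f"{n_mono_fail} violated monotone event-rate ordering"
        )
    return best


def group_summary(groups, time, event) -> pd.DataFrame:
    """Per-group n, events, event rate, and KM median survival."""
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    rows = []
    for k in GROUP_ORDER:
        mask = groups == k
        if not mask.any():
            continue
        n_k = int(mask.sum())
        ev_k = int(event[mask].sum())
        km = km_fit(time[mask], event[mask])
        med = km.median()
        rows.append(
            {
                "risk_group": k,
                "n": n_k,
                "events": ev_k,
                "event_rate": ev_k / n_k,
                "km_median": med if np.isfinite(med) else np.nan,
                "km_median_reached": bool(np.isfinite(med)),
            }
        )
    return pd.DataFrame(rows)


def fold_averaged_stratification(
    oof_risks,
    folds,
    time,
    event,
    min_fraction: float = 0.15,
    search_range=(0.15, 0.85),
    step: float = 0.025,
) -> RiskStratification:
    """Per-fold training-set cutoff search, arithmetic-mean cutoffs,
    held-out assignment via each patient's out-of-fold risk."""
    oof_risks = np.asarray(oof_risks, float)
    folds = np.asarray(folds)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    per_fold = []
    for f in np.unique(folds):
        tr = folds != f
        try:
            cp = search_cutoffs(
                oof_risks[tr],
                time[tr],
                event[tr],
                min_fraction=min_fraction,
                search_range=search_range,
                step=step,
            )
        except ValueError as exc:
            raise ValueError(f"cutoff search failed on fold {f}: {exc}") from exc
        per_fold.append((cp.cutoff_1, cp.cutoff_2))
    c1 = float(np.mean([a for a, _ in per_fold]))
    c2 = float(np.mean([b for _, b in per_fold]))
    groups = assign_groups(oof_risks, c1, c2)
    summary = group_summary(groups, time, event)
    degenerate = summary.shape[0] < 2
    if degenerate:
        stat = np.nan
    else:
        stat = logrank_chisq(groups, time, event)
    return RiskStratification(
        groups=groups,
        cutoffs=CutoffPair(c1, c2, per_fold=per_fold),
        summary=summary,
        logrank=stat,
        degenerate=degenerate,
    )
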