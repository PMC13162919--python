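"""Seeded synthetic survival cohorts with block-correlated feature families.

The generator emulates the structure the downstream analysis assumes:
demographics (age, gender), ordinal staging, 107 radiomic features in 7
correlated families, and a Weibull proportional-hazards outcome with an
independently calibrated exponential censoring distribution.

Radiomic effect vectors act on the unit-variance latent scale; the raw
columns carry per-family affine shifts so families have distinct scales,
which fold-specific standardisation must undo downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "CohortTable", "generate_cohort", "DEFAULT_FAMILY_SIZES"]

# standard radiomic taxonomy; only the 107 total is externally fixed
DEFAULT_FAMILY_SIZES = {
    "FirstOrder": 18,
    "Shape": 14,
    "GLCM": 24,
    "GLRLM": 16,
    "GLSZM": 16,
    "GLDM": 14,
    "NGTDM": 5,
}

# T/N stage distributions conditional on overall stage (synthetic
# convention; the joint distribution is not reproduced from any source)
_T_GIVEN_STAGE = {
    1: {1: 0.6, 2: 0.4},
    2: {1: 0.2, 2: 0.5, 3: 0.3},
    3: {2: 0.3, 3: 0.4, 4: 0.3},
}
_N_GIVEN_STAGE = {
    1: {0: 0.9, 1: 0.1},
    2: {0: 0.5, 1: 0.5},
    3: {1: 0.3, 2: 0.4, 3: 0.3},
}


def _default_group_effects() -> dict:
    # sparse group-structured signal concentrated in the smallest family
    return {"NGTDM": [-0.35, 0.35, 0.25, 0.15, -0.10]}


@dataclass
class CohortSpec:
    """Generative parameters; defaults emulate the target cohort structure."""

    n_patients: int = 398
    stage_probs: tuple = (0.211, 0.093, 0.696)
    age_mean: float = 68.1
    age_sd: float = 10.1
    male_prob: float = 0.686
    family_sizes: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_SIZES))
    within_family_corr: float = 0.5
    true_group_effects: dict = field(default_factory=_default_group_effects)
    clinical_effects: tuple = (0.30, 0.08, 0.08)  # stage, T, N (ordinal)
    demographic_effects: tuple = (0.25, 0.20)  # age per SD, male indicator
    baseline_shape: float = 1.2
    baseline_scale: float | None = None  # None: median event time 1.5 y
    target_censoring: float = 0.118
    include_tumor_count: bool = False
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if abs(sum(self.stage_probs) - 1.0) > 1e-8 or min(self.stage_probs) < 0:
            raise ValueError("stage_probs must be a probability triple summing to 1")
        if any(v <= 0 for v in self.family_sizes.values()):
            raise ValueError("family sizes must be positive")
        if not (0 <= self.within_family_corr < 1):
            raise ValueError("within_family_corr must lie in [0, 1)")
        if not (0 <= self.target_censoring < 1):
            raise ValueError("target_censoring must lie in [0, 1)")
        for fam, eff in self.true_group_effects.items():
            if fam not in self.family_sizes:
                raise ValueError(f"effect family {fam!r} not in family_sizes")
            if len(eff) != self.family_sizes[fam]:
                raise ValueError(
                    f"effect vector for {fam!r} has length {len(eff)}, "
                    f"family has {self.family_sizes[fam]} features"
                )

    @property
    def scale(self) -> float:
        if self.baseline_scale is not None:
            return self.baseline_scale
        return 1.5 / np.log(2.0) ** (1.0 / self.baseline_shape)


@dataclass
class CohortTable:
    """Patient-level table plus the feature -> family taxonomy."""

    data: pd.DataFrame
    taxonomy: dict
    feature_names: list

    @property
    def time(self) -> np.ndarray:
        return self.data["time_years"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    def features(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy()

    def validate(self):
        if self.data.isna().any().any():
            raise ValueError("cohort table contains missing values")
        if set(self.feature_names) != set(self.taxonomy):
            raise ValueError("taxonomy does not cover the feature columns exactly")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be strictly positive")
        if not set(np.unique(self.event)).issubset({0, 1}):
            raise ValueError("event must be coded 0/1")


def _expected_ordinal(table: dict, stage_probs) -> float:
    return sum(
        p * sum(k * q for k, q in table[s].items())
        for s, p in zip((1, 2, 3), stage_probs)
    )


def _draw_conditional(rng, stages, table):
    out = np.empty(stages.size, dtype=int)
    for s, dist in table.items():
        mask = stages == s
        ks = np.array(list(dist))
        ps = np.array(list(dist.values()))
        out[mask] = rng.choice(ks, size=int(mask.sum()), p=ps)
    return out


def linear_predictor(spec: CohortSpec, Z: np.ndarray, stage, t_stage, n_stage,
                     age, male) -> np.ndarray:
    """Centered log-hazard linear predictor of the generating model."""
    fams = list(spec.family_sizes)
    lp = np.zeros(Z.shape[0])
    col = 0
    for fam in fams:
        p_f = spec.family_sizes[fam]
        eff = spec.true_group_effects.get(fam)
        if eff is not None:
            lp += Z[:, col : col + p_f] @ np.asarray(eff, float)
        col += p_f
    c1, c2, c3 = spec.clinical_effects
    probs = spec.stage_probs
    e_stage = sum(k * p for k, p in zip((1, 2, 3), probs))
    lp += c1 * (stage - e_stage)
    lp += c2 * (t_stage - _expected_ordinal(_T_GIVEN_STAGE, probs))
    lp += c3 * (n_stage - _expected_ordinal(_N_GIVEN_STAGE, probs))
    d1, d2 = spec.demographic_effects
    lp += d1 * (age - spec.age_mean) / spec.age_sd
    lp += d2 * (male - spec.male_prob)
    return lp


def event_time_quantile(spec: CohortSpec, lp, q) -> np.ndarray:
    """Inverse CDF of the Weibull PH event-time distribution given lp."""
    return spec.scale * (-np.log(1.0 - np.asarray(q)) / np.exp(lp)) ** (
        1.0 / spec.baseline_shape
    )


def true_absolute_risk(spec: CohortSpec, lp, t_star: float) -> np.ndarray:
    """Generating-model event probability by t_star (no censoring)."""
    H0 = (t_star / spec.scale) ** spec.baseline_shape
    return 1.0 - np.exp(-H0 * np.exp(lp))


def _calibrate_censoring_rate(spec: CohortSpec, pilot_times: np.ndarray) -> float:
    """Bisection for the exponential censoring rate giving the target
    expected censored fraction E[1 - exp(-rate * T)]."""
    target = spec.target_censoring
    if target == 0:
        return 0.0

    def frac(rate):
        return float(np.mean(-np.expm1(-rate * pilot_times)))

    lo, hi = 1e-10, 1e4
    f_lo, f_hi = frac(lo), frac(hi)
    if not (f_lo <= target <= f_hi):
        raise ValueError(
            f"target censoring {target} unreachable; achievable range with "
            f"this baseline is [{f_lo:.4g}, {f_hi:.4g}]"
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort. Same spec (incl. seed) gives byte-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    fams = list(spec.family_sizes)

    stage = rng.choice([1, 2, 3], size=n, p=list(spec.stage_probs))
    t_stage = _draw_conditional(rng, stage, _T_GIVEN_STAGE)
    n_stage = _draw_conditional(rng, stage, _N_GIVEN_STAGE)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    male = (rng.random(n) < spec.male_prob).astype(int)

    # equicorrelated blocks: z = sqrt(rho) u 1 + sqrt(1-rho) eps
    rho = spec.within_family_corr
    blocks = []
    for fam in fams:
        p_f = spec.family_sizes[fam]
        u = rng.normal(size=(n, 1))
        eps = rng.normal(size=(n, p_f))
        blocks.append(np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps)
    Z = np.hstack(blocks)

    lp = linear_predictor(spec, Z, stage, t_stage, n_stage, age, male)
    # Weibull PH: S(t|x) = exp(-(t/scale)^shape * e^lp)
    T = event_time_quantile(spec, lp, rng.random(n))
    T = np.maximum(T, 1e-6)

    # pilot sample for censoring calibration, using the marginal lp
    # distribution via resampling the cohort's linear predictors
    pilot_idx = rng.integers(0, n, 50_000)
    pilot = event_time_quantile(spec, lp[pilot_idx], rng.random(50_000))
    rate = _calibrate_censoring_rate(spec, pilot)
    if rate > 0:
        C = rng.exponential(1.0 / rate, size=n)
    else:
        C = np.full(n, np.inf)
    obs_time = np.minimum(T, C)
    event = (T <= C).astype(int)

    # per-family affine shifts -> distinct raw scales
    X = np.empty_like(Z)
    col = 0
    feature_names = []
    taxonomy = {}
    for k, fam in enumerate(fams):
        p_f = spec.family_sizes[fam]
        scale_f = 1.0 + 2.0 * k
        loc_f = 10.0 * k
        X[:, col : col + p_f] = loc_f + scale_f * Z[:, col : col + p_f]
        for j in range(p_f):
            name = f"{fam}_{j + 1:02d}"
            feature_names.append(name)
            taxonomy[name] = fam
        col += p_f

    data = pd.DataFrame(
        {
            "id": [f"P{i + 1:05d}" for i in range(n)],
            "time_years": obs_time,
            "event": event,
            "age": age,
            "gender": np.where(male == 1, "male", "female"),
            "overall_stage": stage,
            "t_stage": t_stage,
            "n_stage": n_stage,
        }
    )
    if spec.include_tumor_count:
        data["tumor_count"] = 1 + rng.poisson(0.1, size=n)
    data = pd.concat(
        [data, pd.DataFrame(X, columns=feature_names, index=data.index)], axis=1
    )
    table = CohortTable(data=data, taxonomy=taxonomy, feature_names=feature_names)
    table.validate()
    return table
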