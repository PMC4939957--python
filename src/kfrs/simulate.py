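"""Synthetic cohort generator with a proportional-subdistribution-hazard DGP.

The generator emulates a national health-screening cohort aged 50-90:
covariates are drawn independently from the published marginal
frequencies, and fracture outcomes follow the classic indirect
competing-risks construction in which the event-of-interest
subdistribution is a unit-exponential mixture,

    F1(t | x) = 1 - [1 - p_base * (1 - exp(-t))]^exp(x' beta),

so the subdistribution hazard is exactly proportional in exp(x'beta)
and the true coefficient vector is recoverable by a Fine-Gray fit.
A subject is a fracture case with probability F1(inf | x)
= 1 - (1 - p_base)^exp(x'beta); otherwise the first event is death at an
exponential time whose rate may rise with age band.  Independent
censoring is the minimum of an administrative cut-off and an exponential
drop-out time.

``p_base`` defaults are calibrated so that the 7-year fracture CIF of the
reference stratum equals the published reference-profile absolute risks
(2.14% men, 7.49% women): with unit-exponential mixing,
F1(7 | ref) = p_base * (1 - e^-7), hence p_base = anchor / (1 - e^-7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    AGE_BANDS,
    BMI_BANDS,
    COVARIATE_NAMES,
    FEMALE,
    FLAG_NAMES,
    MALE,
    N_COVARIATES,
    Cohort,
)

# ---------------------------------------------------------------------------
# Published study constants (total-cohort marginal frequencies, sHRs, anchors)
# ---------------------------------------------------------------------------


def _normalized(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return p / p.sum()


#: Marginal covariate frequencies of the source cohort (total, by sex).
#: Band proportions are normalized so each block sums to exactly 1.
TABLE1_FREQS: dict[str, dict] = {
    MALE: {
        "age_bands": _normalized([0.5523, 0.3101, 0.1211, 0.0164]),
        "bmi_bands": _normalized([0.0248, 0.3331, 0.2871, 0.3551]),
        "flags": {
            "recent_fracture": 0.0049,
            "current_smoking": 0.3887,
            "high_alcohol": 0.1344,
            "weekly_exercise": 0.5098,
            "recent_glucocorticoid": 0.0079,
            "rheumatoid_arthritis": 0.0117,
            "secondary_osteoporosis": 0.2133,
        },
    },
    FEMALE: {
        "age_bands": _normalized([0.5036, 0.3267, 0.1489, 0.0209]),
        "bmi_bands": _normalized([0.0207, 0.3293, 0.2664, 0.3837]),
        "flags": {
            "recent_fracture": 0.0162,
            "current_smoking": 0.0281,
            "high_alcohol": 0.0166,
            "weekly_exercise": 0.3751,
            "recent_glucocorticoid": 0.0102,
            "rheumatoid_arthritis": 0.0328,
            "secondary_osteoporosis": 0.2436,
        },
    },
}

#: Published subdistribution hazard ratios, in covariate order.
TABLE3_SHR: dict[str, dict[str, float]] = {
    MALE: {
        "age_60_69": 2.02, "age_70_79": 3.94, "age_80_89": 5.66,
        "bmi_lt_18_5": 1.65, "bmi_23_24_9": 0.82, "bmi_ge_25": 0.79,
        "recent_fracture": 3.53, "current_smoking": 1.08, "high_alcohol": 1.37,
        "weekly_exercise": 0.76, "recent_glucocorticoid": 1.87,
        "rheumatoid_arthritis": 1.29, "secondary_osteoporosis": 1.10,
    },
    FEMALE: {
        "age_60_69": 2.15, "age_70_79": 3.61, "age_80_89": 4.72,
        "bmi_lt_18_5": 1.12, "bmi_23_24_9": 0.95, "bmi_ge_25": 0.89,
        "recent_fracture": 1.83, "current_smoking": 1.15, "high_alcohol": 1.20,
        "weekly_exercise": 0.87, "recent_glucocorticoid": 1.51,
        "rheumatoid_arthritis": 1.06, "secondary_osteoporosis": 1.07,
    },
}

#: Published 7-year absolute risk of the reference profile, by sex.
ANCHOR_RISK = {MALE: 0.0214, FEMALE: 0.0749}

#: Baseline all-cause death rates (per year, age 50-59) — artifact choices;
#: the source study reports no mortality rates.
DEFAULT_DEATH_RATE = {MALE: 0.008, FEMALE: 0.005}
DEFAULT_DEATH_AGE_MULTIPLIERS = (1.0, 2.0, 4.0, 8.0)
DEFAULT_DROPOUT_RATE = 0.01


def default_true_beta(sex: str) -> np.ndarray:
    """ln(sHR) in covariate order — the generator's default truth."""
    return np.log([TABLE3_SHR[sex][name] for name in COVARIATE_NAMES])


def default_p_base(sex: str, horizon: float = 7.0) -> float:
    """Mixture parameter giving F1(horizon | reference) = anchor risk."""
    return ANCHOR_RISK[sex] / -math.expm1(-horizon)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data-generating process."""

    n: int
    sex: str
    age_band_probs: np.ndarray = None
    bmi_band_probs: np.ndarray = None
    flag_probs: dict[str, float] = None
    true_beta: np.ndarray = None
    p_base: float = None
    death_rate: float = None
    death_age_multipliers: tuple = DEFAULT_DEATH_AGE_MULTIPLIERS
    admin_censor: float = 7.0
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        freqs = TABLE1_FREQS[self.sex]
        if self.age_band_probs is None:
            self.age_band_probs = freqs["age_bands"].copy()
        if self.bmi_band_probs is None:
            self.bmi_band_probs = freqs["bmi_bands"].copy()
        if self.flag_probs is None:
            self.flag_probs = dict(freqs["flags"])
        if self.true_beta is None:
            self.true_beta = default_true_beta(self.sex)
        if self.p_base is None:
            self.p_base = default_p_base(self.sex)
        if self.death_rate is None:
            self.death_rate = DEFAULT_DEATH_RATE[self.sex]

        self.age_band_probs = np.asarray(self.age_band_probs, dtype=float)
        self.bmi_band_probs = np.asarray(self.bmi_band_probs, dtype=float)
        self.true_beta = np.asarray(self.true_beta, dtype=float)
        for name, probs, k in (
            ("age_band_probs", self.age_band_probs, len(AGE_BANDS)),
            ("bmi_band_probs", self.bmi_band_probs, len(BMI_BANDS)),
        ):
            if probs.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"{name} must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9, got {probs.sum()!r}")
        for name in FLAG_NAMES:
            p = self.flag_probs.get(name)
            if p is None:
                raise ValueError(f"flag_probs is missing {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"flag probability {name}={p} outside [0, 1]")
        if self.true_beta.shape != (N_COVARIATES,):
            raise ValueError(f"true_beta must have length {N_COVARIATES}")
        if not 0.0 < self.p_base < 1.0:
            raise ValueError("p_base must lie in (0, 1)")
        if self.death_rate < 0 or self.dropout_rate < 0:
            raise ValueError("rates must be >= 0")
        if len(self.death_age_multipliers) != len(AGE_BANDS):
            raise ValueError("death_age_multipliers must have one entry per age band")
        if self.admin_censor <= 0:
            raise ValueError("admin_censor must be positive")


def sample_covariates(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw an (n, 13) covariate matrix from independent marginals."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    X = np.zeros((n, N_COVARIATES), dtype=np.float64)
    age_idx = rng.choice(len(AGE_BANDS), size=n, p=config.age_band_probs)
    bmi_idx = rng.choice(len(BMI_BANDS), size=n, p=config.bmi_band_probs)
    for k in range(1, 4):  # reference band 50-59 -> no dummy
        X[:, k - 1] = age_idx == k
    # BMI dummy columns: <18.5 -> 3, 23-24.9 -> 4, >=25 -> 5 (reference 18.5-22.9 = index 1)
    for band_idx, col in ((0, 3), (2, 4), (3, 5)):
        X[:, col] = bmi_idx == band_idx
    for k, name in enumerate(FLAG_NAMES):
        X[:, 6 + k] = rng.random(n) < config.flag_probs[name]
    return X


def fracture_cif(t, x, config: SimulationConfig):
    """Closed-form fracture CIF F1(t | x) of the generating process."""
    eta = np.asarray(x, dtype=float) @ config.true_beta
    inner = 1.0 - config.p_base * -np.expm1(-np.asarray(t, dtype=float))
    return 1.0 - inner ** np.exp(eta)


def simulate_outcomes(
    covariates: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Draw event times/types for given covariates and assemble a Cohort.

    Fracture status and (conditional) fracture time come from one uniform
    draw per subject by CIF inversion; non-fracture subjects get an
    exponential death time whose rate is ``death_rate`` times the age-band
    multiplier.  Censoring is min(admin_censor, exponential drop-out).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.asarray(covariates, dtype=np.float64)
    n = X.shape[0]
    p = config.p_base

    eta = X @ config.true_beta
    exp_eta = np.exp(eta)
    # lifetime fracture probability under the subdistribution mixture
    p_frac = -np.expm1(exp_eta * np.log1p(-p))

    u = rng.random(n)
    is_frac = u < p_frac
    # invert F1(t|x) = u  =>  t = -log(1 - (1 - (1-u)^{1/exp_eta}) / p)
    uu = u[is_frac]
    inner = np.expm1(np.log1p(-uu) / exp_eta[is_frac])  # (1-u)^{1/e^eta} - 1 in (-p, 0)
    t_frac = -np.log1p(inner / p)

    t_event = np.empty(n)
    t_event[is_frac] = t_frac
    # competing death for non-fracture subjects
    age_idx = np.zeros(n, dtype=int)
    for k in range(3):
        age_idx[X[:, k] == 1] = k + 1
    mult = np.asarray(config.death_age_multipliers, dtype=float)[age_idx]
    n_other = int((~is_frac).sum())
    if config.death_rate > 0:
        t_event[~is_frac] = rng.exponential(1.0, size=n_other) / (
            config.death_rate * mult[~is_frac]
        )
    else:
        rng.exponential(1.0, size=n_other)  # keep the stream aligned
        t_event[~is_frac] = np.inf

    # independent censoring
    censor = np.full(n, config.admin_censor)
    if config.dropout_rate > 0:
        censor = np.minimum(censor, rng.exponential(1.0 / config.dropout_rate, size=n))

    observed = np.minimum(t_event, censor)
    event = np.where(t_event <= censor, np.where(is_frac, 1, 2), 0)
    # guard against zero times from floating underflow
    observed = np.maximum(observed, 1e-12)

    width = len(str(n))
    ids = np.array([f"s{i:0{width}d}" for i in range(n)], dtype=object)
    return Cohort(sex=config.sex, ids=ids, X=X, time=observed, event=event)


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Covariates + outcomes in one reproducible call (seeded by config)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = sample_covariates(config, rng)
    return simulate_outcomes(X, config, rng)
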