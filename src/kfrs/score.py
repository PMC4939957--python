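"""The KFRS calculator: published coefficients -> 7-year absolute risk.

The calculator is parameterised by an *anchor*: the absolute 7-year
fracture risk of the reference profile (age 50-59, BMI 18.5-22.9 kg/m2,
no clinical risk factors).  Converting the anchor to a cumulative
subdistribution hazard H_ref = -ln(1 - anchor) and multiplying by the
sHR of every active non-reference covariate level gives

    risk = 1 - exp(-H_ref * prod_k sHR_k^{x_k}),

an exact reparameterisation of the mean-centered cumulative-incidence
form 1 - exp(-exp(sum_k beta_k (x_k - M_k)) * S(t)): both reduce to
1 - exp(-exp(x'beta) * c) with the constant c pinned by the reference
profile, so no covariate means or baseline hazard value are needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import (
    AGE_BANDS,
    COVARIATE_NAMES,
    FLAG_NAMES,
    REFERENCE_BMI,
    SEXES,
    RiskProfile,
    encode_profile,
)
from .finegray import FineGrayFit, predict_cif

#: Display labels for the single-risk-factor table rows, in covariate order.
FACTOR_LABELS = {
    "recent_fracture": "Recent fragility fracture",
    "current_smoking": "Current smoking",
    "high_alcohol": "High alcohol intake",
    "weekly_exercise": "Weekly exercise of one or more times",
    "recent_glucocorticoid": "Recent use of oral glucocorticoids",
    "rheumatoid_arthritis": "Rheumatoid arthritis",
    "secondary_osteoporosis": "Other causes of secondary osteoporosis",
}


@dataclass(frozen=True)
class CoefficientSet:
    """Per-sex log-sHRs plus the reference-profile anchor risk.

    Reference levels carry an implicit log-sHR of 0 and are absent from
    ``log_shr``.
    """

    sex: str
    log_shr: dict[str, float]
    anchor_risk: float
    horizon: float = 7.0
    version: str = "unversioned"

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if not 0.0 < self.anchor_risk < 1.0:
            raise ValueError("anchor_risk must lie in (0, 1)")
        unknown = set(self.log_shr) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariate levels in log_shr: {sorted(unknown)}")

    def shr(self, name: str) -> float:
        return math.exp(self.log_shr.get(name, 0.0))


@dataclass(frozen=True)
class RiskResult:
    """Absolute risk with its multiplicative factor breakdown."""

    risk_pct: float
    hazard_multiplier: float
    components: dict[str, float]
    horizon: float


def published_coefficients(sex: str) -> CoefficientSet:
    """The frozen published model for one sex (shipped as JSON data)."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    raw = json.loads(
        resources.files("kfrs.data").joinpath("published_coefficients.json").read_text()
    )
    block = raw[sex]
    return CoefficientSet(
        sex=sex,
        log_shr={k: math.log(v) for k, v in block["shr"].items()},
        anchor_risk=block["anchor_risk"],
        horizon=float(raw["horizon_years"]),
        version=raw["version"],
    )


def coefficients_from_fit(fit: FineGrayFit, sex: str, horizon: float = 7.0) -> CoefficientSet:
    """Anchor a fitted model: the reference profile's predicted risk at the
    horizon becomes the anchor, the fitted betas become the log-sHRs."""
    reference = np.zeros(len(fit.names))
    anchor = float(predict_cif(fit, reference, horizon))
    return CoefficientSet(
        sex=sex,
        log_shr={name: float(b) for name, b in zip(fit.names, fit.beta)},
        anchor_risk=anchor,
        horizon=horizon,
        version="fitted",
    )


def kfrs_risk(profile: RiskProfile, coeffs: CoefficientSet | None = None) -> RiskResult:
    """7-year absolute osteoporotic-fracture risk for one profile."""
    if coeffs is None:
        coeffs = published_coefficients(profile.sex)
    if profile.sex != coeffs.sex:
        raise ValueError(
            f"profile sex {profile.sex!r} does not match coefficient sex {coeffs.sex!r}"
        )
    x = encode_profile(profile)
    h_ref = -math.log1p(-coeffs.anchor_risk)
    components = {
        name: coeffs.shr(name) for name, active in zip(COVARIATE_NAMES, x) if active
    }
    multiplier = math.exp(sum(coeffs.log_shr.get(n, 0.0) for n in components))
    risk = -math.expm1(-h_ref * multiplier)
    return RiskResult(
        risk_pct=100.0 * risk,
        hazard_multiplier=multiplier,
        components=components,
        horizon=coeffs.horizon,
    )


def round_half_up(value: float, decimals: int = 2) -> float:
    """Half-up rounding used when printing risks (matches the published tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def risk_table_by_age(coeffs: CoefficientSet, rounded: bool = True) -> pd.DataFrame:
    """Risk (%) by age band for no factor and each single factor, normal BMI.

    Rows: "None" plus the seven clinical risk factors; columns: the four
    age bands.  Each cell is the absolute risk for a profile with normal
    BMI, that single factor, and the column's age band.
    """
    rows = {}
    for label, flag in [("None", None)] + [
        (FACTOR_LABELS[f], f) for f in FLAG_NAMES
    ]:
        cells = []
        for age in AGE_BANDS:
            kwargs = {flag: True} if flag else {}
            profile = RiskProfile(
                sex=coeffs.sex, age_band=age, bmi_band=REFERENCE_BMI, **kwargs
            )
            pct = kfrs_risk(profile, coeffs).risk_pct
            cells.append(round_half_up(pct) if rounded else pct)
        rows[label] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(AGE_BANDS))


def risk_by_factor_count(
    coeffs: CoefficientSet, age_band: str, ordering: list[str]
) -> list[float]:
    """Cumulative risks (%) as risk factors are added in a given order.

    The published figure of risk versus number of factors does not state
    which factor combinations were used, so the ordering must be given
    explicitly.  Element k is the risk with the first k factors present
    (element 0 has none), at the given age band and normal BMI.
    """
    unknown = [f for f in ordering if f not in FLAG_NAMES]
    if unknown:
        raise ValueError(f"unknown risk factor(s) {unknown}; choose from {FLAG_NAMES}")
    if len(set(ordering)) != len(ordering):
        raise ValueError("ordering contains duplicate factors")
    out = []
    active: dict[str, bool] = {}
    for k in range(len(ordering) + 1):
        profile = RiskProfile(
            sex=coeffs.sex, age_band=age_band, bmi_band=REFERENCE_BMI, **active
        )
        out.append(kfrs_risk(profile, coeffs).risk_pct)
        if k < len(ordering):
            active[ordering[k]] = True
    return out
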