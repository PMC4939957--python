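"""Domain types, covariate coding and cohort I/O.

The risk model works on nine clinical variables assessed at a routine
health check: age band, BMI band, and seven binary clinical risk factors
(recent fragility fracture, current smoking, high alcohol intake, weekly
exercise, recent oral glucocorticoid use, rheumatoid arthritis, other
causes of secondary osteoporosis).  Age and BMI are modelled only as
bands, with age 50-59 and BMI 18.5-22.9 kg/m2 as reference levels, so a
profile encodes to a length-13 dummy vector that is all zero for the
reference profile.

A cohort row carries the encoded covariates, follow-up time in years and
an event code: 0 = censored, 1 = osteoporotic fracture (the event of
interest), 2 = death (the competing event).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

AGE_BANDS = ("50-59", "60-69", "70-79", "80-89")
BMI_BANDS = ("<18.5", "18.5-22.9", "23-24.9", ">=25")
REFERENCE_AGE = AGE_BANDS[0]
REFERENCE_BMI = BMI_BANDS[1]

FLAG_NAMES = (
    "recent_fracture",
    "current_smoking",
    "high_alcohol",
    "weekly_exercise",
    "recent_glucocorticoid",
    "rheumatoid_arthritis",
    "secondary_osteoporosis",
)

#: Column order of the encoded covariate vector (one sex at a time).
COVARIATE_NAMES = (
    "age_60_69",
    "age_70_79",
    "age_80_89",
    "bmi_lt_18_5",
    "bmi_23_24_9",
    "bmi_ge_25",
) + FLAG_NAMES

N_COVARIATES = len(COVARIATE_NAMES)

# Unicode spellings that may appear in hand-written files.
_BAND_ALIASES = {
    "50–59": "50-59",
    "60–69": "60-69",
    "70–79": "70-79",
    "80–89": "80-89",
    "18.5–22.9": "18.5-22.9",
    "23–24.9": "23-24.9",
    "23-24.9": "23-24.9",
    "≥25": ">=25",
    "≥ 25": ">=25",
}

_BMI_DUMMY_INDEX = {"<18.5": 3, "23-24.9": 4, ">=25": 5}

#: Default study horizon in years (administrative censoring).
HORIZON_YEARS = 7.0


def _canonical_band(value: str, allowed: tuple[str, ...], what: str) -> str:
    v = _BAND_ALIASES.get(str(value).strip(), str(value).strip())
    if v not in allowed:
        raise ValueError(f"unknown {what} {value!r}; expected one of {allowed}")
    return v


@dataclass(frozen=True)
class RiskProfile:
    """One person's covariate levels for scoring."""

    sex: str
    age_band: str = REFERENCE_AGE
    bmi_band: str = REFERENCE_BMI
    recent_fracture: bool = False
    current_smoking: bool = False
    high_alcohol: bool = False
    weekly_exercise: bool = False
    recent_glucocorticoid: bool = False
    rheumatoid_arthritis: bool = False
    secondary_osteoporosis: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        object.__setattr__(
            self, "age_band", _canonical_band(self.age_band, AGE_BANDS, "age band")
        )
        object.__setattr__(
            self, "bmi_band", _canonical_band(self.bmi_band, BMI_BANDS, "BMI band")
        )
        for name in FLAG_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (bool, np.bool_)):
                raise TypeError(f"{name} must be a boolean, got {value!r}")
            object.__setattr__(self, name, bool(value))

    @property
    def flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in FLAG_NAMES}


def encode_profile(profile: RiskProfile) -> np.ndarray:
    """Dummy-encode a profile to the length-13 covariate vector.

    Reference levels (age 50-59, BMI 18.5-22.9) map to all-zero dummy
    blocks, so the reference profile encodes to the zero vector.  The
    coding is injective: bands are one-hot within their block and each
    flag has its own column.
    """
    x = np.zeros(N_COVARIATES, dtype=np.int8)
    if profile.age_band != REFERENCE_AGE:
        x[AGE_BANDS.index(profile.age_band) - 1] = 1
    if profile.bmi_band != REFERENCE_BMI:
        x[_BMI_DUMMY_INDEX[profile.bmi_band]] = 1
    for k, name in enumerate(FLAG_NAMES):
        x[6 + k] = int(getattr(profile, name))
    return x


def decode_covariates(x: np.ndarray, sex: str) -> RiskProfile:
    """Inverse of :func:`encode_profile` (exact on valid vectors)."""
    x = np.asarray(x)
    if x.shape != (N_COVARIATES,):
        raise ValueError(f"covariate vector must have length {N_COVARIATES}")
    age_dummies = x[:3]
    bmi_dummies = x[3:6]
    if age_dummies.sum() > 1 or bmi_dummies.sum() > 1:
        raise ValueError("at most one age dummy and one BMI dummy may be set")
    age_band = AGE_BANDS[int(np.argmax(age_dummies)) + 1] if age_dummies.any() else REFERENCE_AGE
    if bmi_dummies.any():
        bmi_band = {v - 3: k for k, v in _BMI_DUMMY_INDEX.items()}[int(np.argmax(bmi_dummies))]
    else:
        bmi_band = REFERENCE_BMI
    flags = {name: bool(x[6 + k]) for k, name in enumerate(FLAG_NAMES)}
    return RiskProfile(sex=sex, age_band=age_band, bmi_band=bmi_band, **flags)


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort row: id, encoded covariates, follow-up time, event code."""

    id: str
    covariates: np.ndarray
    time: float
    event: int


class Cohort:
    """A single-sex cohort stored column-wise for fast model fitting.

    Parameters
    ----------
    sex : {"male", "female"}
    ids : array of unique subject identifiers
    X : (n, 13) dummy-encoded covariate matrix
    time : (n,) positive follow-up times in years
    event : (n,) event codes in {0, 1, 2}
    """

    def __init__(self, sex: str, ids, X, time, event):
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
        self.sex = sex
        self.ids = np.asarray(ids, dtype=object)
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.time = np.asarray(time, dtype=np.float64)
        self.event = np.asarray(event, dtype=np.int64)
        n = len(self.ids)
        if self.X.shape != (n, N_COVARIATES):
            raise ValueError(f"X must have shape ({n}, {N_COVARIATES}), got {self.X.shape}")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("ids, X, time and event must have matching lengths")
        if len(np.unique(self.ids)) != n:
            raise ValueError("subject ids must be unique")
        bad = ~np.isin(self.event, (0, 1, 2))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"event code must be 0 (censored), 1 (fracture) or 2 (death); "
                f"row {i} (id={self.ids[i]!r}) has event={self.event[i]}"
            )
        nonpos = self.time <= 0
        if nonpos.any():
            i = int(np.flatnonzero(nonpos)[0])
            raise ValueError(
                f"follow-up time must be positive; row {i} (id={self.ids[i]!r}) "
                f"has time={self.time[i]}"
            )

    def __len__(self) -> int:
        return len(self.ids)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Cohort)
            and self.sex == other.sex
            and np.array_equal(self.ids, other.ids)
            and np.array_equal(self.X, other.X)
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.event, other.event)
        )

    @property
    def records(self) -> Iterator[SubjectRecord]:
        for i in range(len(self)):
            yield SubjectRecord(
                id=str(self.ids[i]),
                covariates=self.X[i].copy(),
                time=float(self.time[i]),
                event=int(self.event[i]),
            )

    @classmethod
    def from_records(cls, sex: str, records: list[SubjectRecord]) -> "Cohort":
        return cls(
            sex=sex,
            ids=[r.id for r in records],
            X=np.array([r.covariates for r in records], dtype=np.float64),
            time=[r.time for r in records],
            event=[r.event for r in records],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical tabular form (bands as strings, flags as 0/1)."""
        age = np.full(len(self), REFERENCE_AGE, dtype=object)
        for k in range(3):
            age[self.X[:, k] == 1] = AGE_BANDS[k + 1]
        bmi = np.full(len(self), REFERENCE_BMI, dtype=object)
        for band, col in _BMI_DUMMY_INDEX.items():
            bmi[self.X[:, col] == 1] = band
        data = {"id": self.ids, "sex": self.sex, "age_band": age, "bmi_band": bmi}
        for k, name in enumerate(FLAG_NAMES):
            data[name] = self.X[:, 6 + k].astype(int)
        data["time"] = self.time
        data["event"] = self.event
        return pd.DataFrame(data)


#: Required CSV header, in order.
COHORT_COLUMNS = (
    ("id", "sex", "age_band", "bmi_band") + FLAG_NAMES + ("time", "event")
)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (see :data:`COHORT_COLUMNS` for the dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "age_band": str, "bmi_band": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ValueError(
            f"cohort file {path} has unknown columns {unknown}; "
            f"expected exactly {list(COHORT_COLUMNS)}"
        )
    sexes = df["sex"].unique()
    if len(sexes) != 1:
        raise ValueError(f"cohort file must contain a single sex, found {sorted(sexes)}")
    sex = sexes[0]
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")

    bad_event = ~df["event"].isin((0, 1, 2))
    if bad_event.any():
        i = int(np.flatnonzero(bad_event.to_numpy())[0])
        raise ValueError(
            f"invalid event code {df['event'].iloc[i]} in row {i} "
            f"(id={df['id'].iloc[i]!r}); must be 0, 1 or 2"
        )
    bad_time = df["time"].to_numpy() <= 0
    if bad_time.any():
        i = int(np.flatnonzero(bad_time)[0])
        raise ValueError(
            f"non-positive follow-up time {df['time'].iloc[i]} in row {i} "
            f"(id={df['id'].iloc[i]!r})"
        )

    n = len(df)
    X = np.zeros((n, N_COVARIATES), dtype=np.float64)
    age = df["age_band"].map(lambda v: _canonical_band(v, AGE_BANDS, "age band"))
    bmi = df["bmi_band"].map(lambda v: _canonical_band(v, BMI_BANDS, "BMI band"))
    for k, band in enumerate(AGE_BANDS[1:]):
        X[:, k] = (age == band).to_numpy()
    for band, col in _BMI_DUMMY_INDEX.items():
        X[:, col] = (bmi == band).to_numpy()
    for k, name in enumerate(FLAG_NAMES):
        vals = df[name]
        if not vals.isin((0, 1)).all():
            bad = vals[~vals.isin((0, 1))].iloc[0]
            raise ValueError(f"flag column {name!r} must be 0/1, found {bad!r}")
        X[:, 6 + k] = vals.to_numpy()
    return Cohort(sex=sex, ids=df["id"].to_numpy(object), X=X,
                  time=df["time"].to_numpy(), event=df["event"].to_numpy())


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical CSV form (round-trips through read_cohort)."""
    cohort.to_dataframe().to_csv(path, index=False)
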