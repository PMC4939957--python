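"""Model assessment: calibration, competing-risks discrimination, incidence.

Observed risks are estimated with the Aalen-Johansen cumulative
incidence function so that competing death is handled consistently with
the Fine-Gray model; calibration compares mean predicted risk with the
observed CIF within deciles of predicted risk; discrimination uses the
competing-risks (Wolbers-style) adaptation of Harrell's concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AGE_BANDS, Cohort


def aalen_johansen_cif(cohort_or_time, event=None, t=None, event_of_interest: int = 1):
    """Aalen-Johansen cumulative incidence of fracture at time t.

    Accepts either ``aalen_johansen_cif(cohort, t=...)`` or raw arrays
    ``aalen_johansen_cif(time, event, t)``.  If ``t`` lies beyond the
    last observed time the value at the last time is returned with a
    warning.  Pass ``t=None`` to get the full step curve as a
    ``(times, cif)`` tuple.
    """
    if isinstance(cohort_or_time, Cohort):
        time = cohort_or_time.time
        event_codes = cohort_or_time.event
    else:
        time = np.asarray(cohort_or_time, dtype=float)
        event_codes = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("cohort is empty")

    order = np.argsort(time, kind="stable")
    time = time[order]
    event_codes = event_codes[order]
    n = len(time)

    t_uniq, start = np.unique(time, return_index=True)
    n_at_risk = n - start
    d_interest = np.zeros(len(t_uniq))
    d_any = np.zeros(len(t_uniq))
    idx = np.searchsorted(t_uniq, time)
    np.add.at(d_interest, idx, event_codes == event_of_interest)
    np.add.at(d_any, idx, event_codes > 0)

    # overall (all-cause) survival just before each time, S(t-)
    frac = 1.0 - d_any / n_at_risk
    S = np.cumprod(frac)
    S_prev = np.concatenate([[1.0], S[:-1]])
    cif = np.cumsum(S_prev * d_interest / n_at_risk)

    if t is None:
        return t_uniq, cif
    t = float(t)
    if t > t_uniq[-1]:
        warnings.warn(
            f"requested time {t} is beyond the last observed time {t_uniq[-1]}; "
            "returning the estimate at the last observed time",
            stacklevel=2,
        )
        t = t_uniq[-1]
    pos = np.searchsorted(t_uniq, t, side="right") - 1
    return 0.0 if pos < 0 else float(cif[pos])


@dataclass
class CalibrationTable:
    """Per-decile mean predicted risk vs observed CIF at the horizon."""

    table: pd.DataFrame
    horizon: float

    @property
    def ratios(self) -> np.ndarray:
        return self.table["ratio_obs_pred"].to_numpy()


def decile_calibration(cohort_or_time, event=None, predicted=None, t=7.0,
                       groups: int = 10) -> CalibrationTable:
    """Rank subjects by predicted risk, split into tenths, compare risks.

    Ties (including the degenerate constant-prediction case) are broken
    by stable subject order; the constant case emits a warning since the
    "deciles" then carry no risk ordering.  Ratios are observed/predicted.
    """
    if isinstance(cohort_or_time, Cohort):
        predicted = np.asarray(event if predicted is None else predicted, dtype=float)
        time = cohort_or_time.time
        event_codes = cohort_or_time.event
    else:
        time = np.asarray(cohort_or_time, dtype=float)
        event_codes = np.asarray(event, dtype=int)
        predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted < 0):
        raise ValueError("predicted risks must be non-negative")
    if np.ptp(predicted) == 0:
        warnings.warn(
            "all predicted risks are identical; decile ranks are arbitrary "
            "(stable subject order used)",
            stacklevel=2,
        )
    order = np.argsort(predicted, kind="stable")
    rows = []
    for g, chunk in enumerate(np.array_split(order, groups), start=1):
        mean_pred = float(predicted[chunk].mean())
        observed = aalen_johansen_cif(time[chunk], event_codes[chunk], t)
        rows.append(
            {
                "decile": g,
                "n": len(chunk),
                "mean_predicted": mean_pred,
                "observed_cif": observed,
                "ratio_obs_pred": observed / mean_pred if mean_pred > 0 else np.nan,
            }
        )
    return CalibrationTable(table=pd.DataFrame(rows).set_index("decile"), horizon=t)


def cindex_competing(cohort_or_time, event=None, predicted=None, t=7.0) -> float:
    """Competing-risks concordance (unweighted Wolbers-style definition).

    Cases are subjects with a fracture by ``t``.  For case i, comparable
    partners are subjects still event-free past T_i and subjects whose
    first event was death (at any time).  A pair is concordant when the
    case has the higher predicted risk; ties in the predictor count 1/2.
    """
    if isinstance(cohort_or_time, Cohort):
        predicted = np.asarray(event if predicted is None else predicted, dtype=float)
        time = cohort_or_time.time
        event_codes = cohort_or_time.event
    else:
        time = np.asarray(cohort_or_time, dtype=float)
        event_codes = np.asarray(event, dtype=int)
        predicted = np.asarray(predicted, dtype=float)

    cases = np.flatnonzero((event_codes == 1) & (time <= t))
    if cases.size == 0:
        raise ValueError("no fracture cases by the requested horizon")
    is_death = event_codes == 2

    concordant = 0.0
    comparable = 0
    for i in cases:
        partners = (time > time[i]) | is_death
        partners[i] = False
        m = int(partners.sum())
        if m == 0:
            continue
        r = predicted[partners]
        concordant += float((predicted[i] > r).sum()) + 0.5 * float((predicted[i] == r).sum())
        comparable += m
    if comparable == 0:
        raise ValueError("no comparable pairs for the concordance computation")
    return concordant / comparable


@dataclass
class IncidenceTable:
    """Events, person-years and rates per 1,000 PY with 95% CIs."""

    table: pd.DataFrame


def incidence_rates(cohort_or_time, event=None, strata=None,
                    method: str = "lognormal") -> IncidenceTable:
    """Fracture incidence per 1,000 person-years, overall and by stratum.

    ``strata`` may be None (overall plus age bands when a Cohort is
    given), or an array of per-subject stratum labels.  The default CI is
    the log-normal approximation rate*exp(+-1.96/sqrt(events)); pass
    ``method="exact"`` for exact Poisson (chi-square) intervals.  Strata
    with zero person-years are skipped with a warning; zero-event strata
    report rate 0 with lower bound 0.
    """
    if isinstance(cohort_or_time, Cohort):
        time = cohort_or_time.time
        event_codes = cohort_or_time.event
        if strata is None:
            age_idx = np.zeros(len(cohort_or_time), dtype=int)
            for k in range(3):
                age_idx[cohort_or_time.X[:, k] == 1] = k + 1
            strata = np.array([AGE_BANDS[i] for i in age_idx], dtype=object)
    else:
        time = np.asarray(cohort_or_time, dtype=float)
        event_codes = np.asarray(event, dtype=int)
    if method not in ("lognormal", "exact"):
        raise ValueError("method must be 'lognormal' or 'exact'")

    def one(label, mask):
        py = float(time[mask].sum())
        if py <= 0:
            warnings.warn(f"stratum {label!r} has no person-years; skipped", stacklevel=3)
            return None
        d = int((event_codes[mask] == 1).sum())
        rate = 1000.0 * d / py
        if d == 0:
            lo = 0.0
            hi = 1000.0 * stats.chi2.ppf(0.975, 2) / 2.0 / py
        elif method == "exact":
            lo = 1000.0 * stats.chi2.ppf(0.025, 2 * d) / 2.0 / py
            hi = 1000.0 * stats.chi2.ppf(0.975, 2 * d + 2) / 2.0 / py
        else:
            half = 1.96 / np.sqrt(d)
            lo, hi = rate * np.exp(-half), rate * np.exp(half)
        return {"stratum": label, "events": d, "person_years": py,
                "rate_per_1000py": rate, "ci_low": lo, "ci_high": hi}

    rows = [one("total", np.ones(len(time), dtype=bool))]
    if strata is not None:
        strata = np.asarray(strata, dtype=object)
        for label in pd.unique(strata):
            rows.append(one(label, strata == label))
    rows = [r for r in rows if r is not None]
    return IncidenceTable(table=pd.DataFrame(rows).set_index("stratum"))


def calibration_plot(calibration: CalibrationTable, path) -> None:
    """Predicted-vs-observed per-decile bar plot (optional diagnostic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbl = calibration.table
    x = np.arange(len(tbl))
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - 0.2, 100 * tbl["mean_predicted"], width=0.4, label="predicted")
    ax.bar(x + 0.2, 100 * tbl["observed_cif"], width=0.4, label="observed")
    ax.set_xticks(x, tbl.index)
    ax.set_xlabel("decile of predicted risk")
    ax.set_ylabel(f"{calibration.horizon:g}-year risk (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
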