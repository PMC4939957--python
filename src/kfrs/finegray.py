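"""Fine-Gray subdistribution-hazard regression with IPCW risk sets.

The subdistribution hazard is the instantaneous fracture rate among
subjects who have not yet fractured, *including* those who already died.
Subjects with a competing death therefore remain in the risk set after
their death time with a time-decaying inverse-probability-of-censoring
weight w_i(t) = G(t-)/G(T_i-), where G is the Kaplan-Meier estimate of
the censoring survival function.  The weighted partial likelihood is
maximised by Newton-Raphson with step halving; ties are handled with the
Breslow approximation and the baseline cumulative subdistribution hazard
is the weighted Breslow estimator at the observed fracture times.

Covariates are mean-centered internally, so ``baseline_H`` is the
cumulative hazard of a subject at the cohort covariate means M and
absolute risks follow the mean-centered form
1 - exp(-exp(sum_k beta_k (x_k - M_k)) * H0(t)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import COVARIATE_NAMES, Cohort, RiskProfile, encode_profile

_CONVERGENCE_TOL = 1e-8
_MAX_ITER = 50
_SEPARATION_BOUND = 15.0


class StepFunction:
    """Right-continuous step function with a left-limit accessor."""

    def __init__(self, x: np.ndarray, y: np.ndarray, initial: float):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.initial = float(initial)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if np.any(np.diff(self.x) < 0):
            raise ValueError("breakpoints must be non-decreasing")

    def __call__(self, t):
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right") - 1
        out = np.where(idx >= 0, self.y[np.maximum(idx, 0)], self.initial)
        return out if out.ndim else float(out)

    def left_limit(self, t):
        """Value just before t (i.e. the step function at t-)."""
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="left") - 1
        out = np.where(idx >= 0, self.y[np.maximum(idx, 0)], self.initial)
        return out if out.ndim else float(out)


def censoring_km(cohort: Cohort) -> StepFunction:
    """Kaplan-Meier estimate G(t) of the censoring survival function.

    Censoring (event code 0) is the "event"; fractures and deaths are
    treated as censored observations of the censoring time.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    observed = cohort.event == 0
    if observed.all() and np.all(cohort.time <= 0):
        raise ValueError("all subjects censored at time 0")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.time, event_observed=observed)
    sf = kmf.survival_function_
    return StepFunction(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float), initial=1.0)


def ipcw_weights(cohort: Cohort, G: StepFunction):
    """Per-subject subdistribution risk-set weight functions.

    Returns ``w(t) -> (n,) array``: subject i still event-free at t (t <=
    T_i) has weight 1; a subject who died at T_i < t stays in the risk
    set with weight G(t-)/G(T_i-); a censored or fractured subject has
    weight 0 after T_i.  Where G(T_i-) = 0 the subject leaves the risk
    set (weight 0) rather than raising.
    """
    time = cohort.time
    event = cohort.event

    def w(t: float) -> np.ndarray:
        at_risk = time >= t
        out = np.where(at_risk, 1.0, 0.0)
        past_death = (~at_risk) & (event == 2)
        if past_death.any():
            g_now = G.left_limit(t)
            g_then = np.asarray(G.left_limit(time[past_death]), dtype=float)
            ratio = np.divide(
                g_now, g_then, out=np.zeros_like(g_then), where=g_then > 0
            )
            out[past_death] = ratio
        return out

    return w


@dataclass
class FineGrayFit:
    """Result of a Fine-Gray fit (coefficients on the log-sHR scale)."""

    beta: np.ndarray
    cov: np.ndarray
    names: tuple
    center: np.ndarray                 # covariate means M used for centering
    baseline_H: StepFunction           # cumulative subdistribution hazard at x = M
    n_events: int
    converged: bool
    iterations: int
    loglik: float
    sex: str | None = None
    message: str = ""

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


class _FGData:
    """Pre-sorted cohort arrays and censoring-KM quantities for one fit."""

    def __init__(self, time, event, X, names):
        order = np.argsort(time, kind="stable")
        self.time = np.asarray(time, float)[order]
        self.event = np.asarray(event, int)[order]
        X = np.asarray(X, float)[order]
        self.names = tuple(names)
        self.center = X.mean(axis=0)
        self.Xc = X - self.center
        n, p = X.shape
        self.n, self.p = n, p

        if not (self.event == 1).any():
            raise ValueError("cohort contains no fracture events")
        const = np.flatnonzero(np.ptp(self.Xc, axis=0) == 0)
        if const.size:
            bad = [self.names[j] for j in const]
            raise np.linalg.LinAlgError(
                f"design is singular: covariate(s) {bad} are constant"
            )

        # censoring KM on the original scale (order-invariant)
        kmf = KaplanMeierFitter()
        kmf.fit(self.time, event_observed=self.event == 0)
        sf = kmf.survival_function_
        G = StepFunction(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float), 1.0)
        self.G = G

        # distinct fracture times and per-time aggregates
        is_event = self.event == 1
        self.event_rows = np.flatnonzero(is_event)
        t_events = self.time[is_event]
        self.t_uniq, inverse, self.d = np.unique(
            t_events, return_inverse=True, return_counts=True
        )
        J = len(self.t_uniq)
        self.sum_x_events = np.zeros((J, p))
        np.add.at(self.sum_x_events, inverse, self.Xc[is_event])

        # at-risk suffix index: subjects with T_i >= t_j
        self.k_at_risk = np.searchsorted(self.time, self.t_uniq, side="left")
        # deaths strictly before t_j
        self.death_rows = np.flatnonzero(self.event == 2)
        self.t_death = self.time[self.death_rows]
        self.m_death = np.searchsorted(self.t_death, self.t_uniq, side="left")
        g_death = np.asarray(G.left_limit(self.t_death), float) if self.death_rows.size else np.empty(0)
        self.inv_g_death = np.divide(
            1.0, g_death, out=np.zeros_like(g_death), where=g_death > 0
        )
        self.g_event = np.asarray(G.left_limit(self.t_uniq), float)

        # upper-triangle index pairs for the (p x p) second-moment sums
        iu = np.triu_indices(p)
        self.iu = iu
        self.XX = self.Xc[:, iu[0]] * self.Xc[:, iu[1]]          # (n, p(p+1)/2)
        self.XX_death = self.XX[self.death_rows]
        self.X_death = self.Xc[self.death_rows]

    def _suffix(self, arr):
        return np.cumsum(arr[::-1], axis=0)[::-1]

    def _prefix0(self, arr):
        out = np.cumsum(arr, axis=0)
        pad = np.zeros((1,) + arr.shape[1:])
        return np.concatenate([pad, out], axis=0)

    def quantities(self, beta, need_info=True):
        """Weighted partial log-likelihood, score and information at beta."""
        eta = self.Xc @ beta
        w = np.exp(eta)
        k, m, g = self.k_at_risk, self.m_death, self.g_event

        A0 = self._suffix(w)
        S0 = A0[k].copy()
        A1 = self._suffix(w[:, None] * self.Xc)
        S1 = A1[k].copy()
        if self.death_rows.size:
            wd = w[self.death_rows] * self.inv_g_death
            D0 = self._prefix0(wd)
            D1 = self._prefix0(wd[:, None] * self.X_death)
            S0 += g * D0[m]
            S1 += g[:, None] * D1[m]
        mean = S1 / S0[:, None]

        ll = float(eta[self.event_rows].sum() - self.d @ np.log(S0))
        U = self.sum_x_events.sum(axis=0) - self.d @ mean
        if not need_info:
            return ll, U, None

        A2 = self._suffix(w[:, None] * self.XX)
        S2u = A2[k].copy()
        if self.death_rows.size:
            D2 = self._prefix0(wd[:, None] * self.XX_death)
            S2u += g[:, None] * D2[m]
        p = self.p
        S2 = np.zeros((len(self.t_uniq), p, p))
        S2[:, self.iu[0], self.iu[1]] = S2u
        S2[:, self.iu[1], self.iu[0]] = S2u
        info = np.einsum("j,jkl->kl", self.d, S2 / S0[:, None, None])
        info -= np.einsum("j,jk,jl->kl", self.d, mean, mean)
        return ll, U, info

    def baseline_hazard(self, beta) -> StepFunction:
        """Weighted Breslow estimator at the centered covariates."""
        eta = self.Xc @ beta
        w = np.exp(eta)
        S0 = self._suffix(w)[self.k_at_risk].copy()
        if self.death_rows.size:
            wd = w[self.death_rows] * self.inv_g_death
            S0 += self.g_event * self._prefix0(wd)[self.m_death]
        H = np.cumsum(self.d / S0)
        return StepFunction(self.t_uniq, H, initial=0.0)


def fit_fine_gray(
    cohort: Cohort,
    tol: float = _CONVERGENCE_TOL,
    max_iter: int = _MAX_ITER,
) -> FineGrayFit:
    """Fit the Fine-Gray model to a cohort by Newton-Raphson.

    Raises
    ------
    ValueError
        if the cohort has no fracture events.
    numpy.linalg.LinAlgError
        if the design matrix is singular on the risk sets (the offending
        covariates are named in the message).
    """
    data = _FGData(cohort.time, cohort.event, cohort.X, COVARIATE_NAMES)
    return _fit(data, tol, max_iter, sex=cohort.sex)


def fit_fine_gray_arrays(time, event, X, names=None, tol=_CONVERGENCE_TOL,
                         max_iter=_MAX_ITER) -> FineGrayFit:
    """Array-based fitting entry point (any number of covariates)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(time):
        X = X.T
    if names is None:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    data = _FGData(time, event, X, names)
    return _fit(data, tol, max_iter, sex=None)


def _fit(data: _FGData, tol: float, max_iter: int, sex) -> FineGrayFit:
    p = data.p
    beta = np.zeros(p)
    ll, U, info = data.quantities(beta)
    converged = False
    message = ""
    iterations = 0

    for iterations in range(1, max_iter + 1):
        if np.max(np.abs(U)) < tol:
            converged = True
            iterations -= 1
            break
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            bad = _collinear_columns(data)
            raise np.linalg.LinAlgError(
                f"singular information matrix; collinear covariate(s): {bad}"
            ) from None
        # step halving on likelihood decrease (relative slack: near the
        # optimum the log-likelihood only moves at floating-point level)
        slack = 1e-9 * (1.0 + abs(ll))
        new_beta = beta + step
        for _ in range(15):
            new_ll, new_U, _ = data.quantities(new_beta, need_info=False)
            if new_ll >= ll - slack:
                break
            new_beta = (beta + new_beta) / 2.0
        beta, ll, U = new_beta, new_ll, new_U
        _, _, info = data.quantities(beta)
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            message = (
                "monotone likelihood suspected: |beta| diverged beyond "
                f"{_SEPARATION_BOUND}; estimates are not reliable"
            )
            break
    else:
        message = f"did not converge in {max_iter} iterations"

    if not converged and np.max(np.abs(U)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        bad = _collinear_columns(data)
        raise np.linalg.LinAlgError(
            f"singular information matrix; collinear covariate(s): {bad}"
        ) from None

    return FineGrayFit(
        beta=beta,
        cov=cov,
        names=data.names,
        center=data.center,
        baseline_H=data.baseline_hazard(beta),
        n_events=int(data.d.sum()),
        converged=converged,
        iterations=iterations,
        loglik=ll,
        sex=sex,
        message=message,
    )


def _collinear_columns(data: _FGData) -> list[str]:
    from scipy.linalg import qr

    _, R, piv = qr(data.Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    small = diag < max(data.Xc.shape) * np.finfo(float).eps * (diag.max() or 1.0)
    return [data.names[j] for j in piv[small]] or list(data.names)


def predict_cif(fit: FineGrayFit, covariates, t):
    """Absolute fracture risk 1 - exp(-exp(f(x, M)) * H0(t)).

    ``covariates`` may be a RiskProfile, a single covariate vector or an
    (n, p) matrix; ``t`` a scalar or array of non-negative times.
    """
    if isinstance(covariates, RiskProfile):
        covariates = encode_profile(covariates)
    X = np.asarray(covariates, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("prediction time must be non-negative")
    eta = (X - fit.center) @ fit.beta
    H = fit.baseline_H(t_arr)
    risk = -np.expm1(-np.exp(eta) * H)
    return risk if np.ndim(risk) else float(risk)


def summary(fit: FineGrayFit) -> pd.DataFrame:
    """sHR, 95% Wald CI and two-sided p-value per covariate."""
    se = fit.se
    z = fit.beta / se
    return pd.DataFrame(
        {
            "coef": fit.beta,
            "se": se,
            "sHR": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - 1.96 * se),
            "ci_high": np.exp(fit.beta + 1.96 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=list(fit.names),
    )


def fit_to_dict(fit: FineGrayFit) -> dict:
    """JSON-serializable form of a fit (betas, covariance, baseline steps)."""
    return {
        "sex": fit.sex,
        "names": list(fit.names),
        "beta": fit.beta.tolist(),
        "cov": fit.cov.tolist(),
        "center": fit.center.tolist(),
        "baseline_H": {"times": fit.baseline_H.x.tolist(),
                       "values": fit.baseline_H.y.tolist()},
        "n_events": fit.n_events,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "loglik": fit.loglik,
        "message": fit.message,
    }


def fit_from_dict(d: dict) -> FineGrayFit:
    """Inverse of :func:`fit_to_dict`."""
    return FineGrayFit(
        beta=np.asarray(d["beta"], float),
        cov=np.asarray(d["cov"], float),
        names=tuple(d["names"]),
        center=np.asarray(d["center"], float),
        baseline_H=StepFunction(
            np.asarray(d["baseline_H"]["times"], float),
            np.asarray(d["baseline_H"]["values"], float),
            initial=0.0,
        ),
        n_events=int(d["n_events"]),
        converged=bool(d["converged"]),
        iterations=int(d["iterations"]),
        loglik=float(d["loglik"]),
        sex=d.get("sex"),
        message=d.get("message", ""),
    )


def schoenfeld_residuals(fit: FineGrayFit, cohort: Cohort | None = None,
                         time=None, event=None, X=None):
    """Weighted Schoenfeld residuals and a residual-vs-time slope screen.

    Returns ``(times, residuals, slopes)`` where ``residuals`` has one
    row per fracture event (observed covariates minus the weighted
    risk-set mean at that event time) and ``slopes`` is a DataFrame with
    the per-covariate least-squares slope of residual against event time
    and its p-value — a flat slope is consistent with proportional
    subdistribution hazards.
    """
    if cohort is not None:
        time, event, X, names = cohort.time, cohort.event, cohort.X, fit.names
    else:
        names = fit.names
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    data = _FGData(time, event, X, names)

    eta = data.Xc @ fit.beta
    w = np.exp(eta)
    S0 = data._suffix(w)[data.k_at_risk].copy()
    S1 = data._suffix(w[:, None] * data.Xc)[data.k_at_risk].copy()
    if data.death_rows.size:
        wd = w[data.death_rows] * data.inv_g_death
        S0 += data.g_event * data._prefix0(wd)[data.m_death]
        S1 += data.g_event[:, None] * data._prefix0(wd[:, None] * data.X_death)[data.m_death]
    mean = S1 / S0[:, None]

    event_times = data.time[data.event_rows]
    j_of_event = np.searchsorted(data.t_uniq, event_times)
    residuals = data.Xc[data.event_rows] - mean[j_of_event]

    rows = []
    for k, name in enumerate(names):
        if len(event_times) >= 3 and np.ptp(event_times) > 0:
            res = stats.linregress(event_times, residuals[:, k])
            rows.append((name, res.slope, res.pvalue))
        else:
            rows.append((name, np.nan, np.nan))
    slopes = pd.DataFrame(rows, columns=["covariate", "slope", "p"]).set_index("covariate")
    return event_times, residuals, slopes
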