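"""Downstream Cox proportional-hazards integration of the risk states.

For each endpoint, Cox models on distinct covariate sets (age+sex; age+sex+
risk state; optionally plus binary comorbidity indicators) turn the network's
shift-invariant risk state into absolute 10-year risks.  Coefficients come
from lifelines' CoxPHFitter with the escalating step-size fallback
(0.5 -> 0.1 -> 0.01); the Breslow baseline cumulative hazard at covariates
x = 0 is computed directly from its defining sum so absolute risk is
1 - exp(-H0(t) exp(x'beta)).  Continuous covariates are standardised with
training-set moments only; those moments are frozen before any held-out or
external application.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "CovariateSet",
    "CPHFit",
    "DegenerateCovariateError",
    "fit_cph",
    "breslow_baseline",
    "absolute_risk",
    "predisposition",
    "build_covariates",
]

STEP_SIZES = (0.5, 0.1, 0.01)


class DegenerateCovariateError(ValueError):
    """A covariate column is constant or collinear with the others."""


@dataclass
class CovariateSet:
    """Named covariate columns with frozen standardisation moments.

    ``continuous`` columns are z-scored with moments learned by ``fit`` on
    training data; binary/one-hot columns pass through.  Labels follow the
    analysis convention: AgeSex, AgeSexRiskState, AgeSexComorbid,
    AgeSexComorbidRiskState, or custom.
    """

    label: str
    columns: list[str]
    continuous: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    fitted: bool = False

    def fit(self, df: pd.DataFrame) -> "CovariateSet":
        for c in self.continuous:
            sd = float(df[c].std(ddof=0))
            if sd == 0:
                raise DegenerateCovariateError(f"covariate {c!r} is constant")
            self.means[c] = float(df[c].mean())
            self.sds[c] = sd
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not self.fitted:
            raise RuntimeError("standardisation moments not fitted")
        out = df[self.columns].copy()
        for c in self.continuous:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out


@dataclass
class CPHFit:
    """One endpoint/covariate-set Cox fit: coefficients + Breslow baseline."""

    beta: pd.Series
    se: pd.Series
    baseline_times: np.ndarray  # event times (sorted unique)
    baseline_hazard: np.ndarray  # H0 at those times (nondecreasing, H0(0)=0)
    converged: bool
    step_size: float
    n: int
    n_events: int
    log_likelihood: float

    def linear_predictor(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.beta.index)].to_numpy(dtype=float)
        return np.asarray(X, dtype=float) @ self.beta.to_numpy()

    def H0(self, t: float | np.ndarray) -> np.ndarray | float:
        """Right-continuous step evaluation of the baseline cumulative hazard."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.baseline_hazard])
        out = padded[idx]
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    const = [c for c, s in zip(X.columns, sds) if s == 0]
    if const:
        raise DegenerateCovariateError(f"constant covariate column(s): {const}")
    if arr.shape[1] > 1:
        rank = np.linalg.matrix_rank(arr - arr.mean(axis=0))
        if rank < arr.shape[1]:
            raise DegenerateCovariateError("collinear covariate columns detected")


def fit_cph(X: pd.DataFrame, times: np.ndarray, events: np.ndarray) -> CPHFit:
    """Breslow-tie Cox partial-likelihood fit with step-size fallback.

    Newton iterations via lifelines' CoxPHFitter, retried with step sizes
    0.5, 0.1, 0.01 until convergence; raises after the last fallback.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float),
                         columns=[f"x{i}" for i in range(np.asarray(X).shape[1])])
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    _check_design(X)
    df = X.copy()
    df["__T"], df["__E"] = times, events.astype(int)
    last_err: Exception | None = None
    for step in STEP_SIZES:
        cph = CoxPHFitter(baseline_estimation_method="breslow")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="__T", event_col="__E",
                        fit_options={"step_size": step})
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            last_err = exc
            continue
        beta = cph.params_.copy()
        bt, bh = breslow_baseline(beta.to_numpy(), X.to_numpy(dtype=float), times, events)
        return CPHFit(
            beta=beta,
            se=cph.standard_errors_.copy(),
            baseline_times=bt,
            baseline_hazard=bh,
            converged=True,
            step_size=step,
            n=len(df),
            n_events=int(events.sum()),
            log_likelihood=float(cph.log_likelihood_),
        )
    raise RuntimeError(
        f"Cox fit failed to converge with step sizes {STEP_SIZES}: {last_err}"
    )


def breslow_baseline(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline cumulative hazard at x = 0.

        H0(t) = sum_{event times t_i <= t} d_i / sum_{k: t_k >= t_i} exp(x_k'beta)

    With beta = 0 this is exactly the Nelson-Aalen estimator.  Returns the
    sorted unique event times and H0 evaluated there.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    lp = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    w = np.exp(lp - lp.max())
    scale = np.exp(lp.max())
    order = np.argsort(times, kind="stable")
    t_o, e_o, w_o = times[order], events[order], w[order]
    # risk-set weight sum for a threshold t: total minus weights of t_k < t
    cum_w = np.concatenate([[0.0], np.cumsum(w_o)])
    total = cum_w[-1]
    ev_times = np.unique(t_o[e_o])
    increments = np.empty_like(ev_times)
    for i, t in enumerate(ev_times):
        lo = np.searchsorted(t_o, t, side="left")
        hi = np.searchsorted(t_o, t, side="right")
        d = int(e_o[lo:hi].sum())
        risk_sum = (total - cum_w[lo]) * scale
        increments[i] = d / risk_sum
    H0 = np.cumsum(increments)
    return ev_times, H0


def absolute_risk(fit: CPHFit, x, horizon: float = 10.0) -> np.ndarray | float:
    """Absolute risk 1 - exp(-H0(horizon) e^{x'beta}) within the horizon."""
    if not fit.converged:
        raise RuntimeError("cannot predict from an unconverged fit")
    H = fit.H0(horizon)
    lp = fit.linear_predictor(np.atleast_2d(np.asarray(x, dtype=float))
                              if not isinstance(x, pd.DataFrame) else x)
    risk = -np.expm1(-H * np.exp(lp))
    return float(risk[0]) if np.ndim(x) == 1 and not isinstance(x, pd.DataFrame) else risk


def predisposition(risk_full: float | np.ndarray, risk_ref: float | np.ndarray,
                   ratio_threshold: float = 2.0, risk_threshold: float = 0.10):
    """Predisposition ratio and high-risk flag.

    The ratio compares the full-model absolute 10-year risk with the same
    individual's age/sex-only estimate; the flag marks ratio > 2 together
    with absolute risk > 10%.
    """
    risk_full = np.asarray(risk_full, dtype=float)
    risk_ref = np.asarray(risk_ref, dtype=float)
    if np.any(risk_ref <= 0):
        raise ValueError("reference risk must be positive")
    ratio = risk_full / risk_ref
    flag = (ratio > ratio_threshold) & (risk_full > risk_threshold)
    if ratio.ndim == 0:
        return float(ratio), bool(flag)
    return ratio, flag


def build_covariates(
    age: np.ndarray,
    sex: np.ndarray,
    risk_state: np.ndarray | None = None,
    comorbid: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, CovariateSet]:
    """Assemble a covariate frame and its (unfitted) CovariateSet.

    Sex is one-hot encoded to a single male indicator; age and risk state are
    continuous and will be standardised on training data.
    """
    df = pd.DataFrame({"age": np.asarray(age, dtype=float),
                       "sex_male": (np.asarray(sex) == "male").astype(float)})
    continuous = ["age"]
    label = "AgeSex"
    if comorbid is not None:
        for c in comorbid.columns:
            df[f"cm_{c}"] = comorbid[c].to_numpy(dtype=float)
        label = "AgeSexComorbid"
    if risk_state is not None:
        df["risk_state"] = np.asarray(risk_state, dtype=float)
        continuous = continuous + ["risk_state"]
        label = "AgeSexComorbidRiskState" if comorbid is not None else "AgeSexRiskState"
    return df, CovariateSet(label=label, columns=list(df.columns), continuous=continuous)
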