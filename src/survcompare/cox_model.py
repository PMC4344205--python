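"""Cox proportional hazards by partial-likelihood maximization.

The model: hazard lambda(t | x) = lambda0(t) * exp(x beta), i.e. a linear
model for the log hazard ratio.  beta maximizes the Breslow-tie partial
likelihood via Newton-Raphson (convergence when the score's max absolute
component falls below 1e-6, at most 50 iterations, with step halving);
the baseline cumulative hazard Lambda0 comes from the Breslow estimator,
and per-patient survival curves are S(t) = exp(-Lambda0(t) * exp(x beta)).

Deliberately no shrinkage or penalty of any kind: part of what this package
studies is how an unregularized Cox fit degrades as the number of encoded
covariates grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import StepCurve

__all__ = [
    "CoxFit",
    "CoxError",
    "ConvergenceError",
    "fit_cox",
    "predict_survival_curve",
    "predict_survival_curves",
    "truncate_followup",
]


class CoxError(ValueError):
    pass


class ConvergenceError(CoxError):
    """Newton-Raphson failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[int, float, float]]):
        super().__init__(f"{message}; trace (iter, loglik, max|score|): {trace}")
        self.trace = trace


def truncate_followup(day, status, horizon: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Administratively censor follow-up at ``horizon`` days.

    A Y-year model is learned only from the first Y years of information:
    anything observed past the horizon becomes 'alive at horizon'.
    """
    day = np.asarray(day, dtype=float)
    status = np.asarray(status, dtype=object)
    if horizon is None:
        return day.copy(), status.copy()
    out_status = np.where(day > horizon, "alive", status)
    return np.minimum(day, horizon), out_status.astype(object)


# --- design-matrix encoding -------------------------------------------------

def build_encoding(df: pd.DataFrame) -> dict:
    """Reference-level one-hot map: reference = the most frequent level
    (ties go to the earliest level in category order); numeric columns pass
    through unchanged."""
    enc: dict[str, dict] = {}
    for col in df.columns:
        s = df[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            if isinstance(s.dtype, pd.CategoricalDtype):
                order = [lv for lv in s.cat.categories]
            else:
                order = sorted(pd.unique(s.dropna()))
            counts = s.value_counts()
            best = counts.max() if len(counts) else 0
            ref = next((lv for lv in order if counts.get(lv, 0) == best), order[0])
            enc[col] = {"kind": "categorical", "levels": [str(v) for v in order], "reference": str(ref)}
        else:
            enc[col] = {"kind": "numeric"}
    return enc


def encode_design(df: pd.DataFrame, encoding: dict) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    for col, info in encoding.items():
        if col not in df.columns:
            raise CoxError(f"missing column {col!r}")
        s = df[col]
        if info["kind"] == "numeric":
            cols.append(s.to_numpy(dtype=float))
            names.append(col)
        else:
            vals = s.astype(str).to_numpy()
            known = set(info["levels"])
            unseen = set(vals) - known
            if unseen:
                raise CoxError(
                    f"column {col!r} has level(s) {sorted(unseen)!r} unseen at fit time"
                )
            for lv in info["levels"]:
                if lv == info["reference"]:
                    continue
                cols.append((vals == lv).astype(float))
                names.append(f"{col}={lv}")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _breslow_quantities(X, day, events, beta):
    """Log-likelihood, score and information of the Breslow partial likelihood."""
    xb = X @ beta
    shift = xb.max() if xb.size else 0.0
    r = np.exp(xb - shift)
    order = np.argsort(-day, kind="stable")  # descending time
    Xo, do, ro = X[order], day[order], r[order]
    eo = events[order]
    cr = np.cumsum(ro)
    crx = np.cumsum(ro[:, None] * Xo, axis=0)
    crxx = np.cumsum(ro[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)

    ll, score = 0.0, np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    ev_times = do[eo]
    uniq = np.unique(ev_times)
    # risk set for event time t: all sorted rows with day >= t -> prefix
    last_idx = np.searchsorted(-do, -uniq, side="right") - 1
    for t, li in zip(uniq, last_idx):
        at_t = eo & (do == t)
        d = int(at_t.sum())
        s = Xo[at_t].sum(axis=0)
        R = cr[li]
        Zr = crx[li] / R
        ll += float(s @ beta) - d * (np.log(R) + shift)
        score += s - d * Zr
        info += d * (crxx[li] / R - np.outer(Zr, Zr))
    return ll, score, info


@dataclass
class CoxFit:
    coefficients: pd.Series
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    encoding: dict
    dropped: list[str] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    loglik: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": {k: float(v) for k, v in self.coefficients.items()},
                "baseline_times": self.baseline_times.tolist(),
                "baseline_cumhaz": self.baseline_cumhaz.tolist(),
                "encoding": self.encoding,
                "dropped": self.dropped,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "loglik": self.loglik,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CoxFit":
        d = json.loads(text)
        return cls(
            coefficients=pd.Series(d["coefficients"], dtype=float),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float),
            encoding=d["encoding"],
            dropped=d["dropped"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            loglik=d["loglik"],
        )


def fit_cox(
    features: pd.DataFrame,
    day,
    status,
    horizon: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson fit of the Breslow partial likelihood.

    Follow-up is truncated at ``horizon`` first.  Constant design columns
    carry no contrast and are dropped (recorded in ``fit.dropped``).
    Non-convergence or separation (a coefficient running away) raises
    ``ConvergenceError`` with the iteration trace.
    """
    day_t, status_t = truncate_followup(day, status, horizon)
    events = status_t == "dead"
    if not events.any():
        raise CoxError("no events within the horizon; cannot fit")
    encoding = build_encoding(features)
    X, names = encode_design(features, encoding)
    keep = X.std(axis=0) > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]

    beta = np.zeros(X.shape[1])
    trace: list[tuple[int, float, float]] = []
    ll, score, info = _breslow_quantities(X, day_t, events, beta)
    converged = X.shape[1] == 0
    it = 0
    while not converged and it < max_iter:
        it += 1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, score_new, info_new = _breslow_quantities(X, day_t, events, cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError("step halving failed to improve the likelihood", trace)
        beta, ll, score, info = cand, ll_new, score_new, info_new
        trace.append((it, float(ll), float(np.max(np.abs(score)))))
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError("separation: a coefficient diverged (|beta| > 50)", trace)
        if np.max(np.abs(score)) < tol:
            converged = True
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)

    # Breslow baseline cumulative hazard over the distinct event times.
    r = np.exp(X @ beta) if X.shape[1] else np.ones(len(day_t))
    uniq = np.unique(day_t[events])
    increments = np.empty(uniq.shape)
    for i, t in enumerate(uniq):
        d = int(((day_t == t) & events).sum())
        increments[i] = d / r[day_t >= t].sum()
    cumhaz = np.cumsum(increments)

    return CoxFit(
        coefficients=pd.Series(beta, index=names),
        baseline_times=uniq,
        baseline_cumhaz=cumhaz,
        encoding=encoding,
        dropped=dropped,
        n_iter=it,
        converged=True,
        loglik=float(ll),
    )


def _linear_predictor(fit: CoxFit, rows: pd.DataFrame) -> np.ndarray:
    X, names = encode_design(rows, fit.encoding)
    beta = np.array([fit.coefficients.get(n, 0.0) for n in names])
    return X @ beta


def predict_survival_curve(fit: CoxFit, x: pd.Series | pd.DataFrame, horizon: float) -> StepCurve:
    """Survival curve S(t) = exp(-Lambda0(t) e^{x beta}) for one patient."""
    rows = x.to_frame().T if isinstance(x, pd.Series) else x
    return predict_survival_curves(fit, rows, horizon)[0]


def predict_survival_curves(fit: CoxFit, rows: pd.DataFrame, horizon: float) -> list[StepCurve]:
    lp = _linear_predictor(fit, rows)
    keep = fit.baseline_times <= horizon
    t = fit.baseline_times[keep]
    h0 = fit.baseline_cumhaz[keep]
    return [StepCurve(times=t, values=np.exp(-h0 * np.exp(z))) for z in lp]
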