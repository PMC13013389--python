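"""Fine–Gray subdistribution-hazard regression for competing risks.

The Fine–Gray model regresses the subdistribution hazard of one event
type: subjects who fail from a competing cause remain in the risk set
after their failure, down-weighted by the censoring-distribution ratio
G(t)/G(T_i) (inverse-probability-of-censoring weighting).  This module
implements that estimator as a weighted Cox partial likelihood on an
expanded counting-process dataset — the standard risk-set-expansion
formulation — with robust (sandwich) standard errors.

Covariates are time-fixed here: the exposure entering the competing-risk
sensitivity analysis is the participant's end-of-follow-up
cumulative-average dietary index (subdistribution hazards with internal
time-varying covariates are not well defined).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from nutrisurv.index import QuintileAssignment
from nutrisurv.survival import MODEL_COVARIATES, prepare_covariates

__all__ = ["fit_fine_gray", "fine_gray_quintiles"]


def _censoring_survival(durations: np.ndarray, censored: np.ndarray):
    """Kaplan–Meier of the censoring distribution; returns G(t-) lookup."""
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=censored)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)

    def g_minus(t: np.ndarray) -> np.ndarray:
        # P(C >= t): value of the right-continuous step function just before t
        idx = np.searchsorted(times, np.asarray(t, float), side="left") - 1
        out = np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])
        return out

    return g_minus


def fit_fine_gray(
    data: pd.DataFrame,
    cause: str,
    covariate_cols: list[str],
    duration_col: str = "follow_up_years",
    event_col: str = "event",
) -> tuple[pd.DataFrame, CoxPHFitter]:
    """Fit the subdistribution-hazard model for ``cause``.

    ``data`` has one row per subject; ``event_col`` holds the cause label
    ("none" = censored), and any other label is a competing event.
    Returns a per-covariate summary (coef, se, sHR, CI, p) and the
    underlying weighted Cox fit.
    """
    if (data[event_col] == cause).sum() == 0:
        raise ValueError(f"cause {cause!r} absent from the data")
    T = data[duration_col].to_numpy(float)
    status = np.where(data[event_col] == "none", 0,
                      np.where(data[event_col] == cause, 1, 2))
    X = data[covariate_cols].to_numpy(float)

    g_minus = _censoring_survival(T, (status == 0).astype(int))
    ev_times = np.unique(T[status == 1])
    g_at_ev = g_minus(ev_times)

    # base rows: everyone at risk on (0, T_i], event only for the cause
    starts = [np.zeros(len(T))]
    stops = [T]
    events = [(status == 1).astype(int)]
    weights = [np.ones(len(T))]
    xs = [X]

    # competing failures stay at risk at later target-event times with
    # weight G(t-)/G(T_i-); build the expansion vectorized
    comp = np.flatnonzero(status == 2)
    if len(comp) and len(ev_times):
        first_idx = np.searchsorted(ev_times, T[comp], side="right")
        counts = len(ev_times) - first_idx
        keep = counts > 0
        comp, first_idx, counts = comp[keep], first_idx[keep], counts[keep]
        if len(comp):
            subj = np.repeat(np.arange(len(comp)), counts)
            # per-subject run of consecutive event-time indices
            offs = np.arange(len(subj)) - np.repeat(
                np.cumsum(np.concatenate(([0], counts[:-1]))), counts)
            k = first_idx[subj] + offs
            stop_k = ev_times[k]
            start_k = np.where(offs == 0, T[comp][subj], ev_times[np.maximum(k - 1, 0)])
            gi = g_minus(T[comp])
            w_k = g_at_ev[k] / gi[subj]
            ok = (w_k > 0) & (stop_k > start_k)
            starts.append(start_k[ok])
            stops.append(stop_k[ok])
            events.append(np.zeros(ok.sum(), dtype=int))
            weights.append(w_k[ok])
            xs.append(X[comp][subj[ok]])

    expanded = pd.DataFrame(np.concatenate(xs, axis=0), columns=covariate_cols)
    expanded["start"] = np.concatenate(starts)
    expanded["stop"] = np.concatenate(stops)
    expanded["_event"] = np.concatenate(events)
    expanded["_w"] = np.concatenate(weights)

    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            expanded,
            duration_col="stop",
            entry_col="start",
            event_col="_event",
            weights_col="_w",
            robust=True,
        )
    summary = []
    for term in covariate_cols:
        s = cph.summary.loc[term]
        beta, se = float(s["coef"]), float(s["se(coef)"])
        summary.append({
            "term": term, "coef": beta, "se": se,
            "shr": math.exp(beta),
            "ci_low": math.exp(beta - 1.959963984540054 * se),
            "ci_high": math.exp(beta + 1.959963984540054 * se),
            "p": float(s["p"]),
        })
    return pd.DataFrame(summary), cph


def fine_gray_quintiles(
    outcomes: pd.DataFrame,
    exposure_final: np.ndarray,
    quintiles: QuintileAssignment,
    cause: str,
    model_spec: str = "full",
) -> pd.DataFrame:
    """Subdistribution HRs across exposure quintiles (Q1 reference).

    ``exposure_final`` is the per-participant end-of-follow-up cumulative
    average, aligned with ``outcomes`` rows; quintile membership uses the
    main analysis' fixed cuts.
    """
    if len(exposure_final) != len(outcomes):
        raise ValueError("exposure_final must align with outcomes rows")
    df = prepare_covariates(outcomes)
    df["quintile"] = quintiles.quintile_of(np.asarray(exposure_final, float))
    qcols = []
    for q in range(2, 6):
        df[f"q{q}"] = (df["quintile"] == q).astype(int)
        qcols.append(f"q{q}")
    summary, _ = fit_fine_gray(df, cause, qcols + MODEL_COVARIATES[model_spec])
    out = summary[summary["term"].isin(qcols)].copy()
    out.insert(0, "cause", cause)
    ref = pd.DataFrame([{"cause": cause, "term": "q1", "coef": 0.0, "se": np.nan,
                         "shr": 1.0, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}])
    return pd.concat([ref, out], ignore_index=True)
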