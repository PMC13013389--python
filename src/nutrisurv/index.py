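"""Individual-level dietary index and exposure construction.

The dietary index (DI) of a participant is the energy-weighted mean of
the Nutri-Score values of everything they consume::

    DI = sum_i NS_i * E_i / sum_i E_i

where ``NS_i`` is the item score and ``E_i`` its mean daily energy
contribution.  Higher DI = poorer overall diet quality.  To damp
within-person noise the analysis exposure is the cumulative average of
the DI over all FFQs up to each time point; cohort quintiles of that
exposure (Q1 = healthiest fifth) drive the survival models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_di",
    "cumulative_average",
    "cumulative_average_at",
    "QuintileAssignment",
    "assign_quintiles",
]


def compute_di(intake_items: pd.DataFrame, scores: pd.Series | dict) -> pd.DataFrame:
    """Energy-weighted mean food score per participant visit.

    ``intake_items`` is the item-level frame from
    :func:`nutrisurv.ffq.compute_daily_intakes`; ``scores`` maps item_id
    to its food score.  Zero-energy items contribute nothing; a visit with
    zero total energy raises (such participants should already have been
    excluded).
    """
    scores = pd.Series(scores)
    missing = set(intake_items["item_id"]) - set(scores.index)
    if missing:
        raise KeyError(f"no score for consumed item_ids: {sorted(missing)!r}")
    df = intake_items.copy()
    df["_score"] = df["item_id"].map(scores).astype(float)
    df["_we"] = df["_score"] * df["energy_kcal_day"]
    g = df.groupby(["participant_id", "visit_time"], sort=True)
    out = g.agg(total_energy_kcal=("energy_kcal_day", "sum"), _we=("_we", "sum")).reset_index()
    zero = out["total_energy_kcal"] <= 0
    if zero.any():
        offenders = out.loc[zero, "participant_id"].tolist()[:5]
        raise ValueError(f"zero total energy for participants {offenders!r}; DI undefined")
    out["di"] = out["_we"] / out["total_energy_kcal"]
    return out[["participant_id", "visit_time", "di", "total_energy_kcal"]]


def cumulative_average(di: pd.DataFrame) -> pd.DataFrame:
    """Add the running mean of the DI over each participant's visits.

    Visits are ordered by ``visit_time``; ``cum_avg_di`` at a visit is the
    mean of all DI values up to and including it (no lookahead).
    """
    df = di.sort_values(["participant_id", "visit_time"]).copy()
    df["cum_avg_di"] = df.groupby("participant_id")["di"].expanding().mean().to_numpy()
    return df


def cumulative_average_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    """Cumulative-average exposure for one participant as of time ``t``."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    order = np.argsort(times)
    times, values = times[order], values[order]
    if t < times[0]:
        raise ValueError(f"t={t} precedes the baseline FFQ at {times[0]}")
    return float(values[times <= t].mean())


@dataclass
class QuintileAssignment:
    """Cohort quintiles of an exposure vector.

    ``cuts`` are the 20/40/60/80th percentiles (linear interpolation
    between order statistics); bins are left-closed with ties at a cut
    going to the lower quintile; ``medians`` are the observed per-quintile
    medians used as the trend variable.
    """

    labels: np.ndarray
    cuts: np.ndarray
    medians: np.ndarray

    def quintile_of(self, values: np.ndarray) -> np.ndarray:
        """Quintile (1..5) of new values against the fixed cuts."""
        return np.searchsorted(self.cuts, np.asarray(values, float), side="left") + 1


def assign_quintiles(values: np.ndarray) -> QuintileAssignment:
    """Split an exposure vector into cohort quintiles (Q1 = lowest)."""
    values = np.asarray(values, float)
    if len(values) < 5 or not np.all(np.isfinite(values)):
        raise ValueError("need >= 5 finite values for quintiles")
    if len(np.unique(values)) < 5:
        raise ValueError("fewer than 5 distinct values; quintiles degenerate")
    cuts = np.percentile(values, [20, 40, 60, 80], method="linear")
    labels = np.searchsorted(cuts, values, side="left") + 1
    medians = np.array([np.median(values[labels == q]) for q in range(1, 6)])
    return QuintileAssignment(labels=labels, cuts=cuts, medians=medians)
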