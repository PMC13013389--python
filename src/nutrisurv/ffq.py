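"""FFQ processing: frequency → daily intake, cohort exclusions, and
residual-method energy adjustment.

The food-frequency questionnaire records, per participant and visit, a
frequency level on a nine-level ordinal scale ("never or almost never" up
to "more than six times per day") for each of a fixed list of items (137
in the emulated instrument).  Daily gram and energy intakes follow by
multiplying the daily serving rate by the portion size and the per-100 g
composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FREQUENCY_SERVINGS_PER_DAY",
    "frequency_to_daily",
    "compute_daily_intakes",
    "Intakes",
    "ExclusionReport",
    "apply_exclusions",
    "residual_energy_adjust",
]

# Daily serving rates for the 9 ordinal frequency levels.  The instrument
# prints only the scale endpoints; the interior constants are the standard
# FFQ conventions (fixed configuration, not estimates):
#   1 never, 2 one-to-three/month, 3 once/week, 4 two-to-four/week,
#   5 five-to-six/week, 6 once/day, 7 two-to-three/day, 8 four-to-six/day,
#   9 more than six/day.
FREQUENCY_SERVINGS_PER_DAY: dict[int, float] = {
    1: 0.0,
    2: 2.0 / 30.0,
    3: 1.0 / 7.0,
    4: 3.0 / 7.0,
    5: 5.5 / 7.0,
    6: 1.0,
    7: 2.5,
    8: 5.0,
    9: 7.0,
}

# item-table per-100g columns summed into daily totals (when present)
_TOTAL_COLUMNS = ["energy_kcal", "protein_g", "carb_g", "totalfat_g", "fibre_g", "alcohol_g"]


def frequency_to_daily(level: int) -> float:
    """Servings/day for one ordinal frequency level (1..9)."""
    if not float(level).is_integer() or not 1 <= int(level) <= 9:
        raise ValueError(f"frequency level must be an integer in 1..9, got {level!r}")
    return FREQUENCY_SERVINGS_PER_DAY[int(level)]


class Intakes(NamedTuple):
    """Item-level and total daily intakes per participant visit."""

    items: pd.DataFrame   # participant_id, visit_time, item_id, grams_day, energy_kcal_day
    totals: pd.DataFrame  # participant_id, visit_time, energy_kcal_day, *_day totals


def compute_daily_intakes(responses: pd.DataFrame, items: pd.DataFrame) -> Intakes:
    """Convert long-format FFQ responses into daily intakes.

    ``responses`` columns: participant_id, visit_time, item_id, freq_level.
    ``items`` columns: item_id, portion_g, energy_kcal (plus any of
    protein_g, carb_g, totalfat_g, fibre_g, alcohol_g for totals).
    Items a participant did not report contribute zero; unknown item_ids
    raise.  grams/day = servings/day × portion; item energy = grams/day ×
    kcal/100 g / 100.
    """
    unknown = set(responses["item_id"]) - set(items["item_id"])
    if unknown:
        raise KeyError(f"FFQ responses refer to unknown item_ids: {sorted(unknown)!r}")
    bad = ~responses["freq_level"].isin(range(1, 10))
    if bad.any():
        raise ValueError(
            f"frequency levels outside 1..9 for {int(bad.sum())} response rows"
        )
    df = responses.merge(items, on="item_id", how="left", validate="many_to_one")
    rate = df["freq_level"].map(FREQUENCY_SERVINGS_PER_DAY).to_numpy(float)
    df["grams_day"] = rate * df["portion_g"].to_numpy(float)
    df["energy_kcal_day"] = df["grams_day"] * df["energy_kcal"].to_numpy(float) / 100.0

    agg = {"energy_kcal_day": ("energy_kcal_day", "sum")}
    for col in _TOTAL_COLUMNS[1:]:
        if col in df.columns:
            df[f"_{col}_day"] = df["grams_day"] * df[col].to_numpy(float) / 100.0
            agg[col.replace("_g", "_g_day")] = (f"_{col}_day", "sum")
    totals = (
        df.groupby(["participant_id", "visit_time"], sort=True).agg(**agg).reset_index()
    )
    item_cols = ["participant_id", "visit_time", "item_id", "grams_day", "energy_kcal_day"]
    return Intakes(items=df[item_cols].copy(), totals=totals)


@dataclass
class ExclusionReport:
    """Counts removed per reason, in the order the filters are applied."""

    input_n: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def retained_n(self) -> int:
        return self.input_n - sum(self.removed.values())


# kcal/day plausibility windows: [low, high) retained, i.e. excluded when
# energy < low or energy >= high
ENERGY_LIMITS = {"female": (500.0, 3500.0), "male": (800.0, 4000.0)}


def apply_exclusions(
    cohort: pd.DataFrame, baseline_totals: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the cohort exclusion filters, in order.

    1. missing baseline dietary data (no baseline intake record);
    2. implausible energy: women < 500 or ≥ 3500 kcal/d, men < 800 or
       ≥ 4000 kcal/d (strict ``<`` low, ``>=`` high);
    3. no follow-up (missing or non-positive follow_up_years).

    ``cohort`` needs participant_id, sex ('male'/'female'),
    follow_up_years; ``baseline_totals`` is the visit-0 totals frame from
    :func:`compute_daily_intakes`.  Idempotent by construction.
    """
    report = ExclusionReport(input_n=len(cohort))
    base = baseline_totals.loc[
        baseline_totals["visit_time"] == 0, ["participant_id", "energy_kcal_day"]
    ].rename(columns={"energy_kcal_day": "_baseline_energy"})
    df = cohort.merge(base, on="participant_id", how="left", validate="one_to_one")

    missing = df["_baseline_energy"].isna()
    report.removed["missing_dietary_data"] = int(missing.sum())
    df = df.loc[~missing]

    lims = df["sex"].map(ENERGY_LIMITS)
    low = lims.map(lambda t: t[0]).to_numpy(float)
    high = lims.map(lambda t: t[1]).to_numpy(float)
    e = df["_baseline_energy"].to_numpy(float)
    implausible = (e < low) | (e >= high)
    report.removed["implausible_energy"] = int(implausible.sum())
    df = df.loc[~implausible]

    no_fu = df["follow_up_years"].isna() | (df["follow_up_years"] <= 0)
    report.removed["no_follow_up"] = int(no_fu.sum())
    df = df.loc[~no_fu]

    return df.drop(columns=["_baseline_energy"]), report


def residual_energy_adjust(values: np.ndarray, energy: np.ndarray) -> np.ndarray:
    """Energy-adjust an intake with the residual method.

    OLS of the intake on total energy; the adjusted value is the residual
    plus the fitted value at the sample mean energy.  Preserves the sample
    mean and makes the adjusted values uncorrelated with energy.
    """
    values = np.asarray(values, float)
    energy = np.asarray(energy, float)
    if values.shape != energy.shape or values.ndim != 1:
        raise ValueError("values and energy must be aligned 1-d vectors")
    if len(values) < 3:
        raise ValueError("need at least 3 observations for the residual method")
    if np.ptp(energy) == 0:
        raise ValueError("energy is constant; residual regression undefined")
    fit = sm.OLS(values, sm.add_constant(energy)).fit()
    pred_at_mean = fit.predict([1.0, energy.mean()])[0]
    return fit.resid + pred_at_mean
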