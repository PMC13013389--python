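"""Food and beverage scoring with the updated (2023) Nutri-Score model.

The 2023 Nutri-Score nutrient profiling model assigns every food or
beverage an integer score from its composition per 100 g (foods) or
100 mL (beverages).  Unfavourable components (energy, sugars, saturated
fat, salt) earn "A" points; favourable components (protein, fibre, and
the fruit/vegetable/legume content) earn "C" points.  The final score is
``A - C`` — after a conditional protein rule — and maps onto the five
front-of-pack letters A (best) to E (worst).  For general foods the score
spans −17 to +55; higher means poorer nutritional quality.

All thresholds live in a versioned YAML table shipped with the package
(:func:`table_checksum` fingerprints it); the code is table-driven so a
transcription correction never touches logic.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FoodCategory",
    "NutrientProfile",
    "FoodScore",
    "ConfigurationError",
    "KJ_PER_KCAL",
    "SALT_G_PER_SODIUM_G",
    "points_for_component",
    "compute_unfavourable_points",
    "compute_favourable_points",
    "compute_score",
    "classify_letter",
    "score_extrema",
    "score_dataframe",
    "load_point_tables",
    "table_checksum",
]

_TABLE_RESOURCE = "nutriscore_points_2023.yaml"

KJ_PER_KCAL = 4.184
SALT_G_PER_SODIUM_G = 2.5
KJ_PER_G_SATURATES = 37.0


class ConfigurationError(KeyError):
    """An undefined component/category pairing or malformed point table."""


class FoodCategory(str, Enum):
    """Scoring category of an item.

    ``red_meat_product`` and ``cheese`` use the general-food tables but
    differ in the conditional protein rule; ``water`` bypasses the tables
    entirely and is labelled A with numeric score 0.
    """

    GENERAL = "general_food"
    BEVERAGE = "beverage"
    FATS_OILS = "fats_oils_nuts_seeds"
    CHEESE = "cheese"
    RED_MEAT = "red_meat_product"
    WATER = "water"


# category -> (component-table key, band key); water handled separately
_CATEGORY_TABLE = {
    FoodCategory.GENERAL: ("general", "food"),
    FoodCategory.CHEESE: ("general", "food"),
    FoodCategory.RED_MEAT: ("general", "food"),
    FoodCategory.FATS_OILS: ("fats_oils_nuts_seeds", "fats_oils_nuts_seeds"),
    FoodCategory.BEVERAGE: ("beverage", "beverage"),
}


@dataclass(frozen=True)
class NutrientProfile:
    """Composition of one item per 100 g of food or 100 mL of beverage.

    ``energy_kj`` is kilojoules; masses are grams; ``fvl_percent`` is the
    fruit/vegetable/legume fraction in [0, 100].  ``total_fat_g`` is only
    needed for the fats/oils/nuts/seeds saturates-to-total-fat ratio rule.
    """

    energy_kj: float
    sugars_g: float
    saturated_fat_g: float
    salt_g: float
    fibre_g: float
    protein_g: float
    fvl_percent: float
    total_fat_g: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "energy_kj", "sugars_g", "saturated_fat_g", "salt_g",
            "fibre_g", "protein_g", "fvl_percent", "total_fat_g",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if self.fvl_percent > 100:
            raise ValueError(f"fvl_percent must be <= 100, got {self.fvl_percent!r}")
        if self.total_fat_g > 0 and self.saturated_fat_g > self.total_fat_g * (1 + 1e-9):
            raise ValueError(
                f"saturated_fat_g ({self.saturated_fat_g}) exceeds total_fat_g "
                f"({self.total_fat_g})"
            )


@dataclass(frozen=True)
class FoodScore:
    """Result of scoring one item: point totals, final score and letter."""

    a_points: int
    c_points: int
    score: int
    letter: str


@lru_cache(maxsize=1)
def load_point_tables() -> dict:
    """Load and validate the 2023 point-table file shipped with the package."""
    text = resources.files("nutrisurv.data").joinpath(_TABLE_RESOURCE).read_text()
    cfg = yaml.safe_load(text)
    for cat, groups in cfg["components"].items():
        for group in groups.values():
            for comp, spec in group.items():
                th = spec["thresholds"]
                if any(b <= a for a, b in zip(th, th[1:])):
                    raise ConfigurationError(
                        f"thresholds not strictly increasing for {cat}/{comp}"
                    )
                pts = spec.get("points", list(range(1, len(th) + 1)))
                if len(pts) != len(th) or any(b <= a for a, b in zip(pts, pts[1:])):
                    raise ConfigurationError(f"bad points list for {cat}/{comp}")
    return cfg


def table_checksum() -> str:
    """SHA-256 of the point-table file, for run logs."""
    text = resources.files("nutrisurv.data").joinpath(_TABLE_RESOURCE).read_text()
    return hashlib.sha256(text.encode()).hexdigest()


def _component_spec(component: str, category: FoodCategory, tables: dict | None = None) -> dict:
    tables = tables or load_point_tables()
    if category is FoodCategory.WATER:
        raise ConfigurationError(f"water is not scored by component (component={component!r})")
    key, _ = _CATEGORY_TABLE[category]
    groups = tables["components"][key]
    for group in ("unfavourable", "favourable"):
        if component in groups[group]:
            return groups[group][component]
    raise ConfigurationError(
        f"component {component!r} is not defined for category {category.value!r}"
    )


def points_for_component(
    component: str,
    value: float,
    category: FoodCategory,
    tables: dict | None = None,
) -> int:
    """Points earned by one component value.

    A value strictly above the k-th threshold earns that bin's points; a
    value exactly equal to a threshold earns the lower bin (this boundary
    convention is enforced here and nowhere else).
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"component value must be finite and >= 0, got {value!r}")
    spec = _component_spec(component, category, tables)
    th = spec["thresholds"]
    pts = spec.get("points", list(range(1, len(th) + 1)))
    idx = int(np.searchsorted(th, value, side="left"))  # thresholds strictly below value
    return 0 if idx == 0 else int(pts[idx - 1])


def compute_unfavourable_points(
    profile: NutrientProfile,
    category: FoodCategory,
    tables: dict | None = None,
) -> int:
    """Total "A" points: energy + sugars + saturated fat + salt.

    For fats/oils/nuts/seeds the saturated-fat component is replaced by
    the saturates-to-total-fat ratio (in %); a fat-free item in that
    category earns 0 ratio points by convention.
    """
    if category is FoodCategory.FATS_OILS:
        # added fats: the energy component is the energy from saturates
        # (37 kJ per g of saturated fat), and the saturated-fat component
        # is the saturates-to-total-fat ratio in %
        energy_value = profile.saturated_fat_g * KJ_PER_G_SATURATES
        ratio = (
            100.0 * profile.saturated_fat_g / profile.total_fat_g
            if profile.total_fat_g > 0
            else 0.0
        )
        a = points_for_component("energy", energy_value, category, tables)
        a += points_for_component("sugars", profile.sugars_g, category, tables)
        a += points_for_component("satfat_ratio", ratio, category, tables)
    else:
        a = points_for_component("energy", profile.energy_kj, category, tables)
        a += points_for_component("sugars", profile.sugars_g, category, tables)
        a += points_for_component("saturated_fat", profile.saturated_fat_g, category, tables)
    a += points_for_component("salt", profile.salt_g, category, tables)
    return a


def _protein_points(raw: int, a_points: int, category: FoodCategory, rules: dict) -> int:
    """Conditional protein rule of the 2023 model.

    Cheeses always count protein in full; red meat products count protein
    capped at 2 points; every other food loses its protein points once the
    unfavourable total reaches 11.  Beverages are not subject to the rule.
    """
    if category is FoodCategory.CHEESE or category is FoodCategory.BEVERAGE:
        return raw
    if category is FoodCategory.RED_MEAT:
        return min(raw, int(rules["red_meat_protein_cap"]))
    return 0 if a_points >= int(rules["protein_suppression_min_a_points"]) else raw


def compute_favourable_points(
    profile: NutrientProfile,
    category: FoodCategory,
    a_points: int,
    tables: dict | None = None,
) -> int:
    """Total "C" points: fibre + FVL + (conditionally counted) protein."""
    tables = tables or load_point_tables()
    c = points_for_component("fibre", profile.fibre_g, category, tables)
    c += points_for_component("fvl", profile.fvl_percent, category, tables)
    raw_protein = points_for_component("protein", profile.protein_g, category, tables)
    c += _protein_points(raw_protein, a_points, category, tables["rules"])
    return c


def compute_score(profile: NutrientProfile, category: FoodCategory) -> FoodScore:
    """Score one item: ``score = A - C`` with the conditional protein rule.

    Water bypasses the tables: letter A, numeric score 0 (the number the
    dietary index uses).
    """
    if category is FoodCategory.WATER:
        return FoodScore(a_points=0, c_points=0, score=0, letter="A")
    a = compute_unfavourable_points(profile, category)
    c = compute_favourable_points(profile, category, a)
    score = a - c
    return FoodScore(a_points=a, c_points=c, score=score, letter=classify_letter(score, category))


def classify_letter(score: int, category: FoodCategory) -> str:
    """Map a score to its front-of-pack letter for the given category."""
    if category is FoodCategory.WATER:
        return "A"
    lo, hi = score_extrema(category)
    if not lo <= score <= hi:
        raise ValueError(
            f"score {score} outside attainable range [{lo}, {hi}] for {category.value}"
        )
    _, band_key = _CATEGORY_TABLE[category]
    for letter, upper in load_point_tables()["bands"][band_key]:
        if upper is None or score <= upper:
            return letter
    raise ConfigurationError(f"no band matched score {score} for {category.value}")


def _attainable_points(spec: dict) -> list[int]:
    pts = spec.get("points", list(range(1, len(spec["thresholds"]) + 1)))
    return [0] + [int(p) for p in pts]


def score_extrema(category: FoodCategory, tables: dict | None = None) -> tuple[int, int]:
    """Attainable (min, max) score, by exhaustive combination of per-component
    point values honouring the conditional protein rule."""
    if tables is None:
        return _score_extrema_default(category)
    return _score_extrema(category, tables)


@lru_cache(maxsize=None)
def _score_extrema_default(category: FoodCategory) -> tuple[int, int]:
    return _score_extrema(category, load_point_tables())


def _score_extrema(category: FoodCategory, tables: dict) -> tuple[int, int]:
    if category is FoodCategory.WATER:
        return (0, 0)
    key, _ = _CATEGORY_TABLE[category]
    groups = tables["components"][key]
    a_totals = {0}
    for spec in groups["unfavourable"].values():
        a_totals = {a + p for a in a_totals for p in _attainable_points(spec)}
    protein_set = _attainable_points(groups["favourable"]["protein"])
    fibre_set = _attainable_points(groups["favourable"]["fibre"])
    fvl_set = _attainable_points(groups["favourable"]["fvl"])
    lo, hi = np.inf, -np.inf
    for a in a_totals:
        for p, f, v in itertools.product(protein_set, fibre_set, fvl_set):
            c = f + v + _protein_points(p, a, category, tables["rules"])
            s = a - c
            lo, hi = min(lo, s), max(hi, s)
    return (int(lo), int(hi))


def profile_from_row(row: pd.Series | dict) -> NutrientProfile:
    """Build a :class:`NutrientProfile` from a food-composition table row.

    Expects kcal-based energy (``energy_kcal``) as FFQ databases report it;
    converts to kJ here.  If ``salt_g`` is absent but ``sodium_g`` present,
    salt = sodium × 2.5.
    """
    salt = row.get("salt_g")
    if salt is None or (isinstance(salt, float) and np.isnan(salt)):
        sodium = row.get("sodium_g", 0.0)
        salt = float(sodium) * SALT_G_PER_SODIUM_G
    return NutrientProfile(
        energy_kj=float(row["energy_kcal"]) * KJ_PER_KCAL,
        sugars_g=float(row["sugars_g"]),
        saturated_fat_g=float(row["satfat_g"]),
        salt_g=float(salt),
        fibre_g=float(row["fibre_g"]),
        protein_g=float(row["protein_g"]),
        fvl_percent=float(row["fvl_pct"]),
        total_fat_g=float(row.get("totalfat_g", 0.0) or 0.0),
    )


def score_dataframe(foods: pd.DataFrame) -> pd.DataFrame:
    """Score a food-composition table.

    ``foods`` needs columns ``item_id, category, energy_kcal, sugars_g,
    satfat_g, totalfat_g, salt_g, fibre_g, protein_g, fvl_pct``; returns a
    copy with ``a_points, c_points, score, letter`` appended.
    """
    out = foods.copy()
    a_l, c_l, s_l, letter_l = [], [], [], []
    for _, row in foods.iterrows():
        cat = FoodCategory(row["category"])
        if cat is FoodCategory.WATER:
            fs = compute_score(None, cat)  # type: ignore[arg-type]
        else:
            fs = compute_score(profile_from_row(row), cat)
        a_l.append(fs.a_points)
        c_l.append(fs.c_points)
        s_l.append(fs.score)
        letter_l.append(fs.letter)
    out["a_points"], out["c_points"], out["score"], out["letter"] = a_l, c_l, s_l, letter_l
    return out
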