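"""Nutrient profile models gating claim eligibility.

Two models are provided:

* :func:`fsanz_score` — a points-based scoring criterion in the style
  of the Australia/New Zealand claims regulation: baseline points
  accrue for energy, saturated fat, total sugars and sodium per 100 g;
  modifying points for fruit/veg/nut/legume (FVNL) content, protein and
  fibre are subtracted; a food passes when the final score is below its
  category threshold (beverages < 1, foods < 4, fats/oils < 28).
  The band tables ship as packaged data and can be overridden; they
  encode the criterion's published structure, not the legal text.
* :func:`eu_model_pass` — a configurable per-group threshold model
  (caps on energy, saturated fat, sugars, sodium) standing in for the
  draft European model, whose exact structure is not public here.

Scoring applies uniformly to all foods and claim types; claim-type
specific eligibility rules are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import ConfigError
from .nutrients import FoodGroup, NutrientVector
from .synthetic import ProductRecord
from . import tables

KJ_PER_KCAL = 4.184

#: category pass thresholds: final score must be strictly below
CATEGORY_THRESHOLDS = {1: 1, 2: 4, 3: 28}

# ---------------------------------------------------------------------------
# Points schedule (packaged data; ascending thresholds, one point per band)
# ---------------------------------------------------------------------------
# A component scores k points where k is the number of thresholds strictly
# exceeded. Baseline components accrue points; modifying components subtract.

ENERGY_KJ_BANDS = tuple(335 * k for k in range(1, 11))           # 0-10 points
SATFAT_G_BANDS = tuple(float(k) for k in range(1, 11))           # 0-10
SUGARS_G_BANDS = tuple(4.5 * k for k in range(1, 11))            # 0-10
SODIUM_MG_BANDS = tuple(90 * k for k in range(1, 11))            # 0-10
PROTEIN_G_BANDS = tuple(1.6 * k for k in range(1, 6))            # 0-5
FIBRE_G_BANDS = (0.9, 1.9, 2.8, 3.7, 4.7)                        # 0-5
FVNL_BANDS = ((40.0, 1), (60.0, 2), (80.0, 5))                   # stepped 1/2/5

#: baseline total at or above which protein points need FVNL points >= 5
PROTEIN_GATE_BASELINE = 13
PROTEIN_GATE_FVNL = 5


def _band_points(value: float, bands: Sequence[float]) -> int:
    return sum(1 for t in bands if value > t)


def _fvnl_points(fvnl_percent: float) -> int:
    pts = 0
    for threshold, p in FVNL_BANDS:
        if fvnl_percent > threshold:
            pts = p
    return pts


@dataclass(frozen=True)
class NPSCResult:
    """Outcome of scoring one food."""

    baseline_points: int
    modifying_points: int
    final_score: int
    category: int
    passes: bool

    def __post_init__(self) -> None:
        assert self.final_score == self.baseline_points - self.modifying_points


def fsanz_score(
    nutrients: NutrientVector,
    category: int = 2,
    fvnl_percent: float = 0.0,
) -> NPSCResult:
    """Score one food against the points-based profiling criterion.

    Parameters
    ----------
    nutrients : composition per 100 g (energy in kcal; converted to kJ
        internally since the bands are in kJ).
    category : 1 beverages, 2 foods, 3 fats/oils.
    fvnl_percent : % fruit, vegetable, nut and legume content.
    """
    if category not in CATEGORY_THRESHOLDS:
        raise ValueError(f"category must be one of {sorted(CATEGORY_THRESHOLDS)}")
    if not 0.0 <= fvnl_percent <= 100.0:
        raise ValueError("fvnl_percent must be in [0, 100]")

    energy_kj = nutrients["energy_kcal"] * KJ_PER_KCAL
    baseline = (
        _band_points(energy_kj, ENERGY_KJ_BANDS)
        + _band_points(nutrients["satfat_g"], SATFAT_G_BANDS)
        + _band_points(nutrients["sugars_g"], SUGARS_G_BANDS)
        + _band_points(nutrients["sodium_mg"], SODIUM_MG_BANDS)
    )
    fvnl_pts = _fvnl_points(fvnl_percent)
    fibre_pts = _band_points(nutrients["fibre_g"], FIBRE_G_BANDS)
    protein_pts = _band_points(nutrients["protein_g"], PROTEIN_G_BANDS)
    if baseline >= PROTEIN_GATE_BASELINE and fvnl_pts < PROTEIN_GATE_FVNL:
        protein_pts = 0
    modifying = fvnl_pts + fibre_pts + protein_pts
    score = baseline - modifying
    return NPSCResult(
        baseline_points=baseline,
        modifying_points=modifying,
        final_score=score,
        category=category,
        passes=score < CATEGORY_THRESHOLDS[category],
    )


def eu_model_pass(
    nutrients: NutrientVector,
    group: FoodGroup,
    thresholds: Mapping[FoodGroup, Mapping[str, float]] | None = None,
) -> bool:
    """Threshold model: pass iff every capped nutrient is at or below its cap."""
    if thresholds is None:
        thresholds = tables.EU_THRESHOLDS
    if group not in thresholds:
        raise ConfigError(f"no threshold entry for group {group.value}")
    caps = thresholds[group]
    return all(nutrients[n] <= cap for n, cap in caps.items())


def score_product(product: ProductRecord, model: str = "fsanz") -> bool:
    """Pass/fail for one product under a named model ("fsanz" or "eu")."""
    if model == "fsanz":
        category = 3 if product.group is FoodGroup.OILS else 2
        return fsanz_score(
            product.nutrients_per_100g, category, product.fvnl_percent
        ).passes
    if model == "eu":
        return eu_model_pass(product.nutrients_per_100g, product.group)
    raise ValueError(f"unknown model {model!r}")


def pass_prevalence(
    products: Sequence[ProductRecord],
    model: str = "fsanz",
) -> dict[FoodGroup, float]:
    """Per-group prevalence of claim-carrying AND model-passing foods.

    By construction never exceeds the group's baseline claim prevalence.
    """
    counts: dict[FoodGroup, list[int]] = {}
    for p in products:
        n_pass, n = counts.setdefault(p.group, [0, 0])
        counts[p.group][1] = n + 1
        if p.has_hrc and score_product(p, model):
            counts[p.group][0] = n_pass + 1
    out = {}
    for g, (n_pass, n) in counts.items():
        if n == 0:
            raise ValueError(f"{g.value}: no products")
        out[g] = n_pass / n
    return out
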