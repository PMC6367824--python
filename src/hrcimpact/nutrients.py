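"""Nutrient vectors and food-group vocabulary.

The model tracks a fixed set of dietary quantities. Most are true
nutrients (per 100 g when used as a concentration, per person/day when
used as an intake); fruit and vegetables are carried as food quantities
in grams, not nutrients, and are only non-zero for the fruit-and-veg
food group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Iterator, Mapping

#: Canonical ordering of the tracked dietary quantities.
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "total_fat_g",
    "satfat_g",
    "carbohydrate_g",
    "sugars_g",
    "fibre_g",
    "sodium_mg",
    "fruit_g",
    "veg_g",
)

#: grams of salt per gram of sodium (NaCl molar-mass ratio, fixed convention)
SALT_PER_SODIUM_G = 2.5

#: hard ceiling for an energy concentration: pure fat is ~900 kcal/100 g
MAX_ENERGY_KCAL_PER_100G = 900.0


class FoodGroup(str, enum.Enum):
    """The six Eatwell Guide groups plus the two catch-all groups.

    The Eatwell Guide is the UK government's food-group classification;
    ``COMPOSITE`` holds multi-group foods (pizzas, ready meals) and
    ``MISC`` foods outside the guide (tea, coffee, seasonings).
    """

    STARCHY = "starchy"          # potatoes, bread, rice, pasta, other starchy carbs
    HFSS = "hfss"                # foods and drinks high in fat and/or sugar
    OILS = "oils"                # oils and spreads
    DAIRY = "dairy"              # dairy and alternatives
    PROTEIN = "protein"          # beans, pulses, fish, eggs, meat, other proteins
    FRUIT_VEG = "fruit_veg"      # fruit and vegetables
    COMPOSITE = "composite"
    MISC = "misc"


FOOD_GROUPS: tuple[FoodGroup, ...] = tuple(FoodGroup)


@dataclass(frozen=True)
class NutrientVector:
    """A fixed-length vector over :data:`NUTRIENTS`.

    Units depend on context: per 100 g for concentrations, per
    person/day for intakes. All components must be non-negative;
    signed per-nutrient changes are plain mappings, not vectors.
    """

    energy_kcal: float = 0.0
    protein_g: float = 0.0
    total_fat_g: float = 0.0
    satfat_g: float = 0.0
    carbohydrate_g: float = 0.0
    sugars_g: float = 0.0
    fibre_g: float = 0.0
    sodium_mg: float = 0.0
    fruit_g: float = 0.0
    veg_g: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):  # also rejects NaN
                raise ValueError(f"{f.name} must be >= 0, got {v!r}")

    # -- construction -------------------------------------------------
    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "NutrientVector":
        unknown = set(m) - set(NUTRIENTS)
        if unknown:
            raise ValueError(f"unknown nutrient keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in m.items()})

    # -- views --------------------------------------------------------
    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in NUTRIENTS}

    def __getitem__(self, key: str) -> float:
        if key not in NUTRIENTS:
            raise KeyError(key)
        return getattr(self, key)

    def __iter__(self) -> Iterator[str]:
        return iter(NUTRIENTS)

    # -- arithmetic ---------------------------------------------------
    def scale(self, factor: float) -> "NutrientVector":
        return NutrientVector(**{n: getattr(self, n) * factor for n in NUTRIENTS})

    def add(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(
            **{n: getattr(self, n) + getattr(other, n) for n in NUTRIENTS}
        )

    def hadamard(self, factors: Mapping[str, float]) -> "NutrientVector":
        """Multiply each component by a per-nutrient factor (default 1)."""
        return NutrientVector(
            **{n: getattr(self, n) * float(factors.get(n, 1.0)) for n in NUTRIENTS}
        )

    def validate_concentration(self) -> None:
        """Extra invariant for per-100 g use: energy cannot exceed pure fat."""
        if self.energy_kcal > MAX_ENERGY_KCAL_PER_100G:
            raise ValueError(
                f"energy concentration {self.energy_kcal} kcal/100 g exceeds "
                f"{MAX_ENERGY_KCAL_PER_100G}"
            )


def zeros() -> NutrientVector:
    return NutrientVector()


def total(vectors: Iterator[NutrientVector] | list[NutrientVector]) -> NutrientVector:
    out = NutrientVector()
    for v in vectors:
        out = out.add(v)
    return out
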