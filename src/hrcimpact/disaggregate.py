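"""Splitting group-level purchases into claim and non-claim streams.

The purchase survey reports one sales figure (g/person/day) and one
nutrient intake per food group. To model claim regulation these must be
divided between products that carry a health-related claim and those
that do not, such that the two streams add back exactly to the surveyed
totals.

The division combines three ingredients per group:

* the claim prevalence ``q`` (share of *available* products carrying a
  claim),
* the choice odds ratio ``OR`` (odds of choosing a product when a claim
  is present relative to when it is not), and
* the nutrient quality ratios ``NQR(n)`` (claim-food mean nutrient
  content per 100 g divided by the non-claim mean).

The odds ratio is applied on the odds scale: among purchases, the odds
that an item carries a claim are ``OR`` times the availability odds
``q/(1-q)``, giving the claim sales share

    s = q·OR / (q·OR + (1 - q)).

This is the only reading consistent with a choice-experiment odds ratio
and conservation of total sales; it is isolated in
:func:`hrc_sales_share` so an alternative reading is a one-function
swap.

Given ``s``, the non-claim concentration is solved from the constraint
that the two streams reconstruct the surveyed intake:

    T(n) = S_hrc · c_hrc(n)/100 + S_non · c_non(n)/100,
    c_hrc(n) = NQR(n) · c_non(n)
    ⇒ c_non(n) = 100·T(n) / (S_hrc·NQR(n) + S_non).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .config import ConfigError, ModelConfig, NQRTable, SalesTable
from .nutrients import NUTRIENTS, FoodGroup, NutrientVector


def hrc_sales_share(q: float, or_choice: float) -> float:
    """Sales share of claim-carrying foods implied by prevalence and OR.

    Parameters
    ----------
    q : claim prevalence among available products, in [0, 1].
    or_choice : odds ratio for choosing a product with a claim, > 0.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {q}")
    if or_choice <= 0:
        raise ValueError(f"odds ratio must be > 0, got {or_choice}")
    num = q * or_choice
    return num / (num + (1.0 - q))


def or_from_uniform_boost(q: float, boost: float) -> float:
    """Odds ratio implied by a uniform relative sales boost for claim foods.

    A boost of ``b`` means claim-food sales are ``(1+b)`` times what they
    would be with no choice effect (where the claim share equals ``q``),
    holding total sales fixed. Solving ``s = (1+b)·q`` for the OR gives
    ``OR = (1+b)(1-q) / (1-(1+b)q)``.
    """
    if boost <= -1:
        raise ValueError("boost must be > -1")
    target = (1.0 + boost) * q
    if target >= 1.0:
        raise ValueError(
            f"boost {boost} with prevalence {q} implies a claim share >= 1"
        )
    if q == 0:
        return 1.0
    return (1.0 + boost) * (1.0 - q) / (1.0 - target)


@dataclass(frozen=True)
class GroupSplit:
    """One food group's diet state, split into claim / non-claim streams."""

    group: FoodGroup
    s_hrc: float                 # sales share of claim foods, 0-1
    sales_hrc_g: float           # g/person/day
    sales_non_g: float
    conc_hrc: NutrientVector     # per 100 g
    conc_non: NutrientVector
    intake_hrc: NutrientVector   # per person/day
    intake_non: NutrientVector

    @property
    def sales_total_g(self) -> float:
        return self.sales_hrc_g + self.sales_non_g

    def intake_total(self) -> NutrientVector:
        return self.intake_hrc.add(self.intake_non)


@dataclass
class DietState:
    """Per-group split diet; the core state object of the pipeline."""

    groups: dict[FoodGroup, GroupSplit] = field(default_factory=dict)

    def total_intake(self) -> NutrientVector:
        out = NutrientVector()
        for g in self.groups.values():
            out = out.add(g.intake_total())
        return out

    def total_sales(self) -> float:
        return sum(g.sales_total_g for g in self.groups.values())

    def hrc_sales(self) -> float:
        return sum(g.sales_hrc_g for g in self.groups.values())

    def hrc_intake(self) -> NutrientVector:
        out = NutrientVector()
        for g in self.groups.values():
            out = out.add(g.intake_hrc)
        return out

    def hrc_purchase_share(self) -> float:
        """Claim foods' share of total purchase grams."""
        return self.hrc_sales() / self.total_sales()

    def hrc_energy_share(self) -> float:
        """Claim foods' share of total energy intake."""
        return self.hrc_intake()["energy_kcal"] / self.total_intake()["energy_kcal"]


def split_group(
    group: FoodGroup,
    total_sales_g: float,
    total_intake: NutrientVector,
    q: float,
    or_choice: float,
    nqr: Mapping[str, float],
) -> GroupSplit:
    """Disaggregate one group's sales and intake into the two streams.

    The closed form reconstructs both the sales and the per-nutrient
    intake totals up to float rounding (well within 1e-9 relative).
    """
    if total_sales_g < 0:
        raise ValueError("total sales must be >= 0")
    if total_sales_g == 0:
        if any(total_intake[n] > 0 for n in NUTRIENTS):
            raise ConfigError(f"{group.value}: zero sales but positive intake")
        z = NutrientVector()
        return GroupSplit(group, 0.0, 0.0, 0.0, z, z, z, z)

    for n in NUTRIENTS:
        if not nqr.get(n, 1.0) > 0:
            raise ValueError(f"NQR for {n} must be > 0")

    s = hrc_sales_share(q, or_choice)
    sales_hrc = s * total_sales_g
    sales_non = total_sales_g - sales_hrc

    conc_non = {}
    for n in NUTRIENTS:
        r = float(nqr.get(n, 1.0))
        denom = sales_hrc * r + sales_non
        conc_non[n] = 100.0 * total_intake[n] / denom if denom > 0 else 0.0

    return assemble_split(
        group, s, total_sales_g, NutrientVector.from_mapping(conc_non), nqr
    )


def assemble_split(
    group: FoodGroup,
    s: float,
    total_sales_g: float,
    conc_non: NutrientVector,
    nqr: Mapping[str, float],
) -> GroupSplit:
    """Build a :class:`GroupSplit` from a claim share and fixed non-claim
    composition.

    Shared by the baseline split and the scenario builders so that a
    scenario with unchanged parameters reproduces the baseline state
    bit for bit.
    """
    sales_hrc = s * total_sales_g
    sales_non = total_sales_g - sales_hrc
    conc_hrc = {n: float(nqr.get(n, 1.0)) * conc_non[n] for n in NUTRIENTS}
    intake_hrc = {n: sales_hrc * conc_hrc[n] / 100.0 for n in NUTRIENTS}
    intake_non = {n: sales_non * conc_non[n] / 100.0 for n in NUTRIENTS}
    return GroupSplit(
        group=group,
        s_hrc=s,
        sales_hrc_g=sales_hrc,
        sales_non_g=sales_non,
        conc_hrc=NutrientVector.from_mapping(conc_hrc),
        conc_non=conc_non,
        intake_hrc=NutrientVector.from_mapping(intake_hrc),
        intake_non=NutrientVector.from_mapping(intake_non),
    )


def baseline_disaggregate(
    sales: SalesTable,
    params,
    nqr_table: NQRTable,
    variant: str = "baseline",
) -> DietState:
    """Apply :func:`split_group` to every food group.

    ``params`` maps :class:`FoodGroup` to ``GroupHRCParams``; prevalence
    and NQRs are taken at their central values.
    """
    state = DietState()
    for group, rec in sales.records.items():
        p = params[group]
        state.groups[group] = split_group(
            group,
            rec.sales_g,
            rec.intake,
            p.q_baseline.point,
            p.or_choice.point,
            nqr_table.ratios(group, variant),
        )
    return state


def baseline_from_config(cfg: ModelConfig) -> DietState:
    return baseline_disaggregate(cfg.sales, cfg.hrc_params, cfg.nqr)
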