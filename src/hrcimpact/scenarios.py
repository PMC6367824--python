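"""Counterfactual diet scenarios and diet deltas.

Two families of counterfactuals are built from a baseline
:class:`~hrcimpact.disaggregate.DietState`:

* **Restricted** ("model a"): claims may only remain on products that
  pass a nutrient profile model. Claim prevalence drops to the
  pass-prevalence, the sales split is re-solved with baseline odds
  ratios, and the surviving claim stream takes the pass-subset nutrient
  quality ratios. Foods that lose their claim merge into the non-claim
  stream at the baseline non-claim composition.
* **Reformulated** ("model b"): failing claim foods reformulate to pass,
  so prevalence and the sales split stay at baseline while the claim
  stream's composition moves to the pass-subset quality ratios.

Group sales totals never change (substitution stays within a food
group); total nutrient intake is recomputed and its change relative to
baseline is the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ConfigError, ModelConfig
from .disaggregate import (
    DietState,
    GroupSplit,
    assemble_split,
    baseline_from_config,
    hrc_sales_share,
    or_from_uniform_boost,
)
from .nutrients import NUTRIENTS, FoodGroup, NutrientVector

#: scenario identifiers -> (kind, NQR variant)
MODELS: dict[str, tuple[str, str]] = {
    "1a": ("restricted", "pass_fsanz"),
    "2a": ("restricted", "pass_eu"),
    "1b": ("reformulated", "pass_fsanz"),
    "2b": ("reformulated", "pass_eu"),
}


@dataclass
class DietDelta:
    """Per-nutrient change in population mean intake, scenario − baseline.

    Values are per person/day in each nutrient's native unit
    (kcal, g, or mg for sodium); negative means a reduction.
    """

    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, nutrient: str) -> float:
        return self.values[nutrient]

    def to_report_units(self) -> dict[str, float]:
        """Deltas in reporting units (sodium in grams, rest native)."""
        out = dict(self.values)
        out["sodium_g"] = out.pop("sodium_mg") / 1000.0
        return out


def _rebuild_group(
    base: GroupSplit,
    s_new: float,
    nqr_pass: dict[str, float],
) -> GroupSplit:
    """Re-split a group holding the baseline non-claim composition fixed."""
    return assemble_split(
        base.group, s_new, base.sales_total_g, base.conc_non, nqr_pass
    )


def build_restricted(
    baseline: DietState,
    q_pass: dict[FoodGroup, float],
    nqr_table,
    variant: str,
    params,
    allow_prevalence_increase: bool = False,
) -> DietState:
    """Counterfactual where claims are stripped from failing foods."""
    out = DietState()
    for group, base in baseline.groups.items():
        if group not in q_pass:
            raise ConfigError(f"missing pass-prevalence for group {group.value}")
        qp = q_pass[group]
        qb = params[group].q_baseline.point
        if qp > qb and not allow_prevalence_increase:
            raise ConfigError(
                f"{group.value}: pass-prevalence {qp} exceeds baseline {qb}"
            )
        if base.sales_total_g == 0:
            out.groups[group] = base
            continue
        s_new = hrc_sales_share(qp, params[group].or_choice.point)
        out.groups[group] = _rebuild_group(
            base, s_new, nqr_table.ratios(group, variant)
        )
    return out


def build_reformulated(
    baseline: DietState,
    nqr_table,
    variant: str,
) -> DietState:
    """Counterfactual where failing claim foods reformulate to pass.

    Prevalence, and hence the sales split, stays at baseline; only the
    claim stream's composition changes.
    """
    out = DietState()
    for group, base in baseline.groups.items():
        if base.sales_total_g == 0:
            out.groups[group] = base
            continue
        out.groups[group] = _rebuild_group(
            base, base.s_hrc, nqr_table.ratios(group, variant)
        )
    return out


def uniform_boost_variant(cfg: ModelConfig, boost: float) -> DietState:
    """Baseline diet with every group's OR replaced by a uniform sales boost.

    ``boost`` is the relative increase in claim-food sales over the
    no-choice-effect counterfactual (e.g. 0.16 for a 16% lift), applied
    identically in every food group.
    """
    state = DietState()
    from .disaggregate import split_group  # local to avoid cycle noise

    for group, rec in cfg.sales.records.items():
        q = cfg.hrc_params[group].q_baseline.point
        orc = or_from_uniform_boost(q, boost)
        state.groups[group] = split_group(
            group, rec.sales_g, rec.intake, q, orc,
            cfg.nqr.ratios(group, "baseline"),
        )
    return state


def boost_sensitivity(
    cfg: ModelConfig,
    boost: float = 0.16,
    variant: str = "pass_fsanz",
) -> tuple[DietState, DietState]:
    """Baseline and restricted diet states under a uniform sales boost.

    Sensitivity analysis replacing the per-group choice ORs with the OR
    implied by a uniform relative sales increase of ``boost`` for claim
    foods (applied in every group, including miscellaneous), in both
    the baseline and the restricted arm. Returns
    ``(baseline_state, restricted_state)``.
    """
    base = uniform_boost_variant(cfg, boost)
    restricted = DietState()
    for group, split in base.groups.items():
        p = cfg.hrc_params[group]
        orc = or_from_uniform_boost(p.q_baseline.point, boost)
        s_new = hrc_sales_share(p.q_pass(variant).point, orc)
        restricted.groups[group] = _rebuild_group(
            split, s_new, cfg.nqr.ratios(group, variant)
        )
    return base, restricted


def diet_delta(scenario: DietState, baseline: DietState) -> DietDelta:
    """Per-nutrient population intake difference, scenario − baseline."""
    if set(scenario.groups) != set(baseline.groups):
        raise ConfigError("scenario and baseline cover different food groups")
    s = scenario.total_intake()
    b = baseline.total_intake()
    return DietDelta({n: s[n] - b[n] for n in NUTRIENTS})


def run_scenario(
    cfg: ModelConfig,
    model: str,
    baseline: DietState | None = None,
) -> DietState:
    """Build the diet state for a named model ("baseline", "1a".."2b", "boost16")."""
    if baseline is None:
        baseline = baseline_from_config(cfg)
    if model == "baseline":
        return baseline
    if model == "boost16":
        return uniform_boost_variant(cfg, 0.16)
    try:
        kind, variant = MODELS[model]
    except KeyError:
        raise ConfigError(f"unknown model {model!r}; expected one of "
                          f"{['baseline', *MODELS, 'boost16']}") from None
    if kind == "restricted":
        q_pass = {
            g: p.q_pass(variant).point for g, p in cfg.hrc_params.items()
        }
        return build_restricted(
            baseline, q_pass, cfg.nqr, variant, cfg.hrc_params,
            allow_prevalence_increase=cfg.allow_pass_exceeds_baseline,
        )
    return build_reformulated(baseline, cfg.nqr, variant)
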