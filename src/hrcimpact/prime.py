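"""Population-impact-fraction engine for diet-related mortality.

A simplified comparative-risk-assessment engine in the style of diet
scenario models: each dietary exposure is given a truncated-normal
population distribution; a counterfactual shifts its mean while keeping
the SD; relative risks are applied multiplicatively per unit of
exposure (or per unit of a physiological mediator — body-mass index,
systolic blood pressure, or blood cholesterol — for mediated links);
and the population impact fraction

    PIF = (Σ P(x)·RR(x) − Σ P'(x)·RR(x)) / Σ P(x)·RR(x)

converts the shift into a proportional change in cause-specific deaths.
Multiple links acting on one cause combine multiplicatively on survival
fractions: ``PIF_comb = 1 − Π (1 − PIF_i)``.

The exposure axis is discretised on a 1000-point grid spanning the mean
±6 SD, truncated at zero; RR values are anchored at a reference
exposure (the baseline mean), although the PIF ratio is invariant to
that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import ConfigError, ModelConfig, RiskFactorLink
from .nutrients import NutrientVector
from .scenarios import DietDelta

GRID_POINTS = 1000
GRID_SPAN_SD = 6.0


@dataclass
class IntakeDistribution:
    """Truncated-normal population distribution of one exposure.

    ``mean``/``sd`` are on the exposure's natural per-person/day scale.
    The distribution is truncated at zero and discretised to a
    probability mass vector over ``grid``.
    """

    mean: float
    sd: float
    grid_points: int = GRID_POINTS
    grid: np.ndarray = field(init=False, repr=False)
    pmf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        lo = max(0.0, self.mean - GRID_SPAN_SD * self.sd)
        hi = self.mean + GRID_SPAN_SD * self.sd
        self.grid = np.linspace(lo, hi, self.grid_points)
        a = (lo - self.mean) / self.sd
        b = (hi - self.mean) / self.sd
        dens = stats.truncnorm.pdf(self.grid, a, b, loc=self.mean, scale=self.sd)
        total = dens.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("degenerate exposure distribution")
        self.pmf = dens / total

    def shifted(self, delta: float) -> "IntakeDistribution":
        """Counterfactual with the mean moved by ``delta``, same SD."""
        return IntakeDistribution(self.mean + delta, self.sd, self.grid_points)


def _rr_curve(x: np.ndarray, link: RiskFactorLink, x_ref: float) -> np.ndarray:
    return np.power(link.rr_per_unit.point, (x - x_ref) / link.unit)


def pif(
    base: IntakeDistribution,
    cf: IntakeDistribution,
    link: RiskFactorLink,
    x_ref: float | None = None,
    rr_point: float | None = None,
) -> float:
    """Population impact fraction for one link and one exposure shift.

    ``rr_point`` overrides the link's central relative risk (used by the
    Monte Carlo sampler); the result is invariant to ``x_ref``.
    """
    for dist in (base, cf):
        if not np.isclose(dist.pmf.sum(), 1.0, atol=1e-9):
            raise ValueError("distribution probabilities must sum to 1")
    ref = base.mean if x_ref is None else x_ref
    r = link.rr_per_unit.point if rr_point is None else rr_point
    exp_base = float(np.sum(base.pmf * np.power(r, (base.grid - ref) / link.unit)))
    exp_cf = float(np.sum(cf.pmf * np.power(r, (cf.grid - ref) / link.unit)))
    return (exp_base - exp_cf) / exp_base


def mediated_shift(delta_exposure: float, link: RiskFactorLink) -> float:
    """Convert an exposure change into the mediator change the RR acts on."""
    if link.pathway == "direct":
        raise ConfigError("mediated_shift called on a direct link")
    if link.mediator_slope is None:
        raise ConfigError(f"link {link.exposure}->{link.cause} has no mediator slope")
    return link.mediator_slope * delta_exposure


def link_pif(
    link: RiskFactorLink,
    delta_exposure: float,
    baseline_means: NutrientVector,
    sds: NutrientVector,
    mediators,
    rr_point: float | None = None,
) -> float:
    """PIF for one link given a change in its dietary exposure.

    Direct links shift the exposure's own distribution; mediated links
    shift the mediator's distribution by ``slope × Δexposure``.
    """
    if link.pathway == "direct":
        base = IntakeDistribution(baseline_means[link.exposure], sds[link.exposure])
        cf = base.shifted(delta_exposure)
    else:
        try:
            med = mediators[link.pathway]
        except KeyError:
            raise ConfigError(f"no mediator spec for pathway {link.pathway}") from None
        base = IntakeDistribution(med.mean, med.sd)
        cf = base.shifted(mediated_shift(delta_exposure, link))
    return pif(base, cf, link, rr_point=rr_point)


def combine_pifs(pifs) -> float:
    """Multiplicative combination on survival fractions."""
    surv = 1.0
    for p in pifs:
        surv *= 1.0 - p
    return 1.0 - surv


@dataclass
class DeathsResult:
    """Deaths averted or delayed per year; negative = additional deaths.

    ``total`` combines all non-energy links; ``total_with_energy`` also
    routes the energy change through the body-weight pathway.
    ``by_risk_factor`` rows are computed with each factor's links alone,
    so they do not sum to the combined total.
    """

    total: float
    total_with_energy: float
    by_sex: dict[str, float]
    by_cause_group: dict[str, float]
    by_risk_factor: dict[str, float]
    by_cell: dict[tuple[str, int, str], float] = field(default_factory=dict)


def deaths_averted(
    delta: DietDelta,
    cfg: ModelConfig,
    include_energy: bool = True,
) -> DeathsResult:
    """Convert a diet delta into deaths averted across strata and causes.

    Every aggregation row (total, by sex, by cause group, per risk
    factor, with/without energy) is a sum over population strata of
    ``baseline deaths × combined PIF`` for the relevant link subset.
    """
    means = cfg.baseline_means()
    sds = cfg.intake_sd
    mort_causes = cfg.mortality.causes()
    missing = sorted({l.cause for l in cfg.links} - mort_causes)
    if missing:
        raise ConfigError(f"links reference causes absent from mortality: {missing}")

    energy_links = [l for l in cfg.links if l.risk_group == "energy"]
    other_links = [l for l in cfg.links if l.risk_group != "energy"]

    def pif_of(link: RiskFactorLink) -> float:
        d = delta[link.exposure]
        if d == 0.0:
            return 0.0
        return link_pif(link, d, means, sds, cfg.mediators)

    pif_cache = {id(l): pif_of(l) for l in cfg.links}

    def cause_pif(links) -> dict[str, float]:
        by_cause: dict[str, list[float]] = {}
        for l in links:
            by_cause.setdefault(l.cause, []).append(pif_cache[id(l)])
        return {c: combine_pifs(ps) for c, ps in by_cause.items()}

    def aggregate(links) -> tuple[float, dict, dict, dict]:
        cp = cause_pif(links)
        total = 0.0
        by_sex = {"male": 0.0, "female": 0.0}
        by_cg: dict[str, float] = {}
        by_cell: dict[tuple[str, int, str], float] = {}
        for (sex, age, cause), deaths in cfg.mortality.deaths.items():
            p = cp.get(cause, 0.0)
            averted = deaths * p
            total += averted
            by_sex[sex] += averted
            cg = cfg.cause_groups.get(cause, cause)
            by_cg[cg] = by_cg.get(cg, 0.0) + averted
            by_cell[(sex, age, cause)] = by_cell.get((sex, age, cause), 0.0) + averted
        return total, by_sex, by_cg, by_cell

    total, by_sex, by_cg, by_cell = aggregate(other_links)
    total_with_energy, sex_e, cg_e, cell_e = aggregate(other_links + energy_links)

    by_factor: dict[str, float] = {}
    for factor in sorted({l.risk_group for l in cfg.links if l.risk_group}):
        subset = [l for l in cfg.links if l.risk_group == factor]
        by_factor[factor], _, _, _ = aggregate(subset)

    if include_energy:
        by_sex, by_cg, by_cell = sex_e, cg_e, cell_e

    return DeathsResult(
        total=total,
        total_with_energy=total_with_energy,
        by_sex=by_sex,
        by_cause_group=by_cg,
        by_risk_factor=by_factor,
        by_cell=by_cell,
    )
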