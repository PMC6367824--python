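"""Parameter bundle: domain types, validation, and YAML round-trip.

Everything the pipeline consumes is collected in a :class:`ModelConfig`:
per-food-group claim parameters (prevalence ``q`` and choice odds ratio
``OR``), the nutrient-quality-ratio (NQR) table, baseline sales and
intakes, population intake SDs, population/mortality strata, and the
exposure-to-mortality risk links used by the impact engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .nutrients import NUTRIENTS, FoodGroup, NutrientVector

NQR_VARIANTS: tuple[str, ...] = ("baseline", "pass_fsanz", "pass_eu")

SEXES: tuple[str, ...] = ("male", "female")


class ConfigError(ValueError):
    """Raised for schema or validation problems in a parameter bundle."""


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a 95% confidence interval."""

    point: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.point <= self.hi):
            raise ConfigError(
                f"CI must bracket the point estimate: {self.lo} <= {self.point} <= {self.hi}"
            )

    @classmethod
    def exact(cls, value: float) -> "Estimate":
        return cls(value, value, value)

    @property
    def degenerate(self) -> bool:
        return self.lo == self.point == self.hi


def _check_proportion(e: Estimate, name: str) -> None:
    if not (0.0 <= e.lo and e.hi <= 1.0):
        raise ConfigError(f"{name} must lie in [0, 1]: {e}")


@dataclass(frozen=True)
class GroupHRCParams:
    """Claim parameters for one food group.

    ``q_*`` are proportions of products in the group carrying at least
    one health-related claim: at baseline, and among products that
    would still be eligible under each nutrient profile model.
    ``or_choice`` is the odds ratio for choosing a product when a claim
    is present relative to when it is not.
    """

    group: FoodGroup
    or_choice: Estimate
    q_baseline: Estimate
    q_pass_fsanz: Estimate
    q_pass_eu: Estimate

    def __post_init__(self) -> None:
        if self.or_choice.lo <= 0:
            raise ConfigError(f"{self.group}: or_choice must be > 0")
        for name in ("q_baseline", "q_pass_fsanz", "q_pass_eu"):
            _check_proportion(getattr(self, name), f"{self.group}.{name}")
        if self.group is FoodGroup.MISC and self.or_choice.point != 1.0:
            raise ConfigError("miscellaneous group must have or_choice = 1")

    def q_pass(self, variant: str) -> Estimate:
        if variant == "pass_fsanz":
            return self.q_pass_fsanz
        if variant == "pass_eu":
            return self.q_pass_eu
        if variant == "baseline":
            return self.q_baseline
        raise ConfigError(f"unknown NQR variant {variant!r}")


@dataclass(frozen=True)
class NQREntry:
    """One nutrient quality ratio with its standard error (may be NaN)."""

    nqr: float
    se: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.nqr > 0 and math.isfinite(self.nqr)):
            raise ConfigError(f"NQR must be positive and finite, got {self.nqr}")


@dataclass
class NQRTable:
    """Nutrient quality ratios per (group, variant, nutrient).

    NQR = mean nutrient content per 100 g of claim-carrying foods
    divided by that of non-claim foods. ``variant`` selects the product
    subset defining the numerator: all claim foods (``baseline``) or
    claim foods passing a nutrient profile model.
    """

    entries: dict[tuple[FoodGroup, str, str], NQREntry] = field(default_factory=dict)

    def set(self, group: FoodGroup, variant: str, nutrient: str, nqr: float,
            se: float = float("nan")) -> None:
        if variant not in NQR_VARIANTS:
            raise ConfigError(f"unknown NQR variant {variant!r}")
        if nutrient not in NUTRIENTS:
            raise ConfigError(f"unknown nutrient {nutrient!r}")
        self.entries[(group, variant, nutrient)] = NQREntry(float(nqr), float(se))

    def get(self, group: FoodGroup, variant: str, nutrient: str) -> NQREntry:
        try:
            return self.entries[(group, variant, nutrient)]
        except KeyError:
            raise ConfigError(
                f"missing NQR entry for ({group.value}, {variant}, {nutrient})"
            ) from None

    def ratios(self, group: FoodGroup, variant: str) -> dict[str, float]:
        """Per-nutrient NQR factors for one group/variant (default 1)."""
        out = {}
        for n in NUTRIENTS:
            e = self.entries.get((group, variant, n))
            out[n] = e.nqr if e is not None else 1.0
        return out


@dataclass(frozen=True)
class SalesRecord:
    """Per-group purchases (g/person/day) and the nutrient intake they supply."""

    group: FoodGroup
    sales_g: float
    intake: NutrientVector

    def __post_init__(self) -> None:
        if self.sales_g < 0:
            raise ConfigError(f"{self.group}: sales must be >= 0")
        if self.sales_g == 0 and any(self.intake[n] > 0 for n in NUTRIENTS):
            raise ConfigError(f"{self.group}: zero sales with positive intake")


@dataclass
class SalesTable:
    records: dict[FoodGroup, SalesRecord] = field(default_factory=dict)

    def total_sales(self) -> float:
        return sum(r.sales_g for r in self.records.values())

    def total_intake(self) -> NutrientVector:
        out = NutrientVector()
        for r in self.records.values():
            out = out.add(r.intake)
        return out


@dataclass(frozen=True)
class PopulationStratum:
    sex: str
    age_lo: int       # inclusive lower bound of 5-year band; 85 means 85+
    count: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigError(f"sex must be one of {SEXES}")
        if self.count < 0:
            raise ConfigError("population count must be >= 0")


@dataclass
class MortalityTable:
    """Annual deaths per (sex, age band, cause)."""

    deaths: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def causes(self) -> set[str]:
        return {c for (_, _, c) in self.deaths}

    def total(self) -> float:
        return sum(self.deaths.values())

    def set(self, sex: str, age_lo: int, cause: str, n: float) -> None:
        if n < 0:
            raise ConfigError("death counts must be >= 0")
        self.deaths[(sex, age_lo, cause)] = float(n)


PATHWAYS: tuple[str, ...] = ("direct", "via_bmi", "via_sbp", "via_cholesterol")


@dataclass(frozen=True)
class RiskFactorLink:
    """A dietary exposure's relative-risk link to a cause of death.

    ``rr_per_unit`` is the relative risk per ``unit`` increase of the
    exposure (direct links) or of the mediator (mediated links, where
    ``mediator_slope`` converts exposure units into mediator units).
    """

    exposure: str                 # nutrient key, e.g. "satfat_g"
    cause: str
    rr_per_unit: Estimate
    unit: float                   # exposure (or mediator) units per RR step
    pathway: str = "direct"
    mediator_slope: float | None = None
    risk_group: str = ""          # reporting bucket, e.g. "fats", "salt"

    def __post_init__(self) -> None:
        if self.rr_per_unit.lo <= 0:
            raise ConfigError("rr_per_unit must be > 0")
        if self.unit <= 0:
            raise ConfigError("unit must be > 0")
        if self.pathway not in PATHWAYS:
            raise ConfigError(f"pathway must be one of {PATHWAYS}")
        if self.pathway != "direct" and self.mediator_slope is None:
            raise ConfigError(
                f"mediated link {self.exposure}->{self.cause} needs mediator_slope"
            )
        if self.exposure not in NUTRIENTS:
            raise ConfigError(f"unknown exposure {self.exposure!r}")


@dataclass(frozen=True)
class MediatorSpec:
    """Population distribution of a physiological mediator (e.g. SBP)."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"mediator {self.name}: sd must be > 0")


@dataclass
class ModelConfig:
    """Everything the pipeline needs, validated."""

    hrc_params: dict[FoodGroup, GroupHRCParams]
    nqr: NQRTable
    sales: SalesTable
    intake_sd: NutrientVector
    population: list[PopulationStratum]
    mortality: MortalityTable
    links: list[RiskFactorLink]
    mediators: dict[str, MediatorSpec]
    cause_groups: dict[str, str] = field(default_factory=dict)  # cause -> cvd/cancer
    allow_pass_exceeds_baseline: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        missing = [g.value for g in FoodGroup if g not in self.hrc_params]
        if missing:
            raise ConfigError(f"missing HRC parameters for groups: {missing}")
        link_causes = {l.cause for l in self.links}
        mort_causes = self.mortality.causes()
        orphans = sorted(link_causes - mort_causes) if mort_causes else []
        if orphans:
            raise ConfigError(f"risk links reference unknown causes: {orphans}")

    def baseline_means(self) -> NutrientVector:
        """Population mean intake per person/day, summed over groups."""
        return self.sales.total_intake()


# ---------------------------------------------------------------------------
# YAML (de)serialisation
# ---------------------------------------------------------------------------

def _est_to_list(e: Estimate) -> list[float]:
    return [e.point, e.lo, e.hi]


def _est_from_list(v: Sequence[float]) -> Estimate:
    return Estimate(float(v[0]), float(v[1]), float(v[2]))


def config_to_dict(cfg: ModelConfig) -> dict:
    return {
        "hrc_params": {
            g.value: {
                "or_choice": _est_to_list(p.or_choice),
                "q_baseline": _est_to_list(p.q_baseline),
                "q_pass_fsanz": _est_to_list(p.q_pass_fsanz),
                "q_pass_eu": _est_to_list(p.q_pass_eu),
            }
            for g, p in cfg.hrc_params.items()
        },
        "nqr": [
            {"group": g.value, "variant": v, "nutrient": n,
             "nqr": e.nqr, "se": None if math.isnan(e.se) else e.se}
            for (g, v, n), e in sorted(
                cfg.nqr.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
            )
        ],
        "sales": {
            r.group.value: {"sales_g": r.sales_g, "intake": r.intake.as_dict()}
            for r in cfg.sales.records.values()
        },
        "intake_sd": cfg.intake_sd.as_dict(),
        "population": [asdict(s) for s in cfg.population],
        "mortality": [
            {"sex": sex, "age_lo": age, "cause": cause, "deaths": n}
            for (sex, age, cause), n in sorted(cfg.mortality.deaths.items())
        ],
        "links": [
            {
                "exposure": l.exposure, "cause": l.cause,
                "rr_per_unit": _est_to_list(l.rr_per_unit), "unit": l.unit,
                "pathway": l.pathway, "mediator_slope": l.mediator_slope,
                "risk_group": l.risk_group,
            }
            for l in cfg.links
        ],
        "mediators": {m.name: {"mean": m.mean, "sd": m.sd} for m in cfg.mediators.values()},
        "cause_groups": dict(cfg.cause_groups),
        "allow_pass_exceeds_baseline": cfg.allow_pass_exceeds_baseline,
        "notes": cfg.notes,
    }


def config_from_dict(d: Mapping) -> ModelConfig:
    try:
        hrc = {}
        for gname, p in d["hrc_params"].items():
            g = FoodGroup(gname)
            hrc[g] = GroupHRCParams(
                group=g,
                or_choice=_est_from_list(p["or_choice"]),
                q_baseline=_est_from_list(p["q_baseline"]),
                q_pass_fsanz=_est_from_list(p["q_pass_fsanz"]),
                q_pass_eu=_est_from_list(p["q_pass_eu"]),
            )
        nqr = NQRTable()
        for row in d["nqr"]:
            se = row.get("se")
            nqr.set(FoodGroup(row["group"]), row["variant"], row["nutrient"],
                    row["nqr"], float("nan") if se is None else float(se))
        sales = SalesTable()
        for gname, r in d["sales"].items():
            g = FoodGroup(gname)
            sales.records[g] = SalesRecord(
                g, float(r["sales_g"]), NutrientVector.from_mapping(r["intake"])
            )
        pop = [PopulationStratum(**s) for s in d["population"]]
        mort = MortalityTable()
        for row in d["mortality"]:
            mort.set(row["sex"], int(row["age_lo"]), row["cause"], float(row["deaths"]))
        links = [
            RiskFactorLink(
                exposure=l["exposure"], cause=l["cause"],
                rr_per_unit=_est_from_list(l["rr_per_unit"]), unit=float(l["unit"]),
                pathway=l.get("pathway", "direct"),
                mediator_slope=l.get("mediator_slope"),
                risk_group=l.get("risk_group", ""),
            )
            for l in d["links"]
        ]
        mediators = {
            name: MediatorSpec(name, float(m["mean"]), float(m["sd"]))
            for name, m in d.get("mediators", {}).items()
        }
        return ModelConfig(
            hrc_params=hrc, nqr=nqr, sales=sales,
            intake_sd=NutrientVector.from_mapping(d["intake_sd"]),
            population=pop, mortality=mort, links=links, mediators=mediators,
            cause_groups=dict(d.get("cause_groups", {})),
            allow_pass_exceeds_baseline=bool(d.get("allow_pass_exceeds_baseline", True)),
            notes=d.get("notes", ""),
        )
    except KeyError as exc:
        raise ConfigError(f"missing config key: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: ModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> ModelConfig:
    """Load a full parameter bundle from a YAML file."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return config_from_dict(yaml.safe_load(p.read_text()))
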