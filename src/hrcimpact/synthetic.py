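"""Synthetic study inputs: product survey, sales, population, mortality.

The real study rests on four data sources that cannot be shipped: a
product-label survey (claim prevalence and nutrient content of claim vs
non-claim foods), household purchase data (per-group sales and nutrient
intakes), diet-survey intake SDs, and population/mortality registers.
This module generates all four with the statistical structure the
analysis assumes, so the full pipeline is testable end to end.

Products are drawn per group: a Bernoulli claim flag with the group's
prevalence, then per-nutrient truncated-at-zero normal compositions
whose means differ between claim and non-claim foods (claim foods lower
in energy, saturated fat, sugars and sodium, higher in fibre, matching
the label-survey aggregates). Nutrients are drawn independently — the
source reports only marginal means/SDs. Truncation uses resampling,
not clipping, so sample means stay close to the specified means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import Estimate, ModelConfig, MortalityTable, PopulationStratum, SalesTable
from .nutrients import FoodGroup, NutrientVector
from . import tables

#: per-100 g composition fields carried by survey products
PRODUCT_NUTRIENTS: tuple[str, ...] = (
    "energy_kcal", "protein_g", "total_fat_g", "satfat_g",
    "carbohydrate_g", "sugars_g", "fibre_g", "sodium_mg",
)


@dataclass(frozen=True)
class ProductRecord:
    """One surveyed pre-packaged food."""

    id: int
    group: FoodGroup
    nutrients_per_100g: NutrientVector
    has_hrc: bool
    fvnl_percent: float = 0.0  # % fruit/veg/nut/legume, used by profile scoring

    def __post_init__(self) -> None:
        self.nutrients_per_100g.validate_concentration()
        if not 0.0 <= self.fvnl_percent <= 100.0:
            raise ValueError("fvnl_percent must be in [0, 100]")


@dataclass(frozen=True)
class GroupProductParams:
    """Generator parameters for one group's products."""

    q: float                                  # claim prevalence
    nonclaim_means: Mapping[str, float]       # per 100 g
    claim_means: Mapping[str, float]
    rel_sd: float = tables.PRODUCT_REL_SD
    fvnl_percent: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.rel_sd < 0:
            raise ValueError("negative SD")
        for m in (self.nonclaim_means, self.claim_means):
            if any(v < 0 for v in m.values()):
                raise ValueError("nutrient means must be >= 0")


def default_product_params(
    q_override: Mapping[FoodGroup, float] | None = None,
    shifts: Mapping[str, float] | None = None,
) -> dict[FoodGroup, GroupProductParams]:
    """Per-group generator defaults: packaged means + uniform claim shifts."""
    shifts = dict(tables.CLAIM_MEAN_SHIFTS if shifts is None else shifts)
    cfg = tables.hrc_params_table()
    fvnl = {FoodGroup.FRUIT_VEG: 85.0, FoodGroup.COMPOSITE: 25.0}
    out = {}
    for g, base in tables.PRODUCT_NONCLAIM_MEANS.items():
        claim = {
            n: max(v + shifts.get(n, 0.0), 0.1 * v, 0.0)
            for n, v in base.items()
        }
        q = cfg[g].q_baseline.point if q_override is None else q_override[g]
        out[g] = GroupProductParams(
            q=q, nonclaim_means=dict(base), claim_means=claim,
            fvnl_percent=fvnl.get(g, 0.0),
        )
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws resampled (not clipped) until non-negative."""
    if sd < 0:
        raise ValueError("negative SD")
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out < 0
    # mean >= 0 and moderate rel-SD make this converge in a few rounds
    for _ in range(100):
        n_bad = int(bad.sum())
        if n_bad == 0:
            return out
        out[bad] = rng.normal(mean, sd, n_bad)
        bad = out < 0
    out[out < 0] = 0.0
    return out


def gen_product_survey(
    params: Mapping[FoodGroup, GroupProductParams],
    n_products: int,
    seed: int,
) -> list[ProductRecord]:
    """Draw a synthetic product-label survey.

    ``n_products`` is split evenly across the configured groups; claim
    flags are Bernoulli(q) and compositions truncated normals with
    claim-dependent means.
    """
    if n_products < 1:
        raise ValueError("n_products must be >= 1")
    rng = np.random.default_rng(seed)
    groups = list(params)
    per_group = [n_products // len(groups)] * len(groups)
    for i in range(n_products % len(groups)):
        per_group[i] += 1

    records: list[ProductRecord] = []
    pid = 0
    for g, n_g in zip(groups, per_group):
        p = params[g]
        flags = rng.random(n_g) < p.q
        cols = {}
        for nutrient in PRODUCT_NUTRIENTS:
            mc = p.claim_means.get(nutrient, 0.0)
            mn = p.nonclaim_means.get(nutrient, 0.0)
            vals = np.where(
                flags,
                _truncated_normal(rng, mc, p.rel_sd * mc, n_g),
                _truncated_normal(rng, mn, p.rel_sd * mn, n_g),
            )
            cols[nutrient] = vals
        cols["energy_kcal"] = np.minimum(cols["energy_kcal"], 900.0)
        for i in range(n_g):
            records.append(
                ProductRecord(
                    id=pid,
                    group=g,
                    nutrients_per_100g=NutrientVector.from_mapping(
                        {n: float(cols[n][i]) for n in PRODUCT_NUTRIENTS}
                    ),
                    has_hrc=bool(flags[i]),
                    fvnl_percent=p.fvnl_percent,
                )
            )
            pid += 1
    return records


def products_to_frame(products: Iterable[ProductRecord]) -> pd.DataFrame:
    rows = []
    for p in products:
        row = {"id": p.id, "group": p.group.value, "has_hrc": p.has_hrc,
               "fvnl_percent": p.fvnl_percent}
        row.update({n: p.nutrients_per_100g[n] for n in PRODUCT_NUTRIENTS})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrevalenceEstimate:
    group: FoodGroup
    q: Estimate | None
    n: int
    n_claim: int


def estimate_prevalence(
    products: Sequence[ProductRecord],
) -> dict[FoodGroup, PrevalenceEstimate]:
    """Per-group claim prevalence with Wilson score 95% CIs.

    Groups with no products are flagged with ``q=None``.
    """
    by_group: dict[FoodGroup, list[ProductRecord]] = {}
    for p in products:
        by_group.setdefault(p.group, []).append(p)
    out = {}
    for g, items in by_group.items():
        n = len(items)
        k = sum(p.has_hrc for p in items)
        if n == 0:
            out[g] = PrevalenceEstimate(g, None, 0, 0)
            continue
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        out[g] = PrevalenceEstimate(
            g, Estimate(k / n, max(float(lo), 0.0), min(float(hi), 1.0)), n, k
        )
    return out


@dataclass(frozen=True)
class NQREstimate:
    group: FoodGroup
    nutrient: str
    nqr: float          # NaN when the non-claim mean is zero
    se: float           # NaN when not estimable (single observations)
    n_claim: int
    n_nonclaim: int


def estimate_nqr(
    products: Sequence[ProductRecord],
    np_filter=None,
) -> list[NQREstimate]:
    """Nutrient quality ratios (claim mean / non-claim mean) per group.

    With ``np_filter`` (a predicate on :class:`ProductRecord`), the
    numerator subset is claim-carrying AND passing foods — the
    pass-variant NQR used by the regulation scenarios. SEs come from
    the delta method on the two subgroup means.
    """
    by_group: dict[FoodGroup, list[ProductRecord]] = {}
    for p in products:
        by_group.setdefault(p.group, []).append(p)

    out: list[NQREstimate] = []
    for g, items in by_group.items():
        claim = [p for p in items if p.has_hrc]
        if np_filter is not None:
            claim = [p for p in claim if np_filter(p)]
        nonclaim = [p for p in items if not p.has_hrc]
        if not claim or not nonclaim:
            raise ValueError(
                f"{g.value}: both claim and non-claim subsets must be non-empty"
            )
        for nutrient in PRODUCT_NUTRIENTS:
            xc = np.array([p.nutrients_per_100g[nutrient] for p in claim])
            xn = np.array([p.nutrients_per_100g[nutrient] for p in nonclaim])
            mn = xn.mean()
            if mn == 0:
                out.append(NQREstimate(g, nutrient, float("nan"), float("nan"),
                                       len(xc), len(xn)))
                continue
            mc = xc.mean()
            ratio = mc / mn
            if len(xc) > 1 and len(xn) > 1 and mc > 0:
                se_c = xc.std(ddof=1) / np.sqrt(len(xc))
                se_n = xn.std(ddof=1) / np.sqrt(len(xn))
                se = abs(ratio) * np.sqrt((se_c / mc) ** 2 + (se_n / mn) ** 2)
            else:
                se = float("nan")
            out.append(NQREstimate(g, nutrient, float(ratio), float(se),
                                   len(xc), len(xn)))
    return out


# ---------------------------------------------------------------------------
# Sales / population / mortality generation
# ---------------------------------------------------------------------------

@dataclass
class StudyInputs:
    sales: SalesTable
    population: list[PopulationStratum]
    mortality: MortalityTable
    intake_sd: NutrientVector


def gen_sales_and_mortality(cfg: ModelConfig | None = None, seed: int = 0) -> StudyInputs:
    """Materialise the purchase/population/mortality inputs.

    The tables are deterministic restatements of the configured totals
    (group sales summing to the published per-person intakes, mortality
    counts as non-negative integers per stratum and cause); ``seed`` is
    accepted for interface symmetry with the product generator.
    """
    if cfg is None:
        cfg = tables.study_calibrated_config()
    mort = MortalityTable()
    if sum(s.count for s in cfg.population) > 0:
        for key, n in cfg.mortality.deaths.items():
            mort.deaths[key] = float(round(n))
    return StudyInputs(
        sales=cfg.sales,
        population=list(cfg.population),
        mortality=mort,
        intake_sd=cfg.intake_sd,
    )


def write_inputs(inputs: StudyInputs, outdir: str | Path,
                 products: Sequence[ProductRecord] | None = None) -> None:
    """Write the generated inputs as CSV files (products/sales/population/mortality)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if products is not None:
        products_to_frame(products).to_csv(outdir / "products.csv", index=False)
    pd.DataFrame(
        [
            {"group": r.group.value, "sales_g": r.sales_g, **r.intake.as_dict()}
            for r in inputs.sales.records.values()
        ]
    ).to_csv(outdir / "sales.csv", index=False)
    pd.DataFrame(
        [{"sex": s.sex, "age_lo": s.age_lo, "count": s.count} for s in inputs.population]
    ).to_csv(outdir / "population.csv", index=False)
    pd.DataFrame(
        [
            {"sex": sex, "age_lo": age, "cause": cause, "deaths": n}
            for (sex, age, cause), n in sorted(inputs.mortality.deaths.items())
        ]
    ).to_csv(outdir / "mortality.csv", index=False)
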