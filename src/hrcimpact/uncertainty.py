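"""Monte Carlo uncertainty propagation and tornado decomposition.

Parameter uncertainty is propagated by sampling a full parameter bundle
per iteration, re-running the deterministic pipeline (baseline
disaggregation → scenario → diet delta → deaths averted) on the
sampled bundle, and reading 95% uncertainty intervals (UIs) off the
2.5th/97.5th percentiles of each output cell.

Sampling families (standard practice; each isolated in one function so
it can be swapped):

* ratio parameters (choice ORs, relative risks, nutrient quality
  ratios) — lognormal, with ``σ = ln(upper/lower) / (2·1.96)`` from the
  95% CI, or ``σ ≈ se/point`` for NQRs reported with an SE;
* proportions (claim prevalences) — logit-normal matched to the CI;
* parameters with degenerate CIs are held constant.

Within an iteration one draw of each parameter is shared by the
baseline and the counterfactual (common random numbers); without this
the deltas would be dominated by sampling noise rather than parameter
uncertainty. Parameters are drawn independently of each other.

The tornado analysis re-runs the Monte Carlo varying one parameter
group at a time (prevalence, nutrient means / NQRs, choice ORs,
epidemiological RRs) with all other groups fixed at central values, and
ranks groups by the width of the resulting UI on total deaths averted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .config import ConfigError, Estimate, ModelConfig, NQRTable
from .disaggregate import baseline_from_config
from .nutrients import NUTRIENTS
from .prime import deaths_averted
from .scenarios import diet_delta, run_scenario

PARAMETER_GROUPS: tuple[str, ...] = (
    "prevalence", "nutrient_means", "choice_ORs", "epi_RRs",
)


@dataclass(frozen=True)
class McSpec:
    """Monte Carlo settings."""

    n_iter: int = 10000
    seed: int = 0
    sampled_groups: tuple[str, ...] = PARAMETER_GROUPS

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        unknown = set(self.sampled_groups) - set(PARAMETER_GROUPS)
        if unknown:
            raise ValueError(f"unknown parameter groups: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def lognormal_sigma(e: Estimate) -> float:
    if e.lo <= 0:
        raise ConfigError(f"lognormal parameter needs a positive CI: {e}")
    return math.log(e.hi / e.lo) / (2 * 1.96)


def sample_ratio(rng: np.random.Generator, e: Estimate) -> float:
    """Lognormal draw with median at the point estimate."""
    if e.degenerate:
        return e.point
    return float(e.point * math.exp(rng.normal(0.0, lognormal_sigma(e))))


def sample_proportion(rng: np.random.Generator, e: Estimate) -> float:
    """Logit-normal draw matched to the CI; stays inside (0, 1)."""
    if e.degenerate or e.point in (0.0, 1.0):
        return e.point
    logit = lambda p: math.log(p / (1 - p))
    lo = max(e.lo, 1e-9)
    hi = min(e.hi, 1 - 1e-9)
    sigma = (logit(hi) - logit(lo)) / (2 * 1.96)
    z = rng.normal(logit(e.point), sigma)
    return float(1.0 / (1.0 + math.exp(-z)))


def sample_or_lognormal(
    point: float, lo: float, hi: float, n: int, seed: int
) -> np.ndarray:
    """Vectorised lognormal OR sampler (median ``point``, σ from the CI)."""
    sigma = math.log(hi / lo) / (2 * 1.96)
    rng = np.random.default_rng(seed)
    return point * np.exp(rng.normal(0.0, sigma, n))


# ---------------------------------------------------------------------------
# Bundle sampling
# ---------------------------------------------------------------------------

def sample_parameters(cfg: ModelConfig, spec: McSpec, iteration: int) -> ModelConfig:
    """Draw one perturbed parameter bundle, reproducible per (seed, iteration).

    Sampled values are installed as degenerate estimates so the
    downstream pipeline (which reads ``.point``) sees the draw.
    """
    rng = np.random.default_rng([spec.seed, iteration])
    groups = set(spec.sampled_groups)

    hrc = {}
    for g in sorted(cfg.hrc_params, key=lambda x: x.value):
        p = cfg.hrc_params[g]
        orc, qb, qf, qe = p.or_choice, p.q_baseline, p.q_pass_fsanz, p.q_pass_eu
        if "choice_ORs" in groups:
            orc = Estimate.exact(sample_ratio(rng, orc))
        if "prevalence" in groups:
            qb = Estimate.exact(sample_proportion(rng, qb))
            qf = Estimate.exact(sample_proportion(rng, qf))
            qe = Estimate.exact(sample_proportion(rng, qe))
        hrc[g] = replace(p, or_choice=orc, q_baseline=qb, q_pass_fsanz=qf,
                         q_pass_eu=qe)

    nqr = cfg.nqr
    if "nutrient_means" in groups:
        nqr = NQRTable()
        for key in sorted(cfg.nqr.entries, key=lambda k: (k[0].value, k[1], k[2])):
            e = cfg.nqr.entries[key]
            if math.isnan(e.se) or e.se == 0:
                draw = e.nqr
            else:
                sigma = math.sqrt(math.log1p((e.se / e.nqr) ** 2))
                draw = e.nqr * math.exp(rng.normal(0.0, sigma))
            nqr.set(key[0], key[1], key[2], draw, e.se)

    links = cfg.links
    if "epi_RRs" in groups:
        links = [
            replace(l, rr_per_unit=Estimate.exact(sample_ratio(rng, l.rr_per_unit)))
            for l in cfg.links
        ]

    return replace(cfg, hrc_params=hrc, nqr=nqr, links=links)


# ---------------------------------------------------------------------------
# Pipeline evaluation and Monte Carlo
# ---------------------------------------------------------------------------

def evaluate_pipeline(cfg: ModelConfig, model: str) -> dict[str, float]:
    """One deterministic pipeline run; returns all reported output cells."""
    baseline = baseline_from_config(cfg)
    scenario = run_scenario(cfg, model, baseline=baseline)
    delta = diet_delta(scenario, baseline)
    # by-sex/by-cause rows accompany the main (non-energy) total; the
    # energy-inclusive total is reported as its own row
    deaths = deaths_averted(delta, cfg, include_energy=False)
    out = {f"delta_{n}": delta[n] for n in NUTRIENTS}
    out["deaths_total"] = deaths.total
    out["deaths_total_with_energy"] = deaths.total_with_energy
    for sex, v in deaths.by_sex.items():
        out[f"deaths_{sex}"] = v
    for cg, v in deaths.by_cause_group.items():
        out[f"deaths_{cg}"] = v
    for rf, v in deaths.by_risk_factor.items():
        out[f"deaths_rf_{rf}"] = v
    return out


@dataclass
class MCResult:
    """Point estimates (central parameters) with 95% UIs per output cell."""

    model: str
    spec: McSpec
    point: dict[str, float]
    lo: dict[str, float]
    hi: dict[str, float]
    draws: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def ui_width(self, cell: str) -> float:
        return self.hi[cell] - self.lo[cell]


def monte_carlo(
    cfg: ModelConfig,
    model: str,
    spec: McSpec,
    progress: Callable[[int], None] | None = None,
) -> MCResult:
    """Monte Carlo uncertainty intervals for one scenario's output cells."""
    point = evaluate_pipeline(cfg, model)
    cells = list(point)
    draws = {c: np.empty(spec.n_iter) for c in cells}
    for i in range(spec.n_iter):
        try:
            sampled = sample_parameters(cfg, spec, i)
            res = evaluate_pipeline(sampled, model)
        except Exception as exc:
            raise RuntimeError(f"Monte Carlo iteration {i} failed: {exc}") from exc
        for c in cells:
            draws[c][i] = res.get(c, np.nan)
        if progress is not None and (i + 1) % 1000 == 0:
            progress(i + 1)
    lo = {c: float(np.percentile(draws[c], 2.5)) for c in cells}
    hi = {c: float(np.percentile(draws[c], 97.5)) for c in cells}
    return MCResult(model=model, spec=spec, point=point, lo=lo, hi=hi, draws=draws)


def tornado(
    cfg: ModelConfig,
    model: str,
    spec: McSpec,
    cell: str = "deaths_total",
) -> list[tuple[str, float]]:
    """One-at-a-time UI widths per parameter group, sorted descending.

    Non-varied groups are fixed at their central values.
    """
    widths = []
    for group in PARAMETER_GROUPS:
        res = monte_carlo(cfg, model, replace(spec, sampled_groups=(group,)))
        widths.append((group, res.ui_width(cell)))
    return sorted(widths, key=lambda t: -t[1])
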