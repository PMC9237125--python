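"""ATP-production accounting, aero-type classification, H+/ATP estimation.

ATP accounting applies a fixed table of signed ATP stoichiometric
coefficients to net reaction fluxes: ``total = sum_i c_i * v_i``.  The
coefficients refer to each reaction written in its BiGG direction, so
reactions catalogued as ATP consumers (c = -1) that physiologically run in
reverse during growth — phosphoglycerate kinase, succinyl-CoA synthetase and
acetate kinase — contribute *positively* through the sign of their net flux.
This makes the single signed sum recover the textbook picture in which
ATPS, ACKr, SUCOAS and PGK are the four ATP producers.

The aero-type of a strain is the index of its ``fraction of total ATP
produced through ATP synthase`` within a strictly increasing list of class
boundaries; higher classes are more oxidative phenotypes.

The proton-to-ATP ratio of ATP synthase is estimated by scanning candidate
ratios over a grid (default 2.5..4.5), re-solving growth at each ratio under
the measured exchange constraints and picking the ratio whose predicted
growth rate best matches the observed one (absolute difference; ties go to
the lower ratio).
"""

from __future__ import annotations

import csv
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fba import FluxSolution, PhenotypeConstraints, solve_growth
from .network import MetabolicModel, ValidationError, set_h_per_atp

logger = logging.getLogger("aerotype")

#: ATP stoichiometric coefficients per reaction (reaction written direction).
ATP_COEFFICIENTS: dict[str, int] = {
    "PPK": -1,
    "PPK2": -1,
    "ATPS4rpp": 1,
    "PFK_2": -1,
    "HEX1": -1,
    "PYK": 1,
    "PFK": -1,
    "PPS": -1,
    "PGK": -1,
    "GLGC": -1,
    "PFK_3": -1,
    "GART": -1,
    "PPAKr": 1,
    "ACCOAL": -1,
    "ACS": -1,
    "ACKr": -1,
    "SUCOAS": -1,
}

#: The four reactions whose contributions are reported individually.
BREAKDOWN_REACTIONS = ("ATPS4rpp", "ACKr", "SUCOAS", "PGK")

DEFAULT_AEROTYPE_BOUNDARIES = (0.25, 0.5, 0.75)

DEFAULT_GRID_LO = 2.5
DEFAULT_GRID_HI = 4.5
DEFAULT_GRID_STEP = 0.05

#: Rotational-catalysis ratio: 10 c-ring protons per 3 ATP.
ROTATIONAL_H_PER_ATP = 10.0 / 3.0

#: Growth-rate differences below this are treated as scan ties (LP noise).
TIE_TOLERANCE = 1e-6


def load_atp_table(path: str | Path) -> dict[str, int]:
    """Load an ATP coefficient table CSV (reaction_id, coefficient)."""
    table: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            coef = int(row["coefficient"])
            if coef == 0:
                raise ValueError(f"zero ATP coefficient for {row['reaction_id']}")
            table[row["reaction_id"]] = coef
    return table


def default_atp_table() -> dict[str, int]:
    return dict(ATP_COEFFICIENTS)


@dataclass
class ATPAccount:
    total: float
    by_reaction: dict[str, float]
    fraction_atps: float

    @property
    def breakdown(self) -> dict[str, float]:
        return {r: self.by_reaction.get(r, 0.0) for r in BREAKDOWN_REACTIONS}


@dataclass
class AeroType:
    fraction_atps: float
    class_index: int


@dataclass
class HPerATPEstimate:
    grid: list[float]
    per_replicate_best: dict[str, float]
    median: float
    range: tuple[float, float]
    per_replicate_error: dict[str, float] = field(default_factory=dict)


def total_atp_production(
    solution: FluxSolution,
    table: dict[str, int] | None = None,
    atps_reaction_id: str = "ATPS4rpp",
) -> ATPAccount:
    """Signed ATP production ledger for one optimal flux solution."""
    if not solution.optimal:
        raise ValidationError("ATP accounting requires an optimal solution")
    if table is None:
        table = ATP_COEFFICIENTS
    by_reaction: dict[str, float] = {}
    missing = []
    for rid, coef in table.items():
        if rid in solution.fluxes:
            by_reaction[rid] = coef * solution.fluxes[rid]
        else:
            missing.append(rid)
    if missing:
        logger.warning("ATP table reactions absent from model, skipped: %s",
                       sorted(missing))
    total = sum(by_reaction.values())
    produced = sum(v for v in by_reaction.values() if v > 0)
    atps_contrib = by_reaction.get(atps_reaction_id, 0.0)
    fraction = max(atps_contrib, 0.0) / produced if produced > 0 else 0.0
    return ATPAccount(total=total, by_reaction=by_reaction, fraction_atps=fraction)


def classify_aerotype(
    account: ATPAccount | float,
    boundaries=DEFAULT_AEROTYPE_BOUNDARIES,
) -> AeroType:
    """Class index = number of boundaries strictly below fraction_atps."""
    fraction = account.fraction_atps if isinstance(account, ATPAccount) else float(account)
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction_atps must lie in [0, 1], got {fraction}")
    bounds = list(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("aero-type boundaries must be strictly increasing")
    if any(not 0.0 < b < 1.0 for b in bounds):
        raise ValueError("aero-type boundaries must lie in (0, 1)")
    index = sum(1 for b in bounds if b < fraction)
    return AeroType(fraction_atps=fraction, class_index=index)


def make_grid(lo: float, hi: float, step: float) -> list[float]:
    if not lo < hi:
        raise ValueError("grid_lo must be below grid_hi")
    n = int(round((hi - lo) / step))
    grid = [round(lo + i * step, 10) for i in range(n + 1)]
    if grid[-1] > hi + 1e-9:
        grid.pop()
    return grid


def scan_h_per_atp(
    model: MetabolicModel,
    phenotype: PhenotypeConstraints,
    mu_observed: float,
    expression: dict[str, float] | None = None,
    grid: list[float] | None = None,
    proteome_budget: float | None = None,
) -> tuple[float, float, dict[float, float]]:
    """Scan one replicate; return (best ratio, its |mu error|, mu by ratio)."""
    if grid is None:
        grid = make_grid(DEFAULT_GRID_LO, DEFAULT_GRID_HI, DEFAULT_GRID_STEP)
    mu_by_ratio: dict[float, float] = {}
    for h in grid:
        trial = model.copy()
        set_h_per_atp(trial, h)
        sol = solve_growth(trial, phenotype, expression, proteome_budget)
        if sol.optimal:
            mu_by_ratio[h] = sol.growth_rate
    if not mu_by_ratio:
        raise ValidationError("H+/ATP scan infeasible at every grid ratio")
    # argmin of |mu_pred - mu_obs|; ties (within LP noise) resolve toward the
    # lower ratio, i.e. the most proton-efficient stoichiometry
    errors = {h: abs(mu - mu_observed) for h, mu in mu_by_ratio.items()}
    err_min = min(errors.values())
    best = min(h for h, e in errors.items() if e <= err_min + TIE_TOLERANCE)
    best_mu = mu_by_ratio[best]
    if mu_observed > max(mu_by_ratio.values()) + 1e-9:
        logger.warning(
            "observed growth rate %.3f exceeds every achievable rate; "
            "scan pinned at the most proton-efficient ratio", mu_observed)
    return best, abs(best_mu - mu_observed), mu_by_ratio


def estimate_h_per_atp(
    replicates: dict[str, tuple[MetabolicModel, PhenotypeConstraints, float]],
    expression: dict[str, dict[str, float] | None] | None = None,
    grid_lo: float = DEFAULT_GRID_LO,
    grid_hi: float = DEFAULT_GRID_HI,
    step: float = DEFAULT_GRID_STEP,
    proteome_budget: float | None = None,
) -> HPerATPEstimate:
    """Estimate the proton-to-ATP ratio over replicate strains.

    ``replicates`` maps a replicate name to ``(model, phenotype,
    observed growth rate)``; each replicate may carry its own (variant- and
    evolution-specific) model.  ``expression`` optionally maps replicate
    names to expression-share profiles.
    """
    grid = make_grid(grid_lo, grid_hi, step)
    per_best: dict[str, float] = {}
    per_err: dict[str, float] = {}
    for name, (model, phenotype, mu_obs) in replicates.items():
        expr = (expression or {}).get(name)
        best, err, _ = scan_h_per_atp(model, phenotype, mu_obs, expr, grid,
                                      proteome_budget)
        per_best[name] = best
        per_err[name] = err
    values = list(per_best.values())
    return HPerATPEstimate(
        grid=grid,
        per_replicate_best=per_best,
        median=float(statistics.median(values)),
        range=(min(values), max(values)),
        per_replicate_error=per_err,
    )


def rotational_h_per_atp(c_ring_size: int = 10, f1_symmetry: int = 3) -> float:
    """Closed-form proton-to-ATP ratio from rotor/head symmetry mismatch."""
    if c_ring_size <= 0 or f1_symmetry <= 0:
        raise ValueError("symmetry counts must be positive")
    return c_ring_size / f1_symmetry
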