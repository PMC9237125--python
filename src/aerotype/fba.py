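"""Proteome-constrained growth maximization and proteome-allocation accounting.

The solver maximizes flux through the biomass reaction subject to
steady-state mass balance (``S v = 0``), reaction bounds, measured exchange
rates, and — when an expression profile is supplied — a linear enzyme
capacity bound per reaction:

    v_j <= kcat_j * (phi_g * P_total) / mw_j

where ``phi_g`` is the catalysing gene's expression share (shares sum to 1
over the model's enzymatic genes), ``P_total`` the proteome budget in
gProtein/gDW, ``mw_j`` in kDa and ``kcat_j`` converted to 1/h.  Reversible
reactions are split into forward/backward nonnegative fluxes and the
capacity bound caps their sum, so it limits total usage of the enzyme in
either direction.  Among alternate optima the reported fluxes are the
parsimonious ones (secondary minimization of total absolute flux at fixed
optimal growth).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicModel, ValidationError

logger = logging.getLogger("aerotype")

#: Proteome budget available to metabolic enzymes, gProtein/gDW.
PROTEOME_BUDGET = 0.55

#: LP feasibility/optimality tolerance handed to HiGHS.
LP_TOL = 1e-9

GLUCOSE_EXCHANGE = "EX_glc__D_e"
ACETATE_EXCHANGE = "EX_ac_e"
OXYGEN_EXCHANGE = "EX_o2_e"


@dataclass
class PhenotypeConstraints:
    """Measured exchange rates for one strain (mmol/gDW/h; growth in 1/h)."""

    glucose_uptake: float
    acetate_secretion: float = 0.0
    o2_uptake_max: float = 20.0
    growth_rate_observed: float | None = None
    fix_acetate: bool = True

    def __post_init__(self) -> None:
        for name in ("glucose_uptake", "acetate_secretion", "o2_uptake_max"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.glucose_uptake < 0:
            raise ValueError("glucose_uptake must be nonnegative")
        if self.acetate_secretion < 0:
            raise ValueError("acetate_secretion must be nonnegative")


@dataclass
class FluxSolution:
    status: str                       # "optimal" | "infeasible"
    growth_rate: float
    fluxes: dict[str, float]
    enzyme_demand: dict[str, float]   # gene -> sum |v|/kcat  (mmol/gDW)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class ProteomeAllocation:
    per_protein_mass: dict[str, float]
    total: float
    ats_total: float
    ats_fraction: float


def uniform_expression(model: MetabolicModel) -> dict[str, float]:
    """Equal expression shares over every gene with an enzyme spec."""
    genes = sorted(set(model.enzymes) & model.genes())
    if not genes:
        raise ValidationError("model has no enzymatic genes")
    share = 1.0 / len(genes)
    return {g: share for g in genes}


def normalize_expression(raw: dict[str, float], model: MetabolicModel) -> dict[str, float]:
    """Restrict a raw nonnegative expression vector to model genes, as shares."""
    genes = set(model.enzymes) & model.genes()
    vals = {g: max(float(raw.get(g, 0.0)), 0.0) for g in genes}
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("expression profile has no mass on model genes")
    return {g: v / total for g, v in vals.items()}


def mass_shares(solution: FluxSolution, model: MetabolicModel,
                background: float = 0.0) -> dict[str, float]:
    """Expression shares implied by a flux solution's enzyme usage.

    Shares are proportional to each gene's enzyme mass (mw * |v|/kcat),
    optionally blended with a uniform background fraction so that unused
    enzymes keep a leaky basal expression level.
    """
    genes = sorted(set(model.enzymes) & model.genes())
    mass = {g: model.enzymes[g].molecular_weight * solution.enzyme_demand.get(g, 0.0)
            for g in genes}
    total = sum(mass.values())
    if total <= 0:
        raise ValueError("solution has no enzyme usage")
    uniform = 1.0 / len(genes)
    return {
        g: (1.0 - background) * mass[g] / total + background * uniform
        for g in genes
    }


def _check_expression(expression: dict[str, float]) -> None:
    if any(v < 0 for v in expression.values()):
        raise ValueError("expression shares must be nonnegative")
    total = sum(expression.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"expression shares must sum to 1 (got {total:.6g})")


def _build_lp(model, phenotype, expression, proteome_budget=None):
    """Assemble the split-variable LP.  Returns (rxn order, matrices)."""
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}

    # per-reaction effective bounds after phenotype overlay
    bounds: dict[str, tuple[float, float]] = {
        rid: (model.reactions[rid].lower_bound, model.reactions[rid].upper_bound)
        for rid in rxn_ids
    }
    if phenotype is not None:
        glc = phenotype.glucose_uptake
        bounds[GLUCOSE_EXCHANGE] = (-glc, 0.0)
        if phenotype.fix_acetate:
            bounds[ACETATE_EXCHANGE] = (phenotype.acetate_secretion,
                                        phenotype.acetate_secretion)
        bounds[OXYGEN_EXCHANGE] = (-phenotype.o2_uptake_max, 0.0)

    # split: one forward and one backward column per reaction
    n = len(rxn_ids)
    ncols = 2 * n
    col_bounds = []
    for rid in rxn_ids:
        lb, ub = bounds[rid]
        col_bounds.append((max(lb, 0.0), max(ub, 0.0)))          # forward
        col_bounds.append((max(-ub, 0.0), max(-lb, 0.0)))        # backward

    A_eq = np.zeros((len(met_ids), ncols))
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoichiometry.items():
            i = met_index[met]
            A_eq[i, 2 * j] += coef
            A_eq[i, 2 * j + 1] -= coef

    A_ub_rows, b_ub = [], []
    if expression is not None:
        _check_expression(expression)
        gene_rxns: dict[str, list[int]] = {}
        for j, rid in enumerate(rxn_ids):
            for g in model.reactions[rid].genes:
                if g in model.enzymes:
                    gene_rxns.setdefault(g, []).append(j)
        for g in sorted(gene_rxns):
            share = expression.get(g, 0.0)
            spec = model.enzymes[g]
            cap = spec.kcat * 3600.0 * share * PROTEOME_BUDGET / spec.molecular_weight
            row = np.zeros(ncols)
            for j in gene_rxns[g]:
                row[2 * j] = 1.0
                row[2 * j + 1] = 1.0
            A_ub_rows.append(row)
            b_ub.append(cap)

    if proteome_budget is not None:
        # shared knapsack: total enzyme mass supporting all fluxes is capped,
        # so proteome spent on proton pumping is unavailable elsewhere
        row = np.zeros(ncols)
        for j, rid in enumerate(rxn_ids):
            cost = 0.0
            for g in model.reactions[rid].genes:
                spec = model.enzymes.get(g)
                if spec is not None:
                    cost += spec.molecular_weight / (spec.kcat * 3600.0)
            if cost > 0:
                row[2 * j] = cost
                row[2 * j + 1] = cost
        A_ub_rows.append(row)
        b_ub.append(float(proteome_budget))

    A_ub = np.array(A_ub_rows) if A_ub_rows else None
    b_ub = np.array(b_ub) if A_ub_rows else None
    return rxn_ids, A_eq, A_ub, b_ub, col_bounds


def _solve(c, A_eq, b_eq, A_ub, b_ub, bounds):
    return linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )


def solve_growth(
    model: MetabolicModel,
    phenotype: PhenotypeConstraints | None = None,
    expression: dict[str, float] | None = None,
    proteome_budget: float | None = None,
) -> FluxSolution:
    """Maximize growth; return the parsimonious optimal flux distribution.

    With ``expression`` each reaction is capped by its gene's expression
    share of the proteome (per-gene capacity); with ``proteome_budget`` a
    single shared enzyme-mass budget constrains all fluxes jointly; with
    neither the problem is plain FBA.  Infeasible constraint sets yield
    ``status="infeasible"`` rather than an exception; an unbounded problem
    (uncapped substrate uptake) raises.
    """
    rxn_ids, A_eq, A_ub, b_ub, col_bounds = _build_lp(
        model, phenotype, expression, proteome_budget)
    b_eq = np.zeros(A_eq.shape[0])
    biomass = model.biomass_reaction_id
    j_bio = rxn_ids.index(biomass)

    c = np.zeros(2 * len(rxn_ids))
    c[2 * j_bio] = -1.0
    c[2 * j_bio + 1] = 1.0
    res = _solve(c, A_eq, b_eq, A_ub, b_ub, col_bounds)
    if res.status == 3:
        raise ValidationError("LP unbounded: model must cap substrate uptake")
    if not res.success:
        return FluxSolution("infeasible", 0.0, {}, {})
    mu = float(res.x[2 * j_bio] - res.x[2 * j_bio + 1])

    # parsimonious pass: fix growth at its optimum, minimize total |v|
    bounds2 = list(col_bounds)
    bounds2[2 * j_bio] = (mu, mu)
    bounds2[2 * j_bio + 1] = (0.0, 0.0)
    c2 = np.ones(2 * len(rxn_ids))
    res2 = _solve(c2, A_eq, b_eq, A_ub, b_ub, bounds2)
    x = res2.x if res2.success else res.x

    fluxes = {rid: float(x[2 * j] - x[2 * j + 1]) for j, rid in enumerate(rxn_ids)}
    demand: dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        for g in rxn.genes:
            spec = model.enzymes.get(g)
            if spec is not None:
                demand[g] = demand.get(g, 0.0) + abs(fluxes[rid]) / (spec.kcat * 3600.0)
    return FluxSolution("optimal", mu, fluxes, demand)


def compute_proteome_allocation(
    solution: FluxSolution, model: MetabolicModel
) -> ProteomeAllocation:
    """Total and ATS proteome mass flux: sum_i mw_i * mu * demand_i.

    ``V_i^translation = mu * demand_i`` is the synthesis flux needed to
    sustain the enzyme level diluted by growth; weighting by molecular
    weight gives the per-protein proteome mass allocation.
    """
    if not solution.optimal:
        raise ValidationError("proteome allocation requires an optimal solution")
    mu = solution.growth_rate
    per_protein = {
        g: model.enzymes[g].molecular_weight * mu * d
        for g, d in solution.enzyme_demand.items()
        if g in model.enzymes
    }
    total = sum(per_protein.values())
    ats_total = sum(v for g, v in per_protein.items() if g in model.ats_gene_set)
    if total <= 0:
        logger.warning("zero proteome allocation; ats_fraction reported as 0")
        fraction = 0.0
    else:
        fraction = ats_total / total
    return ProteomeAllocation(per_protein, total, ats_total, fraction)


def knockout(model: MetabolicModel, genes) -> MetabolicModel:
    """Return a copy with every reaction losing all active genes closed."""
    genes = list(genes)
    known = model.genes()
    unknown = [g for g in genes if g not in known]
    if unknown:
        raise ValidationError(f"unknown genes: {unknown}")
    out = model.copy()
    removed = set(genes)
    hit = False
    for rxn in out.reactions.values():
        if rxn.genes and all(g in removed for g in rxn.genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
            hit = True
        elif set(rxn.genes) & removed:
            hit = True
    if not hit:
        logger.warning("knockout of %s affected no reaction", genes)
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> dict[str, PhenotypeConstraints]:
    """Read a phenotype TSV (strain, glucose_uptake, acetate_secretion,
    o2_max, growth_rate [, extra columns]) into per-strain constraints."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"strain", "glucose_uptake", "acetate_secretion", "o2_max",
                "growth_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["strain"])] = PhenotypeConstraints(
            glucose_uptake=float(row["glucose_uptake"]),
            acetate_secretion=float(row["acetate_secretion"]),
            o2_uptake_max=float(row["o2_max"]),
            growth_rate_observed=float(row["growth_rate"]),
        )
    return out


def read_expression_tsv(path):
    """Read an expression TSV (first column gene) into a DataFrame."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any() and df.values.min() < -1e-9:
        logger.warning("expression table contains negative values")
    return df
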