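"""End-to-end orchestration of the aero-type analysis chain.

Stages, in order: load and validate the model; rebuild each strain's
condition-specific model (ETS knockouts, per-condition kcat factor); solve
proteome-constrained growth under the measured exchange rates; compute
proteome allocation, the ATP-production ledger and the aero-type class;
scan the H+/ATP ratio per evolved replicate; decompose the ATS expression
matrix with robust ICA and correlate activities with aero-types; process
the mutation table (dedup, hypermutator flags, effect calls, convergence);
and summarize ATP produced per ATS proteome across strains.

Every stage is a pure function of (inputs, config, seed); the report and
all intermediate tables are written into the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioenergetics, fba, ica, mutations, network

logger = logging.getLogger("aerotype")

REPORT_SCHEMA_VERSION = "1.0"
#: cross-variant coefficient of variation regarded as "approximately equal"
#: ATP output per ATS proteome among evolved strains
DEFAULT_CV_TOLERANCE = 0.2


@dataclass
class RunConfig:
    model: str | None = None             # None -> bundled reference model
    phenotype: str = "phenotype.tsv"
    expression: str | None = "expression.tsv"
    meta: str | None = "meta.tsv"
    mutations: str | None = "mutations.csv"
    outdir: str = "aerotype_out"
    seed: int = 42
    grid_lo: float = bioenergetics.DEFAULT_GRID_LO
    grid_hi: float = bioenergetics.DEFAULT_GRID_HI
    grid_step: float = bioenergetics.DEFAULT_GRID_STEP
    aerotype_boundaries: tuple[float, ...] = bioenergetics.DEFAULT_AEROTYPE_BOUNDARIES
    ica_k_max: int = 8
    ica_restarts: int = ica.DEFAULT_RESTARTS
    min_lineages: int = 4
    proteome_budget: float = fba.PROTEOME_BUDGET
    cv_tolerance: float = DEFAULT_CV_TOLERANCE
    run_ica: bool = True
    run_hscan: bool = True
    run_mutations: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "aerotype_boundaries" in data:
            data["aerotype_boundaries"] = tuple(data["aerotype_boundaries"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["aerotype_boundaries"] = list(self.aerotype_boundaries)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def validate(self) -> None:
        if not Path(self.phenotype).exists():
            raise FileNotFoundError(f"phenotype table missing: {self.phenotype}")
        if self.model is not None and not Path(self.model).exists():
            raise FileNotFoundError(f"model file missing: {self.model}")
        if self.run_ica:
            if self.expression is None or not Path(self.expression).exists():
                raise ValueError("ICA enabled but expression matrix missing")
            if self.meta is None or not Path(self.meta).exists():
                raise ValueError("ICA enabled but condition metadata missing")
        if self.run_mutations and (
                self.mutations is None or not Path(self.mutations).exists()):
            raise ValueError("mutation analysis enabled but table missing")
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid_lo must be below grid_hi")


@dataclass
class StudyReport:
    config: dict
    strains: dict[str, dict]
    h_per_atp: dict | None
    imodulons: dict | None
    correlations: dict | None
    convergence: list | None
    hypermutators: list | None
    effects: dict | None
    ats_efficiency: dict | None
    schema_version: str = REPORT_SCHEMA_VERSION

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True, default=float))


def _condition_model(model: network.MetabolicModel, variant: str,
                     kcat_scale: float) -> network.MetabolicModel:
    if variant and variant != "WT":
        n = int(variant.split("-")[1][0])
        cond = network.build_variant(model, n)
    else:
        cond = model.copy()
    if kcat_scale and kcat_scale != 1.0:
        network.scale_kcats(cond, cond.ats_gene_set, float(kcat_scale))
    return cond


def _stage(name):
    logger.info("stage: %s", name)
    return time.monotonic()


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full analysis chain; see module docstring for stages."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    t = _stage("load model")
    model = (network.load_model(config.model) if config.model
             else network.reference_model())

    t = _stage("solve per condition")
    pheno = pd.read_csv(config.phenotype, sep="\t")
    strains: dict[str, dict] = {}
    classes: dict[str, int] = {}
    for _, row in pheno.iterrows():
        name = str(row["strain"])
        variant = str(row.get("variant", "WT"))
        scale = float(row.get("kcat_scale", 1.0))
        cond_model = _condition_model(model, variant, scale)
        ph = fba.PhenotypeConstraints(
            glucose_uptake=float(row["glucose_uptake"]),
            acetate_secretion=float(row["acetate_secretion"]),
            o2_uptake_max=float(row["o2_max"]),
            growth_rate_observed=float(row["growth_rate"]),
        )
        sol = fba.solve_growth(cond_model, ph, None, config.proteome_budget)
        entry: dict = {
            "variant": variant,
            "phase": str(row.get("phase", "")),
            "status": sol.status,
            "growth_rate_observed": float(row["growth_rate"]),
        }
        if sol.optimal:
            alloc = fba.compute_proteome_allocation(sol, cond_model)
            account = bioenergetics.total_atp_production(sol)
            aero = bioenergetics.classify_aerotype(
                account, config.aerotype_boundaries)
            classes[name] = aero.class_index
            entry.update({
                "growth_rate_predicted": sol.growth_rate,
                "glucose_uptake": -sol.fluxes[fba.GLUCOSE_EXCHANGE],
                "acetate_secretion": sol.fluxes[fba.ACETATE_EXCHANGE],
                "o2_uptake": -sol.fluxes[fba.OXYGEN_EXCHANGE],
                "atp_total": account.total,
                "atp_breakdown": account.breakdown,
                "fraction_atps": account.fraction_atps,
                "aerotype_class": aero.class_index,
                "proteome_total": alloc.total,
                "proteome_ats": alloc.ats_total,
                "ats_fraction": alloc.ats_fraction,
            })
        strains[name] = entry
    pd.DataFrame(strains).T.to_csv(outdir / "strains.tsv", sep="\t")

    h_result = None
    if config.run_hscan:
        t = _stage("H+/ATP scan")
        replicates = {}
        for _, row in pheno.iterrows():
            if str(row.get("phase", "")) != "evolved":
                continue
            name = str(row["strain"])
            cond_model = _condition_model(model, str(row["variant"]),
                                          float(row.get("kcat_scale", 1.0)))
            ph = fba.PhenotypeConstraints(
                glucose_uptake=float(row["glucose_uptake"]),
                acetate_secretion=float(row["acetate_secretion"]),
                o2_uptake_max=float(row["o2_max"]),
            )
            replicates[name] = (cond_model, ph, float(row["growth_rate"]))
        if replicates:
            est = bioenergetics.estimate_h_per_atp(
                replicates, None, config.grid_lo, config.grid_hi,
                config.grid_step, proteome_budget=config.proteome_budget)
            h_result = {
                "median": est.median,
                "range": list(est.range),
                "per_replicate": est.per_replicate_best,
            }

    imodulons_out = None
    correlations_out = None
    if config.run_ica:
        t = _stage("ICA")
        expr = fba.read_expression_tsv(config.expression)
        meta = pd.read_csv(config.meta, sep="\t").fillna({"replicate": ""})
        reference = None
        wt_rows = meta[(meta["phase"] == "wt")]
        for _, r in wt_rows.iterrows():
            if str(r["condition"]).startswith("u"):
                reference = str(r["condition"])
        if reference is None:
            reference = str(meta["condition"].iloc[0])
            logger.warning("no unevolved wild type found; centering on %s",
                           reference)
        centered = ica.center_to_reference(expr, reference)
        result = ica.run_robust_ica(centered, k_max=config.ica_k_max,
                                    n_restarts=config.ica_restarts,
                                    seed=config.seed)
        result.S.to_csv(outdir / "ica_S.tsv", sep="\t")
        result.A.to_csv(outdir / "ica_A.tsv", sep="\t")
        imodulons_out = {c: sorted(g) for c, g in result.imodulons.items()}
        (outdir / "imodulons.json").write_text(json.dumps(imodulons_out, indent=1))
        report = ica.correlate(expr, meta, result.A, classes)
        correlations_out = {
            "endpoint_replicate_rho": report.endpoint_replicate_rho,
            "pre_post_rho": report.pre_post_rho,
            "activity_vs_aerotype_rho": {
                c: {"rho": v[0], "sign": v[1]}
                for c, v in report.activity_vs_aerotype_rho.items()},
        }

    convergence_out = None
    hyper_out = None
    effects_out = None
    if config.run_mutations:
        t = _stage("mutation analysis")
        records = mutations.read_mutations_csv(config.mutations)
        deduped = mutations.dedupe_unique_per_ale(records)
        flags = mutations.flag_hypermutators(deduped)
        hyper_out = sorted(["/".join(k) for k, v in flags.items() if v])
        hits = mutations.detect_convergence(
            deduped, n_lineages=4, min_lineages=config.min_lineages,
            hypermutator_flags=flags)
        convergence_out = [list(h) for h in hits]
        effects_out = {}
        for rec in deduped:
            try:
                call = mutations.classify_effect(rec)
            except ValueError:
                continue
            key = f"{rec.experiment}/{rec.lineage}/{rec.gene}"
            effects_out.setdefault(key, call.summary)

    t = _stage("ATS efficiency")
    report = StudyReport(
        config=dataclasses.asdict(config),
        strains=strains,
        h_per_atp=h_result,
        imodulons=imodulons_out,
        correlations=correlations_out,
        convergence=convergence_out,
        hypermutators=hyper_out,
        effects=effects_out,
        ats_efficiency=None,
    )
    report.ats_efficiency = report_ats_efficiency(report)
    report.to_json(outdir / "report.json")
    return report


def report_ats_efficiency(report: StudyReport) -> dict:
    """ATP produced per ATS proteome mass fraction, per strain, with the
    coefficient of variation across evolved strains."""
    ratios: dict[str, float] = {}
    flagged: list[str] = []
    for name, entry in report.strains.items():
        if entry.get("status") != "optimal":
            continue
        ats_fraction = entry.get("ats_fraction", 0.0)
        if ats_fraction <= 0:
            flagged.append(name)
            continue
        ratios[name] = entry["atp_total"] / ats_fraction
    evolved = [v for name, v in ratios.items()
               if report.strains[name].get("phase") == "evolved"]
    cv = None
    if len(evolved) >= 2:
        cv = float(np.std(evolved) / np.mean(evolved))
    return {
        "per_strain": ratios,
        "undefined": flagged,
        "evolved_cv": cv,
    }
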