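"""Synthetic study generator with planted ground truth.

Emulates the full evolution-study design — four unbranched ETS variants,
each with one unevolved strain and four independently evolved replicate
lineages, plus unevolved and evolved wild types (22 conditions in all) —
so that every analysis stage can be exercised and checked against a
serialized truth file without any external data.

Planted structure:

* phenotypes are forward solutions of the bundled model under a shared
  proteome budget at a chosen true H+/ATP ratio; unevolved strains carry
  per-variant sub-unity ATS kcat factors (unadapted catalytic efficiency /
  regulation of the rewired ETS), evolved strains carry factors calibrated
  by bisection so every variant reaches a common growth plateau;
* the ATS expression matrix (209 genes x 22 conditions) is a block-sparse
  low-rank signal: disjoint gene modules whose activities rise (oxic
  modules) or fall (anoxic modules) with the variant's aero-type class,
  zero in the unevolved wild-type reference column, plus Gaussian noise at
  a chosen signal-to-noise ratio;
* the mutation table plants one convergent mutation per variant in all four
  lineages (including one start-codon loss and one premature stop),
  Poisson-distributed passenger mutations, midpoint duplicates, and one
  mutS hypermutator lineage with a five-fold mutation load.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fba, network
from .mutations import MutationRecord, records_to_frame

logger = logging.getLogger("aerotype")

REGISTRY_SIZE = 209
N_VARIANTS = 4
REPLICATES = ("A", "B", "C", "D")

DEFAULT_H_PER_ATP_TRUE = network.DEFAULT_H_PER_ATP
DEFAULT_PHENOTYPE_NOISE = 0.02
DEFAULT_EXPRESSION_SNR = 10.0
DEFAULT_BACKGROUND_RATE = 2.0
#: common growth plateau the evolved strains are calibrated to, 1/h
MU_PLATEAU = 0.85
#: unadapted ATS kcat factors for the unevolved strains (WT keyed 0)
UNEVOLVED_KCAT_FACTORS = {0: 0.75, 1: 0.45, 2: 0.60, 3: 0.50, 4: 0.35}
GLUCOSE_EXCESS = 50.0
O2_SUPPLY = 40.0

#: convergent mutation target per variant; intergenic regions keyed A-B
DEFAULT_CONVERGENT_GENES = {
    "ETS-1H": "pyrE-rph",
    "ETS-2H": "hns-tdk",
    "ETS-3H": "sdhA",
    "ETS-4H": "yjjX",
}
HYPERMUTATOR_LINEAGE = ("ETS-4H", "C")


@dataclass
class StudyDesign:
    n_variants: int = N_VARIANTS
    replicates: tuple[str, ...] = REPLICATES
    include_wt: bool = True

    @property
    def conditions(self) -> list[str]:
        out = [f"uETS-{n}H" for n in range(1, self.n_variants + 1)]
        out += [f"eETS-{n}H{r}" for n in range(1, self.n_variants + 1)
                for r in self.replicates]
        if self.include_wt:
            out += ["uWT", "eWT"]
        return out

    def parse(self, condition: str) -> tuple[int | None, str, str | None]:
        """Return (variant number or None for WT, phase, replicate)."""
        if condition in ("uWT", "eWT"):
            return None, "wt", None
        phase = "unevolved" if condition.startswith("u") else "evolved"
        body = condition[1:]          # e.g. ETS-3HB
        n = int(body[4])
        rep = body[6:] or None
        return n, phase, rep

    def aerotype_class(self, condition: str) -> int:
        """Planted ordinal aero-type class of a condition (0..3)."""
        n, phase, _ = self.parse(condition)
        if n is None:
            return 2
        return n - 1


@dataclass
class PlantedTruth:
    h_per_atp_true: float
    mu_target: float
    phenotypes: dict[str, dict]
    imodulon_memberships: dict[str, list[str]]
    imodulon_signs: dict[str, str]
    imodulon_activities: dict[str, dict[str, float]]
    aerotype_class: dict[str, int]
    convergent_genes: dict[str, str]
    hypermutator_lineage: tuple[str, str] | None
    noise: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["hypermutator_lineage"] = (
            list(self.hypermutator_lineage) if self.hypermutator_lineage else None)
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        data = json.loads(Path(path).read_text())
        if data.get("hypermutator_lineage"):
            data["hypermutator_lineage"] = tuple(data["hypermutator_lineage"])
        return cls(**data)


# ---------------------------------------------------------------------------
# ATS gene registry
# ---------------------------------------------------------------------------

_SUBSYSTEM_PREFIX = {
    "oxidative phosphorylation": "oxp",
    "glycolysis (EMP)": "emp",
    "glycolysis (ED)": "edp",
    "pentose phosphate": "ppp",
    "pyruvate metabolism": "pyr",
    "TCA": "tca",
}

#: the five ATS subsystem labels (both glycolytic routes form one arm)
_ATS_LABEL = {
    "oxidative phosphorylation": "oxidative phosphorylation",
    "glycolysis (EMP)": "glycolysis",
    "glycolysis (ED)": "glycolysis",
    "pentose phosphate": "pentose phosphate",
    "pyruvate metabolism": "pyruvate metabolism",
    "TCA": "TCA",
}


def ats_registry(model: network.MetabolicModel | None = None,
                 size: int = REGISTRY_SIZE) -> pd.DataFrame:
    """The ATS gene registry: model genes plus synthetic members, grouped
    into the five ATS subsystems (both glycolytic routes counted as one
    glycolysis arm).  Deterministic; columns (gene, subsystem)."""
    if model is None:
        model = network.reference_model()
    rows = []
    seen = set()
    for rxn in model.reactions.values():
        if rxn.subsystem in _SUBSYSTEM_PREFIX:
            for g in rxn.genes:
                if g in model.ats_gene_set and g not in seen:
                    seen.add(g)
                    rows.append((g, _ATS_LABEL[rxn.subsystem]))
    subsystems = list(_SUBSYSTEM_PREFIX)
    i = 0
    while len(rows) < size:
        sub = subsystems[i % len(subsystems)]
        gene = f"{_SUBSYSTEM_PREFIX[sub]}{i + 1:03d}"
        rows.append((gene, _ATS_LABEL[sub]))
        i += 1
    return pd.DataFrame(rows[:size], columns=["gene", "subsystem"])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _condition_model(model, variant: int | None, h_per_atp: float,
                     kcat_scale: float) -> network.MetabolicModel:
    cond = network.build_variant(model, variant) if variant else model.copy()
    network.set_h_per_atp(cond, h_per_atp)
    if kcat_scale != 1.0:
        network.scale_kcats(cond, cond.ats_gene_set, kcat_scale)
    return cond


def _forward_phenotype():
    return fba.PhenotypeConstraints(
        glucose_uptake=GLUCOSE_EXCESS, acetate_secretion=0.0,
        o2_uptake_max=O2_SUPPLY, fix_acetate=False)


def calibrate_kcat_scale(model, variant: int | None, h_per_atp: float,
                         mu_target: float = MU_PLATEAU,
                         lo: float = 0.2, hi: float = 20.0,
                         iterations: int = 40) -> float:
    """Bisect the ATS kcat factor until growth reaches the target plateau."""
    ph = _forward_phenotype()
    for _ in range(iterations):
        mid = (lo * hi) ** 0.5
        cond = _condition_model(model, variant, h_per_atp, mid)
        mu = fba.solve_growth(cond, ph, None, fba.PROTEOME_BUDGET).growth_rate
        if mu < mu_target:
            lo = mid
        else:
            hi = mid
    return (lo * hi) ** 0.5


def gen_phenotypes(
    model: network.MetabolicModel,
    design: StudyDesign,
    h_per_atp_true: float = DEFAULT_H_PER_ATP_TRUE,
    noise_sd: float = DEFAULT_PHENOTYPE_NOISE,
    seed: int = 0,
    mu_target: float = MU_PLATEAU,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Forward-model phenotypes for every study condition.

    Returns the phenotype table and the per-condition truth block
    (noiseless rates plus the kcat factor the condition was solved with).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ph = _forward_phenotype()
    evolved_scale: dict[int | None, float] = {}
    for n in [None] + list(range(1, design.n_variants + 1)):
        evolved_scale[n] = calibrate_kcat_scale(model, n, h_per_atp_true, mu_target)

    rows = []
    truth: dict[str, dict] = {}
    for condition in design.conditions:
        n, phase, rep = design.parse(condition)
        if phase in ("unevolved",) or condition == "uWT":
            scale = UNEVOLVED_KCAT_FACTORS[n or 0]
        else:
            scale = evolved_scale[n]
        cond_model = _condition_model(model, n, h_per_atp_true, scale)
        sol = fba.solve_growth(cond_model, ph, None, fba.PROTEOME_BUDGET)
        if not sol.optimal:
            raise network.ValidationError(f"forward model infeasible: {condition}")
        glc = -sol.fluxes[fba.GLUCOSE_EXCHANGE]
        ac = max(sol.fluxes[fba.ACETATE_EXCHANGE], 0.0)
        o2 = -sol.fluxes[fba.OXYGEN_EXCHANGE]
        mu = sol.growth_rate
        noisy = [v * (1.0 + noise_sd * rng.standard_normal()) if noise_sd > 0 else v
                 for v in (glc, ac, o2, mu)]
        rows.append({
            "strain": condition,
            "variant": f"ETS-{n}H" if n else "WT",
            "phase": phase,
            "replicate": rep or "",
            "glucose_uptake": noisy[0],
            "acetate_secretion": noisy[1],
            "o2_max": noisy[2],
            "growth_rate": noisy[3],
            "kcat_scale": scale,
        })
        truth[condition] = {
            "mu_true": mu, "glucose_uptake": glc, "acetate_secretion": ac,
            "o2_uptake": o2, "kcat_scale": scale,
        }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(
    design: StudyDesign,
    registry: pd.DataFrame,
    k_planted: int = 6,
    snr: float = DEFAULT_EXPRESSION_SNR,
    seed: int = 0,
    baseline: float = 8.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Block-sparse planted expression matrix plus condition metadata.

    Half of the planted modules are "oxic" (activity increasing with the
    aero-type class), half "anoxic" (decreasing); the unevolved wild type
    is the zero-activity reference.  Noise standard deviation is set from
    the planted signal variance and ``snr``.
    """
    if k_planted > 8:
        raise ValueError("k_planted must be at most 8")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    genes = list(registry["gene"])
    conditions = design.conditions

    block_sizes = rng.integers(15, 31, size=k_planted)
    if block_sizes.sum() > len(genes):
        raise ValueError("registry smaller than total planted block size")
    shuffled = list(genes)
    rng.shuffle(shuffled)
    memberships: dict[str, list[str]] = {}
    signs: dict[str, str] = {}
    start = 0
    for j in range(k_planted):
        comp = f"P{j+1}"
        memberships[comp] = sorted(shuffled[start:start + block_sizes[j]])
        signs[comp] = "oxic" if j % 2 == 0 else "anoxic"
        start += block_sizes[j]

    classes = {c: design.aerotype_class(c) for c in conditions}
    mean_class = np.mean(list(classes.values()))
    activities = pd.DataFrame(0.0, index=list(memberships), columns=conditions)
    # per-(variant, phase) offsets shared by replicate lineages: evolved
    # endpoints of one variant correlate strongly with each other, less with
    # their unevolved ancestor (whose rewiring is only partial)
    groups = sorted({(design.parse(c)[0] or 0, design.parse(c)[1])
                     for c in conditions})
    # The class gradient must stay a minority share of each activity's
    # variance: planted sources sharing most of their variance would be
    # mutually dependent and unrecoverable by ICA.  Identifiability comes
    # from the per-(variant, phase) signature; the gradient supplies the
    # oxic/anoxic trend that correlation analysis is meant to detect.
    active = [c for c in conditions if c != "uWT"]
    damp = {c: (0.5 if design.parse(c)[1] == "unevolved" else 1.0) for c in active}
    gradient = np.array([damp[c] * (classes[c] - mean_class) for c in active])
    for j, comp in enumerate(memberships):
        direction = 1.0 if signs[comp] == "oxic" else -1.0
        # each variant's unevolved ancestor shares part of the evolved
        # endpoints' signature, so pre/post correlation is positive but
        # weaker than the correlation among the endpoints themselves
        group_jitter: dict[tuple, float] = {}
        for g in groups:
            group_jitter[g] = 1.7 * rng.standard_normal()
        for (n, phase) in list(group_jitter):
            if phase == "unevolved" and (n, "evolved") in group_jitter:
                group_jitter[(n, phase)] = (0.6 * group_jitter[(n, "evolved")]
                                            + 0.8 * 1.7 * rng.standard_normal())
        jitter = np.array([group_jitter[(design.parse(c)[0] or 0,
                                         design.parse(c)[1])] for c in active])
        jitter = jitter + 0.4 * rng.standard_normal(len(active))
        # strip the jitter's projection onto the class gradient so that the
        # planted oxic/anoxic trend is carried by the gradient term alone
        jitter = jitter - (jitter @ gradient) / (gradient @ gradient) * gradient
        act_vec = direction * 0.8 * gradient + jitter
        for c, a in zip(active, act_vec):
            activities.loc[comp, c] = a

    S_true = pd.DataFrame(0.0, index=genes, columns=list(memberships))
    for comp, members in memberships.items():
        # signed weights: a module has both induced and repressed members;
        # zero-mean sparse sources are also what ICA separates cleanly
        weights = (0.8 + 0.4 * rng.random(len(members)))
        weights *= rng.choice([-1.0, 1.0], size=len(members))
        S_true.loc[members, comp] = weights

    signal = S_true.to_numpy() @ activities.to_numpy()
    sig_var = float(np.var(signal[signal != 0])) if np.any(signal != 0) else 1.0
    noise_sd = np.sqrt(sig_var / snr) if np.isfinite(snr) and snr > 0 else 0.0
    noise = noise_sd * rng.standard_normal(signal.shape)
    X = baseline + signal + noise
    expr = pd.DataFrame(X, index=genes, columns=conditions)
    expr.index.name = "gene"

    meta_rows = []
    for c in conditions:
        n, phase, rep = design.parse(c)
        meta_rows.append({
            "condition": c,
            "variant": f"ETS-{n}H" if n else "WT",
            "replicate": rep or "",
            "phase": phase,
        })
    meta = pd.DataFrame(meta_rows)
    truth = {
        "memberships": {k: list(v) for k, v in memberships.items()},
        "signs": signs,
        "activities": {k: dict(zip(conditions, activities.loc[k])) for k in activities.index},
        "classes": classes,
        "noise_sd": noise_sd,
    }
    return expr, meta, truth


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

# benign / deleterious codon change templates: (ref, alt, sift, ddG)
_BENIGN = [("GCT", "GCC", 0.85, 0.1), ("CTG", "ATG", 0.40, 0.6),
           ("GAT", "GAA", 0.30, 0.9), ("TCT", "ACT", 0.55, 0.3)]
_DELETERIOUS = [("GAA", "AAA", 0.01, 2.6), ("TGT", "TAT", 0.02, 3.1),
                ("GGT", "GAT", 0.03, 2.2)]
_PASSENGER_GENES = [
    "rpoB", "rpoC", "cspC", "ygaH", "proQ", "ydhB", "malT", "fimH", "rph",
    "ilvN", "aceK", "barA", "cyaA", "crp", "fnr", "arcA", "arcB", "envZ",
    "ompR", "rpoS", "relA", "spoT", "dksA", "greA", "nusA", "rho", "pnp",
    "rne", "deaD", "srmB", "recA", "recB", "ruvA", "uvrA", "mfd", "dnaK",
    "groL", "htpG", "clpA", "clpX", "lon", "ftsH", "secA", "yidC", "tatB",
    "lptD", "bamA", "mrcA", "mrdA", "ftsZ", "minC", "mreB", "rodZ", "cysE",
    "metA", "thrA", "ilvC", "leuA", "argA", "proB", "trpE", "tyrA", "pheA",
    "hisG", "serA", "glyA", "purF", "pyrB", "carA", "guaB", "ndk", "adk",
    "gmk", "cmk", "tmk", "thyA", "folA", "ribB", "thiE", "nadB",
]


def gen_mutations(
    design: StudyDesign,
    convergent_genes: dict[str, str] | None = None,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    hypermutator: bool = True,
    seed: int = 0,
) -> tuple[list[MutationRecord], dict]:
    """Mutation table with planted convergence, duplicates and hypermutator.

    Every evolved lineage receives its variant's convergent mutation (also
    injected as a midpoint-sample duplicate), Poisson passengers, and — when
    enabled — the designated lineage gains a mutS mutation plus a five-fold
    passenger load.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    conv = dict(DEFAULT_CONVERGENT_GENES if convergent_genes is None
                else convergent_genes)
    records: list[MutationRecord] = []

    def passenger(exp, lin, sample):
        gene = _PASSENGER_GENES[rng.integers(len(_PASSENGER_GENES))]
        ref, alt, sift, ddg = _BENIGN[rng.integers(len(_BENIGN))]
        return MutationRecord(
            experiment=exp, lineage=lin, sample=sample,
            gene=gene, protein_position=int(rng.integers(2, 400)),
            ref_codon=ref, alt_codon=alt, sift_score=sift, ddG=ddg)

    for n in range(1, design.n_variants + 1):
        exp = f"ETS-{n}H"
        target = conv.get(exp)
        for lin in design.replicates:
            endpoint = f"{exp}-{lin}-end"
            midpoint = f"{exp}-{lin}-mid"
            if target is None:
                continue
            if "-" in target and target[0].islower():
                driver = MutationRecord(
                    experiment=exp, lineage=lin, sample=endpoint, gene=target,
                    mutation_type="intergenic", sift_score=None, ddG=None)
            elif target == "yjjX" and lin == "A":
                # start-codon replacement ATG -> ATA (Met -> Ile)
                driver = MutationRecord(
                    experiment=exp, lineage=lin, sample=endpoint, gene=target,
                    protein_position=1, ref_codon="ATG", alt_codon="ATA",
                    is_start_codon=True, sift_score=0.02, ddG=0.4)
            elif target == "sdhA" and lin == "B":
                # premature termination codon mid-ORF
                driver = MutationRecord(
                    experiment=exp, lineage=lin, sample=endpoint, gene=target,
                    protein_position=int(rng.integers(50, 300)),
                    ref_codon="TAC", alt_codon="TAA", sift_score=None, ddG=None)
            else:
                ref, alt, sift, ddg = _DELETERIOUS[rng.integers(len(_DELETERIOUS))]
                driver = MutationRecord(
                    experiment=exp, lineage=lin, sample=endpoint, gene=target,
                    protein_position=int(rng.integers(2, 400)),
                    ref_codon=ref, alt_codon=alt, sift_score=sift, ddG=ddg)
            records.append(driver)
            # midpoint clone carrying the same mutation (dedup fodder)
            records.append(MutationRecord(
                experiment=driver.experiment, lineage=driver.lineage,
                sample=midpoint, gene=driver.gene,
                protein_position=driver.protein_position,
                ref_codon=driver.ref_codon, alt_codon=driver.alt_codon,
                is_start_codon=driver.is_start_codon,
                sift_score=driver.sift_score, ddG=driver.ddG,
                mutation_type=driver.mutation_type))
            n_passengers = rng.poisson(background_rate)
            is_hyper = hypermutator and (exp, lin) == HYPERMUTATOR_LINEAGE
            if is_hyper:
                records.append(MutationRecord(
                    experiment=exp, lineage=lin, sample=endpoint, gene="mutS",
                    protein_position=int(rng.integers(2, 800)),
                    ref_codon="GAA", alt_codon="AAA", sift_score=0.01, ddG=2.4))
                n_passengers = max(int(5 * max(background_rate, 1.0)), n_passengers * 5)
            for _ in range(n_passengers):
                records.append(passenger(exp, lin, endpoint))

    truth = {
        "convergent_genes": conv,
        "hypermutator_lineage": list(HYPERMUTATOR_LINEAGE) if hypermutator else None,
        "background_rate": background_rate,
    }
    return records, truth


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

def gen_all(
    outdir: str | Path,
    seed: int = 42,
    model: network.MetabolicModel | None = None,
    h_per_atp_true: float = DEFAULT_H_PER_ATP_TRUE,
    phenotype_noise: float = DEFAULT_PHENOTYPE_NOISE,
    expression_snr: float = DEFAULT_EXPRESSION_SNR,
    k_planted: int = 6,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    mu_target: float = MU_PLATEAU,
) -> PlantedTruth:
    """Generate the full synthetic bundle into *outdir*.

    Writes phenotype.tsv, expression.tsv, meta.tsv, mutations.csv,
    truth.json (and model.json when a model was constructed here).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = network.reference_model()
    design = StudyDesign()

    pheno, pheno_truth = gen_phenotypes(
        model, design, h_per_atp_true, phenotype_noise, seed, mu_target)
    registry = ats_registry(model)
    expr, meta, expr_truth = gen_expression(
        design, registry, k_planted, expression_snr, seed)
    records, mut_truth = gen_mutations(
        design, None, background_rate, True, seed)

    pheno.to_csv(outdir / "phenotype.tsv", sep="\t", index=False)
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    records_to_frame(records).to_csv(outdir / "mutations.csv", index=False)
    registry.to_csv(outdir / "ats_registry.tsv", sep="\t", index=False)
    network.save_model(model, outdir / "model.json")

    truth = PlantedTruth(
        h_per_atp_true=h_per_atp_true,
        mu_target=mu_target,
        phenotypes=pheno_truth,
        imodulon_memberships=expr_truth["memberships"],
        imodulon_signs=expr_truth["signs"],
        imodulon_activities=expr_truth["activities"],
        aerotype_class=expr_truth["classes"],
        convergent_genes=mut_truth["convergent_genes"],
        hypermutator_lineage=(tuple(mut_truth["hypermutator_lineage"])
                              if mut_truth["hypermutator_lineage"] else None),
        noise={"phenotype_sd": phenotype_noise,
               "expression_snr": expression_snr,
               "expression_noise_sd": expr_truth["noise_sd"]},
        seed=seed,
    )
    truth.to_json(outdir / "truth.json")
    return truth
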