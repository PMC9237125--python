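"""Stoichiometric network, enzyme parameters and electron-transport variants.

The model is a reduced, elementally balanced network of *E. coli* central
carbon metabolism (EMP and ED glycolysis, oxidative pentose phosphate
pathway, TCA cycle, pyruvate/acetate metabolism) wired to an explicit
electron transport system (ETS) with two NADH:quinone oxidoreductases
(proton-pumping NDH-I, non-pumping NDH-II) and two terminal dioxygen
reductases (cytochrome bo3 = CYO, cytochrome bd = CBD), plus ATP synthase
operating across an explicit periplasmic proton pool.

Reaction and metabolite identifiers follow BiGG conventions where an
equivalent exists (PGK, SUCOAS, ACKr, ATPS4rpp, ...), with reactions written
in their BiGG direction; several of these run net-negative in glycolytic or
fermentative states, which matters for ATP accounting downstream.

Proton bookkeeping: each ETS reaction moves ``2 * (H+/e-)`` protons from
cytosol to periplasm per NADH (or per 1/2 O2), and ATP synthase consumes
``h_per_atp`` periplasmic protons per ATP, returning ``h_per_atp - 1`` to
the cytosol (one proton is incorporated chemically).
"""

from __future__ import annotations

import copy
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

logger = logging.getLogger("aerotype")

SCHEMA_VERSION = "1.0"

#: Protons translocated per electron by each bundled ETS component.  The
#: four unbranched variant totals (1..4 H+/e-) force this assignment up to
#: the NDH/oxidase split; it is a parameter of the model, not a measured fact.
COMPONENT_PROTONS_PER_ELECTRON = {
    "NDH-I": 2.0,
    "NDH-II": 0.0,
    "CYO": 2.0,
    "CBD": 1.0,
}

COMPONENT_REACTIONS = {
    "NDH-I": "NDH1pp",
    "NDH-II": "NDH2pp",
    "CYO": "CYOpp",
    "CBD": "CBDpp",
}

DEHYDROGENASES = ("NDH-I", "NDH-II")
OXIDASES = ("CYO", "CBD")

#: Default rotational-catalysis proton-to-ATP ratio: a 10-subunit c-ring in
#: Fo driving the threefold-symmetric F1 head gives 10/3 protons per ATP.
DEFAULT_H_PER_ATP = 10.0 / 3.0

#: Molecular-mass ratio of the NDH-I complex to monomeric NDH-II (~10x).
NDH1_NDH2_MASS_RATIO = 10.0

#: Protein cost (sum of mw/kcat over pathway enzymes, per glucose) of the
#: EMP glycolytic route relative to the ED route (~3.5x).
EMP_ED_COST_RATIO = 3.5

ATS_SUBSYSTEMS = (
    "oxidative phosphorylation",
    "glycolysis (EMP)",
    "glycolysis (ED)",
    "pentose phosphate",
    "pyruvate metabolism",
    "TCA",
)

SUBSYSTEMS = ATS_SUBSYSTEMS + ("exchange", "biomass")

COMPARTMENTS = ("cytosol", "periplasm", "extracellular")


class SchemaError(ValueError):
    """Model file violates the documented JSON schema."""


class ValidationError(ValueError):
    """Model content violates a structural or balance invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str
    compartment: str
    formula: str = ""
    charge: int = 0


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    genes: list[str] = field(default_factory=list)
    subsystem: str = "exchange"

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0


@dataclass
class EnzymeSpec:
    """Catalytic parameters of one gene product.

    ``molecular_weight`` is in kDa (g/mmol), ``kcat`` in 1/s.
    """

    gene: str
    molecular_weight: float
    kcat: float
    complex: str | None = None


@dataclass
class ETSComponent:
    id: str
    protons_per_electron: float
    reaction_id: str


@dataclass
class ETSVariantDesign:
    name: str
    dehydrogenase: ETSComponent
    oxidase: ETSComponent
    knockouts: list[str]
    h_per_e: int


@dataclass
class MetabolicModel:
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    enzymes: dict[str, EnzymeSpec]
    ets_components: dict[str, ETSComponent]
    ats_gene_set: set[str]
    atps_reaction_id: str
    h_per_atp: float
    design: ETSVariantDesign | None = None

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    @property
    def biomass_reaction_id(self) -> str:
        candidates = [r for r in self.reactions.values() if r.subsystem == "biomass"]
        if not candidates:
            raise ValidationError("model has no biomass reaction")
        # the lumped growth reaction drains far more species than any
        # housekeeping reaction filed under the same subsystem
        return max(candidates, key=lambda r: len(r.stoichiometry)).id

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out.update(rxn.genes)
        return out


# ---------------------------------------------------------------------------
# elemental balance
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValidationError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValidationError(f"malformed formula {formula!r}")
    return counts


def reaction_imbalance(model: MetabolicModel, rxn: Reaction) -> dict[str, float]:
    """Net element/charge excess of products over reactants (empty = balanced)."""
    net: dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        for el, n in parse_formula(met.formula).items():
            net[el] = net.get(el, 0.0) + coef * n
        net["charge"] = net.get("charge", 0.0) + coef * met.charge
    return {k: v for k, v in net.items() if abs(v) > 1e-6}


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> None:
    """Raise :class:`ValidationError` on the first violated invariant."""
    for met_id, met in model.metabolites.items():
        if met.id != met_id:
            raise ValidationError(f"metabolite key {met_id!r} != id {met.id!r}")
        if met.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"metabolite {met_id}: unknown compartment {met.compartment!r}")
    for rxn_id, rxn in model.reactions.items():
        if rxn.id != rxn_id:
            raise ValidationError(f"reaction key {rxn_id!r} != id {rxn.id!r}")
        if rxn.subsystem not in SUBSYSTEMS:
            raise ValidationError(
                f"reaction {rxn_id}: unknown subsystem {rxn.subsystem!r}")
        if rxn.lower_bound > rxn.upper_bound:
            raise ValidationError(f"reaction {rxn_id}: lower_bound > upper_bound")
        missing = [m for m in rxn.stoichiometry if m not in model.metabolites]
        if missing:
            raise ValidationError(f"reaction {rxn_id}: unknown metabolites {missing}")
        if rxn.subsystem not in ("exchange", "biomass"):
            imbalance = reaction_imbalance(model, rxn)
            if imbalance:
                raise ValidationError(
                    f"reaction {rxn_id} is unbalanced: {imbalance}")
    if model.atps_reaction_id not in model.reactions:
        raise ValidationError(
            f"ATP synthase reaction {model.atps_reaction_id!r} missing")
    if model.h_per_atp <= 0:
        raise ValidationError("h_per_atp must be positive")
    for comp_id, comp in model.ets_components.items():
        if comp.reaction_id not in model.reactions:
            raise ValidationError(
                f"ETS component {comp_id}: reaction {comp.reaction_id!r} missing")
        if comp.protons_per_electron not in (0.0, 1.0, 2.0):
            raise ValidationError(
                f"ETS component {comp_id}: protons_per_electron must be 0, 1 or 2")
    gene_subsystems = {
        s for rxn in model.reactions.values() if rxn.subsystem in ATS_SUBSYSTEMS
        for s in [rxn.subsystem]
        if set(rxn.genes) & model.ats_gene_set
    }
    missing_subsystems = set(ATS_SUBSYSTEMS) - gene_subsystems
    if missing_subsystems:
        raise ValidationError(
            f"ats_gene_set does not cover subsystems: {sorted(missing_subsystems)}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    d = {
        "version": SCHEMA_VERSION,
        "metabolites": [asdict(m) for m in model.metabolites.values()],
        "reactions": [asdict(r) for r in model.reactions.values()],
        "enzymes": [asdict(e) for e in model.enzymes.values()],
        "ets_components": [asdict(c) for c in model.ets_components.values()],
        "ats_genes": sorted(model.ats_gene_set),
        "atps_reaction_id": model.atps_reaction_id,
        "h_per_atp": model.h_per_atp,
    }
    if model.design is not None:
        d["design"] = {
            "name": model.design.name,
            "dehydrogenase": model.design.dehydrogenase.id,
            "oxidase": model.design.oxidase.id,
            "knockouts": list(model.design.knockouts),
            "h_per_e": model.design.h_per_e,
        }
    return d


def model_from_dict(data: dict) -> MetabolicModel:
    if not isinstance(data, dict):
        raise SchemaError("model document must be a JSON object")
    if "version" not in data:
        raise SchemaError("missing required field 'version'")
    if str(data["version"]) != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {data['version']!r} (expected {SCHEMA_VERSION})")
    for fieldname in ("metabolites", "reactions", "enzymes", "ets_components",
                      "ats_genes", "atps_reaction_id", "h_per_atp"):
        if fieldname not in data:
            raise SchemaError(f"missing required field {fieldname!r}")
    try:
        metabolites = {m["id"]: Metabolite(**m) for m in data["metabolites"]}
        reactions = {r["id"]: Reaction(**r) for r in data["reactions"]}
        enzymes = {e["gene"]: EnzymeSpec(**e) for e in data["enzymes"]}
        components = {c["id"]: ETSComponent(**c) for c in data["ets_components"]}
    except (TypeError, KeyError) as exc:
        raise SchemaError(f"malformed record: {exc}") from exc
    dup_check = [m["id"] for m in data["metabolites"]]
    if len(dup_check) != len(set(dup_check)):
        raise SchemaError("duplicate metabolite ids")
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        enzymes=enzymes,
        ets_components=components,
        ats_gene_set=set(data["ats_genes"]),
        atps_reaction_id=data["atps_reaction_id"],
        h_per_atp=float(data["h_per_atp"]),
    )
    if "design" in data:
        d = data["design"]
        model.design = ETSVariantDesign(
            name=d["name"],
            dehydrogenase=components[d["dehydrogenase"]],
            oxidase=components[d["oxidase"]],
            knockouts=list(d["knockouts"]),
            h_per_e=int(d["h_per_e"]),
        )
    return model


def save_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))


def load_model(path: str | Path) -> MetabolicModel:
    """Load and fully validate a model JSON file."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    model = model_from_dict(data)
    validate_model(model)
    return model


# ---------------------------------------------------------------------------
# ETS variant construction
# ---------------------------------------------------------------------------

def compute_h_per_e(design: ETSVariantDesign) -> float:
    """Protons translocated per electron along an unbranched NADH->O2 route."""
    return design.dehydrogenase.protons_per_electron + design.oxidase.protons_per_electron


#: dehydrogenase/oxidase pairing for each unbranched variant total.
VARIANT_DESIGNS = {
    1: ("NDH-II", "CBD"),
    2: ("NDH-II", "CYO"),
    3: ("NDH-I", "CBD"),
    4: ("NDH-I", "CYO"),
}


def build_variant(model: MetabolicModel, n: int) -> MetabolicModel:
    """Return a copy of *model* with an unbranched ETS pumping *n* H+/e-.

    Exactly one NADH dehydrogenase and one oxygen reductase stay active; the
    other two components' reactions are closed (bounds fixed to 0) and their
    genes recorded as knockouts in the returned model's design.
    """
    if n not in VARIANT_DESIGNS:
        raise ValueError(f"variant H+/e- must be in 1..4, got {n!r}")
    dehyd_id, oxid_id = VARIANT_DESIGNS[n]
    out = model.copy()
    knockouts: list[str] = []
    for comp in out.ets_components.values():
        if comp.id in (dehyd_id, oxid_id):
            continue
        rxn = out.reactions[comp.reaction_id]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        knockouts.extend(rxn.genes)
    design = ETSVariantDesign(
        name=f"ETS-{n}H",
        dehydrogenase=out.ets_components[dehyd_id],
        oxidase=out.ets_components[oxid_id],
        knockouts=knockouts,
        h_per_e=n,
    )
    assert int(compute_h_per_e(design)) == n
    out.design = design
    return out


def set_h_per_atp(model: MetabolicModel, h: float) -> None:
    """Rewrite the ATP synthase stoichiometry for a proton-to-ATP ratio *h*.

    In place: ``adp + pi + h * h_p -> atp + h2o + (h - 1) * h_c``.  One of
    the *h* translocated protons is consumed chemically in phosphorylation,
    so the reaction stays element- and charge-balanced for any real h > 1.
    """
    if h <= 1.0:
        raise ValueError(f"h_per_atp must exceed 1, got {h}")
    rxn = model.reactions[model.atps_reaction_id]
    rxn.stoichiometry = {
        "adp_c": -1.0, "pi_c": -1.0, "h_p": -h,
        "atp_c": 1.0, "h2o_c": 1.0, "h_c": h - 1.0,
    }
    model.h_per_atp = h


def scale_kcats(model: MetabolicModel, genes, factor: float) -> None:
    """Multiply the kcat of each listed gene's enzyme by *factor* (in place)."""
    if factor <= 0:
        raise ValueError("kcat scale factor must be positive")
    for gene in genes:
        if gene in model.enzymes:
            model.enzymes[gene].kcat *= factor


# ---------------------------------------------------------------------------
# the E. coli respiratory-enzyme registry
# ---------------------------------------------------------------------------

#: The flexible E. coli respiratory repertoire: 15 primary dehydrogenases
#: feeding the quinone pool and 10 terminal reductases draining it.  Only the
#: four oxic components above are modelled explicitly; the registry documents
#: the full branched system the unbranched variants were carved out of.
RESPIRATORY_REGISTRY: dict[str, tuple[str, ...]] = {
    "dehydrogenases": (
        "NADH dehydrogenase I (nuoA-N)",
        "NADH dehydrogenase II (ndh)",
        "succinate dehydrogenase (sdhCDAB)",
        "malate:quinone oxidoreductase (mqo)",
        "glycerol-3-phosphate dehydrogenase, aerobic (glpD)",
        "glycerol-3-phosphate dehydrogenase, anaerobic (glpABC)",
        "formate dehydrogenase N (fdnGHI)",
        "formate dehydrogenase O (fdoGHI)",
        "formate dehydrogenase H (fdhF)",
        "hydrogenase 1 (hyaABC)",
        "hydrogenase 2 (hybOABC)",
        "D-lactate dehydrogenase (dld)",
        "L-lactate dehydrogenase (lldD)",
        "pyruvate oxidase (poxB)",
        "proline dehydrogenase (putA)",
    ),
    "reductases": (
        "cytochrome bo3 oxidase (cyoABCD)",
        "cytochrome bd-I oxidase (cydAB)",
        "cytochrome bd-II oxidase (appBC)",
        "nitrate reductase A (narGHI)",
        "nitrate reductase Z (narZYV)",
        "periplasmic nitrate reductase (napAB)",
        "nitrite reductase (nrfAB)",
        "fumarate reductase (frdABCD)",
        "DMSO reductase (dmsABC)",
        "TMAO reductase (torCA)",
    ),
}


def respiratory_registry() -> dict[str, tuple[str, ...]]:
    return {k: tuple(v) for k, v in RESPIRATORY_REGISTRY.items()}


# ---------------------------------------------------------------------------
# bundled reference network
# ---------------------------------------------------------------------------

_METABOLITES = [
    # id, name, compartment, formula, charge
    ("glc__D_e", "D-glucose", "extracellular", "C6H12O6", 0),
    ("ac_e", "acetate", "extracellular", "C2H3O2", -1),
    ("o2_e", "O2", "extracellular", "O2", 0),
    ("co2_e", "CO2", "extracellular", "CO2", 0),
    ("h2o_e", "H2O", "extracellular", "H2O", 0),
    ("nh4_e", "ammonium", "extracellular", "H4N", 1),
    ("pi_e", "phosphate", "extracellular", "HO4P", -2),
    ("h_p", "H+ (periplasm)", "periplasm", "H", 1),
    ("h_c", "H+ (cytosol)", "cytosol", "H", 1),
    ("h2o_c", "H2O", "cytosol", "H2O", 0),
    ("o2_c", "O2", "cytosol", "O2", 0),
    ("co2_c", "CO2", "cytosol", "CO2", 0),
    ("nh4_c", "ammonium", "cytosol", "H4N", 1),
    ("pi_c", "phosphate", "cytosol", "HO4P", -2),
    ("glc__D_c", "D-glucose", "cytosol", "C6H12O6", 0),
    ("g6p_c", "D-glucose 6-phosphate", "cytosol", "C6H11O9P", -2),
    ("f6p_c", "D-fructose 6-phosphate", "cytosol", "C6H11O9P", -2),
    ("fdp_c", "D-fructose 1,6-bisphosphate", "cytosol", "C6H10O12P2", -4),
    ("dhap_c", "dihydroxyacetone phosphate", "cytosol", "C3H5O6P", -2),
    ("g3p_c", "glyceraldehyde 3-phosphate", "cytosol", "C3H5O6P", -2),
    ("13dpg_c", "3-phospho-D-glyceroyl phosphate", "cytosol", "C3H4O10P2", -4),
    ("3pg_c", "3-phospho-D-glycerate", "cytosol", "C3H4O7P", -3),
    ("2pg_c", "2-phospho-D-glycerate", "cytosol", "C3H4O7P", -3),
    ("pep_c", "phosphoenolpyruvate", "cytosol", "C3H2O6P", -3),
    ("pyr_c", "pyruvate", "cytosol", "C3H3O3", -1),
    ("6pgl_c", "6-phospho-D-glucono-1,5-lactone", "cytosol", "C6H9O9P", -2),
    ("6pgc_c", "6-phospho-D-gluconate", "cytosol", "C6H10O10P", -3),
    ("2ddg6p_c", "2-dehydro-3-deoxy-D-gluconate 6-phosphate", "cytosol", "C6H8O9P", -3),
    ("ru5p__D_c", "D-ribulose 5-phosphate", "cytosol", "C5H9O8P", -2),
    ("xu5p__D_c", "D-xylulose 5-phosphate", "cytosol", "C5H9O8P", -2),
    ("r5p_c", "alpha-D-ribose 5-phosphate", "cytosol", "C5H9O8P", -2),
    ("s7p_c", "sedoheptulose 7-phosphate", "cytosol", "C7H13O10P", -2),
    ("e4p_c", "D-erythrose 4-phosphate", "cytosol", "C4H7O7P", -2),
    ("accoa_c", "acetyl-CoA", "cytosol", "C23H34N7O17P3S", -4),
    ("coa_c", "coenzyme A", "cytosol", "C21H32N7O16P3S", -4),
    ("actp_c", "acetyl phosphate", "cytosol", "C2H3O5P", -2),
    ("ac_c", "acetate", "cytosol", "C2H3O2", -1),
    ("cit_c", "citrate", "cytosol", "C6H5O7", -3),
    ("icit_c", "isocitrate", "cytosol", "C6H5O7", -3),
    ("akg_c", "2-oxoglutarate", "cytosol", "C5H4O5", -2),
    ("succoa_c", "succinyl-CoA", "cytosol", "C25H35N7O19P3S", -5),
    ("succ_c", "succinate", "cytosol", "C4H4O4", -2),
    ("fum_c", "fumarate", "cytosol", "C4H2O4", -2),
    ("mal__L_c", "L-malate", "cytosol", "C4H4O5", -2),
    ("oaa_c", "oxaloacetate", "cytosol", "C4H2O5", -2),
    ("glu__L_c", "L-glutamate", "cytosol", "C5H8NO4", -1),
    ("gln__L_c", "L-glutamine", "cytosol", "C5H10N2O3", 0),
    ("nad_c", "NAD+", "cytosol", "C21H26N7O14P2", -1),
    ("nadh_c", "NADH", "cytosol", "C21H27N7O14P2", -2),
    ("nadp_c", "NADP+", "cytosol", "C21H25N7O17P3", -3),
    ("nadph_c", "NADPH", "cytosol", "C21H26N7O17P3", -4),
    ("atp_c", "ATP", "cytosol", "C10H12N5O13P3", -4),
    ("adp_c", "ADP", "cytosol", "C10H12N5O10P2", -3),
    ("q8_c", "ubiquinone-8", "cytosol", "C49H74O4", 0),
    ("q8h2_c", "ubiquinol-8", "cytosol", "C49H76O4", 0),
]

# id, stoichiometry, (lb, ub), genes, subsystem
_REACTIONS = [
    # --- glucose uptake (PTS) and EMP glycolysis ---
    ("GLCpts", {"glc__D_e": -1, "pep_c": -1, "g6p_c": 1, "pyr_c": 1},
     (0, 1000), ["ptsG"], "glycolysis (EMP)"),
    ("PGI", {"g6p_c": -1, "f6p_c": 1}, (-1000, 1000), ["pgi"], "glycolysis (EMP)"),
    ("PFK", {"atp_c": -1, "f6p_c": -1, "adp_c": 1, "fdp_c": 1, "h_c": 1},
     (0, 1000), ["pfkA"], "glycolysis (EMP)"),
    ("FBA", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, (-1000, 1000), ["fbaA"],
     "glycolysis (EMP)"),
    ("TPI", {"dhap_c": -1, "g3p_c": 1}, (-1000, 1000), ["tpiA"], "glycolysis (EMP)"),
    ("GAPD", {"g3p_c": -1, "nad_c": -1, "pi_c": -1,
              "13dpg_c": 1, "h_c": 1, "nadh_c": 1},
     (-1000, 1000), ["gapA"], "glycolysis (EMP)"),
    # BiGG direction: ATP-consuming; glycolytic flux is negative.
    ("PGK", {"3pg_c": -1, "atp_c": -1, "13dpg_c": 1, "adp_c": 1},
     (-1000, 1000), ["pgk"], "glycolysis (EMP)"),
    ("PGM", {"2pg_c": -1, "3pg_c": 1}, (-1000, 1000), ["gpmA"], "glycolysis (EMP)"),
    ("ENO", {"2pg_c": -1, "h2o_c": 1, "pep_c": 1}, (-1000, 1000), ["eno"],
     "glycolysis (EMP)"),
    ("PYK", {"adp_c": -1, "h_c": -1, "pep_c": -1, "atp_c": 1, "pyr_c": 1},
     (0, 1000), ["pykF"], "glycolysis (EMP)"),
    # --- ED branch ---
    ("G6PDH2r", {"g6p_c": -1, "nadp_c": -1, "6pgl_c": 1, "h_c": 1, "nadph_c": 1},
     (-1000, 1000), ["zwf"], "glycolysis (ED)"),
    ("PGL", {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1},
     (0, 1000), ["pgl"], "glycolysis (ED)"),
    ("EDD", {"6pgc_c": -1, "2ddg6p_c": 1, "h2o_c": 1}, (0, 1000), ["edd"],
     "glycolysis (ED)"),
    ("EDA", {"2ddg6p_c": -1, "g3p_c": 1, "pyr_c": 1}, (0, 1000), ["eda"],
     "glycolysis (ED)"),
    # --- oxidative / non-oxidative pentose phosphate ---
    ("GND", {"6pgc_c": -1, "nadp_c": -1, "co2_c": 1, "nadph_c": 1, "ru5p__D_c": 1},
     (0, 1000), ["gnd"], "pentose phosphate"),
    ("RPE", {"ru5p__D_c": -1, "xu5p__D_c": 1}, (-1000, 1000), ["rpe"],
     "pentose phosphate"),
    ("RPI", {"r5p_c": -1, "ru5p__D_c": 1}, (-1000, 1000), ["rpiA"],
     "pentose phosphate"),
    ("TKT1", {"r5p_c": -1, "xu5p__D_c": -1, "g3p_c": 1, "s7p_c": 1},
     (-1000, 1000), ["tktA"], "pentose phosphate"),
    ("TALA", {"g3p_c": -1, "s7p_c": -1, "e4p_c": 1, "f6p_c": 1},
     (-1000, 1000), ["talB"], "pentose phosphate"),
    ("TKT2", {"e4p_c": -1, "xu5p__D_c": -1, "f6p_c": 1, "g3p_c": 1},
     (-1000, 1000), ["tktA"], "pentose phosphate"),
    # --- pyruvate / acetate metabolism ---
    ("PDH", {"coa_c": -1, "nad_c": -1, "pyr_c": -1,
             "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
     (0, 1000), ["aceE"], "pyruvate metabolism"),
    ("PTAr", {"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1},
     (-1000, 1000), ["pta"], "pyruvate metabolism"),
    # BiGG direction: ATP-consuming; acetate overflow runs it negative.
    ("ACKr", {"ac_c": -1, "atp_c": -1, "actp_c": 1, "adp_c": 1},
     (-1000, 1000), ["ackA"], "pyruvate metabolism"),
    # --- anaplerosis and TCA ---
    ("PPC", {"co2_c": -1, "h2o_c": -1, "pep_c": -1, "h_c": 1, "oaa_c": 1, "pi_c": 1},
     (0, 1000), ["ppc"], "TCA"),
    ("CS", {"accoa_c": -1, "h2o_c": -1, "oaa_c": -1, "cit_c": 1, "coa_c": 1, "h_c": 1},
     (0, 1000), ["gltA"], "TCA"),
    ("ACONT", {"cit_c": -1, "icit_c": 1}, (-1000, 1000), ["acnB"], "TCA"),
    ("ICDHyr", {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1},
     (-1000, 1000), ["icd"], "TCA"),
    ("AKGDH", {"akg_c": -1, "coa_c": -1, "nad_c": -1,
               "co2_c": 1, "nadh_c": 1, "succoa_c": 1},
     (0, 1000), ["sucA"], "TCA"),
    # BiGG direction: ATP-consuming; oxidative TCA flux is negative.
    ("SUCOAS", {"atp_c": -1, "coa_c": -1, "succ_c": -1,
                "adp_c": 1, "pi_c": 1, "succoa_c": 1},
     (-1000, 1000), ["sucC"], "TCA"),
    ("SUCDi", {"q8_c": -1, "succ_c": -1, "fum_c": 1, "q8h2_c": 1},
     (0, 1000), ["sdhA"], "TCA"),
    ("FUM", {"fum_c": -1, "h2o_c": -1, "mal__L_c": 1}, (-1000, 1000), ["fumA"], "TCA"),
    ("MDH", {"mal__L_c": -1, "nad_c": -1, "h_c": 1, "nadh_c": 1, "oaa_c": 1},
     (-1000, 1000), ["mdh"], "TCA"),
    # --- electron transport system ---
    # NDH-I: 2 H+/e- pumped -> 4 H+ per NADH (plus the chemical proton).
    ("NDH1pp", {"nadh_c": -1, "q8_c": -1, "h_c": -5,
                "nad_c": 1, "q8h2_c": 1, "h_p": 4},
     (0, 1000), ["nuoB"], "oxidative phosphorylation"),
    ("NDH2pp", {"nadh_c": -1, "q8_c": -1, "h_c": -1, "nad_c": 1, "q8h2_c": 1},
     (0, 1000), ["ndh"], "oxidative phosphorylation"),
    # CYO: 2 H+/e- -> 4 H+ per 1/2 O2; CBD: 1 H+/e- -> 2 H+ per 1/2 O2.
    ("CYOpp", {"q8h2_c": -1, "o2_c": -0.5, "h_c": -4,
               "q8_c": 1, "h2o_c": 1, "h_p": 4},
     (0, 1000), ["cyoB"], "oxidative phosphorylation"),
    ("CBDpp", {"q8h2_c": -1, "o2_c": -0.5, "h_c": -2,
               "q8_c": 1, "h2o_c": 1, "h_p": 2},
     (0, 1000), ["cydB"], "oxidative phosphorylation"),
    # ATP synthase stoichiometry is rewritten by set_h_per_atp().
    ("ATPS4rpp", {"adp_c": -1, "pi_c": -1, "h_p": -DEFAULT_H_PER_ATP,
                  "atp_c": 1, "h2o_c": 1, "h_c": DEFAULT_H_PER_ATP - 1},
     (-1000, 1000), ["atpA"], "oxidative phosphorylation"),
    ("NADTRHD", {"nad_c": -1, "nadph_c": -1, "nadh_c": 1, "nadp_c": 1},
     (0, 1000), ["sthA"], "oxidative phosphorylation"),
    # --- nitrogen assimilation (lumped into the biomass subsystem) ---
    ("GLUDy", {"akg_c": -1, "h_c": -1, "nadph_c": -1, "nh4_c": -1,
               "glu__L_c": 1, "h2o_c": 1, "nadp_c": 1},
     (-1000, 1000), ["gdhA"], "biomass"),
    ("GLNS", {"atp_c": -1, "glu__L_c": -1, "nh4_c": -1,
              "adp_c": 1, "gln__L_c": 1, "h_c": 1, "pi_c": 1},
     (0, 1000), ["glnA"], "biomass"),
    # --- maintenance (ATP hydrolysis outlet; no hard non-growth floor, so
    # carbon-free states are zero-growth rather than infeasible) ---
    ("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "h_c": 1, "pi_c": 1},
     (0, 1000), [], "biomass"),
    # --- transport (grouped under the exchange subsystem) ---
    ("ACt2r", {"ac_e": -1, "h_p": -1, "ac_c": 1, "h_c": 1},
     (-1000, 1000), [], "exchange"),
    ("PIt2r", {"pi_e": -1, "h_p": -1, "pi_c": 1, "h_c": 1},
     (-1000, 1000), [], "exchange"),
    ("NH4t", {"nh4_e": -1, "nh4_c": 1}, (-1000, 1000), [], "exchange"),
    ("O2t", {"o2_e": -1, "o2_c": 1}, (-1000, 1000), [], "exchange"),
    ("CO2t", {"co2_e": -1, "co2_c": 1}, (-1000, 1000), [], "exchange"),
    ("H2Ot", {"h2o_e": -1, "h2o_c": 1}, (-1000, 1000), [], "exchange"),
    # --- exchanges ---
    ("EX_glc__D_e", {"glc__D_e": -1}, (-10, 0), [], "exchange"),
    ("EX_ac_e", {"ac_e": -1}, (0, 1000), [], "exchange"),
    ("EX_o2_e", {"o2_e": -1}, (-20, 0), [], "exchange"),
    ("EX_co2_e", {"co2_e": -1}, (-1000, 1000), [], "exchange"),
    ("EX_h2o_e", {"h2o_e": -1}, (-1000, 1000), [], "exchange"),
    ("EX_nh4_e", {"nh4_e": -1}, (-1000, 0), [], "exchange"),
    ("EX_pi_e", {"pi_e": -1}, (-1000, 0), [], "exchange"),
    ("EX_h_p", {"h_p": -1}, (-1000, 1000), [], "exchange"),
]

# Lumped biomass demand (per gDW of new biomass), including growth-associated
# ATP maintenance; precursor coefficients follow the standard reduced
# E. coli biomass composition.
_BIOMASS = {
    "3pg_c": -1.496, "accoa_c": -3.7478, "atp_c": -59.81, "e4p_c": -0.361,
    "f6p_c": -0.0709, "g3p_c": -0.129, "g6p_c": -0.205, "gln__L_c": -0.2557,
    "glu__L_c": -4.9414, "h2o_c": -59.81, "nad_c": -3.547, "nadph_c": -13.0279,
    "oaa_c": -1.7867, "pep_c": -0.5191, "pyr_c": -2.8328, "r5p_c": -0.8977,
    "adp_c": 59.81, "akg_c": 4.1182, "coa_c": 3.7478, "h_c": 59.81,
    "nadh_c": 3.547, "nadp_c": 13.0279, "pi_c": 59.81,
}

# gene -> (molecular weight kDa, kcat 1/s, complex).  Masses are the sizes of
# the assembled functional units (NDH-I and ATP synthase are full complexes);
# turnover numbers are rounded literature-scale values.  The NDH-I/NDH-II
# mass ratio (10x) and the EMP/ED pathway cost ratio (~3.5x) are the two
# proteome-economics parameters the variant phenotypes hinge on.
_ENZYMES = [
    ("ptsG", 50.0, 20.0, None),
    ("pgi", 61.0, 20.0, None),
    ("pfkA", 35.0, 11.0, None),
    ("fbaA", 39.0, 7.0, None),
    ("tpiA", 27.0, 43.0, None),
    ("gapA", 36.0, 10.0, None),
    ("pgk", 41.0, 22.0, None),
    ("gpmA", 28.0, 22.0, None),
    ("eno", 46.0, 16.0, None),
    ("pykF", 51.0, 17.0, None),
    ("zwf", 56.0, 18.0, None),
    ("pgl", 37.0, 22.0, None),
    ("edd", 65.0, 25.0, None),
    ("eda", 23.0, 28.0, None),
    ("gnd", 52.0, 13.0, None),
    ("rpe", 25.0, 22.0, None),
    ("rpiA", 23.0, 18.0, None),
    ("tktA", 72.0, 10.0, None),
    ("talB", 35.0, 11.0, None),
    ("aceE", 280.0, 15.0, "PDH"),
    ("pta", 77.0, 25.0, None),
    ("ackA", 43.0, 35.0, None),
    ("ppc", 99.0, 7.0, None),
    ("gltA", 48.0, 9.0, None),
    ("acnB", 94.0, 6.0, None),
    ("icd", 46.0, 9.0, None),
    ("sucA", 190.0, 10.0, "AKGDH"),
    ("sucC", 70.0, 11.0, None),
    ("sdhA", 120.0, 9.0, "SDH"),
    ("fumA", 60.0, 25.0, None),
    ("mdh", 32.0, 25.0, None),
    ("gdhA", 50.0, 18.0, None),
    ("glnA", 52.0, 10.0, None),
    ("sthA", 51.0, 10.0, None),
    ("nuoB", 470.0, 40.0, "NDH-I"),
    ("ndh", 47.0, 15.0, None),
    ("cyoB", 144.0, 30.0, "CYO"),
    ("cydB", 100.0, 25.0, "CBD"),
    ("atpA", 530.0, 70.0, "ATPS"),
    # effective translation machinery: couples growth itself to the budget
    ("rpsA", 2300.0, 2.5, "ribosome"),
]


def reference_model() -> MetabolicModel:
    """Construct the bundled reference network (validated)."""
    metabolites = {
        mid: Metabolite(mid, name, comp, formula, charge)
        for mid, name, comp, formula, charge in _METABOLITES
    }
    reactions = {}
    for rid, stoich, (lb, ub), genes, subsystem in _REACTIONS:
        reactions[rid] = Reaction(rid, {k: float(v) for k, v in stoich.items()},
                                  float(lb), float(ub), list(genes), subsystem)
    reactions["BIOMASS"] = Reaction("BIOMASS", dict(_BIOMASS), 0.0, 1000.0,
                                    ["rpsA"], "biomass")
    enzymes = {g: EnzymeSpec(g, mw, kcat, cplx) for g, mw, kcat, cplx in _ENZYMES}
    components = {
        cid: ETSComponent(cid, COMPONENT_PROTONS_PER_ELECTRON[cid],
                          COMPONENT_REACTIONS[cid])
        for cid in COMPONENT_PROTONS_PER_ELECTRON
    }
    ats_genes = {
        g for rxn in reactions.values()
        if rxn.subsystem in ATS_SUBSYSTEMS for g in rxn.genes
    }
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        enzymes=enzymes,
        ets_components=components,
        ats_gene_set=ats_genes,
        atps_reaction_id="ATPS4rpp",
        h_per_atp=DEFAULT_H_PER_ATP,
    )
    validate_model(model)
    return model


def bundled_model_path() -> Path:
    return Path(__file__).parent / "data" / "reference_model.json"
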