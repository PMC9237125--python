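import logging

import numpy as np
import pytest

from aerotype import fba, network, synth
from aerotype.pipeline import RunConfig, run_study

logging.getLogger("aerotype").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def model():
    return network.reference_model()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic study bundle (seed 42) with its planted truth."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = synth.gen_all(outdir, seed=42)
    return outdir, truth


@pytest.fixture(scope="session")
def study_report(bundle, tmp_path_factory):
    """Full pipeline run over the default bundle."""
    outdir, _ = bundle
    run_dir = tmp_path_factory.mktemp("run")
    config = RunConfig(
        phenotype=str(outdir / "phenotype.tsv"),
        expression=str(outdir / "expression.tsv"),
        meta=str(outdir / "meta.tsv"),
        mutations=str(outdir / "mutations.csv"),
        outdir=str(run_dir),
        seed=42,
    )
    return run_study(config)


def toy_chain_model():
    """Minimal 5-reaction network: uptake -> A -> B -> growth, plus a lossy
    bypass.  Small enough for exhaustive vertex enumeration."""
    mets = {
        "a_e": network.Metabolite("a_e", "A", "extracellular", "C", 0),
        "a_c": network.Metabolite("a_c", "A", "cytosol", "C", 0),
        "b_c": network.Metabolite("b_c", "B", "cytosol", "C", 0),
    }
    rxns = {
        "EX_a": network.Reaction("EX_a", {"a_e": -1}, -5.0, 0.0, [], "exchange"),
        "T_a": network.Reaction("T_a", {"a_e": -1, "a_c": 1}, 0.0, 100.0, [],
                                "exchange"),
        "R1": network.Reaction("R1", {"a_c": -1, "b_c": 1}, 0.0, 3.0, ["g1"],
                               "glycolysis (EMP)"),
        "R2": network.Reaction("R2", {"a_c": -2, "b_c": 1}, 0.0, 100.0, ["g2"],
                               "glycolysis (ED)"),
        "GROW": network.Reaction("GROW", {"b_c": -1}, 0.0, 100.0, [], "biomass"),
    }
    return network.MetabolicModel(
        metabolites=mets, reactions=rxns, enzymes={},
        ets_components={}, ats_gene_set=set(),
        atps_reaction_id="GROW", h_per_atp=10 / 3)


@pytest.fixture
def toy_model():
    return toy_chain_model()
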