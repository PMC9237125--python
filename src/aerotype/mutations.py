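"""Mutation-table processing for adaptive laboratory evolution endpoints.

Sequenced ALE samples include midpoint clones, so the same SNP can appear
several times within one evolution lineage; records are collapsed to one
per (experiment, lineage, gene, position, ref, alt).  Hypermutator samples
(mismatch-repair mutants) are flagged and excluded from convergence
analysis.  Effect calls combine truncation logic (start-codon loss and
premature stop codons under the standard genetic code) with externally
supplied substitution scores: a SNP is deemed deleterious when SIFT < 0.05
and destabilizing when ddG > 2 kcal/mol.  Convergent targets are genes (or
intergenic regions, keyed "geneA-geneB") mutated in at least a minimum
number of independent lineages of the same experiment.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger("aerotype")

SIFT_DELETERIOUS_BELOW = 0.05
DDG_DESTABILIZING_ABOVE = 2.0
DEFAULT_MUTATOR_GENES = frozenset({"mutS", "mutL", "mutH"})
#: a sample is a hypermutator when its mutation count exceeds this multiple
#: of the median per-sample count
HYPERMUTATOR_COUNT_RATIO = 3.0

STOP = "*"
_BASES = set("ACGT")

MUTATION_CSV_COLUMNS = [
    "experiment", "lineage", "sample", "tech_rep", "gene", "protein_position",
    "ref_codon", "alt_codon", "is_start_codon", "sift_score", "ddG",
    "mutation_type",
]


@dataclass(frozen=True)
class MutationRecord:
    experiment: str
    lineage: str
    sample: str
    technical_replicate: str = "1"
    gene: str = ""
    protein_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    sift_score: float | None = None
    ddG: float | None = None
    is_start_codon: bool = False
    mutation_type: str = "SNP"

    def __post_init__(self):
        for codon in (self.ref_codon, self.alt_codon):
            if codon is not None and (len(codon) != 3 or set(codon) - _BASES):
                raise ValueError(f"malformed codon {codon!r} in record for "
                                 f"{self.gene} ({self.experiment}/{self.lineage})")
        if self.sift_score is not None and not 0.0 <= self.sift_score <= 1.0:
            raise ValueError(f"SIFT score outside [0, 1]: {self.sift_score}")

    @property
    def site(self) -> tuple:
        return (self.gene, self.protein_position, self.ref_codon, self.alt_codon)


@dataclass(frozen=True)
class EffectCall:
    truncation: str            # "start_loss" | "premature_stop" | "none"
    sift_deleterious: bool
    destabilizing: bool
    summary: str


def translate_codon(codon: str) -> str:
    """Standard genetic code; returns '*' for stop codons."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - _BASES:
        raise ValueError(f"malformed codon {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return STOP
    return standard_dna_table.forward_table[codon]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dedupe_unique_per_ale(records: list[MutationRecord]) -> list[MutationRecord]:
    """Keep one record per mutation per evolution lineage.

    Midpoint and endpoint samples of the same lineage carrying the same
    (gene, position, ref, alt) collapse to the first occurrence; the same
    mutation in different lineages is retained separately.
    """
    seen: set[tuple] = set()
    out: list[MutationRecord] = []
    for rec in records:
        key = (rec.experiment, rec.lineage) + rec.site
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def flag_hypermutators(
    records: list[MutationRecord],
    mutator_genes: frozenset[str] = DEFAULT_MUTATOR_GENES,
    count_ratio: float = HYPERMUTATOR_COUNT_RATIO,
) -> dict[tuple[str, str], bool]:
    """Per-(experiment, lineage) hypermutator flags.

    A lineage is flagged when it carries a coding mutation in a
    mismatch-repair gene, or when its mutation count exceeds
    ``count_ratio`` times the median count across lineages.
    """
    counts: dict[tuple[str, str], int] = {}
    mutator_hit: dict[tuple[str, str], bool] = {}
    for rec in records:
        key = (rec.experiment, rec.lineage)
        counts[key] = counts.get(key, 0) + 1
        if rec.gene in mutator_genes:
            mutator_hit[key] = True
    if not counts:
        return {}
    med = statistics.median(counts.values())
    flags = {}
    for key, n in counts.items():
        flags[key] = mutator_hit.get(key, False) or (med > 0 and n > count_ratio * med)
        if flags[key]:
            logger.info("hypermutator lineage flagged: %s (%d mutations, "
                        "median %.1f)", key, n, med)
    return flags


def classify_effect(record: MutationRecord) -> EffectCall:
    """Truncation, SIFT and stability calls for a single mutation."""
    if (record.ref_codon is None and record.alt_codon is None
            and record.sift_score is None and record.ddG is None):
        raise ValueError(f"record for {record.gene} carries no effect evidence")
    truncation = "none"
    if record.alt_codon is not None:
        alt_aa = translate_codon(record.alt_codon)
        if record.is_start_codon and record.alt_codon != "ATG":
            truncation = "start_loss"
        elif alt_aa == STOP:
            truncation = "premature_stop"
    sift_del = (record.sift_score is not None
                and record.sift_score < SIFT_DELETERIOUS_BELOW)
    destab = record.ddG is not None and record.ddG > DDG_DESTABILIZING_ABOVE
    if truncation != "none":
        summary = truncation
    elif sift_del and destab:
        summary = "deleterious_destabilizing"
    elif sift_del:
        summary = "deleterious"
    elif destab:
        summary = "destabilizing"
    else:
        summary = "tolerated"
    return EffectCall(truncation=truncation, sift_deleterious=sift_del,
                      destabilizing=destab, summary=summary)


def detect_convergence(
    records: list[MutationRecord],
    n_lineages: int,
    min_lineages: int = 4,
    hypermutator_flags: dict[tuple[str, str], bool] | None = None,
) -> list[tuple[str, str, int]]:
    """Genes mutated in >= min_lineages distinct lineages of one experiment.

    Input should already be deduplicated; flagged hypermutator lineages are
    excluded.  Within each experiment the threshold is capped at the number
    of analyzable (non-flagged) lineages, so convergence across all usable
    replicates is still reported when a hypermutator was removed.  Returns
    (experiment, gene, lineage count) sorted by count descending, then
    gene id.
    """
    flags = hypermutator_flags or {}
    lineages_by_gene: dict[tuple[str, str], set[str]] = {}
    usable_lineages: dict[str, set[str]] = {}
    for rec in records:
        if flags.get((rec.experiment, rec.lineage)):
            continue
        usable_lineages.setdefault(rec.experiment, set()).add(rec.lineage)
        if not rec.gene:
            continue
        lineages_by_gene.setdefault((rec.experiment, rec.gene), set()).add(rec.lineage)
    hits = [
        (exp, gene, len(lin))
        for (exp, gene), lin in lineages_by_gene.items()
        if len(lin) >= min(min_lineages, len(usable_lineages.get(exp, set())))
    ]
    for exp, gene, count in hits:
        if count > n_lineages:
            logger.warning("gene %s counted in %d lineages but experiment "
                           "declares only %d", gene, count, n_lineages)
    return sorted(hits, key=lambda t: (t[0], -t[2], t[1]))


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def _opt(value, cast):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return cast(value)


def read_mutations_csv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path)
    missing = set(MUTATION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(MutationRecord(
            experiment=str(row["experiment"]),
            lineage=str(row["lineage"]),
            sample=str(row["sample"]),
            technical_replicate=str(row["tech_rep"]),
            gene=str(row["gene"]) if not pd.isna(row["gene"]) else "",
            protein_position=_opt(row["protein_position"], lambda v: int(float(v))),
            ref_codon=_opt(row["ref_codon"], str),
            alt_codon=_opt(row["alt_codon"], str),
            is_start_codon=bool(row["is_start_codon"]),
            sift_score=_opt(row["sift_score"], float),
            ddG=_opt(row["ddG"], float),
            mutation_type=str(row["mutation_type"]),
        ))
    return records


def records_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "experiment": r.experiment, "lineage": r.lineage, "sample": r.sample,
            "tech_rep": r.technical_replicate, "gene": r.gene,
            "protein_position": r.protein_position, "ref_codon": r.ref_codon,
            "alt_codon": r.alt_codon, "is_start_codon": r.is_start_codon,
            "sift_score": r.sift_score, "ddG": r.ddG,
            "mutation_type": r.mutation_type,
        })
    return pd.DataFrame(rows, columns=MUTATION_CSV_COLUMNS)
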