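import pytest
from hypothesis import given, settings, strategies as st

from aerotype.mutations import (
    MutationRecord, classify_effect, dedupe_unique_per_ale,
    detect_convergence, flag_hypermutators, read_mutations_csv,
    records_to_frame, translate_codon,
)


def rec(exp="E1", lin="A", sample="s1", gene="sdhA", pos=10,
        ref="GAA", alt="AAA", start=False, sift=None, ddg=None):
    return MutationRecord(experiment=exp, lineage=lin, sample=sample,
                          gene=gene, protein_position=pos, ref_codon=ref,
                          alt_codon=alt, is_start_codon=start,
                          sift_score=sift, ddG=ddg)


class TestDedupe:
    def test_midpoint_duplicate_collapses(self):
        records = [rec(sample="endpoint"), rec(sample="midpoint")]
        assert len(dedupe_unique_per_ale(records)) == 1

    def test_same_snp_in_two_lineages_kept(self):
        records = [rec(lin="A"), rec(lin="B")]
        assert len(dedupe_unique_per_ale(records)) == 2

    def test_empty_input(self):
        assert dedupe_unique_per_ale([]) == []

    def test_idempotent_and_never_grows(self):
        records = [rec(sample=f"s{i}", pos=p) for i in range(3)
                   for p in (10, 10, 20)]
        once = dedupe_unique_per_ale(records)
        assert len(once) <= len(records)
        assert dedupe_unique_per_ale(once) == once

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("AB"), st.sampled_from("xyz"),
                              st.integers(1, 3)), max_size=12))
    def test_dedupe_keys_on_lineage_and_site(self, raw):
        records = [rec(lin=l, sample=s, pos=p) for l, s, p in raw]
        unique = dedupe_unique_per_ale(records)
        keys = {(r.experiment, r.lineage) + r.site for r in unique}
        assert len(keys) == len(unique)
        assert keys == {(r.experiment, r.lineage) + r.site for r in records}


class TestHypermutators:
    def test_mutator_gene_with_high_load_flagged(self):
        records = [rec(lin=l, gene=f"g{i}", pos=i + 1)
                   for l in "ABC" for i in range(3)]
        records += [rec(lin="D", gene="mutS", pos=5)]
        records += [rec(lin="D", gene=f"h{i}", pos=i + 1) for i in range(14)]
        flags = flag_hypermutators(records)
        assert flags[("E1", "D")] is True
        assert not flags[("E1", "A")]

    def test_equal_loads_without_mutator_hits(self):
        records = [rec(lin=l, gene=f"g{i}", pos=i + 1)
                   for l in "ABCD" for i in range(3)]
        assert not any(flag_hypermutators(records).values())

    def test_single_lineage_never_flagged_by_ratio(self):
        records = [rec(lin="A", gene=f"g{i}", pos=i + 1) for i in range(30)]
        assert flag_hypermutators(records) == {("E1", "A"): False}

    def test_count_rule_alone_flags(self):
        records = [rec(lin=l, gene=f"g{i}", pos=i + 1)
                   for l in "ABC" for i in range(2)]
        records += [rec(lin="D", gene=f"g{i}", pos=i + 1) for i in range(9)]
        flags = flag_hypermutators(records)
        assert flags[("E1", "D")] is True


class TestClassifyEffect:
    def test_start_codon_replacement_is_start_loss(self):
        call = classify_effect(rec(gene="yjjX", pos=1, ref="ATG", alt="ATA",
                                   start=True))
        assert call.truncation == "start_loss"
        assert call.summary == "start_loss"

    def test_mid_gene_stop_codon_is_premature_stop(self):
        call = classify_effect(rec(gene="sdhA", pos=120, ref="TAC", alt="TAA"))
        assert call.truncation == "premature_stop"

    def test_sift_threshold_is_strict(self):
        at = classify_effect(rec(sift=0.05))
        below = classify_effect(rec(sift=0.049))
        assert not at.sift_deleterious
        assert below.sift_deleterious

    def test_ddg_threshold(self):
        assert classify_effect(rec(ddg=2.5)).destabilizing
        assert not classify_effect(rec(ddg=2.0)).destabilizing

    def test_classification_is_pure(self):
        r = rec(sift=0.01, ddg=3.0)
        assert classify_effect(r) == classify_effect(r)
        assert classify_effect(r).summary == "deleterious_destabilizing"

    def test_malformed_codon_names_the_record(self):
        with pytest.raises(ValueError, match="sdhA"):
            rec(alt="AXG")

    def test_record_without_evidence_rejected(self):
        bare = MutationRecord(experiment="E1", lineage="A", sample="s",
                              gene="x")
        with pytest.raises(ValueError, match="evidence"):
            classify_effect(bare)

    @pytest.mark.parametrize("codon, aa", [
        ("ATG", "M"), ("TAA", "*"), ("TAG", "*"), ("TGA", "*"), ("TAC", "Y"),
        ("ATA", "I"),
    ])
    def test_standard_genetic_code(self, codon, aa):
        assert translate_codon(codon) == aa


class TestConvergence:
    def four_lineage_hits(self, gene="sdhA"):
        return [rec(lin=l, gene=gene, pos=ord(l)) for l in "ABCD"]

    def test_gene_hit_in_all_lineages_reported(self):
        hits = detect_convergence(self.four_lineage_hits(), n_lineages=4)
        assert hits == [("E1", "sdhA", 4)]

    def test_two_of_four_not_reported_at_threshold_four(self):
        records = [rec(lin=l, gene="yjjX", pos=1) for l in "AB"]
        records += [rec(lin=l, gene=f"other{l}", pos=2) for l in "ABCD"]
        assert detect_convergence(records, n_lineages=4,
                                  min_lineages=4) == []

    def test_degenerate_threshold_reports_everything(self):
        records = [rec(lin="A", gene="a", pos=1), rec(lin="B", gene="b", pos=2)]
        hits = detect_convergence(records, n_lineages=4, min_lineages=1)
        assert {h[1] for h in hits} == {"a", "b"}

    def test_counts_never_exceed_lineage_number(self):
        hits = detect_convergence(self.four_lineage_hits(), n_lineages=4)
        assert all(count <= 4 for _, _, count in hits)

    def test_hypermutator_lineage_excluded_with_adaptive_threshold(self):
        records = self.four_lineage_hits("yjjX")
        flags = {("E1", "C"): True}
        hits = detect_convergence(records, n_lineages=4, min_lineages=4,
                                  hypermutator_flags=flags)
        # the remaining three analyzable lineages still converge
        assert hits == [("E1", "yjjX", 3)]

    def test_intergenic_region_counted_as_unit(self):
        records = [MutationRecord(experiment="E1", lineage=l, sample="s",
                                  gene="pyrE-rph", mutation_type="intergenic")
                   for l in "ABCD"]
        hits = detect_convergence(records, n_lineages=4)
        assert hits == [("E1", "pyrE-rph", 4)]


class TestTabularIO:
    def test_csv_round_trip(self, tmp_path):
        records = [rec(), rec(lin="B", gene="yjjX", pos=1, ref="ATG",
                              alt="ATA", start=True, sift=0.02, ddg=0.4)]
        path = tmp_path / "m.csv"
        records_to_frame(records).to_csv(path, index=False)
        back = read_mutations_csv(path)
        assert back == records

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("experiment,gene\nE1,sdhA\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_mutations_csv(path)
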