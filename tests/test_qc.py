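"""Demultiplexing, reading-frame classification, keep rules and the chimera
screen."""

import numpy as np
import pandas as pd
import pytest

from minicoi import (apply_keep_rules, demultiplex, detect_chimera,
                     frame_classify, reverse_complement, run_qc_pipeline,
                     translate)
from minicoi.qc import ReadQCRecord, SampleTagScheme, SchemeError
from minicoi.sim import SimSpec, make_gut_reads, make_reference_panel


def _read(scheme, panel, insert):
    return (scheme.mid + scheme.tag + panel.forward_member + insert
            + reverse_complement(panel.reverse_member)
            + reverse_complement(scheme.tag) + reverse_complement(scheme.mid))


@pytest.fixture(scope="module")
def setup(small_panel, primers):
    scheme = [SampleTagScheme("S01", "AAGGTTCC", "AGCACG"),
              SampleTagScheme("S02", "AAGGTTCC", "ACGCAG")]
    return small_panel, scheme, primers["mlCOIintF"], primers["jgHCO2198"]


class TestDemultiplex:
    def test_exact_tag_and_primer_assigned(self, setup):
        panel, scheme, fwd, rev = setup
        insert = panel.inserts[0][1]
        reads = [("r1", _read(scheme[0], panel, insert))]
        bins, records = demultiplex(reads, scheme, fwd, rev)
        assert records[0].sample_id == "S01"
        assert records[0].fwd_primer_mismatches == 0
        assert bins["S01"] == [("r1", insert)]

    @pytest.mark.parametrize("n_mm,verdict", [(2, "pass"), (3, "discard_primer")])
    def test_primer_mismatch_ceiling_boundary(self, setup, n_mm, verdict):
        # the stated rule discards only reads with MORE than two mismatches
        panel, scheme, fwd, rev = setup
        insert = panel.inserts[0][1]
        read = list(_read(scheme[0], panel, insert))
        from minicoi.iupac import IUPAC_SETS
        offset = len(scheme[0].mid) + len(scheme[0].tag)
        for i in range(n_mm):
            allowed = IUPAC_SETS[fwd.sequence[i]]
            read[offset + i] = sorted(set("ACGT") - allowed)[0]
        _, records = demultiplex([("r1", "".join(read))], scheme, fwd, rev)
        assert records[0].verdict == verdict

    def test_unknown_tag_is_unassigned(self, setup):
        panel, scheme, fwd, rev = setup
        read = ("r1", "GGGGGGGG" + "TTTTTT" + panel.forward_member
                + panel.inserts[0][1])
        _, records = demultiplex([read], scheme, fwd, rev)
        assert records[0].verdict == "unassigned"

    def test_short_insert_discarded_by_length_floor(self, setup):
        panel, scheme, fwd, rev = setup
        reads = [("r1", _read(scheme[0], panel, panel.inserts[0][1][:100]))]
        _, records = demultiplex(reads, scheme, fwd, rev, min_length=150)
        assert records[0].verdict == "discard_length"

    def test_partition_conserves_reads(self, setup):
        panel, scheme, fwd, rev = setup
        spec = SimSpec(seed=3, n_species=6, n_samples=4, reads_per_sample=25,
                       stop_fraction=0.1, frameshift_fraction=0.1)
        reads, truth, sim_scheme, _ = make_gut_reads(spec, panel)
        reads.append(("junk", "ACGT" * 120))
        bins, records = demultiplex(reads, sim_scheme, fwd, rev)
        assert len(records) == len(reads)
        n_binned = sum(len(v) for v in bins.values())
        n_not_binned = sum(1 for r in records
                           if r.verdict in ("unassigned", "discard_primer",
                                            "discard_length"))
        assert n_binned + n_not_binned == len(reads)

    def test_duplicate_sample_ids_rejected(self, setup):
        panel, scheme, fwd, rev = setup
        bad = [scheme[0], SampleTagScheme("S01", "CCTTGGAA", "ACTATC")]
        with pytest.raises(SchemeError):
            demultiplex([], bad, fwd, rev)


class TestFrameClassify:
    def test_clean_read_has_zero_counters(self, small_panel):
        insert = small_panel.inserts[0][1]
        rec = frame_classify(insert, small_panel.qc_references)
        assert (rec.n_stop_codons, rec.n_frameshifts, rec.n_inserted_codons,
                rec.n_deleted_codons) == (0, 0, 0, 0)

    def test_single_extra_base_is_one_frameshift(self, small_panel):
        insert = small_panel.inserts[0][1]
        read = insert[:100] + "A" + insert[100:]
        rec = frame_classify(read, small_panel.qc_references)
        assert rec.n_frameshifts == 1
        assert rec.n_stop_codons == rec.n_inserted_codons == rec.n_deleted_codons == 0

    def test_whole_codon_deletion_is_not_a_frameshift(self, small_panel):
        insert = small_panel.inserts[0][1]
        read = insert[:99] + insert[102:]
        rec = frame_classify(read, small_panel.qc_references)
        assert rec.n_deleted_codons == 1 and rec.n_frameshifts == 0

    def test_whole_codon_insertion_counted(self, small_panel):
        insert = small_panel.inserts[0][1]
        read = insert[:99] + "AAA" + insert[99:]
        rec = frame_classify(read, small_panel.qc_references)
        assert rec.n_inserted_codons == 1 and rec.n_frameshifts == 0

    def test_stop_substitution_counted(self, small_panel):
        insert = small_panel.inserts[0][1]
        read = insert[:90] + "TAA" + insert[93:]
        rec = frame_classify(read, small_panel.qc_references)
        assert rec.n_stop_codons >= 1

    def test_unalignable_read_flagged(self, small_panel):
        # a homopolymer sits far below the 50% identity floor of the panel
        rec = frame_classify("A" * 240, small_panel.qc_references)
        assert rec.verdict == "unassigned"


class TestKeepRules:
    def _rec(self, stops=0, fs=0, ins=0, dels=0):
        r = ReadQCRecord(read_id="r", n_stop_codons=stops, n_frameshifts=fs,
                         n_inserted_codons=ins, n_deleted_codons=dels,
                         repaired_sequence="ATG" * 10,
                         output_sequence="ATG" * 10 + "A")
        return apply_keep_rules(r)

    @pytest.mark.parametrize("counters,verdict", [
        (dict(), "pass"),
        (dict(dels=3), "pass"),                 # fewer than four deletions
        (dict(dels=4), "discard_deletion"),     # boundary
        (dict(fs=1), "repaired"),
        (dict(fs=2), "discard_frameshift"),
        (dict(fs=1, dels=1), "discard_frameshift"),
        (dict(ins=1), "discard_insertion"),
        (dict(stops=1), "discard_stop"),
        (dict(stops=1, fs=1, ins=2, dels=5), "discard_stop"),  # precedence
    ])
    def test_verdicts(self, counters, verdict):
        assert self._rec(**counters).verdict == verdict

    def test_repair_excises_the_frameshifted_codon(self, small_panel):
        insert = small_panel.inserts[0][1]
        for p in (31, 100, 200, 299):
            read = insert[:p] + insert[p + 1:]
            rec = apply_keep_rules(frame_classify(read, small_panel.qc_references))
            assert rec.verdict == "repaired"
            out = rec.output_sequence
            assert len(out) % 3 == 0
            assert translate(out)[1] == []          # stop-free
            assert len(out) == 3 * (len(insert) // 3 - 1)


class TestChimera:
    def test_two_parent_chimera_detected(self, small_panel):
        inserts = dict(small_panel.inserts)
        a, b = inserts["sp01_r1"], inserts["sp04_r1"]
        call = detect_chimera(a[:150] + b[150:], small_panel.qc_references,
                              min_score_gain=0.01, read_id="chim")
        assert call.is_chimera
        assert call.score > 0.01
        assert 100 <= call.breakpoint <= 200
        assert {p.split("_")[0] for p in call.parents} == {"sp01", "sp04"}

    def test_clonal_read_never_flagged(self, small_panel):
        for rid, seq in small_panel.inserts[:6]:
            call = detect_chimera(seq, small_panel.qc_references,
                                  min_score_gain=0.01)
            assert not call.is_chimera
            assert call.score == pytest.approx(0.0, abs=1e-9)

    def test_identical_references_give_zero_gain(self):
        refs = [("a", "ACGTAGGTCA" * 12), ("b", "ACGTAGGTCA" * 12)]
        call = detect_chimera("ACGTAGGTCA" * 12, refs, min_score_gain=0.01)
        assert not call.is_chimera and call.score == 0.0

    def test_short_read_not_evaluable(self, small_panel):
        call = detect_chimera("ACGT" * 10, small_panel.qc_references,
                              min_segment=30)
        assert not call.evaluable and not call.is_chimera

    def test_two_parent_identity_bounded_below_by_single(self, small_panel):
        rng = np.random.default_rng(2)
        inserts = dict(small_panel.inserts)
        for _ in range(10):
            rid = rng.choice(list(inserts))
            seq = list(inserts[rid])
            for p in rng.choice(len(seq), size=5, replace=False):
                seq[p] = rng.choice(list("ACGT"))
            call = detect_chimera("".join(seq), small_panel.qc_references)
            assert call.best_two_parent_identity >= call.best_single_parent_identity


class TestPipeline:
    def test_planted_verdicts_recovered_and_summary_consistent(self, small_panel, primers):
        spec = SimSpec(seed=13, n_species=6, n_samples=4, reads_per_sample=60,
                       stop_fraction=0.10, frameshift_fraction=0.10,
                       codon_insertion_fraction=0.05,
                       codon_deletion_pass_fraction=0.05,
                       codon_deletion_discard_fraction=0.05)
        reads, truth, scheme, _ = make_gut_reads(spec, small_panel)
        records, bins, summary = run_qc_pipeline(
            reads, scheme, primers["mlCOIintF"], primers["jgHCO2198"],
            small_panel.qc_references)
        df = pd.DataFrame([{"read_id": r.read_id, "verdict": r.verdict}
                           for r in records]).merge(truth, on="read_id")
        agreement = (df.verdict == df.planted_verdict).mean()
        assert agreement >= 0.99
        assert summary["input"] == len(reads)
        assert sum(summary["verdicts"].values()) == len(reads)
        assert summary["final"] == sum(len(v) for v in bins.values())
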