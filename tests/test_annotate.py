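"""Built-in aligner calls, E-value statistics, junction extraction, and the
external-backend contract."""

import math
import os
import stat

import pytest
from Bio.Seq import reverse_complement

from vdjflow.annotate import (
    AlignmentHit,
    AnnotatorConfigError,
    BackendError,
    ScoringParams,
    annotate_builtin,
    compute_evalue,
    extract_junction,
    run_external_annotator,
)
from vdjflow.fastx_io import SeqRecord
from vdjflow.synth import read_truth_table

PARAMS = ScoringParams()


def split_hits(hits):
    by_seg = {"V": [], "D": [], "J": []}
    for h in hits:
        by_seg[h.segment].append(h)
    return by_seg


class TestComputeEvalue:
    def test_zero_score_closed_form(self):
        assert compute_evalue(0, m=100, n=1000, params=PARAMS) == pytest.approx(10000.0)

    def test_score_twenty_closed_form(self):
        # 0.1 * 100 * 1000 * exp(-10)
        expected = 10000.0 * math.exp(-10.0)
        assert compute_evalue(20, m=100, n=1000, params=PARAMS) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.4540, abs=5e-5)

    def test_strictly_decreasing_in_score(self):
        evalues = [compute_evalue(s, 100, 1000, PARAMS) for s in range(0, 200, 7)]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))


class TestBuiltinAnnotation:
    def test_exact_recombinant_gives_perfect_rank1_calls(self, toy_db):
        v, j = toy_db.v_genes[1], toy_db.j_genes[1]
        read = SeqRecord(id="exact", sequence=v.sequence + j.sequence)
        hits, rev_comp = annotate_builtin(read, toy_db, PARAMS)
        assert not rev_comp
        seg = split_hits(hits)
        assert seg["V"][0].gene_call == v.name
        assert seg["V"][0].identity == 1.0
        assert seg["J"][0].gene_call == j.name
        assert seg["J"][0].identity == 1.0

    def test_strand_symmetry(self, toy_db):
        v, j = toy_db.v_genes[0], toy_db.j_genes[0]
        fwd = SeqRecord(id="f", sequence=v.sequence + "GATAGTAGT" + j.sequence)
        rev = SeqRecord(id="r", sequence=reverse_complement(fwd.sequence))
        hits_f, rc_f = annotate_builtin(fwd, toy_db, PARAMS)
        hits_r, rc_r = annotate_builtin(rev, toy_db, PARAMS)
        assert (rc_f, rc_r) == (False, True)
        assert [(h.segment, h.rank, h.gene_call, h.score) for h in hits_f] == [
            (h.segment, h.rank, h.gene_call, h.score) for h in hits_r
        ]
        # intervals agree because both annotate the same orientation
        assert [(h.query_start, h.query_end) for h in hits_f] == [
            (h.query_start, h.query_end) for h in hits_r
        ]

    def test_rank1_has_minimum_evalue_and_unique_ranks(self, toy_db):
        v, j = toy_db.v_genes[2], toy_db.j_genes[0]
        read = SeqRecord(id="x", sequence=v.sequence + "ACGTAC" + j.sequence)
        hits, _ = annotate_builtin(read, toy_db, PARAMS)
        for segment, seg_hits in split_hits(hits).items():
            if not seg_hits:
                continue
            assert [h.rank for h in seg_hits] == list(range(1, len(seg_hits) + 1))
            assert seg_hits[0].e_value == min(h.e_value for h in seg_hits)
            assert len(seg_hits) <= 3

    def test_uncallable_read_returns_empty_hits(self, toy_db):
        # all-N reads never produce a positive-scoring local alignment
        read = SeqRecord(id="junk", sequence="N" * 40)
        hits, _ = annotate_builtin(read, toy_db, PARAMS)
        assert hits == []

    def test_mutation_free_reads_recover_generator_truth(self, toy_db, clean_sim):
        fastq, truth_path, _params = clean_sim
        from vdjflow.fastx_io import read_fastx

        truth = read_truth_table(truth_path)
        n = v_ok = j_ok = 0
        for rec in read_fastx(fastq):
            hits, _ = annotate_builtin(rec, toy_db, PARAMS)
            seg = split_hits(hits)
            n += 1
            v_ok += seg["V"] and seg["V"][0].gene_call == truth[rec.id].true_v
            j_ok += seg["J"] and seg["J"][0].gene_call == truth[rec.id].true_j
        assert n == 200
        assert v_ok == n
        assert j_ok == n


class TestJunctionExtraction:
    def annotate(self, toy_db, seq):
        hits, _ = annotate_builtin(SeqRecord(id="q", sequence=seq), toy_db, PARAMS)
        seg = split_hits(hits)
        return seg["V"][0], seg["J"][0]

    def test_exact_recombinant_junction_matches_construction(self, toy_db):
        v, j = toy_db.v_genes[0], toy_db.j_genes[0]
        insert = "GATAGTAGT"
        seq = v.sequence + insert + j.sequence
        v_hit, j_hit = self.annotate(toy_db, seq)
        call = extract_junction(seq, v_hit, j_hit, toy_db)
        expected_junction = seq[v.anchor : len(v.sequence) + len(insert) + j.anchor + 3]
        assert call.junction == expected_junction
        assert call.cdr3 == expected_junction[3:-3]

    def test_junction_aa_flanked_by_conserved_residues(self, toy_db):
        for v in toy_db.v_genes:
            for j in toy_db.j_genes:
                # 9-nt insert keeps the junction in frame for the toy anchors
                seq = v.sequence + "CATCATCAT" + j.sequence
                v_hit, j_hit = self.annotate(toy_db, seq)
                call = extract_junction(seq, v_hit, j_hit, toy_db)
                assert len(call.junction) % 3 == 0
                assert call.junction_aa[0] == "C"
                assert call.junction_aa[-1] in ("W", "F")

    def test_anchor_outside_aligned_interval_gives_absent(self, toy_db):
        v, j = toy_db.v_genes[0], toy_db.j_genes[0]
        # V hit whose germline interval ends before the cysteine anchor
        v_hit = AlignmentHit(
            gene_call=v.name,
            segment="V",
            score=100,
            e_value=1e-10,
            query_start=0,
            query_end=100,
            germline_start=0,
            germline_end=100,
            identity=1.0,
            rank=1,
            blocks=(((0, 100),), ((0, 100),)),
        )
        j_hit = AlignmentHit(
            gene_call=j.name,
            segment="J",
            score=90,
            e_value=1e-9,
            query_start=100,
            query_end=148,
            germline_start=0,
            germline_end=48,
            identity=1.0,
            rank=1,
            blocks=(((100, 148),), ((0, 48),)),
        )
        seq = "A" * 148
        assert extract_junction(seq, v_hit, j_hit, toy_db) is None


class TestExternalBackend:
    FIXTURE_TSV = (
        "sequence_id\tsequence\tv_call\tj_call\tjunction\n"
        + "".join(
            f"read{i}\tACGTACGT\tIGHV1-1*01\tIGHJ4*01\tTGTGCGTGG\n" for i in range(5)
        )
    )

    def make_stub(self, tmp_path, body):
        script = tmp_path / "stub_annotator.sh"
        script.write_text("#!/bin/sh\n" + body)
        script.chmod(script.stat().st_mode | stat.S_IXUSR)
        return script

    def test_missing_executable_is_config_error(self, tmp_path):
        chunk = tmp_path / "chunk.fasta"
        chunk.write_text(">r\nACGT\n")
        with pytest.raises(AnnotatorConfigError, match="not found"):
            run_external_annotator(chunk, executable=tmp_path / "nope")

    def test_stub_output_parses_into_fixture_records(self, tmp_path):
        fixture = tmp_path / "fixture.tsv"
        fixture.write_text(self.FIXTURE_TSV)
        stub = self.make_stub(tmp_path, f'cp "{fixture}" "$2"\n')
        chunk = tmp_path / "chunk.fasta"
        chunk.write_text(">r\nACGT\n")
        out = run_external_annotator(chunk, executable=stub)
        from vdjflow.airr import parse_airr_tsv

        records = parse_airr_tsv(out)
        assert [r.sequence_id for r in records] == [f"read{i}" for i in range(5)]
        assert all(r.v_call == "IGHV1-1*01" for r in records)

    def test_nonzero_exit_names_chunk(self, tmp_path):
        stub = self.make_stub(tmp_path, "echo boom >&2\nexit 1\n")
        chunk = tmp_path / "chunk_000001.fasta"
        chunk.write_text(">r\nACGT\n")
        with pytest.raises(BackendError, match="chunk_000001"):
            run_external_annotator(chunk, executable=stub)
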