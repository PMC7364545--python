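"""Translation, AIRR TSV parsing, flag derivation and serialization."""

import gzip
import json
import random

import pytest

from vdjflow.airr import (
    AirrFormatError,
    Rearrangement,
    finalize,
    parse_airr_tsv,
    read_ndjson,
    serialize,
    translate,
)

# independent brute-force oracle: plain codon-table lookup, ambiguity -> X
_CODON_TABLE = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def oracle_translate(nt, frame=0):
    out = []
    seq = nt[frame:]
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt,expected",
        [
            ("ATG", "M"),
            ("TAA", "*"),
            ("TAG", "*"),
            ("TGA", "*"),
            ("ATGAA", "M"),  # trailing partial codon dropped
            ("", ""),
        ],
    )
    def test_known_codons(self, nt, expected):
        assert translate(nt) == expected

    def test_frame_offsets(self):
        assert translate("GATGC", 1) == "M"
        assert translate("CCATGA", 2) == "M"

    def test_unresolvable_ambiguity_is_x(self):
        assert translate("NNN") == "X"

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = random.Random(77)
        for _ in range(200):
            nt = "".join(rng.choice("ACGT") for _ in range(300))
            for frame in (0, 1, 2):
                assert translate(nt, frame) == oracle_translate(nt, frame)


class TestParseAirrTsv:
    def test_fixture_rows_parse(self, tmp_path):
        path = tmp_path / "five.tsv"
        rows = "".join(
            f"s{i}\tACGT\tIGHV{i}\tT\n" for i in range(5)
        )
        path.write_text("sequence_id\tsequence\tv_call\trev_comp\n" + rows)
        records = parse_airr_tsv(path)
        assert [r.v_call for r in records] == [f"IGHV{i}" for i in range(5)]
        assert all(r.rev_comp for r in records)

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "h.tsv"
        path.write_text("sequence_id\tsequence\n")
        assert parse_airr_tsv(path) == []

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("sequence\tv_call\nACGT\tIGHV1\n")
        with pytest.raises(AirrFormatError, match="sequence_id"):
            parse_airr_tsv(path)

    def test_ragged_row_reports_line_number(self, tmp_path):
        path = tmp_path / "r.tsv"
        path.write_text("sequence_id\tsequence\ns1\tACGT\ns2\n")
        with pytest.raises(AirrFormatError, match="line 3"):
            parse_airr_tsv(path)

    def test_empty_junction_cell_is_absent(self, tmp_path):
        path = tmp_path / "j.tsv"
        path.write_text("sequence_id\tsequence\tjunction\ns1\tACGT\t\n")
        (rec,) = parse_airr_tsv(path)
        assert rec.junction is None

    def test_unknown_columns_preserved_in_extras(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text(
            "sequence_id\tsequence\tcustom_tag\ns1\tACGT\thello\n"
        )
        (rec,) = parse_airr_tsv(path)
        assert rec.extras["custom_tag"] == "hello"

    def test_secondary_rows_fold_into_hit_lists(self, tmp_path):
        path = tmp_path / "fold.tsv"
        path.write_text(
            "sequence_id\tsequence\tv_call\tv_support\n"
            "s1\tACGT\tIGHV1-1*01\t1e-30\n"
            "s1\tACGT\tIGHV2-5*01\t1e-20\n"
            "s1\tACGT\tIGHV3-7*01\t1e-10\n"
            "s2\tACGT\tIGHV1-1*01\t1e-5\n"
        )
        records = parse_airr_tsv(path)
        assert len(records) == 2
        first = records[0]
        assert [h.gene_call for h in first.v_hits] == [
            "IGHV1-1*01",
            "IGHV2-5*01",
            "IGHV3-7*01",
        ]
        assert [h.rank for h in first.v_hits] == [1, 2, 3]
        assert first.v_call == "IGHV1-1*01"


class TestFinalize:
    def make(self, **kw):
        return Rearrangement(sequence_id="s", sequence="ACGT", **kw)

    def test_junction_length_divisible_by_three_in_frame(self):
        rec = finalize(self.make(junction="A" * 45))
        assert rec.vj_in_frame is True

    def test_junction_length_not_divisible_out_of_frame(self):
        rec = finalize(self.make(junction="A" * 44))
        assert rec.vj_in_frame is False

    def test_backend_supplied_flag_wins(self):
        rec = finalize(self.make(junction="A" * 45, vj_in_frame=False))
        assert rec.vj_in_frame is False

    def test_stop_codon_derived_from_v_frame_translation(self, toy_db):
        # clean synthetic read, then an in-frame TAA inside the V region
        from vdjflow.engine import _annotate_record
        from vdjflow.annotate import ScoringParams
        from vdjflow.fastx_io import SeqRecord

        v, j = toy_db.v_genes[0], toy_db.j_genes[0]
        clean = v.sequence + "GATAGTAGT" + j.sequence
        broken = clean[:90] + "TAA" + clean[93:]
        rec_clean = _annotate_record(
            SeqRecord(id="c", sequence=clean), toy_db, ScoringParams()
        )
        rec_broken = _annotate_record(
            SeqRecord(id="b", sequence=broken), toy_db, ScoringParams()
        )
        assert rec_clean.stop_codon is False and rec_clean.productive is True
        assert rec_broken.stop_codon is True and rec_broken.productive is False
        # cross-check against the translation oracle
        assert "*" in oracle_translate(broken)
        assert "*" not in oracle_translate(clean)

    def test_productive_conjunction_invariant(self, mutated_run):
        _fq, _truth, _out, _stats, records = mutated_run
        for rec in records:
            if None not in (rec.productive, rec.vj_in_frame, rec.stop_codon):
                assert rec.productive == (rec.vj_in_frame and not rec.stop_codon)


class TestSerialize:
    def make_records(self, n=3):
        recs = []
        for i in range(n):
            recs.append(
                finalize(
                    Rearrangement(
                        sequence_id=f"s{i}",
                        sequence="TGTGCGAGATGG" * 4,
                        v_call="IGHV1-1*01",
                        j_call="IGHJ4*01",
                        v_support=1.5e-20,
                        j_support=2.5e-9,
                        junction="TGTGCGAGATGG",
                        junction_aa="CARW",
                        cdr3="GCGAGA",
                        cdr3_aa="AR",
                        cdr3_start=4,
                        cdr3_end=9,
                    )
                )
            )
        return recs

    def test_ndjson_line_count(self, tmp_path):
        out = serialize(self.make_records(3), tmp_path / "o.json.gz")
        with gzip.open(out, "rt") as fh:
            lines = [json.loads(line) for line in fh]
        assert len(lines) == 3
        assert lines[0]["sequence_id"] == "s0"

    def test_tsv_round_trip_rank1_fields(self, tmp_path):
        records = self.make_records(3)
        out = serialize(records, tmp_path / "o.tsv", format="tsv")
        back = parse_airr_tsv(out)
        for orig, parsed in zip(records, back):
            for field in (
                "sequence_id",
                "sequence",
                "v_call",
                "j_call",
                "v_support",
                "j_support",
                "junction",
                "cdr3",
                "cdr3_start",
                "cdr3_end",
                "vj_in_frame",
                "stop_codon",
                "productive",
            ):
                assert getattr(parsed, field) == getattr(orig, field), field

    def test_best_only_drops_hit_lists_keeps_rank1(self, tmp_path, mutated_run):
        _fq, _truth, _out, _stats, records = mutated_run
        sample = records[:20]
        full = read_ndjson(serialize(sample, tmp_path / "full.json.gz", best_only=False))
        best = read_ndjson(serialize(sample, tmp_path / "best.json.gz", best_only=True))
        for f_doc, b_doc in zip(full, best):
            assert "v_hits" in f_doc and "v_hits" not in b_doc
            for key in b_doc:
                assert f_doc[key] == b_doc[key]

    def test_cdr3_coordinate_invariant_on_pipeline_output(self, mutated_run):
        _fq, _truth, _out, _stats, records = mutated_run
        seen = 0
        for rec in records:
            if rec.cdr3 and rec.cdr3_start is not None:
                assert rec.cdr3_end - rec.cdr3_start + 1 == len(rec.cdr3)
                assert len(rec.junction) == len(rec.cdr3) + 6
                # wire coordinates point at the CDR3 on the annotation strand
                seq = rec.annotated_sequence
                assert seq[rec.cdr3_start - 1 : rec.cdr3_end] == rec.cdr3
                seen += 1
        assert seen > 0
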