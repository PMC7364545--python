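"""AIRR-compliant rearrangement records, translation, parsing and output.

Field names and semantics follow the AIRR Rearrangement schema: booleans
serialized as T/F, ``*_start``/``*_end`` coordinates 1-based inclusive on
the wire while internal intervals are 0-based half-open, ``sequence`` in
input orientation with ``rev_comp`` flagging reads annotated on the minus
strand.

"Zipped JSON" output is gzip-compressed newline-delimited JSON — one
object per line — rather than a single JSON array: it streams, and each
line inserts directly into a document database.
"""

from __future__ import annotations

import csv
import gzip
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, List, Optional, Tuple

from Bio.Seq import Seq

from .annotate import AlignmentHit, JunctionCall
from .fastx_io import encode_phred

__all__ = [
    "Rearrangement",
    "AirrFormatError",
    "translate",
    "parse_airr_tsv",
    "finalize",
    "serialize",
    "read_ndjson",
]


class AirrFormatError(ValueError):
    """Malformed AIRR TSV input."""


def translate(nt: str, frame_offset: int = 0) -> str:
    """Translate DNA with the standard genetic code.

    Stops appear as ``*``; codons with ambiguity codes that do not resolve
    to a unique amino acid appear as ``X``; a trailing partial codon is
    dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    trimmed = nt[frame_offset:]
    trimmed = trimmed[: len(trimmed) - len(trimmed) % 3]
    if not trimmed:
        return ""
    return str(Seq(trimmed).translate())


@dataclass
class Rearrangement:
    """One annotated read in AIRR terms, plus the top-3 hit lists."""

    sequence_id: str
    sequence: str  # input orientation
    rev_comp: bool = False
    v_call: Optional[str] = None
    d_call: Optional[str] = None
    j_call: Optional[str] = None
    v_support: Optional[float] = None
    j_support: Optional[float] = None
    v_hits: List[AlignmentHit] = field(default_factory=list)
    d_hits: List[AlignmentHit] = field(default_factory=list)
    j_hits: List[AlignmentHit] = field(default_factory=list)
    junction: Optional[str] = None
    junction_aa: Optional[str] = None
    cdr3: Optional[str] = None
    cdr3_aa: Optional[str] = None
    cdr3_start: Optional[int] = None  # 1-based inclusive, annotation orientation
    cdr3_end: Optional[int] = None
    vj_in_frame: Optional[bool] = None
    stop_codon: Optional[bool] = None
    productive: Optional[bool] = None
    sequence_alignment_aa: Optional[str] = None
    qualities: Optional[List[int]] = None  # input orientation, FASTQ only
    extras: Dict[str, str] = field(default_factory=dict)

    @property
    def annotated_sequence(self) -> str:
        """The sequence in annotation orientation."""
        if self.rev_comp:
            from Bio.Seq import reverse_complement

            return reverse_complement(self.sequence)
        return self.sequence

    def cdr3_qualities(self) -> Optional[List[int]]:
        """Phred scores over the CDR3, or None when inapplicable."""
        if self.qualities is None or self.cdr3_start is None or self.cdr3_end is None:
            return None
        quals = list(reversed(self.qualities)) if self.rev_comp else self.qualities
        return quals[self.cdr3_start - 1 : self.cdr3_end]

    def attach_junction(self, call: Optional[JunctionCall]) -> None:
        if call is None:
            return
        self.junction = call.junction
        self.junction_aa = call.junction_aa
        if call.cdr3:
            self.cdr3 = call.cdr3
            self.cdr3_aa = call.cdr3_aa
            start, end = call.cdr3_interval
            self.cdr3_start = start + 1
            self.cdr3_end = end


def finalize(record: Rearrangement) -> Rearrangement:
    """Fill frame/stop/productive flags the backend did not supply.

    Backend-supplied values always win; derivation only fills gaps.
    ``vj_in_frame`` falls back to junction length divisible by three.
    ``stop_codon`` is scanned over the aligned V-through-J region in the
    V-gene reading frame — untranslated primer tails outside the alignment
    should not fail a record.
    """
    if record.v_hits and record.v_call is None:
        record.v_call = record.v_hits[0].gene_call
    if record.d_hits and record.d_call is None:
        record.d_call = record.d_hits[0].gene_call
    if record.j_hits and record.j_call is None:
        record.j_call = record.j_hits[0].gene_call
    if record.v_support is None and record.v_hits:
        record.v_support = record.v_hits[0].e_value
    if record.j_support is None and record.j_hits:
        record.j_support = record.j_hits[0].e_value

    if record.vj_in_frame is None:
        record.vj_in_frame = (
            record.junction is not None and len(record.junction) % 3 == 0
        )
    if record.stop_codon is None and record.v_hits and record.j_hits:
        v_hit = record.v_hits[0]
        j_hit = record.j_hits[0]
        seq = record.annotated_sequence
        region = seq[v_hit.query_start : j_hit.query_end]
        # codon phase of the V germline at the alignment start sets the frame
        frame = (3 - v_hit.germline_start % 3) % 3
        aa = translate(region, frame)
        record.stop_codon = "*" in aa
        if record.sequence_alignment_aa is None:
            record.sequence_alignment_aa = aa
    if (
        record.productive is None
        and record.vj_in_frame is not None
        and record.stop_codon is not None
    ):
        record.productive = record.vj_in_frame and not record.stop_codon
    return record


# ---------------------------------------------------------------------------
# AIRR TSV parsing

MANDATORY_COLUMNS = ("sequence_id", "sequence")

_BOOL_COLUMNS = {"rev_comp", "productive", "vj_in_frame", "stop_codon", "complete_vdj"}
_FLOAT_COLUMNS = {"v_support", "d_support", "j_support", "v_score", "d_score", "j_score"}
_INT_COLUMNS = {"cdr3_start", "cdr3_end"}
_KNOWN_COLUMNS = {
    "sequence_id",
    "sequence",
    "rev_comp",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "v_support",
    "j_support",
    "vj_in_frame",
    "stop_codon",
    "junction",
    "junction_aa",
    "cdr3",
    "cdr3_aa",
    "cdr3_start",
    "cdr3_end",
    "sequence_alignment_aa",
}


def _parse_bool(text: str) -> Optional[bool]:
    t = text.strip().lower()
    if t in ("t", "true"):
        return True
    if t in ("f", "false"):
        return False
    raise AirrFormatError(f"cannot parse boolean value {text!r}")


def _hit_from_row(row: Dict[str, str], segment: str, rank: int) -> Optional[AlignmentHit]:
    prefix = segment.lower()
    call = row.get(f"{prefix}_call", "").strip()
    if not call:
        return None
    support = row.get(f"{prefix}_support", "").strip()
    score = row.get(f"{prefix}_score", "").strip()

    def coord(name: str, default: int) -> int:
        raw = row.get(name, "").strip()
        return int(raw) if raw else default

    # AIRR wire coordinates are 1-based inclusive
    q_start = coord(f"{prefix}_sequence_start", 1) - 1
    q_end = coord(f"{prefix}_sequence_end", q_start + 1)
    g_start = coord(f"{prefix}_germline_start", 1) - 1
    g_end = coord(f"{prefix}_germline_end", g_start + 1)
    identity_raw = row.get(f"{prefix}_identity", "").strip()
    return AlignmentHit(
        gene_call=call,
        segment=segment,
        score=float(score) if score else 0.0,
        e_value=float(support) if support else math.inf,
        query_start=q_start,
        query_end=q_end,
        germline_start=g_start,
        germline_end=g_end,
        identity=float(identity_raw) / (100.0 if float(identity_raw or 0) > 1 else 1.0)
        if identity_raw
        else 0.0,
        rank=rank,
        cigar=row.get(f"{prefix}_cigar", ""),
    )


def parse_airr_tsv(path: os.PathLike) -> List[Rearrangement]:
    """Parse an AIRR Rearrangement TSV into records.

    Unknown columns are preserved verbatim in each record's ``extras``
    map.  Consecutive rows sharing a ``sequence_id`` (the one-row-per-hit
    dialect some backends emit for rank-2/3 alignments) are folded into a
    single record whose hit lists carry the extra rows.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: List[Rearrangement] = []
    with opener(path, "rt", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AirrFormatError(f"{path}: empty file, expected a header row")
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise AirrFormatError(f"{path}: missing mandatory column {col!r}")
        current: Optional[Rearrangement] = None
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise AirrFormatError(
                    f"{path}: line {line_no} has {len(row)} fields, header has "
                    f"{len(header)}"
                )
            cells = dict(zip(header, row))
            sid = cells["sequence_id"]
            if current is not None and current.sequence_id == sid:
                # secondary-hit row: append its calls to the hit lists
                for segment, hit_list in (
                    ("V", current.v_hits),
                    ("D", current.d_hits),
                    ("J", current.j_hits),
                ):
                    hit = _hit_from_row(cells, segment, rank=len(hit_list) + 1)
                    if hit is not None and len(hit_list) < 3:
                        hit_list.append(hit)
                continue
            rec = _record_from_cells(cells, path, line_no)
            records.append(rec)
            current = rec
    return records


def _record_from_cells(
    cells: Dict[str, str], path: Path, line_no: int
) -> Rearrangement:
    def get(name: str) -> Optional[str]:
        val = cells.get(name, "")
        return val if val != "" else None

    try:
        rec = Rearrangement(
            sequence_id=cells["sequence_id"],
            sequence=cells["sequence"].upper(),
            rev_comp=_parse_bool(cells["rev_comp"]) if get("rev_comp") else False,
            v_call=get("v_call"),
            d_call=get("d_call"),
            j_call=get("j_call"),
            v_support=float(cells["v_support"]) if get("v_support") else None,
            j_support=float(cells["j_support"]) if get("j_support") else None,
            junction=get("junction"),
            junction_aa=get("junction_aa"),
            cdr3=get("cdr3"),
            cdr3_aa=get("cdr3_aa"),
            cdr3_start=int(cells["cdr3_start"]) if get("cdr3_start") else None,
            cdr3_end=int(cells["cdr3_end"]) if get("cdr3_end") else None,
            vj_in_frame=_parse_bool(cells["vj_in_frame"]) if get("vj_in_frame") else None,
            stop_codon=_parse_bool(cells["stop_codon"]) if get("stop_codon") else None,
            productive=_parse_bool(cells["productive"]) if get("productive") else None,
            sequence_alignment_aa=get("sequence_alignment_aa"),
        )
    except (ValueError, KeyError) as exc:
        raise AirrFormatError(f"{path}: line {line_no}: {exc}") from exc
    for segment, hit_list in (("V", rec.v_hits), ("D", rec.d_hits), ("J", rec.j_hits)):
        hit = _hit_from_row(cells, segment, rank=1)
        if hit is not None:
            hit_list.append(hit)
    rec.extras = {k: v for k, v in cells.items() if k not in _KNOWN_COLUMNS and v != ""}
    return rec


# ---------------------------------------------------------------------------
# Serialization

TSV_COLUMNS = [
    "sequence_id",
    "sequence",
    "rev_comp",
    "productive",
    "v_call",
    "d_call",
    "j_call",
    "v_support",
    "j_support",
    "vj_in_frame",
    "stop_codon",
    "junction",
    "junction_aa",
    "cdr3",
    "cdr3_aa",
    "cdr3_start",
    "cdr3_end",
    "sequence_alignment_aa",
]


def _fmt_bool(val: Optional[bool]) -> str:
    if val is None:
        return ""
    return "T" if val else "F"


def _fmt(val: Any) -> str:
    if val is None:
        return ""
    if isinstance(val, bool):
        return _fmt_bool(val)
    if isinstance(val, float):
        return repr(val)
    return str(val)


def _hit_dict(hit: AlignmentHit) -> Dict[str, Any]:
    return {
        "gene_call": hit.gene_call,
        "segment": hit.segment,
        "rank": hit.rank,
        "score": hit.score,
        "e_value": hit.e_value,
        "sequence_start": hit.query_start + 1,
        "sequence_end": hit.query_end,
        "germline_start": hit.germline_start + 1,
        "germline_end": hit.germline_end,
        "identity": hit.identity,
        "cigar": hit.cigar,
        "sequence_alignment": hit.sequence_alignment,
        "germline_alignment": hit.germline_alignment,
    }


def record_to_dict(record: Rearrangement, best_only: bool = False) -> Dict[str, Any]:
    """JSON-ready mapping of one record (AIRR field names, wire coordinates)."""
    doc: Dict[str, Any] = {
        "sequence_id": record.sequence_id,
        "sequence": record.sequence,
        "rev_comp": record.rev_comp,
        "productive": record.productive,
        "v_call": record.v_call,
        "d_call": record.d_call,
        "j_call": record.j_call,
        "v_support": record.v_support,
        "j_support": record.j_support,
        "vj_in_frame": record.vj_in_frame,
        "stop_codon": record.stop_codon,
        "junction": record.junction,
        "junction_aa": record.junction_aa,
        "cdr3": record.cdr3,
        "cdr3_aa": record.cdr3_aa,
        "cdr3_start": record.cdr3_start,
        "cdr3_end": record.cdr3_end,
        "sequence_alignment_aa": record.sequence_alignment_aa,
    }
    if record.qualities is not None:
        doc["quality"] = encode_phred(record.qualities)
    if not best_only:
        doc["v_hits"] = [_hit_dict(h) for h in record.v_hits]
        doc["d_hits"] = [_hit_dict(h) for h in record.d_hits]
        doc["j_hits"] = [_hit_dict(h) for h in record.j_hits]
    if record.extras:
        doc.update(record.extras)
    return doc


def serialize(
    records: Iterable[Rearrangement],
    out_path: os.PathLike,
    format: str = "ndjson_gz",
    best_only: bool = False,
) -> Path:
    """Write records as gzip NDJSON (one JSON object per line) or AIRR TSV.

    The TSV carries rank-1 values only; NDJSON additionally carries the
    top-3 hit lists unless ``best_only`` is set.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if format == "ndjson_gz":
        # fixed mtime in the gzip header keeps byte-identical reruns
        with open(out_path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                for rec in records:
                    line = json.dumps(record_to_dict(rec, best_only=best_only))
                    gz.write(line.encode("utf-8") + b"\n")
    elif format == "tsv":
        with open(out_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(TSV_COLUMNS)
            for rec in records:
                writer.writerow([_fmt(getattr(rec, col)) for col in TSV_COLUMNS])
    else:
        raise ValueError(f"unknown output format {format!r}")
    return out_path


def read_ndjson(path: os.PathLike) -> List[Dict[str, Any]]:
    """Read a (possibly gzipped) NDJSON output file back into dicts."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    docs = []
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(json.loads(line))
    return docs
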