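"""Streaming FASTA/FASTQ I/O, size-based sequence-count estimation and chunking.

The pipeline never holds a whole input file in memory: reads are streamed,
split into bounded temporary chunk files, and each chunk is processed
independently.  FASTQ qualities are Sanger/Illumina-1.8 Phred+33; other
offsets are rejected rather than guessed.
"""

from __future__ import annotations

import gzip
import io
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional, Sequence

__all__ = [
    "SeqRecord",
    "ChunkPlan",
    "FastxParseError",
    "PhredEncodingError",
    "read_fastx",
    "write_fastx",
    "decode_phred",
    "encode_phred",
    "estimate_sequence_count",
    "plan_chunks",
    "write_chunks",
    "sniff_format",
]

PHRED_OFFSET = 33
PHRED_MAX = 93

#: how many leading records the count estimator averages over
ESTIMATOR_SAMPLE = 500
#: default chunks handed to each worker, for load balancing
CHUNKS_PER_WORKER = 4
#: hard cap on records per chunk, bounding temp-file size
MAX_CHUNK_RECORDS = 50_000

GZIP_MAGIC = b"\x1f\x8b"


class FastxParseError(ValueError):
    """Malformed FASTA/FASTQ input; carries the 0-based record index."""

    def __init__(self, message: str, record_index: Optional[int] = None):
        if record_index is not None:
            message = f"record {record_index}: {message}"
        super().__init__(message)
        self.record_index = record_index


class PhredEncodingError(ValueError):
    """Quality character below the expected offset (wrong encoding?)."""


@dataclass
class SeqRecord:
    """One sequencing read.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` the remainder (possibly empty).  ``qualities`` is a
    list of integer Phred scores for FASTQ input and ``None`` for FASTA.
    """

    id: str
    sequence: str
    description: str = ""
    qualities: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastxParseError(f"empty sequence for record {self.id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FastxParseError(
                f"quality length {len(self.qualities)} != sequence length "
                f"{len(self.sequence)} for record {self.id!r}"
            )

    @property
    def header(self) -> str:
        return f"{self.id} {self.description}".rstrip()


@dataclass
class ChunkPlan:
    """Where the input was split and how many records each piece holds."""

    estimated_total: int
    records_per_chunk: int
    format: str  # "fasta" | "fastq"
    chunk_paths: List[Path] = field(default_factory=list)
    chunk_counts: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.records_per_chunk < 1:
            raise ValueError("records_per_chunk must be >= 1")


def decode_phred(quality_text: str, offset: int = PHRED_OFFSET) -> List[int]:
    """Decode an ASCII quality string to integer Phred scores (code - offset)."""
    scores = []
    for i, ch in enumerate(quality_text):
        q = ord(ch) - offset
        if q < 0:
            raise PhredEncodingError(
                f"quality character {ch!r} at position {i} is below offset "
                f"{offset}; input may use a different Phred encoding"
            )
        scores.append(q)
    return scores


def encode_phred(scores: Sequence[int], offset: int = PHRED_OFFSET) -> str:
    return "".join(chr(q + offset) for q in scores)


def _is_gzip(path: os.PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def _open_text(path: os.PathLike) -> IO[str]:
    """Open plain or gzip text transparently (magic-byte detection)."""
    if _is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii")


def sniff_format(path: os.PathLike) -> str:
    """Return ``"fasta"`` or ``"fastq"`` from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped[0] == ">":
                return "fasta"
            if stripped[0] == "@":
                return "fastq"
            raise FastxParseError(
                f"cannot determine format: first non-blank character is "
                f"{stripped[0]!r}, expected '>' or '@'"
            )
    # empty file: caller treats as an empty stream; default to fasta
    return "fasta"


def _parse_fasta(fh: IO[str]) -> Iterator[SeqRecord]:
    header: Optional[str] = None
    seq_parts: List[str] = []
    index = 0
    for line in fh:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield _make_record(header, "".join(seq_parts), None, index)
                index += 1
            header = line[1:]
            seq_parts = []
        else:
            if header is None:
                raise FastxParseError("sequence data before first '>' header", 0)
            seq_parts.append(line.strip())
    if header is not None:
        yield _make_record(header, "".join(seq_parts), None, index)


def _parse_fastq(fh: IO[str]) -> Iterator[SeqRecord]:
    index = 0
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.strip():
            continue
        if not header.startswith("@"):
            raise FastxParseError(
                f"expected '@' header, got {header[:30]!r}", index
            )
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline().rstrip("\n")
        if not plus:
            raise FastxParseError("truncated record (missing '+' line)", index)
        if not plus.startswith("+"):
            raise FastxParseError(
                f"expected '+' separator, got {plus[:30]!r}", index
            )
        if len(seq) != len(qual):
            raise FastxParseError(
                f"sequence length {len(seq)} != quality length {len(qual)}",
                index,
            )
        yield _make_record(header[1:], seq, qual, index)
        index += 1


def _make_record(
    header: str, seq: str, qual: Optional[str], index: int
) -> SeqRecord:
    if not header.strip():
        raise FastxParseError("missing header", index)
    if not seq:
        raise FastxParseError("empty sequence", index)
    parts = header.split(None, 1)
    rid = parts[0]
    desc = parts[1] if len(parts) > 1 else ""
    try:
        qualities = decode_phred(qual) if qual is not None else None
    except PhredEncodingError as exc:
        raise FastxParseError(str(exc), index) from exc
    return SeqRecord(
        id=rid, sequence=seq.upper(), description=desc, qualities=qualities
    )


def read_fastx(path: os.PathLike, format: str = "auto") -> Iterator[SeqRecord]:
    """Stream records from a FASTA/FASTQ file, plain or gzip-compressed.

    An empty file yields an empty stream, not an error.
    """
    if format == "auto":
        format = sniff_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    fh = _open_text(path)
    try:
        parser = _parse_fasta(fh) if format == "fasta" else _parse_fastq(fh)
        yield from parser
    finally:
        fh.close()


def format_record(record: SeqRecord, format: str) -> str:
    """Serialize one record; FASTA sequence always on a single line."""
    if format == "fasta":
        return f">{record.header}\n{record.sequence}\n"
    quals = record.qualities
    if quals is None:
        # FASTQ output of a quality-less record: maximal confidence placeholder
        qual_text = "I" * len(record.sequence)
    else:
        qual_text = encode_phred(quals)
    return f"@{record.header}\n{record.sequence}\n+\n{qual_text}\n"


def write_fastx(
    records: Iterable[SeqRecord], path: os.PathLike, format: str
) -> int:
    """Write records to ``path`` (gzip if the name ends in .gz); return count."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt", encoding="ascii") as fh:
        for rec in records:
            fh.write(format_record(rec, format))
            n += 1
    return n


class _CountingTextReader:
    """Wrap a text stream, tracking decoded bytes consumed per line."""

    def __init__(self, fh: IO[str]):
        self._fh = fh
        self.bytes_read = 0

    def readline(self) -> str:
        line = self._fh.readline()
        self.bytes_read += len(line)
        return line

    def __iter__(self) -> Iterator[str]:
        for line in self._fh:
            self.bytes_read += len(line)
            yield line


def estimate_sequence_count(path: os.PathLike) -> int:
    """Estimate the number of records from file size.

    Parses up to the first ``ESTIMATOR_SAMPLE`` records, takes the mean
    decompressed bytes per record, and divides the (decompressed) file size
    by it.  Files with at most ``ESTIMATOR_SAMPLE`` records are counted
    exactly.  For gzip inputs the total decompressed size is extrapolated
    from the sampled prefix's compression ratio.
    """
    path = Path(path)
    file_size = path.stat().st_size
    if file_size == 0:
        return 0
    gz = _is_gzip(path)

    raw = open(path, "rb")
    try:
        if gz:
            stream: IO[str] = io.TextIOWrapper(
                gzip.GzipFile(fileobj=raw), encoding="ascii"
            )
        else:
            stream = io.TextIOWrapper(raw, encoding="ascii")
        counting = _CountingTextReader(stream)
        fmt = None
        # sniff from the stream itself to avoid a second pass
        first = counting.readline()
        while first and not first.strip():
            first = counting.readline()
        if not first:
            return 0
        ch = first.strip()[0]
        if ch == ">":
            fmt = "fasta"
        elif ch == "@":
            fmt = "fastq"
        else:
            raise FastxParseError(
                f"cannot determine format from leading character {ch!r}"
            )

        n_sampled = 0
        if fmt == "fastq":
            while True:
                for _ in range(3):
                    if not counting.readline():
                        raise FastxParseError(
                            "truncated record while sampling", n_sampled
                        )
                n_sampled += 1
                if n_sampled >= ESTIMATOR_SAMPLE:
                    break
                nxt = counting.readline()
                if not nxt:
                    return n_sampled
        else:
            # FASTA: count headers; the record consuming the last sampled
            # header ends when the next '>' (or EOF) is seen.
            n_sampled = 1
            while True:
                pos_before = counting.bytes_read
                line = counting.readline()
                if not line:
                    return n_sampled
                if line.startswith(">"):
                    if n_sampled >= ESTIMATOR_SAMPLE:
                        # bytes of the sample exclude this next header
                        counting.bytes_read = pos_before
                        break
                    n_sampled += 1

        sampled_decompressed = counting.bytes_read
        mean_record = sampled_decompressed / n_sampled
        if gz:
            # one streaming decompression pass (no parsing) measures the
            # true decompressed size; the compressed size is a poor proxy
            total_decompressed = float(sampled_decompressed)
            while True:
                block = stream.read(1 << 20)
                if not block:
                    break
                total_decompressed += len(block)
        else:
            total_decompressed = float(file_size)
        return max(n_sampled, round(total_decompressed / mean_record))
    finally:
        raw.close()


def plan_chunks(
    estimated_total: int,
    n_workers: int,
    user_chunk_size: Optional[int] = None,
    *,
    format: str = "fasta",
    chunks_per_worker: int = CHUNKS_PER_WORKER,
    max_chunk_records: int = MAX_CHUNK_RECORDS,
) -> ChunkPlan:
    """Pick a chunk size balancing load across workers.

    Each worker gets about ``chunks_per_worker`` chunks so that stragglers
    even out; a hard cap bounds temp-file size.  A user-supplied chunk size
    wins unconditionally.
    """
    if estimated_total < 0:
        raise ValueError("estimated_total must be >= 0")
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if user_chunk_size is not None:
        if user_chunk_size <= 0:
            raise ValueError("chunk size must be a positive integer")
        rpc = user_chunk_size
    else:
        rpc = min(
            max_chunk_records,
            max(1, math.ceil(estimated_total / (chunks_per_worker * n_workers))),
        )
    return ChunkPlan(
        estimated_total=estimated_total, records_per_chunk=rpc, format=format
    )


def write_chunks(
    records: Iterable[SeqRecord], plan: ChunkPlan, tmpdir: os.PathLike
) -> ChunkPlan:
    """Split ``records`` into chunk files of ``plan.records_per_chunk`` each.

    Chunks preserve input order; concatenating them reproduces the input
    record stream exactly.  On failure the partial chunk files are removed.
    """
    tmpdir = Path(tmpdir)
    tmpdir.mkdir(parents=True, exist_ok=True)
    ext = ".fasta" if plan.format == "fasta" else ".fastq"
    plan.chunk_paths = []
    plan.chunk_counts = []
    fh: Optional[IO[str]] = None
    count_in_chunk = 0
    try:
        for rec in records:
            if fh is None or count_in_chunk >= plan.records_per_chunk:
                if fh is not None:
                    fh.close()
                    plan.chunk_counts.append(count_in_chunk)
                chunk_path = tmpdir / f"chunk_{len(plan.chunk_paths):06d}{ext}"
                fh = open(chunk_path, "w", encoding="ascii")
                plan.chunk_paths.append(chunk_path)
                count_in_chunk = 0
            fh.write(format_record(rec, plan.format))
            count_in_chunk += 1
        if fh is not None:
            fh.close()
            plan.chunk_counts.append(count_in_chunk)
    except BaseException:
        if fh is not None:
            fh.close()
        for p in plan.chunk_paths:
            try:
                p.unlink()
            except OSError:
                pass
        raise
    return plan
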