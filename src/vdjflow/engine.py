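"""Pipeline orchestration: estimate, chunk, annotate in parallel, filter, merge.

The input is split into bounded chunk files; each chunk is processed
whole by one worker (annotate, parse, finalize, filter) and the finished
chunks are merged strictly in chunk-index order, so the output is a pure
function of the input and the configuration — the worker count and
chunking are unobservable in the result.  Workers are separate processes
with no shared mutable state: a chunk path goes in, picklable records
come out.
"""

from __future__ import annotations

import csv
import json
import logging
import os
import tempfile
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from .annotate import (
    AnnotatorConfigError,
    ScoringParams,
    annotate_builtin,
    extract_junction,
    run_external_annotator,
)
from .airr import Rearrangement, finalize, parse_airr_tsv, serialize
from .fastx_io import (
    SeqRecord,
    estimate_sequence_count,
    plan_chunks,
    read_fastx,
    sniff_format,
    write_chunks,
)
from .filters import FilterConfig, FilterOutcome, apply_filters
from .germline import GermlineDB, load_germline_fasta, toy_db_paths

__all__ = ["RunConfig", "RunStats", "run", "run_api"]

logger = logging.getLogger("vdjflow")


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    input_path: os.PathLike
    out_path: Optional[os.PathLike] = None
    backend: str = "builtin"  # "builtin" | "external"
    executable_path: Optional[os.PathLike] = None
    backend_options: Sequence[str] = ()
    germline_v: Optional[os.PathLike] = None
    germline_d: Optional[os.PathLike] = None
    germline_j: Optional[os.PathLike] = None
    anchors: Optional[os.PathLike] = None
    n_workers: int = 1
    user_chunk_size: Optional[int] = None
    out_format: str = "ndjson_gz"
    best_only: bool = False
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    tmpdir: Optional[os.PathLike] = None
    keep_tmp: bool = False
    seed: Optional[int] = None
    emit_removed: bool = False

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.backend not in ("builtin", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "external" and self.executable_path is None:
            raise AnnotatorConfigError(
                "external backend requires an executable path"
            )
        if self.germline_v is None:
            toy = toy_db_paths()
            self.germline_v = toy["v"]
            self.germline_d = toy["d"]
            self.germline_j = toy["j"]
            self.anchors = toy["anchors"]


@dataclass
class RunStats:
    estimated_input: int = 0
    actual_input: int = 0
    n_chunks: int = 0
    annotated: int = 0
    kept: int = 0
    removed_by_reason: Dict[str, int] = field(default_factory=dict)
    elapsed: float = 0.0

    def to_dict(self) -> Dict:
        return {
            "estimated_input": self.estimated_input,
            "actual_input": self.actual_input,
            "n_chunks": self.n_chunks,
            "annotated": self.annotated,
            "kept": self.kept,
            "removed": self.actual_input - self.kept,
            "removed_by_reason": dict(self.removed_by_reason),
            "elapsed_seconds": round(self.elapsed, 3),
        }


# --------------------------------------------------------------------------
# Worker side.  A worker processes whole chunks; the germline database is
# loaded once per process and cached.

_DB_CACHE: Dict[Tuple, GermlineDB] = {}


def _get_db(cfg: "_WorkerContext") -> GermlineDB:
    key = (str(cfg.germline_v), str(cfg.germline_d), str(cfg.germline_j), str(cfg.anchors))
    db = _DB_CACHE.get(key)
    if db is None:
        db = load_germline_fasta(
            v_path=cfg.germline_v,
            j_path=cfg.germline_j,
            d_path=cfg.germline_d,
            anchors=cfg.anchors,
            require_anchors=cfg.backend == "builtin",
        )
        _DB_CACHE[key] = db
    return db


@dataclass(frozen=True)
class _WorkerContext:
    backend: str
    germline_v: str
    germline_d: Optional[str]
    germline_j: str
    anchors: Optional[str]
    scoring: ScoringParams
    filter_config: FilterConfig
    executable: Optional[str]
    backend_options: Tuple[str, ...]
    format: str


def _annotate_record(rec: SeqRecord, db: GermlineDB, scoring: ScoringParams) -> Rearrangement:
    hits, rev_comp = annotate_builtin(rec, db, scoring)
    v_hits = [h for h in hits if h.segment == "V"]
    d_hits = [h for h in hits if h.segment == "D"]
    j_hits = [h for h in hits if h.segment == "J"]
    record = Rearrangement(
        sequence_id=rec.id,
        sequence=rec.sequence,
        rev_comp=rev_comp,
        v_hits=v_hits,
        d_hits=d_hits,
        j_hits=j_hits,
        qualities=rec.qualities,
    )
    if v_hits and j_hits:
        call = extract_junction(record.annotated_sequence, v_hits[0], j_hits[0], db)
        record.attach_junction(call)
    return finalize(record)


def _process_chunk(
    index: int, chunk_path: str, ctx: _WorkerContext
) -> Tuple[int, List[Rearrangement], List[Tuple[Rearrangement, FilterOutcome]], int]:
    """Annotate, finalize and filter one chunk; fully self-contained."""
    db = _get_db(ctx)
    if ctx.backend == "builtin":
        records = [
            _annotate_record(rec, db, ctx.scoring)
            for rec in read_fastx(chunk_path, ctx.format)
        ]
    else:
        tsv_path = run_external_annotator(
            chunk_path,
            executable=ctx.executable,
            extra_options=ctx.backend_options,
        )
        records = [finalize(r) for r in parse_airr_tsv(tsv_path)]
        # reattach FASTQ qualities: the backend TSV does not carry them
        quals = {
            rec.id: rec.qualities for rec in read_fastx(chunk_path, ctx.format)
        }
        for r in records:
            r.qualities = quals.get(r.sequence_id)
        try:
            Path(tsv_path).unlink()
        except OSError:
            pass
    kept, outcomes, _counts = apply_filters(records, ctx.filter_config)
    removed = [
        (rec, out) for rec, out in zip(records, outcomes) if not out.passed
    ]
    return index, kept, removed, len(records)


# --------------------------------------------------------------------------
# Driver side.


def _iter_chunk_results(
    chunk_paths: List[Path], ctx: _WorkerContext, n_workers: int
) -> Iterator[Tuple[int, List[Rearrangement], List[Tuple[Rearrangement, FilterOutcome]], int]]:
    """Yield chunk results strictly in chunk-index order.

    With one worker, chunks run inline; otherwise they are dispatched to a
    process pool and buffered until their turn comes.
    """
    if n_workers == 1 or len(chunk_paths) <= 1:
        for i, path in enumerate(chunk_paths):
            yield _process_chunk(i, str(path), ctx)
        return
    with ProcessPoolExecutor(max_workers=n_workers) as pool:
        futures = [
            pool.submit(_process_chunk, i, str(path), ctx)
            for i, path in enumerate(chunk_paths)
        ]
        # completion order is arbitrary; buffer and release in index order
        pending: Dict[int, Tuple] = {}
        next_index = 0
        for fut in futures:
            result = fut.result()
            pending[result[0]] = result
            while next_index in pending:
                yield pending.pop(next_index)
                next_index += 1


def run(config: RunConfig, collect: bool = False) -> Tuple[Optional[Path], RunStats, Optional[List[Rearrangement]]]:
    """Execute the pipeline; returns (output path, stats, records-if-collected)."""
    started = time.monotonic()
    input_path = Path(config.input_path)
    if not input_path.exists():
        raise FileNotFoundError(f"input file not found: {input_path}")
    if config.backend == "external":
        # fail before any chunk is written
        from shutil import which

        exe = Path(config.executable_path)
        if which(str(exe)) is None and not (exe.exists() and os.access(exe, os.X_OK)):
            raise AnnotatorConfigError(
                f"external annotator executable not found or not runnable: {exe}"
            )

    fmt = sniff_format(input_path)
    estimated = estimate_sequence_count(input_path)
    plan = plan_chunks(
        estimated, config.n_workers, config.user_chunk_size, format=fmt
    )
    logger.info(
        "estimated %d records; %d records per chunk", estimated, plan.records_per_chunk
    )

    base_tmp = Path(config.tmpdir) if config.tmpdir else Path(tempfile.gettempdir())
    base_tmp.mkdir(parents=True, exist_ok=True)
    work_dir = Path(tempfile.mkdtemp(prefix="vdjflow_", dir=base_tmp))

    ctx = _WorkerContext(
        backend=config.backend,
        germline_v=str(config.germline_v),
        germline_d=str(config.germline_d) if config.germline_d else None,
        germline_j=str(config.germline_j),
        anchors=str(config.anchors) if config.anchors else None,
        scoring=config.scoring,
        filter_config=config.filter_config,
        executable=str(config.executable_path) if config.executable_path else None,
        backend_options=tuple(config.backend_options),
        format=fmt,
    )

    stats = RunStats(estimated_input=estimated)
    out_path = Path(config.out_path) if config.out_path else None
    removed_path = (
        Path(str(out_path) + ".removed.tsv") if out_path and config.emit_removed else None
    )
    collected: Optional[List[Rearrangement]] = [] if collect else None
    stats.removed_by_reason = {}

    try:
        plan = write_chunks(read_fastx(input_path, fmt), plan, work_dir)
        stats.n_chunks = len(plan.chunk_paths)

        removed_fh = None
        removed_writer = None
        if removed_path is not None:
            removed_fh = open(removed_path, "w", newline="")
            removed_writer = csv.writer(removed_fh, delimiter="\t", lineterminator="\n")
            removed_writer.writerow(
                ["sequence_id", "failed_reasons", "v_call", "j_call"]
            )

        def merged() -> Iterator[Rearrangement]:
            for _idx, kept, removed, n_records in _iter_chunk_results(
                plan.chunk_paths, ctx, config.n_workers
            ):
                stats.actual_input += n_records
                stats.kept += len(kept)
                for rec, outcome in removed:
                    for reason in outcome.failed_reasons:
                        stats.removed_by_reason[reason] = (
                            stats.removed_by_reason.get(reason, 0) + 1
                        )
                    if removed_writer is not None:
                        removed_writer.writerow(
                            [
                                rec.sequence_id,
                                ",".join(sorted(outcome.failed_reasons)),
                                rec.v_call or "",
                                rec.j_call or "",
                            ]
                        )
                for rec in kept:
                    stats.annotated += 1 if (rec.v_call or rec.j_call) else 0
                    if collected is not None:
                        collected.append(rec)
                    yield rec
                for rec, _out in removed:
                    stats.annotated += 1 if (rec.v_call or rec.j_call) else 0

        try:
            if out_path is not None:
                serialize(
                    merged(), out_path, format=config.out_format, best_only=config.best_only
                )
            else:
                for _ in merged():
                    pass
        except BaseException:
            if out_path is not None and out_path.exists():
                out_path.unlink()
            raise
        finally:
            if removed_fh is not None:
                removed_fh.close()
    finally:
        if not config.keep_tmp:
            for p in sorted(work_dir.glob("*")):
                try:
                    p.unlink()
                except OSError:
                    pass
            try:
                work_dir.rmdir()
            except OSError:
                pass

    stats.elapsed = time.monotonic() - started
    if out_path is not None:
        summary_path = Path(str(out_path) + ".stats.json")
        with open(summary_path, "w") as fh:
            json.dump(stats.to_dict(), fh, indent=2)
            fh.write("\n")
        logger.info(
            "kept %d / %d records (%d chunks, %.1fs)",
            stats.kept,
            stats.actual_input,
            stats.n_chunks,
            stats.elapsed,
        )
    return out_path, stats, collected


def run_api(
    query: os.PathLike, **options
) -> Tuple[List[Rearrangement], RunStats]:
    """Single-call programmatic entry point.

    Identical computation to :func:`run`, but the annotated, filtered
    records come back as in-memory objects; files are written only when
    ``out_path`` is supplied.

    >>> records, stats = run_api("reads.fastq")        # doctest: +SKIP
    >>> stats.kept == len(records)                     # doctest: +SKIP
    True
    """
    config = RunConfig(input_path=query, **options)
    _out, stats, records = run(config, collect=True)
    return records or [], stats
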