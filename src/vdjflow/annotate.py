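"""Gene-segment assignment and junction extraction.

Two backends produce per-read annotations:

* an external IgBLAST-compatible executable, invoked once per chunk file
  (never per read) and expected to write an AIRR Rearrangement TSV;
* a built-in aligner that assigns V/(D)/J segments by local alignment
  (Smith–Waterman recurrence with affine gaps) of each read — and its
  reverse complement — against the germline database.  The built-in
  backend is a deliberately simple test/fallback annotator, not a
  reimplementation of IgBLAST's statistics.

The built-in backend proceeds in annotation order: the read orientation is
the strand with the best V-gene score; the top three V hits are kept; J
genes are aligned to the region right of the best V hit's query end; D
genes (when the locus has any) to the region between the best V end and
best J start.  Raw scores are converted to BLAST-style expectation values
through the Karlin–Altschul form E = K·m·n·exp(−λ·S) with fixed constants,
so thresholding and ordering are exactly reproducible.
"""

from __future__ import annotations

import math
import os
import shutil
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Seq import reverse_complement

from .fastx_io import SeqRecord
from .germline import GermlineDB, GermlineGene

__all__ = [
    "ScoringParams",
    "AlignmentHit",
    "JunctionCall",
    "BackendError",
    "AnnotatorConfigError",
    "compute_evalue",
    "annotate_builtin",
    "extract_junction",
    "run_external_annotator",
]

#: E-value above which a segment is reported as "no call"
NO_CALL_EVALUE = 1000.0
#: minimum aligned bases for a D-segment call; shorter matches are noise
MIN_D_ALIGNED = 5


class BackendError(RuntimeError):
    """The external annotator failed on a chunk."""

    def __init__(self, message: str, chunk_path: Optional[os.PathLike] = None):
        if chunk_path is not None:
            message = f"chunk {chunk_path}: {message}"
        super().__init__(message)
        self.chunk_path = chunk_path


class AnnotatorConfigError(ValueError):
    """Backend misconfiguration detected before any chunk was processed."""


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and Karlin–Altschul constants for the built-in backend.

    The constants are fixed rather than estimated from the scoring system:
    only the ordering and thresholding behaviour of the E-values matters to
    the pipeline, and fixed constants keep results exactly reproducible.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    karlin_k: float = 0.1
    karlin_lambda: float = 0.5

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.karlin_k <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")


@dataclass
class AlignmentHit:
    """One gene-segment alignment, 0-based half-open intervals.

    ``query_*`` coordinates are on the annotation-orientation sequence
    (the reverse complement of the input read when ``rev_comp`` is set on
    the record).
    """

    gene_call: str
    segment: str
    score: float
    e_value: float
    query_start: int
    query_end: int
    germline_start: int
    germline_end: int
    identity: float
    rank: int
    cigar: str = ""
    sequence_alignment: str = ""
    germline_alignment: str = ""
    # aligned coordinate blocks kept for anchor mapping; not serialized
    blocks: Optional[Tuple[Tuple[Tuple[int, int], ...], Tuple[Tuple[int, int], ...]]] = field(
        default=None, repr=False, compare=False
    )


@dataclass
class JunctionCall:
    """IMGT junction (C...W/F inclusive) and the CDR3 it encloses."""

    junction: str
    junction_aa: str
    cdr3: str
    cdr3_aa: str
    #: 0-based half-open CDR3 interval on the annotation-orientation sequence
    cdr3_interval: Tuple[int, int]


def compute_evalue(score: float, m: int, n: int, params: ScoringParams) -> float:
    """Karlin–Altschul expectation value E = K·m·n·exp(−λ·S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence and database lengths must be >= 1")
    if score < 0:
        raise ValueError("score must be >= 0")
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


_ALIGNER_CACHE: dict = {}


def _aligner(params: ScoringParams) -> Align.PairwiseAligner:
    aligner = _ALIGNER_CACHE.get(params)
    if aligner is None:
        aligner = Align.PairwiseAligner(
            mode="local",
            match_score=params.match,
            mismatch_score=params.mismatch,
            open_gap_score=params.gap_open,
            extend_gap_score=params.gap_extend,
        )
        _ALIGNER_CACHE[params] = aligner
    return aligner


def _alignment_details(
    query: str, germline: str, alignment
) -> Tuple[tuple, tuple, float, str, str, str]:
    """Blocks, identity, cigar and gapped alignment strings for one alignment."""
    q_blocks, g_blocks = alignment.aligned
    q_blocks = tuple((int(s), int(e)) for s, e in q_blocks)
    g_blocks = tuple((int(s), int(e)) for s, e in g_blocks)
    matches = 0
    columns = 0
    q_parts: List[str] = []
    g_parts: List[str] = []
    cigar_ops: List[str] = []
    q_start = q_blocks[0][0]
    if q_start:
        cigar_ops.append(f"{q_start}S")
    prev_q_end: Optional[int] = None
    prev_g_end: Optional[int] = None
    for (qs, qe), (gs, ge) in zip(q_blocks, g_blocks):
        if prev_q_end is not None:
            q_gap = qs - prev_q_end  # read bases absent from germline
            g_gap = gs - prev_g_end  # germline bases absent from read
            if q_gap:
                cigar_ops.append(f"{q_gap}I")
                q_parts.append(query[prev_q_end:qs])
                g_parts.append("-" * q_gap)
                columns += q_gap
            if g_gap:
                cigar_ops.append(f"{g_gap}D")
                q_parts.append("-" * g_gap)
                g_parts.append(germline[prev_g_end:gs])
                columns += g_gap
        qseg = query[qs:qe]
        gseg = germline[gs:ge]
        matches += sum(a == b for a, b in zip(qseg, gseg))
        columns += qe - qs
        cigar_ops.append(f"{qe - qs}M")
        q_parts.append(qseg)
        g_parts.append(gseg)
        prev_q_end, prev_g_end = qe, ge
    tail = len(query) - q_blocks[-1][1]
    if tail:
        cigar_ops.append(f"{tail}S")
    identity = matches / columns if columns else 0.0
    return (
        q_blocks,
        g_blocks,
        identity,
        "".join(cigar_ops),
        "".join(q_parts),
        "".join(g_parts),
    )


def _rank_segment(
    seq: str,
    region: Tuple[int, int],
    genes: Sequence[GermlineGene],
    db_length: int,
    params: ScoringParams,
    min_aligned: int = 1,
) -> List[AlignmentHit]:
    """Score one segment's genes against a query region; keep the top 3.

    Hits are ordered by ascending E-value, then descending score, then
    germline file order (deterministic tie-break).  A segment whose best
    E-value exceeds ``NO_CALL_EVALUE`` yields no hits.
    """
    start, end = region
    sub = seq[start:end]
    if not sub or not genes:
        return []
    aligner = _aligner(params)
    m = len(seq)  # E-value query length: the full annotated sequence
    scored = []
    for order, gene in enumerate(genes):
        score = aligner.score(sub, gene.sequence)
        if score <= 0:
            continue
        e_value = compute_evalue(score, m, db_length, params)
        scored.append((e_value, -score, order, gene, score))
    scored.sort(key=lambda t: t[:3])
    hits: List[AlignmentHit] = []
    for rank, (e_value, _negscore, _order, gene, score) in enumerate(scored[:3], start=1):
        if rank == 1 and e_value > NO_CALL_EVALUE:
            return []
        if e_value > NO_CALL_EVALUE:
            continue
        alignment = aligner.align(sub, gene.sequence)[0]
        q_blocks, g_blocks, identity, cigar, q_aln, g_aln = _alignment_details(
            sub, gene.sequence, alignment
        )
        aligned_len = sum(qe - qs for qs, qe in q_blocks)
        if aligned_len < min_aligned:
            if rank == 1:
                return []
            continue
        # shift query coordinates from region-local to sequence-absolute
        q_blocks_abs = tuple((qs + start, qe + start) for qs, qe in q_blocks)
        hits.append(
            AlignmentHit(
                gene_call=gene.name,
                segment=gene.segment,
                score=score,
                e_value=e_value,
                query_start=q_blocks_abs[0][0],
                query_end=q_blocks_abs[-1][1],
                germline_start=g_blocks[0][0],
                germline_end=g_blocks[-1][1],
                identity=identity,
                rank=rank,
                cigar=cigar,
                sequence_alignment=q_aln,
                germline_alignment=g_aln,
                blocks=(q_blocks_abs, g_blocks),
            )
        )
    # ranks may have gaps after filtering; renumber 1..k
    for i, hit in enumerate(hits, start=1):
        hit.rank = i
    return hits


def annotate_builtin(
    record: SeqRecord,
    db: GermlineDB,
    params: ScoringParams = ScoringParams(),
) -> Tuple[List[AlignmentHit], bool]:
    """Assign V/(D)/J segments to one read with the built-in aligner.

    Returns the combined hit list (top-3 per segment) and whether the read
    had to be reverse-complemented into annotation orientation.  Uncallable
    reads return an empty hit list, never an error.
    """
    fwd = record.sequence
    rev = reverse_complement(fwd)
    aligner = _aligner(params)
    best_fwd = max((aligner.score(fwd, g.sequence) for g in db.v_genes), default=0.0)
    best_rev = max((aligner.score(rev, g.sequence) for g in db.v_genes), default=0.0)
    rev_comp = best_rev > best_fwd
    seq = rev if rev_comp else fwd

    n_total = len(seq)
    v_hits = _rank_segment(
        seq, (0, n_total), db.v_genes, db.total_length("V"), params
    )
    hits: List[AlignmentHit] = list(v_hits)

    j_region_start = v_hits[0].query_end if v_hits else 0
    j_hits = _rank_segment(
        seq, (j_region_start, n_total), db.j_genes, db.total_length("J"), params
    )
    hits.extend(j_hits)

    if db.d_genes and v_hits and j_hits:
        d_region = (v_hits[0].query_end, j_hits[0].query_start)
        if d_region[1] - d_region[0] >= MIN_D_ALIGNED:
            d_hits = _rank_segment(
                seq,
                d_region,
                db.d_genes,
                db.total_length("D"),
                params,
                min_aligned=MIN_D_ALIGNED,
            )
            hits.extend(d_hits)
    return hits, rev_comp


def _map_germline_to_query(
    blocks: Tuple[Tuple[Tuple[int, int], ...], Tuple[Tuple[int, int], ...]],
    g_pos: int,
) -> Optional[int]:
    """Project a germline coordinate through the alignment onto the query.

    Returns ``None`` when the position falls outside the aligned germline
    interval or in a gapped column.
    """
    q_blocks, g_blocks = blocks
    for (qs, _qe), (gs, ge) in zip(q_blocks, g_blocks):
        if gs <= g_pos < ge:
            return qs + (g_pos - gs)
    return None


def _map_codon(hit: AlignmentHit, anchor: int) -> Optional[Tuple[int, int]]:
    """Query interval of a germline codon; None if clipped, gapped or split."""
    if hit.blocks is None:
        return None
    first = _map_germline_to_query(hit.blocks, anchor)
    last = _map_germline_to_query(hit.blocks, anchor + 2)
    if first is None or last is None or last - first != 2:
        return None
    return first, last + 1


def extract_junction(
    seq: str,
    v_hit: AlignmentHit,
    j_hit: AlignmentHit,
    db: GermlineDB,
) -> Optional[JunctionCall]:
    """Call the IMGT junction on the annotation-orientation sequence.

    The conserved-cysteine codon of the V gene and the conserved
    tryptophan/phenylalanine codon of the J gene are projected through the
    alignments onto query coordinates; the junction is the codon span from
    one through the other inclusive, and the CDR3 is the junction minus the
    two anchor codons.  Absent (a legitimate outcome, not an error) when
    either anchor is not covered by its alignment or maps to a gapped
    column.
    """
    from .airr import translate  # local import: airr depends on this module

    v_gene = db.gene(v_hit.gene_call)
    j_gene = db.gene(j_hit.gene_call)
    if v_gene.anchor is None or j_gene.anchor is None:
        return None
    cys = _map_codon(v_hit, v_gene.anchor)
    jan = _map_codon(j_hit, j_gene.anchor)
    if cys is None or jan is None:
        return None
    jct_start, jct_end = cys[0], jan[1]
    if jct_end <= jct_start:
        return None
    junction = seq[jct_start:jct_end]
    cdr3_start, cdr3_end = cys[1], jan[0]
    if cdr3_end < cdr3_start:
        return None
    cdr3 = seq[cdr3_start:cdr3_end]
    return JunctionCall(
        junction=junction,
        junction_aa=translate(junction),
        cdr3=cdr3,
        cdr3_aa=translate(cdr3),
        cdr3_interval=(cdr3_start, cdr3_end),
    )


def run_external_annotator(
    chunk_path: os.PathLike,
    executable: os.PathLike,
    out_path: Optional[os.PathLike] = None,
    extra_options: Sequence[str] = (),
) -> Path:
    """Run an IgBLAST-compatible executable on one chunk file.

    Backend contract: ``executable [extra_options...] CHUNK OUT_TSV`` must
    write an AIRR Rearrangement TSV (the AIRR output dialect, as produced
    by ``igblastn -outfmt 19``, ideally with the three best germline hits
    per segment) to ``OUT_TSV`` and exit 0.  Real IgBLAST is wrapped by a
    two-line shim that maps this contract onto its flag set.
    """
    chunk_path = Path(chunk_path)
    executable = Path(executable)
    if shutil.which(str(executable)) is None and not (
        executable.exists() and os.access(executable, os.X_OK)
    ):
        raise AnnotatorConfigError(
            f"external annotator executable not found or not runnable: {executable}"
        )
    if out_path is None:
        out_path = chunk_path.with_suffix(chunk_path.suffix + ".airr.tsv")
    out_path = Path(out_path)
    cmd = [str(executable), *extra_options, str(chunk_path), str(out_path)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise BackendError(
            f"annotator exited {proc.returncode}; command: {' '.join(cmd)}; "
            f"stderr: {proc.stderr.strip()[:2000]}",
            chunk_path=chunk_path,
        )
    if not out_path.exists():
        raise BackendError(
            f"annotator exited 0 but wrote no output at {out_path}",
            chunk_path=chunk_path,
        )
    return out_path
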