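"""Synthetic immunoglobulin read generation with ground truth.

Reads are built by toy V(D)J recombination: a V gene trimmed at its 3'
end, untemplated N-nucleotides, a trimmed D core, more N-nucleotides, and
a trimmed J gene.  Somatic hypermutation is then applied as uniform
per-base substitutions, and sequencing errors as further substitutions
that also drop the Phred score at the error position.  By default each
rearrangement is resampled until it is productive (junction in frame, no
stop codon before mutation), emulating an expressed cDNA repertoire in
which non-productive chains are a small minority; mutations and
sequencing errors can still break reads downstream, which is exactly what
the quality filters are for.

Every read gets a truth-table row (true genes, true junction, mutation
count) so annotator recovery is measurable exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .airr import translate
from .fastx_io import SeqRecord, write_fastx
from .germline import GermlineDB

__all__ = [
    "SimParams",
    "TruthRecord",
    "simulate_repertoire",
    "make_filter_fixture",
    "read_truth_table",
]

BASES = np.array(list("ACGT"))
_PRODUCTIVE_ATTEMPTS = 200


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic repertoire."""

    n_reads: int = 1000
    mutation_rate: float = 0.02
    max_trim: int = 3
    max_n_insert: int = 6
    error_rate: float = 0.005
    quality_high: int = 40
    quality_low: int = 10
    seed: int = 0
    productive_only: bool = True

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        for name in ("mutation_rate", "error_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TruthRecord:
    sequence_id: str
    true_v: str
    true_d: str  # "" when the locus has no D genes
    true_j: str
    true_junction: str
    n_mutations: int


def _substitute(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _build_rearrangement(
    rng: np.random.Generator, db: GermlineDB, params: SimParams
) -> Tuple[str, str, str, str, str]:
    """One pre-mutation read: (sequence, v_name, d_name, j_name, junction)."""
    v = db.v_genes[rng.integers(0, len(db.v_genes))]
    j = db.j_genes[rng.integers(0, len(db.j_genes))]
    d = db.d_genes[rng.integers(0, len(db.d_genes))] if db.d_genes else None

    for _ in range(_PRODUCTIVE_ATTEMPTS):
        trim_v = int(rng.integers(0, params.max_trim + 1))
        trim_j = int(rng.integers(0, params.max_trim + 1))
        n1 = "".join(BASES[rng.integers(0, 4, int(rng.integers(0, params.max_n_insert + 1)))])
        n2 = "".join(BASES[rng.integers(0, 4, int(rng.integers(0, params.max_n_insert + 1)))])
        d_core = ""
        if d is not None:
            d5 = int(rng.integers(0, params.max_trim + 1))
            d3 = int(rng.integers(0, params.max_trim + 1))
            d_core = d.sequence[d5 : len(d.sequence) - d3]
        v_part = v.sequence[: len(v.sequence) - trim_v]
        j_part = j.sequence[trim_j:]
        seq = v_part + n1 + d_core + n2 + j_part
        # junction: conserved Cys codon through the J anchor codon, inclusive
        j_anchor_pos = len(v_part) + len(n1) + len(d_core) + len(n2) + (j.anchor - trim_j)
        junction = seq[v.anchor : j_anchor_pos + 3]
        if not params.productive_only:
            break
        in_frame = len(junction) % 3 == 0
        if in_frame and "*" not in translate(seq):
            break
    return seq, v.name, (d.name if d is not None else ""), j.name, junction


def _mutate(
    rng: np.random.Generator, seq: str, rate: float
) -> Tuple[str, int, np.ndarray]:
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hit):
        chars[i] = _substitute(rng, chars[i])
    return "".join(chars), int(hit.sum()), hit


def simulate_repertoire(
    db: GermlineDB,
    params: SimParams,
    out_fastq: os.PathLike,
    out_truth: Optional[os.PathLike] = None,
) -> Tuple[Path, Path]:
    """Write a synthetic FASTQ repertoire and its truth table.

    Deterministic under ``params.seed``: repeated runs produce
    byte-identical files.
    """
    out_fastq = Path(out_fastq)
    if out_truth is None:
        out_truth = out_fastq.with_suffix(".truth.tsv")
    out_truth = Path(out_truth)

    def generate():
        with open(out_truth, "w") as truth_fh:
            truth_fh.write(
                "sequence_id\ttrue_v\ttrue_d\ttrue_j\ttrue_junction\tn_mutations\n"
            )
            for i in range(params.n_reads):
                # one independent stream per read: the rearrangement draw is
                # unaffected by how many numbers the noise model consumes
                rng = np.random.default_rng([params.seed, i])
                sid = f"sim_{i:06d}"
                seq, v_name, d_name, j_name, junction = _build_rearrangement(
                    rng, db, params
                )
                mutated, n_mut, _ = _mutate(rng, seq, params.mutation_rate)
                observed, _n_err, err_mask = _mutate(
                    rng, mutated, params.error_rate
                )
                quals = np.full(len(observed), params.quality_high, dtype=int)
                quals[err_mask] = params.quality_low
                truth_fh.write(
                    f"{sid}\t{v_name}\t{d_name}\t{j_name}\t{junction}\t{n_mut}\n"
                )
                yield SeqRecord(
                    id=sid, sequence=observed, qualities=list(map(int, quals))
                )

    write_fastx(generate(), out_fastq, "fastq")
    return out_fastq, out_truth


def read_truth_table(path: os.PathLike) -> Dict[str, TruthRecord]:
    truth: Dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            truth[row["sequence_id"]] = TruthRecord(
                sequence_id=row["sequence_id"],
                true_v=row["true_v"],
                true_d=row["true_d"],
                true_j=row["true_j"],
                true_junction=row["true_junction"],
                n_mutations=int(row["n_mutations"]),
            )
    return truth


def make_filter_fixture(db: GermlineDB) -> Tuple[List[SeqRecord], Dict[str, Optional[str]]]:
    """Six reads engineered to exercise each quality filter exactly once.

    Returns the reads plus the expected failure reason per read id
    (``None`` for the clean read).  With the default filters plus a CDR3
    Phred threshold of 20, exactly the clean read survives and each filter
    removes exactly one read.
    """
    v = db.v_genes[0]
    j = db.j_genes[0]
    assert v.anchor is not None and j.anchor is not None
    q_hi = 40

    def rec(sid: str, seq: str, quals: Optional[List[int]] = None) -> SeqRecord:
        return SeqRecord(
            id=sid, sequence=seq, qualities=quals or [q_hi] * len(seq)
        )

    filler = "GATAGTAGT"  # 9 nt, stop-free, keeps the junction in frame
    clean_seq = v.sequence + filler + j.sequence
    reads: List[SeqRecord] = [rec("clean", clean_seq)]
    expected: Dict[str, Optional[str]] = {"clean": None}

    # E-value: only the last 22 V bases remain.  The V hit still wins and
    # covers the Cys anchor, but 22 matched bases put the V E-value above
    # 1e-6 while the full-length J keeps the J E-value far below it.
    evalue_seq = v.sequence[-22:] + filler + j.sequence
    reads.append(rec("fail_evalue", evalue_seq))
    expected["fail_evalue"] = "evalue"

    # stop codon: one in-frame codon inside the V region becomes TAA
    pos = 150  # codon-aligned (pos % 3 == 0), upstream of the junction
    stop_seq = clean_seq[:pos] + "TAA" + clean_seq[pos + 3 :]
    reads.append(rec("fail_stop", stop_seq))
    expected["fail_stop"] = "stop_codon"

    # frame: filler length not divisible by 3; pick the variant whose
    # frameshifted tail stays stop-free so only the frame filter trips
    for extra in ("A", "AG", "AC", "GT"):
        frame_seq = v.sequence + filler + extra + j.sequence
        if "*" not in translate(frame_seq):
            break
    else:  # pragma: no cover - toy DB guarantees a stop-free variant
        raise AssertionError("no stop-free frameshift variant found")
    reads.append(rec("fail_frame", frame_seq))
    expected["fail_frame"] = "out_of_frame"

    # missing CDR3: V truncated at the Cys codon end joined directly to a J
    # anchor codon -> junction is exactly C+W/F, a zero-length CDR3.  The J
    # is chosen so the local V alignment cannot chance-extend across the
    # join (any extension prefix against the V tail scores <= 0), which
    # would steal the J anchor from the J alignment.
    v_tail = v.sequence[v.anchor + 3 : v.anchor + 9]

    def extendable(post: str) -> bool:
        running = 0
        for a, b in zip(v_tail, post):
            running += 2 if a == b else -1
            if running > 0:
                return True
        return False

    for j_cdr3 in db.j_genes:
        post_anchor = j_cdr3.sequence[j_cdr3.anchor : j_cdr3.anchor + 6]
        if not extendable(post_anchor):
            break
    else:  # pragma: no cover - toy DB guarantees a non-extendable J
        raise AssertionError("no extension-proof J gene found")
    nocdr3_seq = v.sequence[: v.anchor + 3] + j_cdr3.sequence[j_cdr3.anchor :]
    reads.append(rec("fail_cdr3", nocdr3_seq))
    expected["fail_cdr3"] = "no_cdr3"

    # CDR3 Phred: one base inside the CDR3 at quality 2
    quals = [q_hi] * len(clean_seq)
    quals[v.anchor + 4] = 2  # inside the CDR3 (just after the Cys codon)
    reads.append(rec("fail_phred", clean_seq, quals))
    expected["fail_phred"] = "cdr3_phred"

    return reads, expected
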