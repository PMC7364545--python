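"""Post-annotation quality filters with per-record failure accounting.

Five individually-toggleable filters remove reads that (1) miss the V and
J assignment E-value threshold, (2) contain a stop codon in the translated
V-through-J region, (3) are out of frame across the V–J junction, (4) lack
a CDR3, or (5) have any CDR3 base below a user-chosen Phred score.  Every
enabled filter is evaluated on every record — no short-circuiting — so the
failure accounting is complete, and records that could not be annotated at
all are conservatively failed rather than erroring: the pipeline never
halts on a bad read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .airr import Rearrangement

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "FILTER_REASONS",
    "filter_evalue",
    "filter_stop_codon",
    "filter_in_frame",
    "filter_cdr3_present",
    "filter_cdr3_phred",
    "apply_filters",
]

FILTER_REASONS = ("evalue", "stop_codon", "out_of_frame", "no_cdr3", "cdr3_phred")

DEFAULT_EVALUE_THRESHOLD = 1.0e-6


@dataclass(frozen=True)
class FilterConfig:
    """Which filters run and with what thresholds.

    The four standard filters default to on with an E-value threshold of
    1.0e-6; the CDR3 Phred filter is off until the user supplies a
    threshold.
    """

    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    enable_evalue: bool = True
    enable_stop_codon: bool = True
    enable_in_frame: bool = True
    enable_cdr3_present: bool = True
    cdr3_phred_min: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.cdr3_phred_min is not None and not (0 <= self.cdr3_phred_min <= 93):
            raise ValueError("cdr3_phred_min must be in [0, 93]")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        return cls(
            enable_evalue=False,
            enable_stop_codon=False,
            enable_in_frame=False,
            enable_cdr3_present=False,
            cdr3_phred_min=None,
        )


@dataclass
class FilterOutcome:
    passed: bool
    failed_reasons: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_reasons)


def filter_evalue(record: Rearrangement, threshold: float) -> bool:
    """Both V and J assignments must be present and at or below threshold."""
    return (
        record.v_support is not None
        and record.j_support is not None
        and record.v_support <= threshold
        and record.j_support <= threshold
    )


def filter_stop_codon(record: Rearrangement) -> bool:
    """Pass only records positively known to be stop-free."""
    return record.stop_codon is False


def filter_in_frame(record: Rearrangement) -> bool:
    return record.vj_in_frame is True


def filter_cdr3_present(record: Rearrangement) -> bool:
    return bool(record.cdr3)


def filter_cdr3_phred(record: Rearrangement, min_q: int) -> bool:
    """Every CDR3 base call must reach ``min_q``.

    FASTA records (no qualities) pass, as do records without a CDR3 — the
    presence filter owns that failure.
    """
    quals = record.cdr3_qualities()
    if quals is None:
        return True
    return all(q >= min_q for q in quals)


def evaluate(record: Rearrangement, config: FilterConfig) -> FilterOutcome:
    """Run every enabled filter on one record."""
    reasons = set()
    if config.enable_evalue and not filter_evalue(record, config.evalue_threshold):
        reasons.add("evalue")
    if config.enable_stop_codon and not filter_stop_codon(record):
        reasons.add("stop_codon")
    if config.enable_in_frame and not filter_in_frame(record):
        reasons.add("out_of_frame")
    if config.enable_cdr3_present and not filter_cdr3_present(record):
        reasons.add("no_cdr3")
    if config.cdr3_phred_min is not None and not filter_cdr3_phred(
        record, config.cdr3_phred_min
    ):
        reasons.add("cdr3_phred")
    return FilterOutcome(passed=not reasons, failed_reasons=frozenset(reasons))


def apply_filters(
    records: Sequence[Rearrangement], config: FilterConfig
) -> Tuple[List[Rearrangement], List[FilterOutcome], Dict[str, int]]:
    """Filter a batch, returning kept records, per-record outcomes and
    aggregate failure counts per reason."""
    kept: List[Rearrangement] = []
    outcomes: List[FilterOutcome] = []
    counts: Dict[str, int] = {reason: 0 for reason in FILTER_REASONS}
    for rec in records:
        outcome = evaluate(rec, config)
        outcomes.append(outcome)
        if outcome.passed:
            kept.append(rec)
        else:
            for reason in outcome.failed_reasons:
                counts[reason] += 1
    return kept, outcomes, counts
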