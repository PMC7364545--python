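"""Germline V/D/J reference databases with junction-anchor metadata.

The built-in annotator needs, beyond the germline sequences themselves, the
position of the conserved cysteine codon near the 3' end of each V gene and
of the conserved tryptophan/phenylalanine codon in each J gene: the IMGT
junction runs from the one through the other, inclusive.  IgBLAST carries
that knowledge internally; here it travels as a 2-column sidecar table
(gene name, 0-based codon-start offset) so the FASTA files stay standard.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from Bio import SeqIO

__all__ = ["GermlineGene", "GermlineDB", "GermlineError", "load_germline_fasta", "load_toy_db"]


class GermlineError(ValueError):
    """Invalid or inconsistent germline database input."""


@dataclass(frozen=True)
class GermlineGene:
    name: str
    segment: str  # "V" | "D" | "J"
    sequence: str
    anchor: Optional[int] = None  # 0-based codon start of C (V) or W/F (J)
    functional: bool = True

    def __post_init__(self) -> None:
        if self.segment not in ("V", "D", "J"):
            raise GermlineError(f"{self.name}: unknown segment {self.segment!r}")
        if not self.sequence:
            raise GermlineError(f"{self.name}: empty sequence")
        if self.anchor is not None:
            if self.anchor < 0 or self.anchor + 3 > len(self.sequence):
                raise GermlineError(
                    f"{self.name}: anchor {self.anchor} outside sequence of "
                    f"length {len(self.sequence)}"
                )

    @property
    def anchor_codon(self) -> Optional[str]:
        if self.anchor is None:
            return None
        return self.sequence[self.anchor : self.anchor + 3]


@dataclass
class GermlineDB:
    species: str = "synthetic"
    locus: str = "IGH"
    v_genes: List[GermlineGene] = field(default_factory=list)
    d_genes: List[GermlineGene] = field(default_factory=list)
    j_genes: List[GermlineGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.v_genes or not self.j_genes:
            raise GermlineError("a germline database needs at least one V and one J gene")
        names = [g.name for seg in (self.v_genes, self.d_genes, self.j_genes) for g in seg]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GermlineError(f"duplicate gene names: {sorted(dupes)}")
        self._by_name = {
            g.name: g
            for seg in (self.v_genes, self.d_genes, self.j_genes)
            for g in seg
        }

    def genes(self, segment: str) -> List[GermlineGene]:
        return {"V": self.v_genes, "D": self.d_genes, "J": self.j_genes}[segment]

    def gene(self, name: str) -> GermlineGene:
        return self._by_name[name]

    def total_length(self, segment: str) -> int:
        """Summed sequence length of one segment's genes (E-value search space)."""
        return sum(len(g.sequence) for g in self.genes(segment))


def _read_segment_fasta(path: Path, segment: str) -> List[tuple[str, str]]:
    entries: List[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if name in seen:
            raise GermlineError(f"duplicate gene name {name!r} in {path}")
        seen.add(name)
        entries.append((name, str(rec.seq).upper()))
    return entries


def _read_anchor_table(path: Path) -> Dict[str, int]:
    anchors: Dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise GermlineError(f"anchor table row {row!r} needs 2 columns")
            name, offset = row[0].strip(), row[1].strip()
            try:
                anchors[name] = int(offset)
            except ValueError as exc:
                raise GermlineError(
                    f"anchor offset for {name!r} is not an integer: {offset!r}"
                ) from exc
    return anchors


def load_germline_fasta(
    v_path: Path,
    j_path: Path,
    d_path: Optional[Path] = None,
    anchors: Optional[Path] = None,
    *,
    species: str = "synthetic",
    locus: str = "IGH",
    require_anchors: bool = True,
) -> GermlineDB:
    """Load V/(D)/J FASTA files plus an optional anchor sidecar table.

    D genes are optional (light chains and TCR alpha have none).  When
    ``require_anchors`` is set — as it must be for the built-in backend,
    which cannot call junctions without them — every V and J gene must
    appear in the anchor table.
    """
    anchor_map = _read_anchor_table(Path(anchors)) if anchors else {}

    def build(path: Optional[Path], segment: str) -> List[GermlineGene]:
        if path is None:
            return []
        genes = []
        for name, seq in _read_segment_fasta(Path(path), segment):
            anchor = anchor_map.get(name)
            if segment in ("V", "J") and anchor is None and require_anchors:
                raise GermlineError(
                    f"{segment} gene {name!r} has no junction anchor in the "
                    f"anchor table; the built-in backend requires one"
                )
            genes.append(
                GermlineGene(name=name, segment=segment, sequence=seq, anchor=anchor)
            )
        return genes

    db = GermlineDB(
        species=species,
        locus=locus,
        v_genes=build(Path(v_path), "V"),
        d_genes=build(Path(d_path), "D") if d_path else [],
        j_genes=build(Path(j_path), "J"),
    )
    return db


def toy_db_paths() -> Dict[str, Path]:
    """Paths of the packaged toy IGH database (3 V, 2 D, 2 J genes)."""
    data = Path(__file__).parent / "data"
    return {
        "v": data / "toy_v.fasta",
        "d": data / "toy_d.fasta",
        "j": data / "toy_j.fasta",
        "anchors": data / "toy_anchors.tsv",
    }


def load_toy_db() -> GermlineDB:
    """Load the small packaged germline set used for simulation and tests."""
    paths = toy_db_paths()
    return load_germline_fasta(
        v_path=paths["v"], j_path=paths["j"], d_path=paths["d"], anchors=paths["anchors"]
    )
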