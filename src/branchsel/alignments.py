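"""Reading, validation and screening of per-gene codon alignments.

A gene enters the selection analysis as an in-frame nucleotide alignment
(one FASTA file per gene).  Before any model fitting the alignment is
screened for internal or terminal stop codons: CodeML rejects sequences
containing stops, so a gene with any stop codon in any sequence is excluded
from the batch rather than silently truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Data import CodonTable

GAP = "-"
_ALPHABET = set("ACGTN-")
_NAME_RE = re.compile(r"^\S+$")

DEFAULT_EXTENSIONS = (".fas", ".fasta", ".fa")


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI translation table: codon -> amino acid plus a stop-codon set."""

    table_id: int
    codon_table: Mapping[str, str]
    stop_codons: frozenset[str]

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        if len(forward) + len(stops) != 64:
            raise AlignmentError(f"translation table {table_id} does not cover 64 codons")
        return cls(table_id=table_id, codon_table=forward, stop_codons=stops)


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


@dataclass
class CodonAlignment:
    """In-frame coding alignment for one gene, keyed by species name.

    Invariants: equal-length sequences, length divisible by 3, alphabet
    restricted to A/C/G/T/N/-, unique whitespace-free species names.
    """

    gene_id: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"{self.gene_id}: sequences of unequal length {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise AlignmentError(f"{self.gene_id}: length {lengths.pop()} not divisible by 3")
        for name, seq in self.sequences.items():
            if not _NAME_RE.match(name):
                raise AlignmentError(f"{self.gene_id}: invalid species name {name!r}")
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise AlignmentError(f"{self.gene_id}: illegal characters {sorted(bad)} in {name}")

    @property
    def n_codons(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values()))) // 3

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def codons(self, species: str) -> list[str]:
        seq = self.sequences[species].upper()
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass(frozen=True)
class Exclusion:
    """A gene dropped from the batch, with the reason recorded."""

    gene_id: str
    reason: str


@dataclass
class StopScreenResult:
    passed: bool
    # species -> 0-based codon indices holding a stop
    stop_positions: dict[str, list[int]]


def taxa_of(aln: CodonAlignment) -> frozenset[str]:
    """Species set of an alignment (drives species-tree pruning)."""
    return frozenset(aln.sequences)


def screen_stop_codons(aln: CodonAlignment, code: GeneticCode = STANDARD_CODE) -> StopScreenResult:
    """Fail iff any non-gap codon of any sequence is a stop codon.

    Codons containing gap characters are skipped; codons containing N are
    ambiguous and never count as stops (avoids false exclusions).  Terminal
    stop codons fail too, since CodeML rejects them.
    """
    positions: dict[str, list[int]] = {}
    for name in aln.sequences:
        hits = [
            i
            for i, codon in enumerate(aln.codons(name))
            if GAP not in codon and "N" not in codon and codon in code.stop_codons
        ]
        if hits:
            positions[name] = hits
    return StopScreenResult(passed=not positions, stop_positions=positions)


def read_gene_alignment(path: Path) -> CodonAlignment:
    """Read a single FASTA file into a CodonAlignment (gene_id = file stem)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path.name}: no FASTA records")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise AlignmentError(f"{path.name}: duplicate species name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return CodonAlignment(gene_id=path.stem, sequences=sequences)


def read_gene_alignments(
    directory: Path, extensions: Iterable[str] = DEFAULT_EXTENSIONS
) -> tuple[list[CodonAlignment], list[Exclusion]]:
    """Read every per-gene FASTA in a folder.

    Malformed files are reported as exclusions, never fatal; an empty
    folder is a configuration error.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise AlignmentError(f"alignment folder not found: {directory}")
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in set(extensions))
    if not files:
        raise AlignmentError(f"no alignment files with extensions {tuple(extensions)} in {directory}")
    alignments: list[CodonAlignment] = []
    exclusions: list[Exclusion] = []
    for path in files:
        try:
            alignments.append(read_gene_alignment(path))
        except (AlignmentError, ValueError) as exc:
            exclusions.append(Exclusion(gene_id=path.stem, reason=f"unreadable: {exc}"))
    return alignments, exclusions


def write_gene_alignment(aln: CodonAlignment, path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.sequences.items():
            fh.write(f">{name}\n{seq}\n")


def write_exclusion_log(exclusions: Iterable[Exclusion], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\treason\n")
        for exc in exclusions:
            fh.write(f"{exc.gene_id}\t{exc.reason}\n")
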