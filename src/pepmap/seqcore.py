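"""Nucleotide and protein sequence primitives.

Genetic code, reverse complement, six-frame translation with coordinate
bookkeeping, FASTA I/O, and substitution-matrix loading.  Coordinates are
1-based inclusive throughout; minus-strand intervals are reported with
start > end (BLAST tabular convention) and normalized by downstream writers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Valid reading frames: +1..+3 forward, -1..-3 on the reverse complement.
FRAMES = (1, 2, 3, -1, -2, -3)


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside its alphabet."""


@dataclass(frozen=True)
class NucleotideSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - NT_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid table.  The standard code is the default."""

    name: str = "standard"
    table: dict[str, str] = field(default_factory=lambda: dict(_STANDARD_TABLE))

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 codons, got {len(self.table)}")

    def translate_codon(self, codon: str) -> str:
        if "N" in codon:
            return "X"
        return self.table[codon]


def _build_standard_table() -> dict[str, str]:
    bases = "TCAG"
    # Built from Biopython to avoid hand-typing 64 entries.
    table: dict[str, str] = {}
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                codon = b1 + b2 + b3
                table[codon] = str(Seq(codon).translate())
    return table


_STANDARD_TABLE = _build_standard_table()
STANDARD_CODE = GeneticCode()


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Reverse complement; an involution on valid sequences."""
    return NucleotideSequence(seq.id, seq.residues.translate(_COMPLEMENT)[::-1])


def translate_frame(
    seq: NucleotideSequence, frame: int, code: GeneticCode = STANDARD_CODE
) -> ProteinSequence:
    """Translate one of the six reading frames.

    Positive frames read the forward strand starting at offset ``frame - 1``;
    negative frames read the reverse complement starting at ``|frame| - 1``.
    Stop codons are rendered as ``*``; codons containing N as ``X``.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    residues = seq.residues if frame > 0 else seq.residues.translate(_COMPLEMENT)[::-1]
    offset = abs(frame) - 1
    n_codons = max(0, (len(residues) - offset) // 3)
    aa = []
    for i in range(n_codons):
        start = offset + 3 * i
        aa.append(code.translate_codon(residues[start : start + 3]))
    return ProteinSequence(f"{seq.id}|frame{frame:+d}", "".join(aa))


def aa_to_genomic(
    frame: int, aa_start: int, aa_end: int, contig_length: int
) -> tuple[int, int]:
    """Convert a 1-based AA interval in a frame translation to genomic nt.

    Returns 1-based inclusive coordinates; for negative frames the pair is
    reported with start > end, encoding the strand by coordinate order.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    if not 1 <= aa_start <= aa_end:
        raise IndexError(f"bad AA interval [{aa_start}, {aa_end}]")
    offset = abs(frame) - 1
    translated_len = (contig_length - offset) // 3
    if aa_end > translated_len:
        raise IndexError(
            f"AA index {aa_end} beyond frame {frame:+d} translation "
            f"({translated_len} AAs for contig of {contig_length} nt)"
        )
    lo = offset + 3 * (aa_start - 1) + 1  # frame-local first nt, 1-based
    hi = offset + 3 * aa_end
    if frame > 0:
        return lo, hi
    return contig_length - lo + 1, contig_length - hi + 1


def read_fasta(path: str | Path, kind: str = "nt") -> list:
    """Read a FASTA file (wrapped or single-line; LF or CRLF).

    ``kind`` selects the record type: ``nt`` or ``aa``.  Duplicate ids raise.
    """
    cls = NucleotideSequence if kind == "nt" else ProteinSequence
    records = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(cls(rec.id, str(rec.seq)))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate FASTA ids in {path}: {dupes}")
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def dedupe_peptides(records: Iterable[ProteinSequence]) -> list[ProteinSequence]:
    """Keep one record per distinct (uppercased) AA string, first-seen id wins."""
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        key = rec.residues.upper()
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


@dataclass(frozen=True)
class SubstitutionMatrix:
    """AA substitution matrix parsed from an NCBI-format text file."""

    name: str
    scores: dict[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        pair = (a, b)
        if pair not in self.scores:
            # Unknown residues score through the X column.
            pair = (a if (a, a) in self.scores else "X",
                    b if (b, b) in self.scores else "X")
        return self.scores[pair]

    @property
    def alphabet(self) -> str:
        return "".join(sorted({a for a, _ in self.scores}))


BUNDLED_MATRICES = ("PAM30", "PAM250", "BLOSUM45", "BLOSUM62", "BLOSUM90")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("pepmap").joinpath("data", name)))


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled NCBI-format matrix (PAM30, PAM250, BLOSUM45/62/90)."""
    name = name.upper()
    if name not in BUNDLED_MATRICES:
        raise ValueError(f"unknown matrix {name!r}; bundled: {BUNDLED_MATRICES}")
    arr = substitution_matrices.read(str(_data_path(name + ".txt")))
    scores: dict[tuple[str, str], int] = {}
    for a in arr.alphabet:
        for b in arr.alphabet:
            scores[(a, b)] = int(arr[a, b])
    return SubstitutionMatrix(name, scores)


def iter_six_frames(
    seq: NucleotideSequence, code: GeneticCode = STANDARD_CODE
) -> Iterator[tuple[int, ProteinSequence]]:
    """Yield (frame, translation) for all six frames, skipping empty ones."""
    for frame in FRAMES:
        prot = translate_frame(seq, frame, code)
        if len(prot):
            yield frame, prot
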