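"""Sequence alphabets, conservation groups, and FASTA/alignment I/O.

Shared foundation for every stage: IUPAC-degenerate nucleotide sequences
(as used in mixed primers), protein sequences with ``X`` for residues an
Edman read could not identify, and the six conservation groups used to
call two aligned residues "similar" in Clustal-style annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_complement, ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Map from IUPAC nucleotide code to the set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code not in ("U", "X")  # X is a non-standard alias for N in Biopython's table
}

#: All 15 valid IUPAC nucleotide codes (4 concrete + 11 degenerate).
IUPAC_CODES: frozenset[str] = frozenset(IUPAC_SETS)

#: The 20 standard amino acids.
AMINO_ACIDS: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Valid protein residue letters: the 20 amino acids plus X (unidentified).
PROTEIN_LETTERS: frozenset[str] = AMINO_ACIDS | {"X"}

#: Residues treated as hydrophobic in hydrophobic-block scans.
HYDROPHOBIC: frozenset[str] = frozenset("VLIMFYWA")

GAP = "-"


def complement_iupac(base: str) -> str:
    """Complement a single IUPAC nucleotide code.

    The complement of a degenerate code is the code denoting the set of
    complements of its bases (R={A,G} -> Y={T,C}; N and S/W are
    self-complementary).
    """
    b = base.upper()
    if b not in IUPAC_CODES:
        raise ValueError(f"invalid IUPAC nucleotide code: {base!r}")
    return ambiguous_dna_complement[b]


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence over the IUPAC alphabet.

    Residues are stored uppercase; lowercase input (sometimes used to mark
    flanking context) is normalized on construction.  ``topology`` is
    ``"linear"`` or ``"circular"``; circular sequences arise from
    self-ligated restriction fragments.
    """

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")
        for i, ch in enumerate(self.residues):
            if ch not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC nucleotide code {ch!r} at position {i + 1}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


def reverse_complement(seq: NucSeq | str) -> NucSeq | str:
    """Reverse-complement a sequence under IUPAC semantics; topology preserved."""
    if isinstance(seq, str):
        return "".join(complement_iupac(b) for b in reversed(seq.upper()))
    rc = "".join(complement_iupac(b) for b in reversed(seq.residues))
    return NucSeq(id=seq.id, residues=rc, topology=seq.topology)


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence over the 20 amino acids plus X (unknown)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        for i, ch in enumerate(self.residues):
            if ch not in PROTEIN_LETTERS:
                raise ValueError(f"invalid protein residue {ch!r} at position {i + 1}")

    def __len__(self) -> int:
        return len(self.residues)


#: Default conservation groups: residues within a group are "similar".
#: Covers 18 of the 20 amino acids; C and H belong to no group and are
#: similar only to themselves by identity, never by group.
DEFAULT_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("EDQN"),
    frozenset("VLIM"),
    frozenset("FYW"),
    frozenset("GPA"),
    frozenset("KR"),
    frozenset("ST"),
)


@dataclass(frozen=True)
class ConservationScheme:
    """A partition of (most of) the amino-acid alphabet into similarity groups."""

    groups: tuple[frozenset[str], ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError(f"conservation groups are not disjoint: {sorted(seen & g)}")
            seen |= g

    def group_of(self, residue: str) -> frozenset[str] | None:
        r = residue.upper()
        for g in self.groups:
            if r in g:
                return g
        return None

    def covered(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g
        return frozenset(out)


DEFAULT_SCHEME = ConservationScheme()


def same_group(a: str, b: str, scheme: ConservationScheme = DEFAULT_SCHEME) -> bool:
    """True iff a and b co-occur in one conservation group.

    Identity is deliberately NOT similarity: (A, A) is False here and must
    be reported separately as an identity.  X is never similar to anything.
    """
    a, b = a.upper(), b.upper()
    for r in (a, b):
        if r not in PROTEIN_LETTERS:
            raise ValueError(f"invalid protein residue {r!r}")
    if a == b or "X" in (a, b):
        return False
    g = scheme.group_of(a)
    return g is not None and b in g


@dataclass(frozen=True)
class AlignmentBlock:
    """A block of equal-length gapped sequences (gap character '-')."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("alignment block is empty")
        width = len(self.rows[0])
        for rid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise ValueError(f"row {rid!r} has length {len(row)}, expected {width}")
            if "." in row:
                raise ValueError(f"row {rid!r} uses '.' as gap; only '-' is accepted")
            for ch in row:
                if ch != GAP and ch.upper() not in PROTEIN_LETTERS:
                    raise ValueError(f"invalid residue {ch!r} in row {rid!r}")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def ungapped(self, index: int) -> str:
        return self.rows[index].replace(GAP, "")

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(row[j] for row in self.rows)


# ---------------------------------------------------------------------------
# FASTA I/O (Bio.SeqIO underneath)

def read_protein_fasta(path: str | Path) -> list[ProteinSeq]:
    return [ProteinSeq(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_dna_fasta(path: str | Path, topology: str = "linear") -> list[NucSeq]:
    return [
        NucSeq(id=rec.id, residues=str(rec.seq), topology=topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[NucSeq | ProteinSeq], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_alignment_fasta(path: str | Path) -> AlignmentBlock:
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    return AlignmentBlock(ids=tuple(ids), rows=tuple(rows))
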