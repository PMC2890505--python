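"""Degenerate back-translation and inverse-PCR primer construction.

A peptide determined by Edman degradation is back-translated into a single
IUPAC-degenerate oligonucleotide covering every codon combination for that
peptide ("mixed primers").  Six-fold degenerate residues (L, R, S) cannot
be covered by one IUPAC codon without also encoding other amino acids, so
the codon table carries alternatives and the caller picks one per design
(e.g. L -> TTR restricts to the TTA/TTG pair).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from Bio.Seq import Seq

from .alphabet_core import IUPAC_SETS, AMINO_ACIDS, NucSeq, ProteinSeq, reverse_complement

#: Candidate degenerate codons per amino acid; the first entry is the default.
#: Every entry expands only to codons of that amino acid (verified at import).
DEFAULT_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCN",),
    "C": ("TGY",),
    "D": ("GAY",),
    "E": ("GAR",),
    "F": ("TTY",),
    "G": ("GGN",),
    "H": ("CAY",),
    "I": ("ATH",),
    "K": ("AAR",),
    # YTN is NOT usable for L: it would also cover TTY = Phe
    "L": ("YTR", "CTN", "TTR"),
    "M": ("ATG",),
    "N": ("AAY",),
    "P": ("CCN",),
    "Q": ("CAR",),
    "R": ("CGN", "AGR"),
    "S": ("TCN", "AGY"),
    "T": ("ACN",),
    "V": ("GTN",),
    "W": ("TGG",),
    "Y": ("TAY",),
}


def expand_degenerate(seq: str) -> Iterator[str]:
    """Yield every concrete sequence denoted by an IUPAC-degenerate string."""
    pools = [sorted(IUPAC_SETS[b]) for b in seq.upper()]
    for combo in itertools.product(*pools):
        yield "".join(combo)


class DegenerateCodonTable:
    """Amino acid -> ordered candidate degenerate codons (first = default)."""

    def __init__(self, codons: Mapping[str, Sequence[str]] | None = None) -> None:
        self.codons: dict[str, tuple[str, ...]] = {
            aa: tuple(c.upper() for c in cs) for aa, cs in (codons or DEFAULT_CODONS).items()
        }
        self._validate()

    def _validate(self) -> None:
        # YTN expands to 8 codons; exhaustive translation check is cheap for all entries
        for aa, entries in self.codons.items():
            if aa not in AMINO_ACIDS:
                raise ValueError(f"codon table key {aa!r} is not an amino acid")
            if not entries:
                raise ValueError(f"no codon entry for {aa}")
            for codon in entries:
                if len(codon) != 3 or any(b not in IUPAC_SETS for b in codon):
                    raise ValueError(f"{codon!r} is not a 3-letter IUPAC codon")
                translated = {str(Seq(c).translate()) for c in expand_degenerate(codon)}
                if translated != {aa}:
                    raise ValueError(
                        f"codon {codon} for {aa} also encodes {sorted(translated - {aa})}"
                    )

    def codon_for(self, aa: str, override: str | None = None) -> str:
        if override is not None:
            if override.upper() not in self.codons.get(aa, ()):
                # allow arbitrary override codons, but they must still be exclusive
                DegenerateCodonTable({aa: (override,)})
            return override.upper()
        if aa not in self.codons:
            raise ValueError(f"no codon known for residue {aa!r}")
        return self.codons[aa][0]


DEFAULT_TABLE = DegenerateCodonTable()


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-degenerate oligo with strand, 5'-phosphate flag and provenance."""

    seq: NucSeq
    strand: str  # sense | antisense
    phospho5: bool
    source_peptide: ProteinSeq
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"strand must be sense or antisense, got {self.strand!r}")
        if len(self.seq) < 1:
            raise ValueError("primer is empty")


def back_translate(
    peptide: ProteinSeq | str,
    table: DegenerateCodonTable = DEFAULT_TABLE,
    overrides: Mapping[str, str] | None = None,
) -> NucSeq:
    """Back-translate a peptide to one degenerate nucleotide sequence.

    ``overrides`` maps residue letters to the codon to use for every
    occurrence of that residue (e.g. ``{"L": "TTR"}``).  X back-translates
    to NNN (any codon) since the residue is unknown.
    """
    if isinstance(peptide, str):
        peptide = ProteinSeq(id="peptide", residues=peptide)
    if len(peptide) == 0:
        raise ValueError("peptide is empty")
    overrides = {k.upper(): v for k, v in (overrides or {}).items()}
    parts = []
    for aa in peptide.residues:
        if aa == "X":
            parts.append("NNN")
        else:
            parts.append(table.codon_for(aa, overrides.get(aa)))
    return NucSeq(id=f"{peptide.id}_bt", residues="".join(parts))


def design_primer(
    peptide: ProteinSeq | str,
    strand: str = "sense",
    target_len: int | None = None,
    table: DegenerateCodonTable = DEFAULT_TABLE,
    overrides: Mapping[str, str] | None = None,
    phospho5: bool = True,
    name: str = "",
) -> DegeneratePrimer:
    """Design a degenerate primer of ``target_len`` nt from a peptide.

    Sense primers trim surplus bases from the 3' end of the back-translation;
    antisense primers trim surplus from the 5' end and then reverse-complement,
    so that the primer's 3' end always points into the peptide's interior.
    """
    if isinstance(peptide, str):
        peptide = ProteinSeq(id="peptide", residues=peptide)
    bt = back_translate(peptide, table, overrides)
    n = len(bt)
    if target_len is None:
        target_len = n
    if target_len <= 0:
        raise ValueError(f"target_len must be positive, got {target_len}")
    if target_len > n:
        raise ValueError(f"target_len {target_len} exceeds back-translation length {n}")
    if strand == "sense":
        window = bt.residues[:target_len]
        seq = NucSeq(id=name or f"{peptide.id}_sense", residues=window)
    elif strand == "antisense":
        window = bt.residues[n - target_len :]
        seq = NucSeq(id=name or f"{peptide.id}_anti", residues=reverse_complement(window))
    else:
        raise ValueError(f"strand must be sense or antisense, got {strand!r}")
    return DegeneratePrimer(
        seq=seq, strand=strand, phospho5=phospho5, source_peptide=peptide, name=name
    )


def degeneracy(primer: DegeneratePrimer | NucSeq | str) -> int:
    """Number of distinct concrete oligos in the mixture."""
    if isinstance(primer, DegeneratePrimer):
        residues = primer.seq.residues
    elif isinstance(primer, NucSeq):
        residues = primer.residues
    else:
        residues = primer.upper()
    d = 1
    for b in residues:
        d *= len(IUPAC_SETS[b])
    return d


def _sets_match(a: str, b: str) -> bool:
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def find_binding_sites(
    primer: DegeneratePrimer | NucSeq | str,
    template: NucSeq,
    max_mismatch: int = 0,
) -> list[tuple[int, str, int]]:
    """All primer placements on a template, both strands, wrapping if circular.

    A position matches when the IUPAC base sets of primer and template
    intersect; a placement is a hit when at most ``max_mismatch`` positions
    fail that test.  Returned positions are 1-based plus-strand coordinates
    of the template base under the primer's 5' end on the given strand
    (leftmost covered base for '+', rightmost for '-').
    """
    if isinstance(primer, DegeneratePrimer):
        pseq = primer.seq.residues
    elif isinstance(primer, NucSeq):
        pseq = primer.residues
    else:
        pseq = primer.upper()
    t = template.residues
    n, m = len(t), len(pseq)
    if m == 0 or n == 0:
        return []
    if m > n and not template.is_circular:
        return []
    if m > n:  # circular template shorter than primer: disallow multi-wrap
        return []
    doubled = t + t if template.is_circular else t
    starts = range(n) if template.is_circular else range(n - m + 1)
    hits: list[tuple[int, str, int]] = []
    rc = reverse_complement(pseq)
    for start in starts:
        window = doubled[start : start + m]
        mm_plus = sum(1 for a, b in zip(pseq, window) if not _sets_match(a, b))
        if mm_plus <= max_mismatch:
            hits.append((start + 1, "+", mm_plus))
        mm_minus = sum(1 for a, b in zip(rc, window) if not _sets_match(a, b))
        if mm_minus <= max_mismatch:
            # 5' end of a minus-strand primer sits on the rightmost covered base
            pos = (start + m - 1) % n + 1
            hits.append((pos, "-", mm_minus))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits
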