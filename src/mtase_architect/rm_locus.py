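"""Restriction-modification locus arithmetic, cleavage, and methylation logic.

Covers the genomic bookkeeping around an R-M system: ORF/protein length
arithmetic, gene-pair orientation and intergenic gaps, recognition-site
mapping and cleavage (NruI cuts the palindrome TCG^CGA bluntly in the
middle), methylation-sensitivity rules (Dam methylation of the overlapping
TCGCGATC context blocks NruI but not its isoschizomer Sbo13I), an in-silico
inverse PCR over self-ligated digestion fragments, and the transparent
evidence vote used to call a methylase N6mA vs N4mC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .alphabet_core import IUPAC_SETS, NucSeq, reverse_complement
from .primer_design import DegeneratePrimer, find_binding_sites


@dataclass(frozen=True)
class EnzymeSpec:
    """Recognition site plus cut offsets (between-base, from site start)."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition site is empty")
        for ch in self.recognition.upper():
            if ch not in IUPAC_SETS:
                raise ValueError(f"invalid IUPAC code {ch!r} in recognition site")
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def blunt(self) -> bool:
        return self.cut_top == self.cut_bottom

    @property
    def overhang(self) -> int:
        return self.cut_bottom - self.cut_top


#: NruI and Sbo13I are isoschizomers: same site TCG^CGA, same blunt cut.
NRUI = EnzymeSpec(name="NruI", recognition="TCGCGA", cut_top=3, cut_bottom=3)
SBO13I = EnzymeSpec(name="Sbo13I", recognition="TCGCGA", cut_top=3, cut_bottom=3)


@dataclass(frozen=True)
class MethylationRule:
    """Blocking (or tolerance) of cleavage by methylation in a site context.

    ``context`` is an IUPAC string containing the recognition site at
    ``site_offset`` (0-based); ``methylated_pos`` is the 0-based position
    within the context whose methylation triggers the rule; ``blocked``
    says whether a methylated match blocks cleavage.
    """

    enzyme: str
    context: str
    site_offset: int
    methylated_pos: int
    blocked: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "context", self.context.upper())
        if not 0 <= self.methylated_pos < len(self.context):
            raise ValueError("methylated_pos outside context")
        if self.site_offset < 0:
            raise ValueError("site_offset must be >= 0")


#: Dam methylation of the A shared by TCGCGA|TC blocks NruI...
NRUI_DAM_BLOCK = MethylationRule(
    enzyme="NruI", context="TCGCGATC", site_offset=0, methylated_pos=5, blocked=True
)
#: ...but the same methylated context is still cleaved by Sbo13I.
SBO13I_DAM_TOLERANT = MethylationRule(
    enzyme="Sbo13I", context="TCGCGATC", site_offset=0, methylated_pos=5, blocked=False
)

DEFAULT_RULES: tuple[MethylationRule, ...] = (NRUI_DAM_BLOCK, SBO13I_DAM_TOLERANT)


@dataclass(frozen=True)
class Gene:
    name: str
    role: str  # R | M | C
    start: int  # 1-based inclusive
    end: int
    strand: str  # + | -

    def __post_init__(self) -> None:
        if self.role not in ("R", "M", "C"):
            raise ValueError(f"gene role must be R, M or C, got {self.role!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad gene bounds {self.start}..{self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RMLocus:
    sequence: NucSeq
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"gene {g.name} extends past the sequence end")
            if g.length_bp % 3 != 0:
                raise ValueError(f"gene {g.name}: length {g.length_bp} not divisible by 3")


def orf_protein_length(orf_bp: int) -> int:
    """Protein length encoded by a complete ORF (start..stop inclusive).

    An ORF of 3(n+1) bp encodes n amino acids: one codon is the stop.
    """
    if orf_bp % 3 != 0:
        raise ValueError(f"{orf_bp} bp is not a complete ORF (not divisible by 3)")
    if orf_bp < 6:
        raise ValueError(f"{orf_bp} bp is too short for a complete ORF (need >= 6)")
    return orf_bp // 3 - 1


@dataclass(frozen=True)
class GenePairReport:
    gene_a: str
    gene_b: str
    orientation: str  # divergent | convergent | tandem
    gap_bp: int
    overlap: bool


def _orientation(a: Gene, b: Gene) -> str:
    """Orientation of an adjacent gene pair (a upstream of b on the plus axis)."""
    if a.strand == b.strand:
        return "tandem"
    # opposite strands: divergent when transcribed away from the gap (<- ... ->)
    return "divergent" if a.strand == "-" else "convergent"


def locus_layout(locus: RMLocus) -> list[GenePairReport]:
    """Orientation and intergenic gap for each adjacent gene pair."""
    if len(locus.genes) < 2:
        raise ValueError("need at least 2 genes for a layout report")
    genes = sorted(locus.genes, key=lambda g: g.start)
    reports = []
    for a, b in zip(genes, genes[1:]):
        gap = b.start - a.end - 1
        overlap = gap < 0
        reports.append(
            GenePairReport(
                gene_a=a.name,
                gene_b=b.name,
                orientation=_orientation(a, b),
                gap_bp=max(gap, 0),
                overlap=overlap,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Sites, methylation, cleavage


def _matches_at(dna: str, pos: int, pattern: str) -> bool:
    if pos < 0 or pos + len(pattern) > len(dna):
        return False
    return all(dna[pos + k] in IUPAC_SETS[p] for k, p in enumerate(pattern))


def find_sites(dna: NucSeq, enzyme: EnzymeSpec) -> list[int]:
    """1-based start positions of the recognition site on the plus strand.

    For palindromic sites (such as TCGCGA) the plus-strand scan finds every
    double-stranded site.
    """
    seq = dna.residues
    return [
        i + 1
        for i in range(len(seq) - len(enzyme.recognition) + 1)
        if _matches_at(seq, i, enzyme.recognition)
    ]


def dam_sites(dna: NucSeq) -> frozenset[int]:
    """1-based positions of the Dam-methylated A in every GATC (plus strand)."""
    seq = dna.residues
    return frozenset(i + 2 for i in range(len(seq) - 3) if seq[i : i + 4] == "GATC")


def site_is_blocked(
    dna: NucSeq,
    site_pos: int,
    enzyme: EnzymeSpec,
    methylation_marks: frozenset[int] = frozenset(),
    rules: Sequence[MethylationRule] = DEFAULT_RULES,
) -> bool:
    """Does any methylation rule block cleavage at this site?

    ``methylation_marks`` are 1-based plus-strand positions of methylated
    bases (explicit annotations; ``dam_sites`` can auto-mark GATC).
    """
    seq = dna.residues
    for rule in rules:
        if rule.enzyme != enzyme.name:
            continue
        ctx_start = site_pos - 1 - rule.site_offset  # 0-based context start
        if not _matches_at(seq, ctx_start, rule.context):
            continue
        meth_pos_1b = ctx_start + rule.methylated_pos + 1
        if meth_pos_1b in methylation_marks and rule.blocked:
            return True
    return False


def cleave(
    dna: NucSeq,
    enzyme: EnzymeSpec,
    methylation_marks: frozenset[int] = frozenset(),
    rules: Sequence[MethylationRule] = DEFAULT_RULES,
) -> list[NucSeq]:
    """Digest: fragments split at recognition_start + cut_top, skipping
    methylation-blocked sites.  Linear DNA with k cuts yields k+1 fragments;
    circular DNA yields k fragments (linearized at the first cut)."""
    seq = dna.residues
    cuts = [
        p - 1 + enzyme.cut_top  # 0-based between-base cut coordinate
        for p in find_sites(dna, enzyme)
        if not site_is_blocked(dna, p, enzyme, methylation_marks, rules)
    ]
    if not cuts:
        return [dna] if dna.is_circular is False else [dna]
    frags: list[str] = []
    if dna.is_circular:
        rotated = seq[cuts[0] :] + seq[: cuts[0]]
        rel = [c - cuts[0] for c in cuts] + [len(seq)]
        for a, b in zip(rel, rel[1:]):
            frags.append(rotated[a:b])
    else:
        bounds = [0] + cuts + [len(seq)]
        for a, b in zip(bounds, bounds[1:]):
            frags.append(seq[a:b])
    return [
        NucSeq(id=f"{dna.id}_frag{i + 1}", residues=f, topology="linear")
        for i, f in enumerate(frags)
        if f
    ]


# ---------------------------------------------------------------------------
# In-silico inverse PCR


@dataclass(frozen=True)
class Amplicon:
    sequence: str
    fragment_id: str
    fwd_pos: int  # 1-based position of the plus-strand primer 5' end on the circle
    rev_pos: int  # 1-based position of the minus-strand primer 5' end on the circle
    crosses_junction: bool


def simulate_inverse_pcr(
    genome: NucSeq,
    enzyme: EnzymeSpec,
    primers: tuple[DegeneratePrimer, DegeneratePrimer],
    max_mismatch: int = 0,
    rules: Sequence[MethylationRule] = DEFAULT_RULES,
    methylation_marks: frozenset[int] = frozenset(),
) -> list[Amplicon]:
    """Digest, self-ligate each fragment into a circle, and amplify.

    On each circular fragment, every pairing of a plus-strand binding of one
    primer with a minus-strand binding of the other yields a product running
    5'->3' from the plus primer around the circle to the minus primer's 5'
    end.  Products that span the ligation junction (the joined former
    fragment ends) are the inverse-PCR products of interest and are flagged.
    """
    fragments = cleave(genome, enzyme, methylation_marks, rules)
    if len(find_sites(genome, enzyme)) == 0:
        return []
    amplicons: list[Amplicon] = []
    for frag in fragments:
        circle = NucSeq(id=frag.id, residues=frag.residues, topology="circular")
        n = len(circle)
        hits = {0: find_binding_sites(primers[0], circle, max_mismatch),
                1: find_binding_sites(primers[1], circle, max_mismatch)}
        for i, j in ((0, 1), (1, 0)):
            for fwd_pos, fwd_strand, _ in hits[i]:
                if fwd_strand != "+":
                    continue
                for rev_pos, rev_strand, _ in hits[j]:
                    if rev_strand != "-":
                        continue
                    # product spans fwd_pos .. rev_pos walking forward, wrapping
                    length = (rev_pos - fwd_pos) % n + 1
                    doubled = circle.residues * 2
                    product = doubled[fwd_pos - 1 : fwd_pos - 1 + length]
                    crosses = fwd_pos + length - 1 > n
                    amplicons.append(
                        Amplicon(
                            sequence=product,
                            fragment_id=frag.id,
                            fwd_pos=fwd_pos,
                            rev_pos=rev_pos,
                            crosses_junction=crosses,
                        )
                    )
    amplicons.sort(key=lambda a: (a.fragment_id, a.fwd_pos, a.rev_pos))
    return amplicons


# ---------------------------------------------------------------------------
# Methylation-type evidence vote


@dataclass(frozen=True)
class MethylationEvidence:
    """The experimental observations bearing on N6mA vs N4mC for one methylase."""

    dotblot_n6ma: str = "untested"  # pos | neg | untested
    dotblot_n4mc: str = "untested"
    mrr_restricted: str = "untested"  # yes | no | untested
    dam_overlap_cleaved: str = "untested"  # yes | no | untested
    homology_hint: str = "none"  # N6mA | N4mC | none

    def __post_init__(self) -> None:
        for f, allowed in (
            (self.dotblot_n6ma, {"pos", "neg", "untested"}),
            (self.dotblot_n4mc, {"pos", "neg", "untested"}),
            (self.mrr_restricted, {"yes", "no", "untested"}),
            (self.dam_overlap_cleaved, {"yes", "no", "untested"}),
            (self.homology_hint, {"N6mA", "N4mC", "none"}),
        ):
            if f not in allowed:
                raise ValueError(f"invalid evidence value {f!r}")


def call_methylation_type(ev: MethylationEvidence) -> tuple[str, tuple[str, ...]]:
    """Transparent majority vote over the evidence fields.

    Votes: a positive N6mA dot blot -> N6mA; positive N4mC dot blot ->
    N4mC; Mrr restriction of the methylase-carrying plasmid -> N6mA (Mrr
    restricts adenine-methylated DNA here), non-restriction leans N4mC;
    cleavage of the Dam-methylated overlap context leans N4mC (the shared A
    is evidently not the protected base), blocking leans N6mA; a homology
    hint votes its type.  Majority wins; a tie is inconclusive.
    """
    votes: list[tuple[str, str]] = []
    if ev.dotblot_n6ma == "pos":
        votes.append(("N6mA", "N6mA dot blot positive"))
    if ev.dotblot_n4mc == "pos":
        votes.append(("N4mC", "N4mC dot blot positive"))
    if ev.mrr_restricted == "yes":
        votes.append(("N6mA", "plasmid restricted by Mrr"))
    elif ev.mrr_restricted == "no":
        votes.append(("N4mC", "plasmid not restricted by Mrr"))
    if ev.dam_overlap_cleaved == "no":
        votes.append(("N6mA", "Dam-methylated overlap site blocked"))
    elif ev.dam_overlap_cleaved == "yes":
        votes.append(("N4mC", "Dam-methylated overlap site still cleaved"))
    if ev.homology_hint in ("N6mA", "N4mC"):
        votes.append((ev.homology_hint, f"homology to known {ev.homology_hint} methylases"))
    if not votes:
        raise ValueError("no evidence: every field is untested")
    rationale = tuple(f"{t}: {why}" for t, why in votes)
    n6 = sum(1 for t, _ in votes if t == "N6mA")
    n4 = len(votes) - n6
    if n6 > n4:
        return "N6mA", rationale
    if n4 > n6:
        return "N4mC", rationale
    return "inconclusive", rationale


# ---------------------------------------------------------------------------
# Gene-table I/O (GFF-like TSV: name, role, start, end, strand)


def write_gene_table(genes: Iterable[Gene], path: str | Path) -> None:
    lines = ["name\trole\tstart\tend\tstrand"]
    lines += [f"{g.name}\t{g.role}\t{g.start}\t{g.end}\t{g.strand}" for g in genes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_table(path: str | Path) -> tuple[Gene, ...]:
    lines = Path(path).read_text().splitlines()
    genes = []
    for line in lines[1:]:
        if not line.strip():
            continue
        name, role, start, end, strand = line.split("\t")
        genes.append(Gene(name=name, role=role, start=int(start), end=int(end), strand=strand))
    return tuple(genes)
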