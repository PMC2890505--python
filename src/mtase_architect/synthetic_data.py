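"""Synthetic inputs with ground truth for every pipeline stage.

Three generators: methyltransferase proteins with motif blocks planted in
the canonical order of a chosen group (alpha, beta, gamma, or the
NruI/Sbo13I-like gamma subgroup); R-M loci with R/M(/C) ORFs in configured
orientations and an intergenic gap; and protein families mutated from a
common parent along a recorded tree, with substitutions biased to stay
within conservation groups.  Every emitted record carries a truth object
whose coordinates can be verified by slicing the emitted sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alphabet_core import AMINO_ACIDS, HYDROPHOBIC, DEFAULT_SCHEME, ConservationScheme, NucSeq, ProteinSeq, reverse_complement
from .motif_scan import MotifDef, MotifElement, load_motif_config, parse_motif_config
from .rm_locus import Gene, RMLocus

_AA = sorted(AMINO_ACIDS)
_HYDRO = sorted(HYDROPHOBIC)

#: Canonical planted motif orders per group (TRD slot = where the
#: target-recognition domain's spacer goes).  Motifs III and VIII are left
#: out: they have no residue consensus, so nothing concrete can be planted.
GROUP_ORDERS: dict[str, tuple[str, ...]] = {
    "alpha": ("X", "I", "II", "TRD", "IV", "V", "VI", "VII"),
    "beta": ("IV", "V", "VI", "VII", "TRD", "X", "I", "II"),
    "gamma": ("X", "I", "II", "IV", "V", "VI", "VII", "TRD"),
    "subgroup": ("Xa", "X", "I", "II", "IV", "IVa", "V", "VI", "VII", "TRD"),
}

#: Motif IV variant planted per group (gamma uses NPPY; the subgroup's
#: signature is DPPY in a gamma order).
GROUP_IV_VARIANT: dict[str, str] = {"alpha": "D", "beta": "D", "gamma": "N", "subgroup": "D"}

#: Synthetic stand-in patterns for motifs IVa and Xa, whose real consensus
#: exists only as figure content: concrete, arbitrary block patterns that the
#: generator plants and the scanner finds via configuration.
SYNTHETIC_EXTRA_MOTIFS = """\
IVa     pattern      S-W-E-x-K-P
Xa      pattern      W-K-D-x-R-C
"""

#: Default scan/plant configuration for synthetic runs: the prose-derived
#: defaults plus the synthetic IVa/Xa block patterns.
def synthetic_motif_config() -> dict[str, MotifDef]:
    config = load_motif_config()
    config.update(parse_motif_config(SYNTHETIC_EXTRA_MOTIFS))
    return config


@dataclass(frozen=True)
class PlantedMotif:
    label: str
    start: int  # 1-based inclusive
    end: int
    variant: str = ""


@dataclass(frozen=True)
class SyntheticTruth:
    group: str = ""
    motifs: tuple[PlantedMotif, ...] = ()
    trd_span: tuple[int, int] | None = None
    tree_newick: str = ""
    bipartition: tuple[frozenset[str], frozenset[str]] | None = None
    genes: tuple[Gene, ...] = ()
    gap_bp: int | None = None
    planted_sites: tuple[int, ...] = ()


def _sample_pattern_instance(elements: Sequence[MotifElement], rng: np.random.Generator) -> str:
    """One concrete string matching a compiled pattern (spacers at min length)."""
    out = []
    for e in elements:
        if e.kind == "spacer":
            out.extend(rng.choice(_AA) for _ in range(e.min_len))
        elif e.kind == "any":
            out.append(rng.choice(_AA))
        else:  # set or group
            out.append(rng.choice(sorted(e.residues)))
    return "".join(out)


def gen_mtase(
    group: str,
    length: int = 320,
    noise: float = 0.0,
    seed: int = 0,
    motif_config: Mapping[str, MotifDef] | None = None,
    min_trd: int = 60,
    noise_in_motifs: bool = False,
) -> tuple[ProteinSeq, SyntheticTruth]:
    """A synthetic methyltransferase with motif blocks in the group's order.

    Background residues are uniform over the 20 amino acids; each motif
    instance is sampled from its pattern's residue sets (fully hydrophobic
    windows for window-type motifs); the TRD is a motif-free spacer of at
    least ``min_trd`` residues at the group's canonical position.  ``noise``
    substitutes that fraction of residues outside planted motifs (inside
    too if ``noise_in_motifs``).
    """
    if group not in GROUP_ORDERS:
        raise ValueError(f"unknown group {group!r}; choose from {sorted(GROUP_ORDERS)}")
    rng = np.random.default_rng(seed)
    config = dict(motif_config if motif_config is not None else synthetic_motif_config())
    order = GROUP_ORDERS[group]
    iv_variant = GROUP_IV_VARIANT[group]

    instances: list[tuple[str, str]] = []  # (label, concrete string); TRD slot -> ("TRD","")
    for label in order:
        if label == "TRD":
            instances.append(("TRD", ""))
            continue
        d = config.get(label)
        if d is None:
            raise ValueError(f"motif config lacks a pattern for planted motif {label}")
        if d.kind == "pattern":
            model = d.compiled()
            elems = list(model.elements)
            if label == "IV":
                elems[0] = MotifElement(kind="set", residues=frozenset(iv_variant))
            instances.append((label, _sample_pattern_instance(elems, rng)))
        else:
            instances.append((label, "".join(rng.choice(_HYDRO) for _ in range(d.window))))

    n_blocks = sum(1 for lbl, _ in instances if lbl != "TRD")
    total_motif = sum(len(s) for _, s in instances)
    # inter-block linkers: short random gaps; TRD slot gets the long spacer
    min_linker, max_linker = 4, 12
    min_needed = total_motif + min_trd + (n_blocks - 1) * min_linker + 2 * min_linker
    if length < min_needed:
        raise ValueError(f"length {length} too short; need at least {min_needed} for group {group}")

    linker_slots = n_blocks + 1  # before first, between blocks, after last (TRD folded in)
    linkers = [int(rng.integers(min_linker, max_linker + 1)) for _ in range(linker_slots)]
    budget = length - total_motif - sum(linkers) - min_trd
    if budget < 0:
        linkers = [min_linker] * linker_slots
        budget = length - total_motif - sum(linkers) - min_trd
    trd_len = min_trd + budget  # remaining residues enlarge the TRD

    seq: list[str] = []
    motifs: list[PlantedMotif] = []
    trd_span: tuple[int, int] | None = None
    li = 0

    def bg(k: int) -> None:
        seq.extend(rng.choice(_AA) for _ in range(k))

    bg(linkers[li]); li += 1
    for label, s in instances:
        if label == "TRD":
            start = len(seq) + 1
            bg(trd_len)
            trd_span = (start, len(seq))
            continue
        start = len(seq) + 1
        seq.extend(s)
        variant = iv_variant if label == "IV" else ""
        motifs.append(PlantedMotif(label=label, start=start, end=len(seq), variant=variant))
        if li < len(linkers):
            bg(linkers[li]); li += 1
    if len(seq) < length:
        # pad at the very end; for TRD-terminal groups this extends the TRD
        start_pad = len(seq) + 1
        bg(length - len(seq))
        if order[-1] == "TRD" and trd_span is not None:
            trd_span = (trd_span[0], len(seq))
    seq = seq[:length]

    protected = np.zeros(length, dtype=bool)
    if not noise_in_motifs:
        for m in motifs:
            protected[m.start - 1 : m.end] = True
    if noise > 0:
        for i in range(length):
            if not protected[i] and rng.random() < noise:
                seq[i] = rng.choice(_AA)

    protein = ProteinSeq(id=f"syn_{group}_{seed}", residues="".join(seq))
    truth = SyntheticTruth(group=group, motifs=tuple(motifs), trd_span=trd_span)
    return protein, truth


# ---------------------------------------------------------------------------
# Sequence families


def _mutate(
    residues: str,
    n_subs: int,
    rng: np.random.Generator,
    scheme: ConservationScheme,
    within_group_prob: float,
) -> str:
    seq = list(residues)
    if not seq:
        return residues
    positions = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for i in positions:
        g = scheme.group_of(seq[i])
        if g is not None and len(g) > 1 and rng.random() < within_group_prob:
            choices = sorted(g - {seq[i]})
        else:
            choices = sorted(AMINO_ACIDS - {seq[i]})
        seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


def gen_family(
    parent_length: int = 200,
    n_leaves: int = 6,
    subs_per_branch: int = 6,
    seed: int = 0,
    scheme: ConservationScheme = DEFAULT_SCHEME,
    within_group_prob: float = 0.7,
    deep_subs: int | None = None,
) -> tuple[list[ProteinSeq], SyntheticTruth]:
    """A protein family produced by duplicate-and-mutate along a binary tree.

    The root is split into two clades; the branch into each clade carries
    ``deep_subs`` substitutions (default 5x the within-clade rate), then
    leaves within a clade each diverge by ``subs_per_branch``.  Truth is the
    clade bipartition (and a newick string of the generating topology).
    Substitutions stay within the residue's conservation group with
    probability ``within_group_prob``.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    parent = "".join(rng.choice(_AA) for _ in range(parent_length))
    if deep_subs is None:
        deep_subs = 5 * subs_per_branch
    n_a = (n_leaves + 1) // 2
    ancestors = {
        "A": _mutate(parent, deep_subs, rng, scheme, within_group_prob),
        "B": _mutate(parent, deep_subs, rng, scheme, within_group_prob),
    }
    leaves: list[ProteinSeq] = []
    clade_a: list[str] = []
    clade_b: list[str] = []
    for i in range(n_leaves):
        clade = "A" if i < n_a else "B"
        name = f"{clade}{i if clade == 'A' else i - n_a}"
        residues = _mutate(ancestors[clade], subs_per_branch, rng, scheme, within_group_prob)
        leaves.append(ProteinSeq(id=name, residues=residues))
        (clade_a if clade == "A" else clade_b).append(name)
    newick = f"(({','.join(clade_a)}),({','.join(clade_b)}));"
    truth = SyntheticTruth(
        tree_newick=newick,
        bipartition=(frozenset(clade_a), frozenset(clade_b)),
    )
    return leaves, truth


# ---------------------------------------------------------------------------
# R-M loci


@dataclass(frozen=True)
class GeneRequest:
    name: str
    role: str  # R | M | C
    length_bp: int  # complete ORF including stop; divisible by 3
    strand: str


#: NruI-like default geometry: divergent R and M with a 326-bp gap.
NRUI_LIKE = (
    GeneRequest(name="nruIR", role="R", length_bp=660, strand="-"),
    GeneRequest(name="nruIM", role="M", length_bp=804, strand="+"),
)
#: Sbo13I-like: controller + R tandem, M opposite.
SBO13I_LIKE = (
    GeneRequest(name="sbo13IC", role="C", length_bp=240, strand="+"),
    GeneRequest(name="sbo13IR", role="R", length_bp=660, strand="+"),
    GeneRequest(name="sbo13IM", role="M", length_bp=804, strand="-"),
)

_STOPS = ("TAA", "TAG", "TGA")


def _random_orf(length_bp: int, rng: np.random.Generator, gc: float) -> str:
    """A plausible ORF: ATG, random non-stop codons, one stop codon."""
    if length_bp % 3 != 0 or length_bp < 6:
        raise ValueError(f"ORF length {length_bp} must be >= 6 and divisible by 3")
    bases = "ACGT"
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codons = ["ATG"]
    for _ in range(length_bp // 3 - 2):
        while True:
            codon = "".join(rng.choice(list(bases), p=p) for _ in range(3))
            if codon not in _STOPS:
                break
        codons.append(codon)
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), p=p) for _ in range(n))


def gen_rm_locus(
    genes: Sequence[GeneRequest] = NRUI_LIKE,
    gap_bp: int | Sequence[int] = 326,
    flank_bp: int = 60,
    seed: int = 0,
    gc: float = 0.5,
    plant_sites: Sequence[int] = (),
    dam_overlap: bool = False,
) -> tuple[RMLocus, SyntheticTruth]:
    """An R-M locus with the requested gene geometry and intergenic gap(s).

    ``gap_bp`` is one gap size for all adjacent pairs or one per pair.
    ``plant_sites`` gives 1-based positions (within the final sequence)
    where a TCGCGA site is written over the background; with
    ``dam_overlap`` each planted site is extended to the TCGCGATC context.
    Planted sites must fall outside gene extents.
    """
    rng = np.random.default_rng(seed)
    n_gaps = len(genes) - 1
    gaps = [gap_bp] * n_gaps if isinstance(gap_bp, int) else list(gap_bp)
    if len(gaps) != n_gaps:
        raise ValueError(f"need {n_gaps} gap sizes, got {len(gaps)}")
    parts: list[str] = [_random_dna(flank_bp, rng, gc)]
    placed: list[Gene] = []
    pos = flank_bp
    for i, req in enumerate(genes):
        orf = _random_orf(req.length_bp, rng, gc)
        if req.strand == "-":
            orf = reverse_complement(orf)
        start = pos + 1
        parts.append(orf)
        pos += req.length_bp
        placed.append(Gene(name=req.name, role=req.role, start=start, end=pos, strand=req.strand))
        if i < n_gaps:
            if gaps[i] < 0:
                raise ValueError("overlapping requested genes (negative gap)")
            parts.append(_random_dna(gaps[i], rng, gc))
            pos += gaps[i]
    parts.append(_random_dna(flank_bp, rng, gc))
    seq = list("".join(parts))

    site = "TCGCGATC" if dam_overlap else "TCGCGA"
    for sp in plant_sites:
        if sp < 1 or sp + len(site) - 1 > len(seq):
            raise ValueError(f"planted site at {sp} falls outside the locus")
        for g in placed:
            if not (sp + len(site) - 1 < g.start or sp > g.end):
                raise ValueError(f"planted site at {sp} overlaps gene {g.name}")
        seq[sp - 1 : sp - 1 + len(site)] = site
    # scrub accidental recognition sites so planted ones are the only ones
    keep = set(plant_sites)
    text = "".join(seq)
    i = text.find("TCGCGA")
    while i != -1:
        if (i + 1) in keep:
            i = text.find("TCGCGA", i + 1)
            continue
        seq[i] = "A" if seq[i] != "A" else "G"
        text = "".join(seq)
        i = text.find("TCGCGA", max(i - 5, 0))  # a mutation could shift a site

    locus = RMLocus(
        sequence=NucSeq(id=f"syn_locus_{seed}", residues="".join(seq)),
        genes=tuple(placed),
    )
    truth = SyntheticTruth(
        genes=tuple(placed),
        gap_bp=gaps[0] if gaps else None,
        planted_sites=tuple(plant_sites),
    )
    return locus, truth
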