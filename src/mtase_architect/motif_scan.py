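"""Motif-block models and scanners for amino-methyltransferase proteins.

Amino-methyltransferases carry short conserved blocks (motifs X, I, II, III
around AdoMet binding; IV--VIII around catalysis) whose prose consensus can
be written in a small pattern language:

    element      meaning
    ``G``        literal residue
    ``[DNS]``    any residue of the set (variant-bearing when >1 residue)
    ``x``        any amino acid (never X-the-unknown)
    ``x(m,n)``   spacer of m..n arbitrary residues
    ``@VLIM``    conservation-group wildcard (matches the group, scores 0.5)

Elements are joined with ``-``: ``"[DNS]-P-P-Y"`` is the catalytic P-loop,
with variant D/N/S read off the first element.  Hydrophobic blocks (motifs
VII and X) have no residue consensus and are found as windows with a
minimum count of hydrophobic residues instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .alphabet_core import AMINO_ACIDS, HYDROPHOBIC, ProteinSeq

#: Motif label vocabulary (III and VIII exist as labels but ship no default pattern).
MOTIF_LABELS = ("Xa", "X", "I", "II", "III", "IV", "IVa", "V", "VI", "VII", "VIII")


@dataclass(frozen=True)
class MotifElement:
    kind: str  # set | any | group | spacer
    residues: frozenset[str] = frozenset()
    min_len: int = 1
    max_len: int = 1


@dataclass(frozen=True)
class MotifModel:
    label: str
    elements: tuple[MotifElement, ...]
    spec: str = ""

    def __post_init__(self) -> None:
        if not any(e.kind != "spacer" for e in self.elements):
            raise ValueError(f"motif {self.label}: needs at least one non-spacer element")
        for e in self.elements:
            if e.kind == "spacer" and not (0 <= e.min_len <= e.max_len):
                raise ValueError(f"motif {self.label}: bad spacer bounds {e.min_len}..{e.max_len}")

    @property
    def variant_element(self) -> int | None:
        """Index of the element whose matched residue names the variant
        (first multi-residue literal set), or None."""
        for i, e in enumerate(self.elements):
            if e.kind == "set" and len(e.residues) > 1:
                return i
        return None


@dataclass(frozen=True)
class MotifHit:
    motif_label: str
    variant_tag: str
    start: int  # 1-based inclusive
    end: int
    matched: str
    score: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad hit coordinates {self.start}..{self.end}")


_TOKEN_RE = re.compile(
    r"""^(?:
        (?P<spacer>x\((?P<min>\d+),(?P<max>\d+)\)) |
        (?P<any>x) |
        (?P<set>\[(?P<setres>[A-WYZ]+)\]) |
        (?P<group>@(?P<groupres>[A-WYZ]+)) |
        (?P<single>[A-WYZ])
    )$""",
    re.VERBOSE,
)


def compile_motif(spec: str, label: str = "?") -> MotifModel:
    """Compile a text pattern into a MotifModel; errors name the bad token."""
    elements: list[MotifElement] = []
    for i, tok in enumerate(spec.strip().split("-")):
        m = _TOKEN_RE.match(tok)
        if m is None:
            raise ValueError(f"motif pattern {spec!r}: cannot parse token {tok!r} (element {i + 1})")
        if m.group("spacer"):
            elements.append(
                MotifElement(kind="spacer", min_len=int(m.group("min")), max_len=int(m.group("max")))
            )
        elif m.group("any"):
            elements.append(MotifElement(kind="any"))
        elif m.group("set"):
            res = frozenset(m.group("setres"))
            _check_residues(res, spec, i)
            elements.append(MotifElement(kind="set", residues=res))
        elif m.group("group"):
            res = frozenset(m.group("groupres"))
            _check_residues(res, spec, i)
            elements.append(MotifElement(kind="group", residues=res))
        else:
            res = frozenset(m.group("single"))
            _check_residues(res, spec, i)
            elements.append(MotifElement(kind="set", residues=res))
    return MotifModel(label=label, elements=tuple(elements), spec=spec.strip())


def _check_residues(res: frozenset[str], spec: str, i: int) -> None:
    bad = res - AMINO_ACIDS
    if bad:
        raise ValueError(f"motif pattern {spec!r}: invalid residues {sorted(bad)} (element {i + 1})")


def _element_match(e: MotifElement, residue: str) -> float | None:
    """Per-position score: 1 for literal/any match, 0.5 via group wildcard,
    None for no match.  X (unidentified residue) matches nothing."""
    if residue == "X":
        return None
    if e.kind == "set":
        return 1.0 if residue in e.residues else None
    if e.kind == "any":
        return 1.0
    if e.kind == "group":
        return 0.5 if residue in e.residues else None
    raise AssertionError(e.kind)


def scan(protein: ProteinSeq, model: MotifModel) -> list[MotifHit]:
    """All matches of a motif model, including overlapping ones.

    Order is deterministic: by start position, then shorter match first.
    Spacer positions may contain anything (including X); score is the mean
    per-position score over non-spacer elements.
    """
    seq = protein.residues
    hits: list[MotifHit] = []

    def extend(pos: int, elem_idx: int, scores: list[float], start: int, variant: str) -> None:
        if elem_idx == len(model.elements):
            hits.append(
                MotifHit(
                    motif_label=model.label,
                    variant_tag=variant,
                    start=start + 1,
                    end=pos,
                    matched=seq[start:pos],
                    score=sum(scores) / len(scores),
                )
            )
            return
        e = model.elements[elem_idx]
        if e.kind == "spacer":
            for gap in range(e.min_len, e.max_len + 1):
                if pos + gap <= len(seq):
                    extend(pos + gap, elem_idx + 1, scores, start, variant)
            return
        if pos >= len(seq):
            return
        s = _element_match(e, seq[pos])
        if s is None:
            return
        v = variant
        if model.variant_element == elem_idx:
            v = seq[pos]
        extend(pos + 1, elem_idx + 1, scores + [s], start, v)

    for start in range(len(seq)):
        extend(start, 0, [], start, "")
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


# ---------------------------------------------------------------------------
# Endonuclease catalytic sites


@dataclass(frozen=True)
class CatalyticSiteModel:
    """Dyad + spacer + tail pattern, e.g. [PD]-D ... x(21,21) ... E-V-K."""

    dyad: str = "[PD]-D"
    spacer: tuple[int, int] = (21, 21)
    tail: str = "E-V-K"

    def to_motif(self) -> MotifModel:
        lo, hi = self.spacer
        if not 0 <= lo <= hi:
            raise ValueError(f"bad spacer bounds {lo}..{hi}")
        return compile_motif(f"{self.dyad}-x({lo},{hi})-{self.tail}", label="catalytic")


#: PD/DD-X21-EVK site seen in the NruI/Sbo13I-type endonucleases.
PD_EVK_SITE = CatalyticSiteModel()
#: DD-X20-QIK, the Mrr-endonuclease-like catalytic site.
MRR_LIKE_SITE = CatalyticSiteModel(dyad="D-D", spacer=(20, 20), tail="Q-I-K")


@dataclass(frozen=True)
class CatalyticHit:
    start: int
    end: int
    spacer_len: int
    matched: str


def scan_catalytic(protein: ProteinSeq, model: CatalyticSiteModel = PD_EVK_SITE) -> list[CatalyticHit]:
    """Every placement where dyad, spacer length within bounds, and tail match."""
    motif = model.to_motif()
    n_dyad = len(model.dyad.split("-"))
    n_tail = len(model.tail.split("-"))
    out = []
    for h in scan(protein, motif):
        span = h.end - h.start + 1
        out.append(
            CatalyticHit(start=h.start, end=h.end, spacer_len=span - n_dyad - n_tail, matched=h.matched)
        )
    return out


# ---------------------------------------------------------------------------
# Hydrophobic blocks (motifs VII and X carry no residue consensus)


def scan_hydrophobic_block(
    protein: ProteinSeq,
    window: int = 5,
    min_hydrophobic: int = 4,
    region: tuple[int, int] | None = None,
    label: str = "hydrophobic",
) -> list[MotifHit]:
    """Windows whose hydrophobic-residue count meets the threshold.

    Hydrophobic set: V, L, I, M, F, Y, W, A.  Overlapping qualifying
    windows are reduced to local maxima: windows are ranked by hydrophobic
    fraction (ties to the leftmost) and kept greedily without overlap, so a
    5/5 core is reported once rather than as three shifted 4/5 windows.
    ``region`` restricts the scan to 1-based inclusive coordinates.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(protein)
    lo, hi = region if region is not None else (1, n)
    if region is not None and not (1 <= lo <= hi):
        raise ValueError(f"bad region {lo}..{hi}")
    if lo > n:
        raise ValueError(f"region {lo}..{hi} outside protein of length {n}")
    hi = min(hi, n)
    seq = protein.residues
    candidates: list[MotifHit] = []
    for start in range(lo - 1, hi - window + 1):
        win = seq[start : start + window]
        count = sum(1 for r in win if r in HYDROPHOBIC)
        if count >= min_hydrophobic:
            candidates.append(
                MotifHit(
                    motif_label=label,
                    variant_tag="",
                    start=start + 1,
                    end=start + window,
                    matched=win,
                    score=count / window,
                )
            )
    candidates.sort(key=lambda h: (-h.score, h.start))
    kept: list[MotifHit] = []
    for c in candidates:
        if all(c.end < k.start or c.start > k.end for k in kept):
            kept.append(c)
    kept.sort(key=lambda h: h.start)
    return kept


# ---------------------------------------------------------------------------
# Motif configuration (one motif per record; plain text, editable)

#: Default motif definitions distilled from the prose consensus of each block.
#: Motifs III and VIII have no published consensus and are disabled; motifs
#: IVa and Xa have no default pattern at all (their consensus is figure-only)
#: and must come from user configuration.
DEFAULT_MOTIF_CONFIG = """\
# label  kind         definition
I       pattern      G-x-G
II      pattern      [DE]-[IL]
IV      pattern      [DNS]-P-P-Y
V       pattern      D-L-Y-x-x-A-[GS]
VI      pattern      G-x(1,6)-[VLIM]
VII     hydrophobic  window=5 min=4
X       hydrophobic  window=5 min=4
"""

#: Standard-γ motif V consensus, for comparison against the family variant.
STANDARD_GAMMA_V = "[ND]-L-Y-x-x-F-[LVI]"


@dataclass(frozen=True)
class MotifDef:
    label: str
    kind: str  # pattern | hydrophobic
    pattern: str = ""
    window: int = 5
    min_hydrophobic: int = 4
    region: tuple[int, int] | None = None

    def compiled(self) -> MotifModel:
        if self.kind != "pattern":
            raise ValueError(f"motif {self.label} is not a pattern motif")
        return compile_motif(self.pattern, label=self.label)


def parse_motif_config(text: str) -> dict[str, MotifDef]:
    """Parse the one-motif-per-line config dialect (see DEFAULT_MOTIF_CONFIG)."""
    defs: dict[str, MotifDef] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"motif config line {lineno}: expected 'label kind definition'")
        label, kind = parts[0], parts[1]
        if label in defs:
            raise ValueError(f"motif config line {lineno}: duplicate label {label}")
        if kind == "pattern":
            d = MotifDef(label=label, kind="pattern", pattern=parts[2])
            d.compiled()  # validate eagerly
        elif kind == "hydrophobic":
            kv = dict(p.split("=", 1) for p in parts[2:])
            region = None
            if "region" in kv:
                a, b = kv["region"].split(":")
                region = (int(a), int(b))
            d = MotifDef(
                label=label,
                kind="hydrophobic",
                window=int(kv.get("window", 5)),
                min_hydrophobic=int(kv.get("min", 4)),
                region=region,
            )
        else:
            raise ValueError(f"motif config line {lineno}: unknown kind {kind!r}")
        defs[label] = d
    return defs


def load_motif_config(path: str | Path | None = None) -> dict[str, MotifDef]:
    if path is None:
        return parse_motif_config(DEFAULT_MOTIF_CONFIG)
    return parse_motif_config(Path(path).read_text())


def scan_all(protein: ProteinSeq, config: dict[str, MotifDef] | None = None) -> list[MotifHit]:
    """Scan a protein with every motif in a config; hits sorted by start."""
    config = config if config is not None else load_motif_config()
    hits: list[MotifHit] = []
    for label, d in config.items():
        if d.kind == "pattern":
            hits.extend(scan(protein, d.compiled()))
        else:
            region = d.region
            if region is not None and region[0] > len(protein):
                continue
            hits.extend(
                scan_hydrophobic_block(
                    protein, window=d.window, min_hydrophobic=d.min_hydrophobic,
                    region=region, label=label,
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.motif_label))
    return hits
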