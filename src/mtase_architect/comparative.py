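"""Comparative sequence analysis: identity/similarity, trees, and layout.

Percent identity and percent similarity are computed over alignment columns
where neither sequence is gapped; "similar" means the two residues share a
conservation group ((E,D,Q,N), (V,L,I,M), (F,Y,W), (G,P,A), (K,R), (S,T)).
Local alignment with BLOSUM62 and gap open 11 / extend 1 (the common
database-search default) is the default scoring; global mode exists for
controlled comparisons.  Families are summarized two ways: an unrooted
single-linkage (minimum-linkage) distance tree, and a 2-D force-directed
layout in which attraction is proportional to pairwise similarity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .alphabet_core import (
    AlignmentBlock,
    ConservationScheme,
    DEFAULT_SCHEME,
    GAP,
    ProteinSeq,
    same_group,
)


@dataclass(frozen=True)
class PairwiseResult:
    aligned_a: str
    aligned_b: str
    identity_pct: float
    similarity_pct: float
    aligned_length: int  # columns with no gap in either row
    score: float

    def __post_init__(self) -> None:
        if not (self.identity_pct <= self.similarity_pct + 1e-9):
            raise ValueError("identity cannot exceed similarity")


def _aligner(mode: str, gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST-style affine cost open+k*extend: Biopython charges open on the first
    # gap position, so open_gap_score = -(open + extend)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _gapped_strings(alignment) -> tuple[str, str]:
    """Build gapped strings covering only the aligned region (local-safe)."""
    t, q = alignment.target, alignment.query
    blocks_t, blocks_q = alignment.aligned
    a_parts: list[str] = []
    b_parts: list[str] = []
    prev_t = blocks_t[0][0]
    prev_q = blocks_q[0][0]
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if ts > prev_t:
            a_parts.append(str(t[prev_t:ts]))
            b_parts.append(GAP * (ts - prev_t))
        if qs > prev_q:
            a_parts.append(GAP * (qs - prev_q))
            b_parts.append(str(q[prev_q:qs]))
        a_parts.append(str(t[ts:te]))
        b_parts.append(str(q[qs:qe]))
        prev_t, prev_q = te, qe
    return "".join(a_parts), "".join(b_parts)


def percent_identity_similarity(
    aligned_a: str,
    aligned_b: str,
    scheme: ConservationScheme = DEFAULT_SCHEME,
) -> tuple[float, float, int]:
    """(identity %, similarity %, gap-free columns) for two gapped rows.

    Denominator: columns where neither row has a gap.  X counts as neither
    identical nor similar.  Similarity includes identities (a residue is
    trivially similar to itself), so similarity >= identity always.
    """
    ident = simil = denom = 0
    for a, b in zip(aligned_a, aligned_b):
        if a == GAP or b == GAP:
            continue
        denom += 1
        if a == b and a != "X":
            ident += 1
            simil += 1
        elif same_group(a, b, scheme):
            simil += 1
    if denom == 0:
        return 0.0, 0.0, 0
    return 100.0 * ident / denom, 100.0 * simil / denom, denom


def align_pair(
    a: ProteinSeq,
    b: ProteinSeq,
    mode: str = "local",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    matrix: str = "BLOSUM62",
    scheme: ConservationScheme = DEFAULT_SCHEME,
) -> PairwiseResult:
    """Optimal pairwise alignment plus identity/similarity percentages."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty sequence")
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be global or local, got {mode!r}")
    aligner = _aligner(mode, gap_open, gap_extend, matrix)
    alignment = aligner.align(a.residues, b.residues)[0]
    ga, gb = _gapped_strings(alignment)
    ident, simil, denom = percent_identity_similarity(ga, gb, scheme)
    return PairwiseResult(
        aligned_a=ga,
        aligned_b=gb,
        identity_pct=ident,
        similarity_pct=simil,
        aligned_length=denom,
        score=float(alignment.score),
    )


def consensus_line(block: AlignmentBlock, scheme: ConservationScheme = DEFAULT_SCHEME) -> str:
    """Clustal-style annotation: '*' identical column, ':' same-group column.

    A column with any gap, or containing X, is blank; '*' requires every
    residue identical (and known); ':' requires all residues to fall in a
    single conservation group without being identical.
    """
    out = []
    for j in range(block.width):
        col = block.column(j)
        if GAP in col or "X" in col:
            out.append(" ")
            continue
        if len(set(col)) == 1:
            out.append("*")
            continue
        groups = {scheme.group_of(r) for r in col}
        out.append(":" if len(groups) == 1 and None not in groups else " ")
    return "".join(out)


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (m < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "matrix", m)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def distance_matrix(
    seqs: list[ProteinSeq] | None = None,
    mode: str = "global",
    alignment: AlignmentBlock | None = None,
    **align_kwargs,
) -> DistanceMatrix:
    """Pairwise d(i,j) = 1 - identity_fraction(i,j).

    Either from per-pair optimal alignments of raw sequences, or from the
    rows of a precomputed multiple alignment (then each pair is scored on
    its gap-free columns of that alignment).
    """
    if alignment is not None:
        labels = alignment.ids
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ident, _, _ = percent_identity_similarity(alignment.rows[i], alignment.rows[j])
                m[i, j] = m[j, i] = 1.0 - ident / 100.0
        return DistanceMatrix(labels=labels, matrix=m)
    if seqs is None or len(seqs) < 2:
        raise ValueError("need >=2 sequences or a precomputed alignment")
    labels = tuple(s.id for s in seqs)
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = align_pair(seqs[i], seqs[j], mode=mode, **align_kwargs)
            m[i, j] = m[j, i] = 1.0 - res.identity_pct / 100.0
    return DistanceMatrix(labels=labels, matrix=m)


# ---------------------------------------------------------------------------
# Minimum-linkage (single-linkage) unrooted tree


@dataclass(frozen=True)
class UnrootedTree:
    root: TreeNode
    merges: tuple[tuple[float, frozenset[str], frozenset[str]], ...]

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf, format="newick")
        return buf.getvalue().strip()

    def leaf_names(self) -> frozenset[str]:
        return frozenset(t.name for t in self.root.tips())


def minimum_linkage_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Agglomerative single-linkage clustering rendered as an unrooted tree.

    Inter-cluster distance is the minimum pairwise distance; merge heights
    are therefore non-decreasing.  Ties break toward the lexicographically
    smallest (representative label) pair, so the result is deterministic.
    Branch lengths are ultrametric: leaves sit at depth height/2 below each
    merge.  The root of the final merge is suppressed into a trifurcation
    where possible, yielding an unrooted topology.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 labels to build a tree")
    # cluster state: representative = min label, members, node, height
    clusters: dict[str, dict] = {
        lab: {"members": frozenset([lab]), "node": TreeNode(name=lab, length=None), "height": 0.0}
        for lab in dm.labels
    }
    # single-linkage distance between clusters
    def linkage(c1: dict, c2: dict) -> float:
        return min(dm.get(a, b) for a in c1["members"] for b in c2["members"])

    merges: list[tuple[float, frozenset[str], frozenset[str]]] = []
    while len(clusters) > 1:
        reps = sorted(clusters)
        best: tuple[float, str, str] | None = None
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                d = linkage(clusters[r1], clusters[r2])
                cand = (d, r1, r2)
                if best is None or cand < best:
                    best = cand
        d, r1, r2 = best
        c1, c2 = clusters.pop(r1), clusters.pop(r2)
        h = d
        node = TreeNode(children=[c1["node"], c2["node"]])
        c1["node"].length = max(h / 2.0 - c1["height"], 0.0)
        c2["node"].length = max(h / 2.0 - c2["height"], 0.0)
        merges.append((h, c1["members"], c2["members"]))
        clusters[min(r1, r2)] = {
            "members": c1["members"] | c2["members"],
            "node": node,
            "height": h / 2.0,
        }
    root = next(iter(clusters.values()))["node"]
    root = _suppress_root(root)
    return UnrootedTree(root=root, merges=tuple(merges))


def _suppress_root(root: TreeNode) -> TreeNode:
    """Fold the top bifurcation into a trifurcation (unrooted convention)."""
    if len(root.children) != 2:
        return root
    a, b = root.children
    internal = b if not b.is_tip() else (a if not a.is_tip() else None)
    if internal is None:
        return root  # two leaves: a single edge, nothing to suppress
    other = a if internal is b else b
    root.remove(internal)
    root.remove(other)
    other.length = (other.length or 0.0) + (internal.length or 0.0)
    for child in list(internal.children):
        internal.remove(child)
        root.append(child)
    root.append(other)
    return root


# ---------------------------------------------------------------------------
# Force-directed similarity layout


@dataclass(frozen=True)
class LayoutResult:
    labels: tuple[str, ...]
    coords: np.ndarray  # (n, 2)
    seed: int
    iterations: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords).all():
            raise ValueError("layout produced non-finite coordinates")


def force_layout(
    similarity: np.ndarray,
    labels: tuple[str, ...] | None = None,
    iterations: int = 300,
    seed: int = 0,
    k: float = 1.0,
) -> LayoutResult:
    """Fruchterman-Reingold-style layout driven by a similarity matrix.

    Attraction between i and j is k * s_ij * d (proportional to similarity
    and distance); repulsion is uniform k^2 / d for every pair; displacement
    per step is capped by a linearly cooling temperature.  Fixed seed =>
    reproducible coordinates.  A single node is placed at the origin.
    """
    s = np.asarray(similarity, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if not np.allclose(s, s.T):
        raise ValueError("similarity matrix is not symmetric")
    if s.min() < -1e-12 or s.max() > 1 + 1e-12:
        raise ValueError("similarities must lie in [0, 1]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n = s.shape[0]
    if labels is None:
        labels = tuple(str(i) for i in range(n))
    if n == 1:
        return LayoutResult(labels=labels, coords=np.zeros((1, 2)), seed=seed, iterations=iterations)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    t0 = 0.1 * max(np.sqrt(n), 1.0)
    for it in range(iterations):
        t = t0 * (1.0 - it / iterations)  # linear cooling
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-6)
        unit = delta / dist[..., None]
        rep = (k * k / dist)[..., None] * unit
        att = (k * s * dist)[..., None] * unit
        disp = (rep - att).sum(axis=1)
        norms = np.maximum(np.linalg.norm(disp, axis=1), 1e-12)
        step = np.minimum(norms, t)
        pos = pos + disp / norms[:, None] * step[:, None]
    pos = pos - pos.mean(axis=0)
    return LayoutResult(labels=labels, coords=pos, seed=seed, iterations=iterations)
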