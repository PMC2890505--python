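"""Linear motif-block architecture of a methyltransferase and its group call.

Amino-methyltransferase groups are defined by the order of three regions:
the AdoMet-binding motif cluster (X-I-II-III), the catalytic cluster
(IV-V-VI-VII-VIII), and the target-recognition domain (TRD):

    alpha:  AdoMet - TRD - catalytic          (motif IV = DPPY)
    beta:   catalytic - TRD - AdoMet          (motif IV = DPPY or SPPY)
    gamma:  AdoMet - catalytic - TRD          (motif IV = NPPY)

The NruI/Sbo13I-type subgroup is a gamma-order architecture whose motif IV
is DPPY rather than NPPY and which carries two extra blocks, Xa (N-terminal)
and IVa (between IV and V).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

from .alphabet_core import ProteinSeq
from .motif_scan import MotifDef, MotifHit, load_motif_config, scan_all

#: Canonical within-cluster label orders (left-to-right along the sequence).
ADOMET_ORDER: tuple[str, ...] = ("Xa", "X", "I", "II", "III")
CATALYTIC_ORDER: tuple[str, ...] = ("IV", "IVa", "V", "VI", "VII", "VIII")

#: Labels counted toward the cluster-presence thresholds.
ADOMET_CORE = frozenset(("X", "I", "II", "III"))
CATALYTIC_SUPPORT = frozenset(("V", "VI", "VII"))

DEFAULT_MIN_TRD = 40  # aa; a TRD is a domain, not a gap


def cluster_of(label: str) -> str | None:
    if label in ADOMET_ORDER:
        return "adomet"
    if label in CATALYTIC_ORDER:
        return "catalytic"
    return None


@dataclass(frozen=True)
class MethylaseArchitecture:
    hits: tuple[MotifHit, ...]
    trd_span: tuple[int, int] | None = None
    group_call: str = "unclassified"  # alpha | beta | gamma | unclassified
    subgroup_flag: bool = False
    evidence: tuple[str, ...] = ()

    def order_string(self) -> str:
        """Motif order with the TRD inserted positionally, e.g. 'X-I-II-III-IV-TRD'."""
        items: list[tuple[int, str]] = [(h.start, h.motif_label) for h in self.hits]
        if self.trd_span is not None:
            items.append((self.trd_span[0], "TRD"))
        return "-".join(lbl for _, lbl in sorted(items))


# ---------------------------------------------------------------------------
# Hit selection


def assignment_key(hits: Sequence[MotifHit]) -> tuple[float, float, float, float]:
    """Ranking key for a candidate hit assignment (higher is better).

    Primary: total score.  Ties: smaller summed cluster span (compact
    clusters — motif blocks are spatially clustered, and an equal-scoring
    stray hit far from its cluster is noise), then leftmost (smaller sum of
    starts), then smaller sum of ends.  Every component is additive over
    the two cluster chains, which keeps the optimization exactly solvable.
    """
    total = sum(h.score for h in hits)
    disp = 0.0
    for cluster in ("adomet", "catalytic", None):
        members = [h for h in hits if cluster_of(h.motif_label) == cluster]
        if members:
            disp += max(h.end for h in members) - min(h.start for h in members)
    return (total, -disp, -sum(h.start for h in hits), -sum(h.end for h in hits))


@dataclass(frozen=True)
class _Chain:
    hits: tuple[MotifHit, ...]
    score: float
    sum_starts: int
    sum_ends: int

    @property
    def first_start(self) -> int:
        return self.hits[0].start if self.hits else 0

    @property
    def last_end(self) -> int:
        return self.hits[-1].end if self.hits else 0

    @property
    def span(self) -> int:
        return self.last_end - self.first_start if self.hits else 0


_EMPTY = _Chain(hits=(), score=0.0, sum_starts=0, sum_ends=0)


def _forward_chains(cluster_hits: list[MotifHit], order: tuple[str, ...]) -> list[_Chain]:
    """Best chain *ending* at each hit of one cluster.

    A chain takes at most one hit per label, non-overlapping, with labels
    in canonical order along the sequence.  For a fixed ending hit, span is
    a function of first_start, so the DP key (score, first_start,
    -sum_starts, -sum_ends) agrees with assignment_key and substructure is
    optimal.
    """
    idx = {lbl: k for k, lbl in enumerate(order)}
    hits = sorted(cluster_hits, key=lambda h: (h.start, h.end, idx[h.motif_label]))
    best_at: list[_Chain] = []
    for i, h in enumerate(hits):
        best = _Chain(hits=(h,), score=h.score, sum_starts=h.start, sum_ends=h.end)
        for j, g in enumerate(hits[:i]):
            if g.end >= h.start or idx[g.motif_label] >= idx[h.motif_label]:
                continue
            p = best_at[j]
            cand = _Chain(
                hits=p.hits + (h,),
                score=p.score + h.score,
                sum_starts=p.sum_starts + h.start,
                sum_ends=p.sum_ends + h.end,
            )
            if (cand.score, cand.first_start, -cand.sum_starts, -cand.sum_ends) > (
                best.score, best.first_start, -best.sum_starts, -best.sum_ends
            ):
                best = cand
        best_at.append(best)
    return best_at


def _backward_chains(cluster_hits: list[MotifHit], order: tuple[str, ...]) -> list[_Chain]:
    """Best chain *starting* at each hit (for the second cluster block);
    mirror of _forward_chains with key (score, -last_end, -sum_starts,
    -sum_ends)."""
    idx = {lbl: k for k, lbl in enumerate(order)}
    hits = sorted(cluster_hits, key=lambda h: (h.start, h.end, idx[h.motif_label]))
    best_from: list[_Chain] = [None] * len(hits)  # type: ignore[list-item]
    for i in range(len(hits) - 1, -1, -1):
        h = hits[i]
        best = _Chain(hits=(h,), score=h.score, sum_starts=h.start, sum_ends=h.end)
        for j in range(i + 1, len(hits)):
            g = hits[j]
            if g.start <= h.end or idx[g.motif_label] <= idx[h.motif_label]:
                continue
            p = best_from[j]
            cand = _Chain(
                hits=(h,) + p.hits,
                score=h.score + p.score,
                sum_starts=h.start + p.sum_starts,
                sum_ends=h.end + p.sum_ends,
            )
            if (cand.score, -cand.last_end, -cand.sum_starts, -cand.sum_ends) > (
                best.score, -best.last_end, -best.sum_starts, -best.sum_ends
            ):
                best = cand
        best_from[i] = best
    return best_from


def _combine_key(c1: _Chain, c2: _Chain) -> tuple[float, float, float, float]:
    return (
        c1.score + c2.score,
        -(c1.span + c2.span),
        -(c1.sum_starts + c2.sum_starts),
        -(c1.sum_ends + c2.sum_ends),
    )


def longest_free_span(hits: Sequence[MotifHit], protein_length: int) -> int:
    """Length of the longest hit-free span (terminal spans included)."""
    if not hits:
        return protein_length
    ordered = sorted(hits, key=lambda h: h.start)
    best = max(ordered[0].start - 1, protein_length - ordered[-1].end)
    for prev, nxt in zip(ordered, ordered[1:]):
        best = max(best, nxt.start - prev.end - 1)
    return best


def choose_hits(
    all_hits: list[MotifHit], protein_length: int | None = None
) -> tuple[MotifHit, ...]:
    """Pick at most one hit per motif label, maximizing total score.

    Constraints: chosen hits do not overlap; within each cluster the chosen
    labels appear in canonical order (an Xa-X-I-II-III subsequence for the
    AdoMet cluster, IV-IVa-V-VI-VII-VIII for the catalytic cluster); and the
    two clusters form contiguous blocks along the sequence — they do not
    interleave, mirroring the three group architectures.  Either cluster
    block may come first (that order is what distinguishes the groups).

    Selection is two-stage.  Stage 1 finds, for each cluster-ordering class
    (AdoMet-only, catalytic-only, AdoMet-then-catalytic, catalytic-then-
    AdoMet), the best assignment by assignment_key (total score, then
    compact clusters, then leftmost).  Stage 2 compares the class finalists
    by total score, then by the longest motif-free span the assignment
    leaves (the presumptive TRD: a reading that carves out a clean domain
    beats one that chops it up), then by assignment_key's tie components.
    Hits with labels outside both clusters are added afterwards, greedily,
    where they do not overlap.
    """
    a_hits = [h for h in all_hits if h.motif_label in ADOMET_ORDER]
    c_hits = [h for h in all_hits if h.motif_label in CATALYTIC_ORDER]
    other = [h for h in all_hits if cluster_of(h.motif_label) is None]
    if protein_length is None:
        protein_length = max((h.end for h in all_hits), default=0)

    fwd_a, fwd_c = _forward_chains(a_hits, ADOMET_ORDER), _forward_chains(c_hits, CATALYTIC_ORDER)
    bwd_a, bwd_c = _backward_chains(a_hits, ADOMET_ORDER), _backward_chains(c_hits, CATALYTIC_ORDER)

    finalists: dict[str, tuple[_Chain, _Chain]] = {"empty": (_EMPTY, _EMPTY)}

    def consider(cls: str, c1: _Chain, c2: _Chain) -> None:
        if cls not in finalists or _combine_key(c1, c2) > _combine_key(*finalists[cls]):
            finalists[cls] = (c1, c2)

    for chain in fwd_a:
        consider("A", chain, _EMPTY)
    for chain in fwd_c:
        consider("C", chain, _EMPTY)
    # first block from forward chains (best per ending hit), second block from
    # backward chains (best per starting hit); prefix-max over first blocks
    for cls, first_chains, second_chains in (("AC", fwd_a, bwd_c), ("CA", fwd_c, bwd_a)):
        firsts = sorted(first_chains, key=lambda ch: ch.last_end)
        prefix: list[_Chain] = []
        running = _EMPTY
        for ch in firsts:
            if _combine_key(ch, _EMPTY) > _combine_key(running, _EMPTY):
                running = ch
            prefix.append(running)
        ends = [ch.last_end for ch in firsts]
        for second in second_chains:
            i = bisect_right(ends, second.first_start - 1) - 1
            if i >= 0 and prefix[i].hits:
                consider(cls, prefix[i], second)

    def final_key(pair: tuple[_Chain, _Chain]) -> tuple:
        hits = pair[0].hits + pair[1].hits
        score, neg_disp, neg_ss, neg_se = _combine_key(*pair)
        return (score, longest_free_span(hits, protein_length), neg_disp, neg_ss, neg_se)

    best_pair = max(finalists.values(), key=final_key)
    chosen = sorted(best_pair[0].hits + best_pair[1].hits, key=lambda h: h.start)

    # greedy placement of out-of-vocabulary labels
    taken = list(chosen)
    for h in sorted(other, key=lambda h: (-h.score, h.start, h.motif_label)):
        if any(t.motif_label == h.motif_label for t in taken):
            continue
        if all(h.end < t.start or h.start > t.end for t in taken):
            taken.append(h)
    return tuple(sorted(taken, key=lambda h: h.start))


# ---------------------------------------------------------------------------
# TRD inference


def infer_trd(
    hits: tuple[MotifHit, ...],
    protein_length: int,
    min_len: int = DEFAULT_MIN_TRD,
) -> tuple[int, int] | None:
    """The longest hit-free span that could be the target-recognition domain.

    Candidates are the N-terminal span before the first chosen hit, the
    C-terminal span after the last, and every gap between consecutive
    chosen hits.  Inter-motif linkers are short, so the ``min_len`` floor
    (a TRD is a domain, not a gap) keeps them out.  Ties go to the
    C-terminal-most candidate.
    """
    if len(hits) < 2:
        return None
    ordered = sorted(hits, key=lambda h: h.start)
    spans: list[tuple[int, int]] = []
    if ordered[0].start > 1:
        spans.append((1, ordered[0].start - 1))
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start > prev.end + 1:
            spans.append((prev.end + 1, nxt.start - 1))
    if ordered[-1].end < protein_length:
        spans.append((ordered[-1].end + 1, protein_length))
    best_span: tuple[int, int] | None = None
    for s in spans:
        length = s[1] - s[0] + 1
        if length < min_len:
            continue
        if best_span is None or length > best_span[1] - best_span[0] + 1 or (
            length == best_span[1] - best_span[0] + 1 and s[0] > best_span[0]
        ):
            best_span = s
    return best_span


# ---------------------------------------------------------------------------
# Group assignment


def assign_group(
    hits: tuple[MotifHit, ...],
    trd_span: tuple[int, int] | None,
) -> tuple[str, bool, tuple[str, ...]]:
    """Call alpha/beta/gamma from cluster order relative to the TRD.

    Cluster positions are summarized by the *median* start of their chosen
    hits, which tolerates a single stray hit (e.g. a spurious hydrophobic
    window called as motif X far from the true cluster) without flipping
    the call.  Requirements before any call: motif IV present, at least one
    of V/VI/VII supporting it, and at least two of X/I/II/III.
    """
    evidence: list[str] = []
    by_label = {h.motif_label: h for h in hits}
    if "IV" not in by_label:
        return "unclassified", False, ("no catalytic anchor (motif IV missing)",)
    adomet = [h for h in hits if h.motif_label in ADOMET_ORDER]
    catalytic = [h for h in hits if h.motif_label in CATALYTIC_ORDER]
    n_core = sum(1 for h in adomet if h.motif_label in ADOMET_CORE)
    n_support = sum(1 for h in catalytic if h.motif_label in CATALYTIC_SUPPORT)
    evidence.append(f"AdoMet cluster: {n_core} of X/I/II/III found (need >=2)")
    evidence.append(f"catalytic cluster: IV plus {n_support} of V/VI/VII (need >=1)")
    if n_core < 2 or n_support < 1:
        return "unclassified", False, tuple(evidence + ["cluster evidence too weak"])
    if trd_span is None:
        return "unclassified", False, tuple(evidence + ["no TRD-sized motif-free span"])
    m_a = median(h.start for h in adomet)
    m_c = median(h.start for h in catalytic)
    ts, te = trd_span
    evidence.append(f"median starts: AdoMet={m_a:g}, catalytic={m_c:g}; TRD={ts}..{te}")
    if m_a < ts <= te < m_c:
        group = "alpha"
        evidence.append("order AdoMet-TRD-catalytic -> alpha")
    elif m_c < ts <= te < m_a:
        group = "beta"
        evidence.append("order catalytic-TRD-AdoMet -> beta")
    elif m_a < m_c < ts:
        group = "gamma"
        evidence.append("order AdoMet-catalytic-TRD -> gamma")
    else:
        return "unclassified", False, tuple(evidence + ["cluster/TRD order matches no group"])
    variant = by_label["IV"].variant_tag
    evidence.append(f"motif IV variant: {variant}PPY")
    subgroup = False
    if group == "gamma":
        has_iva, has_xa = "IVa" in by_label, "Xa" in by_label
        evidence.append(f"IVa present: {has_iva}; Xa present: {has_xa}")
        subgroup = variant == "D" and has_iva and has_xa
        if subgroup:
            evidence.append("gamma order + DPPY + IVa + Xa -> NruI/Sbo13I-like subgroup")
    return group, subgroup, tuple(evidence)


def classify(
    protein: ProteinSeq,
    config: dict[str, MotifDef] | None = None,
    min_trd: int = DEFAULT_MIN_TRD,
) -> MethylaseArchitecture:
    """Scan, select one hit per motif, infer the TRD, and call the group."""
    chosen = choose_hits(scan_all(protein, config), protein_length=len(protein))
    trd = infer_trd(chosen, len(protein), min_len=min_trd)
    group, subgroup, evidence = assign_group(chosen, trd)
    return MethylaseArchitecture(
        hits=chosen, trd_span=trd, group_call=group, subgroup_flag=subgroup, evidence=evidence
    )
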