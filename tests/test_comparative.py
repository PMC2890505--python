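"""Pairwise identity/similarity, consensus lines, trees, force layout."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode

from mtase_architect.alphabet_core import AlignmentBlock, ProteinSeq
from mtase_architect.comparative import (
    DistanceMatrix,
    align_pair,
    consensus_line,
    distance_matrix,
    force_layout,
    minimum_linkage_tree,
    percent_identity_similarity,
)
from mtase_architect.synthetic_data import gen_family


def naive_single_linkage(labels, mat):
    """Independent agglomeration oracle: min pairwise distance between
    clusters, lexicographic tie-break on representative labels."""
    clusters = {lab: frozenset([lab]) for lab in labels}
    merges = []
    idx = {lab: i for i, lab in enumerate(labels)}
    while len(clusters) > 1:
        best = None
        reps = sorted(clusters)
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1 :]:
                d = min(mat[idx[a], idx[b]] for a in clusters[r1] for b in clusters[r2])
                if best is None or (d, r1, r2) < best:
                    best = (d, r1, r2)
        d, r1, r2 = best
        merges.append((d, clusters[r1] | clusters[r2]))
        clusters[min(r1, r2)] = clusters.pop(r1) | clusters.pop(r2)
        if max(r1, r2) in clusters:
            del clusters[max(r1, r2)]
    return merges


class TestAlignPair:
    def test_identical_single_residue(self):
        r = align_pair(ProteinSeq(id="a", residues="S"), ProteinSeq(id="b", residues="S"))
        assert r.identity_pct == 100.0

    def test_hand_alignment_mgfled_vs_mgflad(self):
        r = align_pair(
            ProteinSeq(id="a", residues="MGFLED"), ProteinSeq(id="b", residues="MGFLAD"),
            mode="global",
        )
        # E vs A share no conservation group: similarity equals identity here
        assert r.identity_pct == pytest.approx(100 * 5 / 6)
        assert r.similarity_pct == pytest.approx(100 * 5 / 6)

    def test_group_pair_counts_toward_similarity_only(self):
        r = align_pair(
            ProteinSeq(id="a", residues="WWDWW"), ProteinSeq(id="b", residues="WWEWW"),
            mode="global",
        )
        assert r.identity_pct == pytest.approx(80.0)
        assert r.similarity_pct == pytest.approx(100.0)  # D/E are one group

    def test_symmetry(self):
        a = ProteinSeq(id="a", residues="MGFLEDWDLSYDEINELTDN")
        b = ProteinSeq(id="b", residues="MGFLADWDLSYDEINELLTDN")
        r1, r2 = align_pair(a, b), align_pair(b, a)
        assert r1.identity_pct == pytest.approx(r2.identity_pct)
        assert r1.similarity_pct == pytest.approx(r2.similarity_pct)

    def test_identity_never_exceeds_similarity(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = ProteinSeq(id="a", residues="".join(rng.choice(aas, 30)))
            b = ProteinSeq(id="b", residues="".join(rng.choice(aas, 30)))
            r = align_pair(a, b, mode="global")
            assert r.identity_pct <= r.similarity_pct <= 100.0

    def test_x_scores_nothing(self):
        ident, simil, denom = percent_identity_similarity("XD", "XE")
        assert (ident, simil, denom) == (0.0, 50.0, 2)


class TestConsensusLine:
    def test_star_colon_space(self):
        block = AlignmentBlock(ids=("a", "b", "c"), rows=("LDDL", "LELD", "LQD-"))
        # col1 identical L -> '*'; col2 {D,E,Q} one group -> ':';
        # col3 {D,L,D} -> ' '; col4 has a gap -> ' '
        assert consensus_line(block) == "*:  "

    def test_x_column_blank(self):
        block = AlignmentBlock(ids=("a", "b"), rows=("X", "X"))
        assert consensus_line(block) == " "


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        seqs = [ProteinSeq(id="a", residues="MGFLED"), ProteinSeq(id="b", residues="MGFLED")]
        dm = distance_matrix(seqs, mode="global")
        assert dm.get("a", "b") == pytest.approx(0.0)

    def test_disjoint_equal_length_pair_distance_one(self):
        # no shared residues, gap-free global alignment
        seqs = [ProteinSeq(id="a", residues="DDDDD"), ProteinSeq(id="b", residues="KKKKK")]
        dm = distance_matrix(seqs, mode="global")
        assert dm.get("a", "b") == pytest.approx(1.0)

    def test_matches_per_pair_align_calls(self):
        seqs, _ = gen_family(parent_length=60, n_leaves=4, subs_per_branch=4, seed=3)
        dm = distance_matrix(seqs, mode="global")
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                if i < j:
                    r = align_pair(a, b, mode="global")
                    assert dm.matrix[i, j] == pytest.approx(1 - r.identity_pct / 100)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("a", "b"), matrix=np.array([[0, 1], [2, 0]], float))

    def test_from_precomputed_alignment(self):
        block = AlignmentBlock(ids=("a", "b"), rows=("MGF-ED", "MGFL-D"))
        dm = distance_matrix(alignment=block)
        # gap-free columns: M,G,F,D -> all identical -> distance 0
        assert dm.get("a", "b") == pytest.approx(0.0)


class TestMinimumLinkageTree:
    def test_two_taxa_midpoint_split(self):
        dm = DistanceMatrix(labels=("A", "B"), matrix=np.array([[0, 0.4], [0.4, 0]]))
        t = minimum_linkage_tree(dm)
        tips = {n.name: n.length for n in t.root.tips()}
        assert tips == {"A": pytest.approx(0.2), "B": pytest.approx(0.2)}

    def test_three_taxa_merge_order_by_hand(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            matrix=np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], float),
        )
        t = minimum_linkage_tree(dm)
        assert [sorted(a | b) for _, a, b in t.merges] == [["A", "B"], ["A", "B", "C"]]
        assert [h for h, _, _ in t.merges] == [1.0, 5.0]

    def test_newick_parses_and_has_all_leaves(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C", "D"),
            matrix=squareform([0.2, 0.9, 0.8, 0.85, 0.95, 0.3]),
        )
        t = minimum_linkage_tree(dm)
        parsed = TreeNode.read([t.to_newick()])
        assert {n.name for n in parsed.tips()} == {"A", "B", "C", "D"}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_oracle_and_scipy_heights(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        labels = tuple(chr(65 + i) for i in range(n))
        cond = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
        mat = squareform(cond)
        dm = DistanceMatrix(labels=labels, matrix=mat)
        t = minimum_linkage_tree(dm)
        oracle = naive_single_linkage(labels, mat)
        assert [(h, a | b) for h, a, b in t.merges] == [(h, m) for h, m in oracle]
        # heights monotone non-decreasing (single-linkage property)
        heights = [h for h, _, _ in t.merges]
        assert heights == sorted(heights)
        # scipy cross-check of the merge heights
        scipy_heights = sorted(linkage(cond, method="single")[:, 2])
        assert np.allclose(sorted(heights), scipy_heights)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            minimum_linkage_tree(DistanceMatrix(labels=("A",), matrix=np.zeros((1, 1))))

    def test_recovers_planted_bipartition_zero_noise(self):
        for seed in range(20):
            seqs, truth = gen_family(
                parent_length=120, n_leaves=6, subs_per_branch=2, seed=seed, deep_subs=30
            )
            dm = distance_matrix(seqs, mode="global")
            t = minimum_linkage_tree(dm)
            first_all_a = next(
                a | b for h, a, b in t.merges if len(a | b) == 3
            )
            assert first_all_a in truth.bipartition


class TestForceLayout:
    def test_single_node_at_origin(self):
        lr = force_layout(np.ones((1, 1)))
        assert np.allclose(lr.coords, 0.0)

    def test_reproducible_for_fixed_seed(self):
        sim = np.full((5, 5), 0.3)
        np.fill_diagonal(sim, 1.0)
        a = force_layout(sim, iterations=50, seed=9)
        b = force_layout(sim, iterations=50, seed=9)
        assert np.array_equal(a.coords, b.coords)

    def test_two_planted_families_separate(self):
        n = 10
        sim = np.full((n, n), 0.05)
        sim[:5, :5] = 0.8
        sim[5:, 5:] = 0.8
        np.fill_diagonal(sim, 1.0)
        wins = 0
        for seed in range(10):
            lr = force_layout(sim, iterations=200, seed=seed)
            d = np.linalg.norm(lr.coords[:, None] - lr.coords[None, :], axis=-1)
            intra = np.concatenate([d[:5, :5][np.triu_indices(5, 1)],
                                    d[5:, 5:][np.triu_indices(5, 1)]])
            inter = d[:5, 5:].ravel()
            if np.median(intra) < np.median(inter):
                wins += 1
        assert wins >= 9

    def test_pure_repulsion_spreads_with_node_count(self):
        def mean_dist(n, seed=0):
            lr = force_layout(np.zeros((n, n)), iterations=150, seed=seed)
            d = np.linalg.norm(lr.coords[:, None] - lr.coords[None, :], axis=-1)
            return d[np.triu_indices(n, 1)].mean()

        assert mean_dist(12) > mean_dist(3)

    def test_invalid_similarity_rejected(self):
        with pytest.raises(ValueError):
            force_layout(np.array([[0.0, 2.0], [2.0, 0.0]]))
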