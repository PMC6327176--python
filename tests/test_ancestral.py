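"""Guide trees, Fitch parsimony reconstruction, and consensus sequences."""

import itertools

import numpy as np
import pytest

from symprop import (GuideTree, RepeatAlignment, build_guide_tree,
                     consensus_sequence, p_distance_matrix,
                     reconstruct_ancestral_set)

# hand-computed UPGMA example: p-distances over 8 columns
HAND_ALN = RepeatAlignment(
    labels=["A", "B", "C", "D"],
    rows=["AAAAAAAA",   # A
          "AAAAAAAT",   # B: d(A,B) = 1/8
          "AATTTTTT",   # C: d(A,C) = 6/8, d(B,C) = 5/8
          "TTTTTTTT"],  # D: d(A,D) = 1,  d(B,D) = 7/8, d(C,D) = 2/8
)


def test_p_distance_hand_matrix():
    mat = p_distance_matrix(HAND_ALN)
    expected = np.array([
        [0, 1 / 8, 6 / 8, 1.0],
        [1 / 8, 0, 5 / 8, 7 / 8],
        [6 / 8, 5 / 8, 0, 2 / 8],
        [1.0, 7 / 8, 2 / 8, 0]])
    np.testing.assert_allclose(mat, expected)


def test_p_distance_excludes_gap_columns():
    aln = RepeatAlignment(labels=["x", "y"], rows=["A-AT", "AG-T"])
    # only columns 0 and 3 compared: identical
    assert p_distance_matrix(aln)[0, 1] == pytest.approx(0.0)


def test_p_distance_all_gap_comparison_error():
    aln = RepeatAlignment(labels=["x", "y"], rows=["A--", "-GG"])
    with pytest.raises(ValueError):
        p_distance_matrix(aln)


def test_upgma_merge_order_matches_hand_computation():
    # hand UPGMA: merge (A,B) at height .0625, then (C,D) at .125,
    # then the root joins both at .40625
    gt = build_guide_tree(HAND_ALN, "UPGMA")
    tree = gt.tree
    clades = {frozenset(t.name for t in c.get_terminals()): c
              for c in tree.find_clades() if not c.is_terminal()}
    assert frozenset("AB") in clades
    assert frozenset("CD") in clades
    assert frozenset("ABCD") in clades
    # ultrametric: every root-to-leaf distance equal
    depths = tree.depths()
    leaf_depths = [d for c, d in depths.items() if c.is_terminal()]
    assert max(leaf_depths) - min(leaf_depths) < 1e-12
    assert leaf_depths[0] == pytest.approx(0.40625)


def test_upgma_outlier_splits_first():
    aln = RepeatAlignment(labels=["r1", "r2", "r3"],
                          rows=["AAAA", "AAAA", "TTTT"])
    gt = build_guide_tree(aln, "UPGMA")
    root_children = gt.tree.root.clades
    sides = [sorted(t.name for t in c.get_terminals())
             for c in root_children]
    assert ["r3"] in sides and ["r1", "r2"] in sides


def test_upgma_outlier_never_joins_first(rng):
    # max-mean-distance row cannot participate in the first merge
    rows = ["ADKLMNPQ", "ADKLMNPT", "ADKLMNGQ", "WWWWWWWW"]
    aln = RepeatAlignment(labels=[f"r{i}" for i in range(4)], rows=rows)
    gt = build_guide_tree(aln, "UPGMA")
    # the deepest internal node (first merge) excludes the outlier r3
    internals = [c for c in gt.tree.find_clades() if not c.is_terminal()]
    first = max(internals,
                key=lambda c: gt.tree.depths()[c])
    assert "r3" not in {t.name for t in first.get_terminals()}


def test_nj_tree_recovers_split():
    gt = build_guide_tree(HAND_ALN, "NJ")
    assert sorted(gt.leaf_labels()) == ["A", "B", "C", "D"]
    newick = gt.to_newick()
    assert newick.count("(") >= 2


def test_newick_round_trip():
    gt = build_guide_tree(HAND_ALN, "UPGMA")
    back = GuideTree.from_newick(gt.to_newick())
    assert sorted(back.leaf_labels()) == sorted(gt.leaf_labels())


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def brute_force_root_sets(tree: GuideTree, aln: RepeatAlignment,
                          ) -> list[frozenset]:
    """Independent oracle: per column, the root states achieving the
    exhaustive minimum mutation count over all internal labelings."""
    row_of = dict(zip(aln.labels, aln.rows))
    internals = [c for c in tree.tree.find_clades() if not c.is_terminal()]
    edges = []
    for c in tree.tree.find_clades():
        for child in c.clades:
            edges.append((c, child))
    # optimal internal labels only ever use states observed at the leaves
    alphabet = sorted({c for row in aln.rows for c in row})
    out = []
    for col in range(aln.n_columns):
        best_by_root: dict[str, int] = {}
        for labels in itertools.product(alphabet, repeat=len(internals)):
            state = {id(c): s for c, s in zip(internals, labels)}
            for leaf in tree.tree.get_terminals():
                state[id(leaf)] = row_of[leaf.name][col]
            cost = sum(state[id(a)] != state[id(b)] for a, b in edges)
            root_state = state[id(tree.tree.root)]
            if root_state not in best_by_root or cost < best_by_root[root_state]:
                best_by_root[root_state] = cost
        overall = min(best_by_root.values())
        out.append(frozenset(s for s, c in best_by_root.items()
                             if c == overall))
    return out


def _quartet_tree() -> GuideTree:
    return GuideTree.from_newick("((A:1,B:1)ab:1,(C:1,D:1)cd:1)root:0;")


def test_fitch_identical_leaves_singleton():
    aln = RepeatAlignment(labels=list("ABCD"), rows=["KK"] * 4)
    result = reconstruct_ancestral_set(aln, _quartet_tree(), "root")
    assert result.column_sets == [frozenset("K"), frozenset("K")]
    assert result.sequences == ["KK"]


def test_fitch_union_at_root():
    # column states S,S,T,T on ((A,B),(C,D)) -> root set {S,T}
    aln = RepeatAlignment(labels=list("ABCD"), rows=["S", "S", "T", "T"])
    result = reconstruct_ancestral_set(aln, _quartet_tree(), "root")
    assert result.column_sets == [frozenset("ST")]
    assert result.sequences == ["S", "T"]
    assert result.n_combinations == 2


def test_fitch_hand_quartet_multiple_columns():
    aln = RepeatAlignment(labels=list("ABCD"),
                          rows=["SAK", "SAK", "TAK", "TGK"])
    result = reconstruct_ancestral_set(aln, _quartet_tree(), "root")
    assert result.column_sets == [frozenset("ST"), frozenset("A"),
                                  frozenset("K")]
    assert result.sequences == ["SAK", "TAK"]


@pytest.mark.parametrize("seed", range(4))
def test_fitch_root_sets_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    alphabet = "AST"  # small alphabet keeps the oracle exhaustive
    rows = ["".join(rng.choice(list(alphabet), size=6)) for _ in range(5)]
    aln = RepeatAlignment(labels=[f"L{i}" for i in range(5)], rows=rows)
    tree = GuideTree.from_newick(
        "(((L0:1,L1:1)a:1,L2:1)b:1,(L3:1,L4:1)c:1)root:0;")
    result = reconstruct_ancestral_set(aln, tree, "root")
    oracle = brute_force_root_sets(tree, aln)
    assert result.column_sets == oracle


def test_enumeration_count_and_cap():
    aln = RepeatAlignment(labels=list("ABCD"),
                          rows=["SA", "TA", "SG", "TG"])
    result = reconstruct_ancestral_set(aln, _quartet_tree(), "root")
    assert result.n_combinations == 4
    assert len(result.sequences) == 4
    assert result.sequences == sorted(result.sequences)  # lexicographic
    capped = reconstruct_ancestral_set(aln, _quartet_tree(), "root", cap=3)
    assert capped.capped and len(capped.sequences) == 3


def test_gap_stripped_from_emitted_sequences():
    aln = RepeatAlignment(labels=list("ABCD"),
                          rows=["A-K", "A-K", "A-K", "A-K"])
    result = reconstruct_ancestral_set(aln, _quartet_tree(), "root")
    assert result.sequences == ["AK"]


def test_reconstruct_invalid_cap():
    aln = RepeatAlignment(labels=list("ABCD"), rows=["A"] * 4)
    with pytest.raises(ValueError):
        reconstruct_ancestral_set(aln, _quartet_tree(), "root", cap=0)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_identical_rows():
    aln = RepeatAlignment(labels=["a", "b", "c"], rows=["MKV"] * 3)
    assert consensus_sequence(aln) == "MKV"


def test_consensus_majority_and_tie_policies():
    aln = RepeatAlignment(labels=["a", "b", "c"], rows=["AG", "AG", "GG"])
    assert consensus_sequence(aln) == "AG"
    tie = RepeatAlignment(labels=["a", "b"], rows=["A", "G"])
    assert consensus_sequence(tie, "alphabetical") == "A"
    assert consensus_sequence(tie, "emit-all") == ["A", "G"]
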