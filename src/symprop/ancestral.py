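"""Guide trees over repeat sequences and ancestral/consensus reconstruction.

Symmetrizing a tandem-repeat protein starts from a gapped alignment of its
repeats. A guide tree built on pairwise p-distances exposes divergent
repeats (they split off first), and ancestral states at internal nodes are
inferred by Fitch parsimony with full enumeration of tied reconstructions,
yielding the candidate set of consensus/ancestral repeat sequences.

Trees are held as Bio.Phylo clades and serialize to Newick.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Clade, Tree
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

__all__ = [
    "RepeatAlignment",
    "GuideTree",
    "AncestralSet",
    "p_distance_matrix",
    "build_guide_tree",
    "reconstruct_ancestral_set",
    "consensus_sequence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass
class RepeatAlignment:
    """Equal-length gapped repeat sequences with labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("alignment rows differ in length")
        allowed = set(AMINO_ACIDS + GAP)
        for label, row in zip(self.labels, self.rows):
            bad = set(row.upper()) - allowed
            if bad:
                raise ValueError(f"row {label!r} contains non-amino-acid "
                                 f"symbols {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, source) -> "RepeatAlignment":
        records = list(SeqIO.parse(source, "fasta"))
        return cls(labels=[r.id for r in records],
                   rows=[str(r.seq) for r in records])


@dataclass
class GuideTree:
    """Rooted binary tree over repeat labels, Newick-serializable."""

    tree: Tree
    method: str = ""

    def __post_init__(self) -> None:
        leaves = self.leaf_labels()
        if len(leaves) != len(set(leaves)):
            raise ValueError("duplicate leaf labels")

    def leaf_labels(self) -> list[str]:
        return [t.name for t in self.tree.get_terminals()]

    def node(self, node_id: str) -> Clade:
        if node_id in ("root", ""):
            return self.tree.root
        for clade in self.tree.find_clades():
            if clade.name == node_id:
                return clade
        raise KeyError(f"no node named {node_id!r} in tree")

    def to_newick(self) -> str:
        buf = StringIO()
        Phylo.write(self.tree, buf, "newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, source) -> "GuideTree":
        if isinstance(source, str) and source.lstrip().startswith("("):
            source = StringIO(source)
        return cls(tree=Phylo.read(source, "newick"))


@dataclass
class AncestralSet:
    """Per-column candidate residue sets at one tree node, plus enumerations."""

    node_id: str
    column_sets: list[frozenset[str]]
    sequences: list[str] = field(default_factory=list)
    capped: bool = False

    @property
    def n_combinations(self) -> int:
        out = 1
        for s in self.column_sets:
            out *= len(s)
        return out


# ---------------------------------------------------------------------------
# Distances and guide trees
# ---------------------------------------------------------------------------

def p_distance_matrix(aln: RepeatAlignment) -> np.ndarray:
    """Pairwise p-distances: mismatches over pairwise-gap-free columns."""
    n = len(aln.rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = comp = 0
            for a, b in zip(aln.rows[i], aln.rows[j]):
                if a == GAP or b == GAP:
                    continue
                comp += 1
                mism += a != b
            if comp == 0:
                raise ValueError(f"rows {aln.labels[i]!r} and "
                                 f"{aln.labels[j]!r} share no gap-free column")
            mat[i, j] = mat[j, i] = mism / comp
    return mat


def build_guide_tree(aln: RepeatAlignment, method: str = "UPGMA",
                     ) -> GuideTree:
    """Rooted guide tree over the repeats by UPGMA or neighbor joining.

    UPGMA (average-linkage clustering on p-distances) yields an ultrametric
    tree. NJ trees are unrooted by construction and are rooted here at the
    midpoint of their longest leaf-to-leaf path.
    """
    method = method.upper()
    dist = p_distance_matrix(aln)
    if method == "UPGMA":
        return GuideTree(tree=_upgma_tree(dist, aln.labels), method="UPGMA")
    if method == "NJ":
        if len(aln.rows) < 3:
            raise ValueError("NJ requires at least 3 sequences")
        tree = _nj_tree(dist, aln.labels)
        tree.root_at_midpoint()
        return GuideTree(tree=tree, method="NJ")
    raise ValueError(f"unknown tree method {method!r}")


def _upgma_tree(dist: np.ndarray, labels: list[str]) -> Tree:
    n = len(labels)
    if n == 2:
        h = dist[0, 1] / 2.0
        root = Clade(name="n2", branch_length=0.0)
        root.clades = [Clade(name=labels[0], branch_length=h),
                       Clade(name=labels[1], branch_length=h)]
        return Tree(root=root, rooted=True)
    linkage = average(squareform(dist, checks=False))
    clades: dict[int, tuple[Clade, float]] = {
        i: (Clade(name=labels[i]), 0.0) for i in range(n)}
    for k, (a, b, height, _cnt) in enumerate(linkage):
        ca, ha = clades[int(a)]
        cb, hb = clades[int(b)]
        h = height / 2.0  # ultrametric node height
        ca.branch_length = h - ha
        cb.branch_length = h - hb
        node = Clade(name=f"n{n + k}")
        node.clades = [ca, cb]
        clades[n + k] = (node, h)
    root = clades[2 * n - 2][0]
    root.branch_length = 0.0
    return Tree(root=root, rooted=True)


def _nj_tree(dist: np.ndarray, labels: list[str]) -> Tree:
    """Saitou–Nei neighbor joining; returns an (arbitrarily rooted) tree."""
    d = dist.astype(float).copy()
    nodes = [Clade(name=lab) for lab in labels]
    active = list(range(len(labels)))
    next_name = len(labels)
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        nodes[i].branch_length = max(li, 0.0)
        nodes[j].branch_length = max(lj, 0.0)
        parent = Clade(name=f"n{next_name}")
        next_name += 1
        parent.clades = [nodes[i], nodes[j]]
        # distances to the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]
    i, j = active
    nodes[i].branch_length = d[i, j] / 2.0
    nodes[j].branch_length = d[i, j] / 2.0
    root = Clade(name="root")
    root.clades = [nodes[i], nodes[j]]
    return Tree(root=root, rooted=True)


# ---------------------------------------------------------------------------
# Fitch parsimony and consensus
# ---------------------------------------------------------------------------

def _fitch_column_sets(clade: Clade, states: dict[str, str],
                       ) -> tuple[frozenset[str], int]:
    """Bottom-up Fitch pass: (state set, mutation count) for one column."""
    if clade.is_terminal():
        return frozenset(states[clade.name]), 0
    child_sets, cost = [], 0
    for child in clade.clades:
        s, c = _fitch_column_sets(child, states)
        child_sets.append(s)
        cost += c
    inter = frozenset.intersection(*child_sets)
    if inter:
        return inter, cost
    return frozenset.union(*child_sets), cost + 1


def reconstruct_ancestral_set(aln: RepeatAlignment, tree: GuideTree,
                              node: str = "root", cap: int = 10_000,
                              ) -> AncestralSet:
    """Fitch-parsimony state sets at a tree node, with tie enumeration.

    Each column is reconstructed independently by the bottom-up Fitch pass
    (intersection where non-empty, else union). The gap symbol is treated
    as a 21st character state during reconstruction and stripped from the
    emitted sequences. All combinations of tied states are enumerated in
    lexicographic order up to ``cap`` sequences.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    leaf_labels = set(tree.leaf_labels())
    if leaf_labels != set(aln.labels):
        raise ValueError("tree leaves do not match alignment labels")
    target = tree.node(node)
    row_of = dict(zip(aln.labels, aln.rows))
    column_sets: list[frozenset[str]] = []
    for col in range(aln.n_columns):
        states = {lab: row_of[lab][col] for lab in aln.labels}
        s, _cost = _fitch_column_sets(target, states)
        column_sets.append(s)

    total = 1
    for s in column_sets:
        total *= len(s)
    capped = total > cap
    choices = [sorted(s) for s in column_sets]
    sequences: list[str] = []
    for combo in itertools.islice(itertools.product(*choices), cap):
        sequences.append("".join(c for c in combo if c != GAP))
    return AncestralSet(node_id=node, column_sets=column_sets,
                        sequences=sequences, capped=capped)


def consensus_sequence(aln: RepeatAlignment, tie_policy: str = "alphabetical",
                       ) -> str | list[str]:
    """Column-majority consensus of the alignment.

    ``tie_policy='alphabetical'`` resolves ties to the alphabetically first
    residue and returns one string; ``'emit-all'`` enumerates every tied
    variant (lexicographic order) and returns a list. Gap-majority columns
    are dropped from the output.
    """
    if tie_policy not in ("alphabetical", "emit-all"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    per_column: list[list[str]] = []
    for col in range(aln.n_columns):
        counts: dict[str, int] = {}
        for row in aln.rows:
            counts[row[col]] = counts.get(row[col], 0) + 1
        top = max(counts.values())
        winners = sorted(c for c, k in counts.items() if k == top)
        per_column.append(winners)
    if tie_policy == "alphabetical":
        return "".join(w[0] for w in per_column if w[0] != GAP)
    out = []
    for combo in itertools.product(*per_column):
        out.append("".join(c for c in combo if c != GAP))
    return out
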