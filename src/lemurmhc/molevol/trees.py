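"""Neighbour-joining trees, bootstrap resampling and majority-rule consensus.

The NJ implementation follows the classic agglomerative algorithm with the
Q-criterion and rate-corrected limb lengths; ties are broken on the smallest
(i, j) index pair so runs are deterministic. Bootstrap replicates resample
alignment columns with replacement, each replicate drawing from an RNG
substream keyed by (seed, replicate), and the consensus keeps internal edges
supported by at least the collapse threshold (reported as integer percent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..seqcore import Sequence
from .distances import DistanceMatrix, k2p_matrix


@dataclass
class Node:
    """A tree node; leaves carry a label, internal nodes may carry support."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset({self.label})
        out: set[str] = set()
        for child in self.children:
            out |= child.leaf_labels()
        return frozenset(out)

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        tag = ""
        if with_support and self.support is not None:
            tag = str(int(round(self.support)))
        return f"({inner}){tag}:{self.length:.6f}"


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary trifurcating/multifurcating root."""

    root: Node

    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def newick(self, with_support: bool = True) -> str:
        inner = ",".join(c._newick(with_support) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset[str], float]:
        """Internal-edge splits as the leaf set on the child side, mapped to
        branch length. Trivial splits are omitted, as are zero-length internal
        edges: an edge of length zero carries no signal for the split it would
        define (so e.g. identical sequences yield no supported splits at all).
        """
        leaves = self.leaf_labels()
        out: dict[frozenset[str], float] = {}

        def walk(node: Node) -> None:
            for child in node.children:
                if not child.is_leaf:
                    side = child.leaf_labels()
                    if 1 < len(side) < len(leaves) and child.length > 1e-12:
                        out[_canonical(side, leaves)] = child.length
                walk(child)

        walk(self.root)
        return out

    def support_values(self) -> dict[frozenset[str], float]:
        leaves = self.leaf_labels()
        out: dict[frozenset[str], float] = {}

        def walk(node: Node) -> None:
            for child in node.children:
                if not child.is_leaf and child.support is not None:
                    out[_canonical(child.leaf_labels(), leaves)] = child.support
                walk(child)

        walk(self.root)
        return out


def _canonical(side: frozenset[str], leaves: frozenset[str]) -> frozenset[str]:
    """Orient a split away from the lexicographically smallest leaf so the
    two sides of an unrooted edge hash identically."""
    ref = min(leaves)
    return frozenset(leaves - side) if ref in side else side


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbour-joining tree from a symmetric distance matrix.

    Negative limb lengths are clamped to zero with the deficit moved onto the
    sister limb, preserving the joined pair's summed length.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    d = matrix.values.astype(float).copy()
    nodes: list[Node] = [Node(label=lab) for lab in matrix.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties resolved on the smallest (i, j) position pair
        flat = np.argmin(q)
        i_loc, j_loc = divmod(flat, m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = Node(children=[child_i, child_j])
        # grow the matrix with the new node's distances
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    # three-point formulas close the final trifurcation exactly
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(length, 0.0)
    return PhyloTree(root=Node(children=[nodes[a], nodes[b], nodes[c]]))


def majority_consensus(
    replicate_trees: list[PhyloTree],
    collapse: float = 0.5,
) -> PhyloTree:
    """Majority-rule consensus over bootstrap replicate trees.

    Internal edges present in >= ``collapse`` of replicates are kept (support
    reported as percent); all others are collapsed into multifurcations.
    Branch lengths are averaged over the replicates containing each edge
    (leaf edges over all replicates).
    """
    if not replicate_trees:
        raise ValueError("no replicate trees")
    leaves = replicate_trees[0].leaf_labels()
    n_reps = len(replicate_trees)

    split_count: dict[frozenset[str], int] = {}
    split_len: dict[frozenset[str], float] = {}
    leaf_len: dict[str, float] = {lab: 0.0 for lab in leaves}
    for tree in replicate_trees:
        if tree.leaf_labels() != leaves:
            raise ValueError("replicate trees disagree on the leaf set")
        for split, length in tree.bipartitions().items():
            split_count[split] = split_count.get(split, 0) + 1
            split_len[split] = split_len.get(split, 0.0) + length

        def collect(node: Node) -> None:
            for child in node.children:
                if child.is_leaf:
                    leaf_len[child.label] += child.length
                collect(child)

        collect(tree.root)

    kept = sorted(
        (
            (count / n_reps, split)
            for split, count in split_count.items()
            if count / n_reps >= collapse
        ),
        key=lambda item: (-item[0], sorted(item[1])),
    )

    root = Node(
        children=[
            Node(label=lab, length=leaf_len[lab] / n_reps) for lab in sorted(leaves)
        ]
    )
    for frac, split in kept:
        if not _insert_split(
            root, split, frac * 100.0, split_len[split] / split_count[split]
        ):
            continue  # incompatible with a higher-supported split (ties at 50%)
    return PhyloTree(root=root)


def _insert_split(
    root: Node, split: frozenset[str], support: float, length: float
) -> bool:
    """Group the children spanning ``split`` under a new internal node."""
    node = root
    while True:
        for child in node.children:
            child_leaves = child.leaf_labels()
            if split < child_leaves:
                node = child
                break
        else:
            break
    spanning = [c for c in node.children if c.leaf_labels() <= split]
    covered: set[str] = set()
    for c in spanning:
        covered |= c.leaf_labels()
    if covered != set(split):
        return False
    for c in spanning:
        node.children.remove(c)
    node.children.append(
        Node(support=support, length=length, children=spanning)
    )
    return True


def bootstrap_consensus(
    sequences: list[Sequence],
    gamma_a: float | None = 1.0,
    n_reps: int = 2000,
    collapse: float = 0.5,
    seed: int = 0,
) -> PhyloTree:
    """Bootstrap majority-rule consensus NJ tree from an aligned set.

    Alignment columns are resampled with replacement per replicate; each
    replicate's K2P(+gamma) distances feed neighbour joining. Edges below the
    collapse threshold are removed; supports are percentages.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    arr = np.array([list(s.nucleotides) for s in sequences])
    n_cols = arr.shape[1]
    replicates = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = [
            Sequence(s.id, "".join(row))
            for s, row in zip(sequences, arr[:, cols])
        ]
        replicates.append(nj_tree(k2p_matrix(resampled, gamma_a)))
    return majority_consensus(replicates, collapse=collapse)
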