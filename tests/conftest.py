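import numpy as np
import pytest

from lemurmhc import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def noise_free_study():
    """A small noise-free synthetic study shared across tests."""
    config = SimulationConfig(
        seed=11,
        alleles_per_species=(6, 4, 3),
        n_animals=(8, 5, 6),
        clones_per_pcr=12,
        error_rate=0.0,
        chimera_rate=0.0,
        contaminant_rate=0.0,
    )
    return simulate_study(config)


def tree_distances(tree):
    """Leaf-to-leaf path-length matrix of a PhyloTree, as a nested dict."""

    def leaf_depths(node):
        if node.is_leaf:
            return {node.label: node.length}
        out = {}
        for child in node.children:
            for label, depth in leaf_depths(child).items():
                out[label] = depth + node.length
        return out

    dists = {}

    def visit(node):
        child_maps = [leaf_depths(c) for c in node.children]
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for la, da in child_maps[i].items():
                    for lb, db in child_maps[j].items():
                        dists[frozenset((la, lb))] = da + db
        for child in node.children:
            visit(child)

    root = tree.root
    # the root is not an edge: remove its (zero) length contribution
    root.length = 0.0
    visit(root)
    return dists


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive lengths; returns (labels, matrix,
    set of nontrivial splits). Distances are exactly additive on the tree."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # each active cluster: (leaf set, {leaf: distance to cluster root})
    clusters = [({lab}, {lab: 0.0}) for lab in labels]
    splits = []
    dist = {}
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (sa, da), (sb, db) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + la + dy + lb
        merged = sa | sb
        depths = {x: d + la for x, d in da.items()}
        depths.update({y: d + lb for y, d in db.items()})
        if 1 < len(merged) < n_taxa - 1:
            splits.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, depths))
    (sa, da), (sb, db) = clusters
    bridge = rng.uniform(0.05, 1.0)
    for x, dx in da.items():
        for y, dy in db.items():
            dist[frozenset((x, y))] = dx + dy + bridge
    if 1 < len(sa) < n_taxa - 1:
        splits.append(frozenset(sa))
    matrix = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            matrix[a, b] = matrix[b, a] = dist[frozenset((labels[a], labels[b]))]
    ref = min(labels)
    canonical = {
        frozenset(set(labels) - s) if ref in s else s for s in splits
    }
    canonical = {s for s in canonical if 1 < len(s) < n_taxa - 1}
    return labels, matrix, canonical
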