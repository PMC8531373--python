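"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from skbio import DistanceMatrix

from cranionet.neighbornet import circular_splits

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# tree-metric oracle helpers
# ---------------------------------------------------------------------------

def random_binary_tree_metric(
    rng: np.random.Generator, n: int
) -> tuple[DistanceMatrix, set[frozenset[str]]]:
    """Random edge-weighted binary tree -> (additive metric, nontrivial splits).

    Built independently of any package code: random sequential joins,
    path lengths by graph traversal, bipartitions read off the edges.
    Splits are canonicalized to the side not containing the first label.
    """
    labels = [f"T{i + 1}" for i in range(n)]
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        a = active.pop(int(rng.integers(len(active))))
        b = active.pop(int(rng.integers(len(active))))
        p = next_id
        next_id += 1
        adj[p] = []
        for child in (a, b):
            w = float(rng.uniform(0.1, 1.0))
            adj[p].append((child, w))
            adj[child].append((p, w))
        active.append(p)

    D = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n):
            D[s, t] = dist[t]
    D = (D + D.T) / 2.0  # float addition order along paths

    def leaves_beyond(u: int, forbidden: int) -> set[int]:
        seen = {u}
        stack = [u]
        out = set()
        while stack:
            x = stack.pop()
            if x < n:
                out.add(x)
            for v, _ in adj[x]:
                if v != forbidden and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return out

    splits: set[frozenset[str]] = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < v:
                side = {labels[i] for i in leaves_beyond(u, v)}
                if 2 <= len(side) <= n - 2:
                    if labels[0] in side:
                        side = set(labels) - side
                    splits.add(frozenset(side))
    return DistanceMatrix(D, labels), splits


def tree_nontrivial_splits_from_newick(
    newick: str, labels: list[str]
) -> set[frozenset[str]]:
    """Nontrivial bipartitions of a newick tree, canonicalized."""
    import dendropy

    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    n = len(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        leaves = {leaf.taxon.label for leaf in node.leaf_iter()}
        if 2 <= len(leaves) <= n - 2:
            if labels[0] in leaves:
                leaves = set(labels) - leaves
            out.add(frozenset(leaves))
    return out


def planted_circular_metric(
    order: list[str],
    rng: np.random.Generator,
    n_nontrivial: int = 5,
    trivial_weight: float = 0.3,
) -> tuple[DistanceMatrix, dict[frozenset[str], float]]:
    """Forward-generate distances from weighted circular splits of ``order``.

    All trivial splits receive ``trivial_weight``; ``n_nontrivial``
    randomly chosen non-trivial interval splits receive random positive
    weights.  Returns the metric (labels in sorted order) and the
    planted side->weight map, sides canonicalized to exclude the first
    label in sorted order.
    """
    labels = sorted(order)
    n = len(labels)
    sides = circular_splits(order)
    nontrivial = [s for s in sides if 1 < len(s) < n - 1]
    chosen = rng.choice(len(nontrivial), size=min(n_nontrivial, len(nontrivial)), replace=False)
    planted: dict[frozenset[str], float] = {}

    def canon(side: frozenset[str]) -> frozenset[str]:
        return side if labels[0] not in side else frozenset(set(labels) - side)

    for s in sides:
        if len(s) == 1 or len(s) == n - 1:
            planted[canon(s)] = trivial_weight
    for k in chosen:
        planted[canon(nontrivial[int(k)])] = float(rng.uniform(0.5, 2.0))

    mat = np.zeros((n, n))
    for side, w in planted.items():
        mem = np.array([lab in side for lab in labels])
        sep = mem[:, None] != mem[None, :]
        mat[sep] += w
    return DistanceMatrix(mat, labels), planted


@pytest.fixture
def quartet_tree_dm() -> DistanceMatrix:
    """Additive metric of the 4-taxon tree ((A,B),(C,D)) with unit branches."""
    d = np.array(
        [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
    )
    return DistanceMatrix(d, list("ABCD"))


@pytest.fixture
def focal_fixture():
    from cranionet.io import load_focal_sites_fixture

    return load_focal_sites_fixture()
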