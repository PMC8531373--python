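"""NeighborNet circular split networks from distance matrices.

NeighborNet generalizes neighbor-joining: instead of committing to a
tree, it agglomerates taxa into a *circular ordering* and then fits a
weighted system of *circular splits* — bipartitions whose sides are
intervals of that ordering — to the observed distances.  Conflicting
phylogenetic signal appears as incompatible splits with positive
weight, drawn by network viewers as boxes; perfectly tree-like input
collapses back to the tree's splits.

The construction has two stages:

1. **Ordering** (:func:`neighbornet_order`).  Taxa start as singleton
   clusters.  At each step the pair of clusters minimizing the
   neighbor-joining Q-criterion is selected; within the chosen pair,
   the node pair minimizing the same criterion on the refined
   collection (the two clusters broken into singleton nodes) decides
   how the cluster paths link up.  Clusters are kept to at most two
   active nodes by a 3-to-2 reduction with equal-thirds weighting:

       d(u, w) = 2/3 d(x, w) + 1/3 d(y, w)
       d(v, w) = 1/3 d(y, w) + 2/3 d(z, w)
       d(u, v) = (d(x, y) + d(x, z) + d(y, z)) / 3

   for a path x - y - z replaced by u - v.  When three or fewer nodes
   remain they are closed into a cycle, and the reductions are expanded
   in reverse to yield a circular ordering of all taxa.

2. **Weighting** (:func:`estimate_split_weights`).  The n(n-1)/2
   interval splits of the ordering define split metrics delta_s (1 for
   pairs separated by s).  Weights solve the least-squares problem
   min || d - sum_s w_s delta_s ||, by default under w_s >= 0
   (non-negative least squares, active-set method); splits with
   negligible weight are dropped.

Ties in both selection criteria are broken toward the lowest node index
pair, making the whole construction deterministic.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import nnls
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

__all__ = [
    "Split",
    "CircularSplitSystem",
    "NeighborNet",
    "NeighborNetResults",
    "neighbornet_order",
    "circular_splits",
    "estimate_split_weights",
    "split_decomposition_distance",
    "nj_tree",
    "write_nexus_splits",
    "read_nexus_splits",
]


# ---------------------------------------------------------------------------
# split system containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """One bipartition of the taxon set with a non-negative weight.

    ``side_a`` is stored canonically as the side *not* containing the
    first taxon of the system's taxa list.
    """

    side_a: frozenset[str]
    weight: float

    def separates(self, p: str, q: str) -> bool:
        return (p in self.side_a) != (q in self.side_a)

    @property
    def size(self) -> int:
        return len(self.side_a)

    def is_trivial(self, ntax: int) -> bool:
        return self.size == 1 or self.size == ntax - 1


@dataclass(frozen=True)
class CircularSplitSystem:
    """A circular ordering of taxa plus weighted interval splits."""

    taxa: tuple[str, ...]
    circular_order: tuple[str, ...]
    splits: tuple[Split, ...]

    def __post_init__(self) -> None:
        if set(self.taxa) != set(self.circular_order):
            raise ValueError("circular_order must be a permutation of taxa")
        taxon_set = set(self.taxa)
        anchor = self.taxa[0]
        for s in self.splits:
            if not s.side_a or not (s.side_a < taxon_set):
                raise ValueError("split side must be a proper nonempty subset of taxa")
            if anchor in s.side_a:
                raise ValueError(
                    f"split side must exclude the anchor taxon {anchor!r}"
                )
            if s.weight < 0:
                raise ValueError("split weights must be non-negative")

    @property
    def ntax(self) -> int:
        return len(self.taxa)

    def nontrivial_splits(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial(self.ntax)]

    def is_circular(self) -> bool:
        """Check every split is an interval of the circular ordering."""
        pos = {t: i for i, t in enumerate(self.circular_order)}
        n = self.ntax
        for s in self.splits:
            idx = sorted(pos[t] for t in s.side_a)
            gaps = sum(
                1
                for a, b in zip(idx, idx[1:] + [idx[0] + n])
                if (b - a) % n != 1
            )
            # an interval of a cycle has exactly one wrap-around gap
            if gaps > 1:
                return False
        return True


def _canonical_splits(
    taxa: Sequence[str], raw: Sequence[tuple[frozenset[str], float]]
) -> tuple[Split, ...]:
    anchor = taxa[0]
    taxon_set = set(taxa)
    splits = []
    for side, w in raw:
        if anchor in side:
            side = frozenset(taxon_set - side)
        splits.append(Split(side_a=side, weight=float(w)))
    splits.sort(key=lambda s: (-s.weight, tuple(sorted(s.side_a))))
    return tuple(splits)


# ---------------------------------------------------------------------------
# ordering (agglomeration / reduction / expansion)
# ---------------------------------------------------------------------------

def _validate_dm(dm: DistanceMatrix, min_n: int) -> None:
    if dm.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} taxa, got {dm.shape[0]}")
    if not np.isfinite(dm.data).all():
        raise ValueError("distance matrix contains non-finite values")


def neighbornet_order(dm: DistanceMatrix) -> list[str]:
    """Compute the NeighborNet circular ordering of the taxa.

    Deterministic: ties in both selection criteria are broken toward
    the lowest node-index pair.  The returned ordering is normalized to
    start at the first taxon and run toward its lower-indexed
    neighbour.
    """
    _validate_dm(dm, 4)
    labels = list(dm.ids)
    n = len(labels)

    # active-node distance table, node ids 0..n-1 are taxa
    D: dict[int, dict[int, float]] = {
        i: {j: float(dm.data[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    clusters: list[list[int]] = [[i] for i in range(n)]
    reductions: list[tuple[int, int, int, int, int]] = []
    next_id = n

    def cluster_dist(A: list[int], B: list[int]) -> float:
        return sum(D[x][y] for x in A for y in B) / (len(A) * len(B))

    def reduce3(x: int, y: int, z: int) -> tuple[int, int]:
        nonlocal next_id
        u, v = next_id, next_id + 1
        next_id += 2
        others = [w for w in D if w not in (x, y, z)]
        D[u] = {}
        D[v] = {}
        for w in others:
            duw = (2.0 / 3.0) * D[x][w] + (1.0 / 3.0) * D[y][w]
            dvw = (1.0 / 3.0) * D[y][w] + (2.0 / 3.0) * D[z][w]
            D[u][w] = duw
            D[w][u] = duw
            D[v][w] = dvw
            D[w][v] = dvw
        duv = (D[x][y] + D[x][z] + D[y][z]) / 3.0
        D[u][v] = duv
        D[v][u] = duv
        for dead in (x, y, z):
            del D[dead]
            for row in D.values():
                row.pop(dead, None)
        reductions.append((u, v, x, y, z))
        return u, v

    while sum(len(c) for c in clusters) > 3:
        clusters.sort(key=min)
        m = len(clusters)
        cd = [[0.0] * m for _ in range(m)]
        for i in range(m):
            for j in range(i + 1, m):
                cd[i][j] = cd[j][i] = cluster_dist(clusters[i], clusters[j])
        R = [sum(row) for row in cd]

        best: tuple[int, int] | None = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * cd[i][j] - R[i] - R[j]
                if q < best_q:
                    best_q = q
                    best = (i, j)
        assert best is not None
        ia, ib = best
        A, B = clusters[ia], clusters[ib]

        # refine: other clusters stay whole, A and B split into nodes
        others = [clusters[k] for k in range(m) if k not in (ia, ib)]
        pool = sorted(A) + sorted(B)
        m_hat = len(others) + len(pool)
        Rhat: dict[int, float] = {}
        for x in pool:
            Rhat[x] = sum(cluster_dist([x], C) for C in others) + sum(
                D[x][z] for z in pool if z != x
            )
        best_nodes: tuple[int, int] | None = None
        best_q = np.inf
        for x in sorted(A):
            for y in sorted(B):
                q = (m_hat - 2) * D[x][y] - Rhat[x] - Rhat[y]
                if q < best_q:
                    best_q = q
                    best_nodes = (x, y)
        assert best_nodes is not None
        x, y = best_nodes

        # orient the paths so x sits at the end of A and y at the start of B
        if A[-1] != x:
            A = list(reversed(A))
        if B[0] != y:
            B = list(reversed(B))
        path = A + B
        while len(path) > 2:
            u, v = reduce3(path[0], path[1], path[2])
            path = [u, v] + path[3:]
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(path)

    # close the remaining nodes (2 or 3) into a cycle
    clusters.sort(key=min)
    cycle: list[int] = [node for c in clusters for node in c]

    for u, v, x, y, z in reversed(reductions):
        L = len(cycle)
        if L == 2:
            if set(cycle) != {u, v}:
                raise AssertionError("inconsistent reduction stack")
            cycle = [x, y, z] if cycle[0] == u else [z, y, x]
            continue
        iu = cycle.index(u)
        if cycle[(iu + 1) % L] == v:
            rotated = cycle[iu:] + cycle[:iu]  # starts [u, v, ...]
            cycle = [x, y, z] + rotated[2:]
        elif cycle[(iu - 1) % L] == v:
            iv = (iu - 1) % L
            rotated = cycle[iv:] + cycle[:iv]  # starts [v, u, ...]
            cycle = [z, y, x] + rotated[2:]
        else:
            raise AssertionError("reduced pair not adjacent in cycle")

    if sorted(cycle) != list(range(n)):
        raise AssertionError("expansion did not restore all taxa")

    # normalize rotation and direction
    i0 = cycle.index(0)
    cycle = cycle[i0:] + cycle[:i0]
    if n > 2 and cycle[1] > cycle[-1]:
        cycle = [cycle[0]] + list(reversed(cycle[1:]))
    return [labels[i] for i in cycle]


# ---------------------------------------------------------------------------
# split weight estimation
# ---------------------------------------------------------------------------

def circular_splits(order: Sequence[str]) -> list[frozenset[str]]:
    """Enumerate all n(n-1)/2 interval splits of a circular ordering.

    Each split is given as the interval side that excludes the first
    element of ``order``.
    """
    order = list(order)
    n = len(order)
    return [
        frozenset(order[i: j + 1])
        for i in range(1, n)
        for j in range(i, n)
    ]


def _pair_index(n: int) -> list[tuple[int, int]]:
    return [(p, q) for p in range(n) for q in range(p + 1, n)]


def estimate_split_weights(
    dm: DistanceMatrix,
    order: Sequence[str],
    nonneg: bool = True,
    drop_threshold: float = 1e-8,
) -> CircularSplitSystem:
    """Least-squares split weights for the interval splits of ``order``.

    Solves ``min || d - X w ||`` where column s of the design matrix X
    is the split metric of interval split s (1 for separated taxon
    pairs).  With ``nonneg`` (default) the weights are constrained to
    be >= 0 via an active-set NNLS solver; otherwise an unconstrained
    least-squares solution is used.  Splits with weight at or below
    ``drop_threshold`` are discarded (trivial singleton splits are kept
    whenever their weight survives — they carry the terminal edge
    lengths of the drawn network).
    """
    _validate_dm(dm, 2)
    labels = list(dm.ids)
    if sorted(order) != sorted(labels):
        raise ValueError("order must cover exactly the taxa of the distance matrix")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxa labels")
    n = len(labels)
    sides = circular_splits(order)
    pairs = _pair_index(n)
    X = np.zeros((len(pairs), len(sides)))
    member = [
        np.array([labels[i] in side for i in range(n)]) for side in sides
    ]
    for col, mem in enumerate(member):
        for row, (p, q) in enumerate(pairs):
            if mem[p] != mem[q]:
                X[row, col] = 1.0
    dvec = np.array([dm.data[p, q] for p, q in pairs])
    if nonneg:
        w, _ = nnls(X, dvec)
    else:
        w, *_ = np.linalg.lstsq(X, dvec, rcond=None)
    raw = [
        (side, float(wi))
        for side, wi in zip(sides, w)
        if wi > drop_threshold
    ]
    return CircularSplitSystem(
        taxa=tuple(labels),
        circular_order=tuple(order),
        splits=_canonical_splits(labels, raw),
    )


def split_decomposition_distance(css: CircularSplitSystem) -> DistanceMatrix:
    """Distance matrix induced by a split system (sum of separating weights)."""
    n = css.ntax
    mat = np.zeros((n, n))
    for s in css.splits:
        mem = np.array([t in s.side_a for t in css.taxa])
        sep = mem[:, None] != mem[None, :]
        mat[sep] += s.weight
    return DistanceMatrix(mat, list(css.taxa))


# ---------------------------------------------------------------------------
# neighbor joining oracle
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as newick text (via scikit-bio).

    Used as an independent check: on additive (tree-like) distances the
    NeighborNet split system must reduce to this tree's bipartitions.
    """
    _validate_dm(dm, 3)
    tree = _skbio_nj(dm)
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


# ---------------------------------------------------------------------------
# NEXUS (SplitsTree-4 dialect)
# ---------------------------------------------------------------------------

def write_nexus_splits(css: CircularSplitSystem, path: str | Path) -> Path:
    """Write TAXA + SPLITS blocks loadable by SplitsTree 4.

    The CYCLE line uses 1-based taxon indices; each MATRIX row lists a
    split's weight and the members of the side containing taxon 1.
    Split rows are ordered by weight descending, then lexicographically.
    """
    path = Path(path)
    taxa = css.taxa
    index = {t: i + 1 for i, t in enumerate(taxa)}
    lines = ["#nexus", "", "BEGIN Taxa;", f"DIMENSIONS ntax={css.ntax};", "TAXLABELS"]
    for i, t in enumerate(taxa, start=1):
        lines.append(f"[{i}] '{t}'")
    lines += [";", "END; [Taxa]", "", "BEGIN Splits;"]
    lines.append(f"DIMENSIONS ntax={css.ntax} nsplits={len(css.splits)};")
    lines.append("FORMAT labels=no weights=yes confidences=no intervals=no;")
    lines.append("PROPERTIES cyclic;")
    lines.append("CYCLE " + " ".join(str(index[t]) for t in css.circular_order) + ";")
    lines.append("MATRIX")
    for k, s in enumerate(css.splits, start=1):
        side1 = sorted(index[t] for t in taxa if t not in s.side_a)
        lines.append(
            f"[{k}, size={len(side1)}]\t{s.weight:.10g}\t"
            + " ".join(str(i) for i in side1) + ","
        )
    lines += [";", "END; [Splits]", ""]
    path.write_text("\n".join(lines))
    return path


def read_nexus_splits(path: str | Path) -> CircularSplitSystem:
    """Read back a splits NEXUS file written by :func:`write_nexus_splits`."""
    text = Path(path).read_text()
    taxlabels = re.findall(r"\[\d+\]\s+'([^']*)'", text)
    if not taxlabels:
        raise ValueError(f"{path}: no TAXLABELS found")
    cyc = re.search(r"CYCLE\s+([0-9 ]+);", text)
    if not cyc:
        raise ValueError(f"{path}: no CYCLE line")
    order = [taxlabels[int(i) - 1] for i in cyc.group(1).split()]
    raw: list[tuple[frozenset[str], float]] = []
    matrix = text.split("MATRIX", 1)[1]
    for line in matrix.splitlines():
        line = line.strip().rstrip(",")
        if not line or line.startswith((";", "END")):
            continue
        m = re.match(r"\[\d+, size=\d+\]\s+(\S+)\s+([0-9 ]+)$", line)
        if not m:
            continue
        weight = float(m.group(1))
        side1 = frozenset(taxlabels[int(i) - 1] for i in m.group(2).split())
        raw.append((side1, weight))
    return CircularSplitSystem(
        taxa=tuple(taxlabels),
        circular_order=tuple(order),
        splits=_canonical_splits(taxlabels, raw),
    )


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class NeighborNet:
    """Split-network model for a labelled distance matrix.

    Parameters
    ----------
    dm
        Symmetric, hollow distance matrix with >= 4 taxa.

    Examples
    --------
    >>> res = NeighborNet(dm).fit()
    >>> res.circular_order
    >>> res.split_system.nontrivial_splits()
    """

    def __init__(self, dm: DistanceMatrix):
        _validate_dm(dm, 4)
        self.dm = dm

    def fit(
        self, nonneg: bool = True, drop_threshold: float = 1e-8
    ) -> "NeighborNetResults":
        order = neighbornet_order(self.dm)
        css = estimate_split_weights(
            self.dm, order, nonneg=nonneg, drop_threshold=drop_threshold
        )
        return NeighborNetResults(self, css)


class NeighborNetResults:
    """Fitted circular split system with residual diagnostics."""

    def __init__(self, model: NeighborNet, split_system: CircularSplitSystem):
        self.model = model
        self.split_system = split_system

    @property
    def circular_order(self) -> tuple[str, ...]:
        return self.split_system.circular_order

    @property
    def nsplits(self) -> int:
        return len(self.split_system.splits)

    def fitted(self) -> DistanceMatrix:
        """Distances reconstructed from the weighted splits."""
        return split_decomposition_distance(self.split_system)

    @property
    def residual_norm(self) -> float:
        """Euclidean norm of observed-minus-fitted over taxon pairs."""
        obs = self.model.dm.filter(self.split_system.taxa).data
        fit = self.fitted().data
        iu = np.triu_indices_from(obs, k=1)
        return float(np.linalg.norm(obs[iu] - fit[iu]))

    def to_nexus(self, path: str | Path) -> Path:
        return write_nexus_splits(self.split_system, path)

    def summary(self) -> str:
        css = self.split_system
        lines = [
            "NeighborNet split network",
            "=" * 40,
            f"taxa:              {css.ntax}",
            f"circular order:    {' '.join(css.circular_order)}",
            f"splits retained:   {self.nsplits} "
            f"({len(css.nontrivial_splits())} non-trivial)",
            f"residual norm:     {self.residual_norm:.6g}",
            "",
            f"{'weight':>12}  split (side without " + css.taxa[0] + ")",
        ]
        for s in css.splits[:20]:
            lines.append(f"{s.weight:>12.5f}  {{{', '.join(sorted(s.side_a))}}}")
        if self.nsplits > 20:
            lines.append(f"... {self.nsplits - 20} more")
        return "\n".join(lines)
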