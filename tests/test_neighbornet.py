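"""NeighborNet ordering, split-weight estimation, NEXUS round trips."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from cranionet.neighbornet import (
    NeighborNet,
    circular_splits,
    estimate_split_weights,
    neighbornet_order,
    nj_tree,
    read_nexus_splits,
    split_decomposition_distance,
    write_nexus_splits,
)
from conftest import (
    planted_circular_metric,
    random_binary_tree_metric,
    tree_nontrivial_splits_from_newick,
)


def _contiguous(order, group):
    """True if the taxa in ``group`` occupy consecutive cycle positions."""
    n = len(order)
    pos = sorted(order.index(g) for g in group)
    span = [(p - pos[0]) % n for p in pos]
    if sorted(span) == list(range(len(group))):
        return True
    # wrap-around: the complement must then be contiguous
    comp = [t for t in order if t not in group]
    pos = sorted(order.index(c) for c in comp)
    span = [(p - pos[0]) % n for p in pos]
    return sorted(span) == list(range(len(comp)))


class TestOrdering:
    def test_quartet_cherries_contiguous(self, quartet_tree_dm):
        order = neighbornet_order(quartet_tree_dm)
        assert _contiguous(order, {"A", "B"})
        assert _contiguous(order, {"C", "D"})

    def test_equal_distances_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(d, list("ABCDE"))
        first = neighbornet_order(dm)
        assert sorted(first) == list("ABCDE")
        for _ in range(3):
            assert neighbornet_order(dm) == first

    def test_planted_splits_are_intervals_of_recovered_order(self):
        rng = np.random.default_rng(42)
        true_order = ["A", "C", "E", "B", "F", "D"]
        dm, planted = planted_circular_metric(true_order, rng, n_nontrivial=4)
        order = neighbornet_order(dm)
        for side in planted:
            assert _contiguous(order, side), (side, order)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), list("ABC"))
        with pytest.raises(ValueError, match="at least 4"):
            neighbornet_order(dm)

    def test_nan_rejected(self):
        d = np.zeros((4, 4))
        dm = DistanceMatrix(d, list("ABCD"))
        dm.data[0, 1] = dm.data[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            neighbornet_order(dm)


class TestSplitWeights:
    def test_planted_weights_recovered(self):
        rng = np.random.default_rng(0)
        true_order = ["A", "C", "E", "B", "F", "D", "G", "H"]
        dm, planted = planted_circular_metric(true_order, rng, n_nontrivial=5)
        css = estimate_split_weights(dm, neighbornet_order(dm))
        got = {s.side_a: s.weight for s in css.splits}
        for side, w in planted.items():
            assert got.get(side, 0.0) == pytest.approx(w, abs=1e-6)
        extras = set(got) - set(planted)
        assert all(got[s] < 1e-6 for s in extras)
        rec = split_decomposition_distance(css)
        assert np.abs(rec.filter(dm.ids).data - dm.data).max() < 1e-8

    def test_tree_metric_yields_exactly_tree_splits(self, quartet_tree_dm):
        css = estimate_split_weights(quartet_tree_dm, neighbornet_order(quartet_tree_dm))
        nontrivial = {frozenset(s.side_a) for s in css.nontrivial_splits()}
        assert nontrivial == {frozenset({"C", "D"})}
        trivial_weights = [s.weight for s in css.splits if s.is_trivial(4)]
        assert len(trivial_weights) == 4
        assert all(w == pytest.approx(1.0, abs=1e-8) for w in trivial_weights)

    def test_zero_matrix_gives_no_splits(self):
        dm = DistanceMatrix(np.zeros((5, 5)), list("ABCDE"))
        css = estimate_split_weights(dm, list("ABCDE"))
        assert css.splits == ()

    def test_candidate_split_count(self):
        order = list("ABCDEF")
        assert len(circular_splits(order)) == 6 * 5 // 2

    def test_nonneg_weights_and_circularity(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            m = rng.uniform(0.2, 2.0, (7, 7))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            dm = DistanceMatrix(m, [f"t{i}" for i in range(7)])
            css = NeighborNet(dm).fit().split_system
            assert all(s.weight >= 0 for s in css.splits)
            assert css.is_circular()

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0.2, 2.0, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(6)]
        dm = DistanceMatrix(m, labels)
        perm = [3, 0, 5, 1, 4, 2]
        dm_p = DistanceMatrix(m[np.ix_(perm, perm)], [labels[i] for i in perm])
        base = {
            (s.side_a, round(s.weight, 9))
            for s in NeighborNet(dm).fit().split_system.splits
        }
        permuted_css = NeighborNet(dm_p).fit().split_system
        # canonicalize permuted system's sides to exclude labels[0]
        taxa = set(labels)
        permuted = set()
        for s in permuted_css.splits:
            side = s.side_a if labels[0] not in s.side_a else frozenset(taxa - s.side_a)
            permuted.add((side, round(s.weight, 9)))
        assert base == permuted


class TestReconstruction:
    def test_single_split_metric(self):
        from cranionet.neighbornet import CircularSplitSystem, Split

        css = CircularSplitSystem(
            taxa=("A", "B", "C", "D"),
            circular_order=("A", "B", "C", "D"),
            splits=(Split(frozenset({"C", "D"}), 1.0),),
        )
        dm = split_decomposition_distance(css)
        assert dm["A", "C"] == 1.0
        assert dm["A", "B"] == 0.0

    def test_empty_system_gives_zero_matrix(self):
        from cranionet.neighbornet import CircularSplitSystem

        css = CircularSplitSystem(
            taxa=("A", "B", "C", "D"),
            circular_order=("A", "B", "C", "D"),
            splits=(),
        )
        assert split_decomposition_distance(css).data.max() == 0.0


class TestNJOracle:
    def _bruteforce_quartet(self, dm):
        """Best quartet topology by least-squares over the 3 pairings."""
        labels = list(dm.ids)
        best, best_sse = None, np.inf
        for pair in itertools.combinations(labels, 2):
            side = frozenset(pair)
            other = frozenset(set(labels) - side)
            # 5-parameter tree: 4 pendant edges + 1 internal
            pairs = list(itertools.combinations(range(4), 2))
            X = np.zeros((6, 5))
            for r, (i, j) in enumerate(pairs):
                X[r, i] = X[r, j] = 1
                sep = (labels[i] in side) != (labels[j] in side)
                X[r, 4] = 1.0 if sep else 0.0
            y = np.array([dm.data[i, j] for i, j in pairs])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = ((X @ coef - y) ** 2).sum()
            if sse < best_sse - 1e-12:
                best_sse, best = sse, (side if labels[0] not in side else other)
        return best

    def test_quartet_topology_matches_bruteforce(self, quartet_tree_dm):
        newick = nj_tree(quartet_tree_dm)
        got = tree_nontrivial_splits_from_newick(newick, list(quartet_tree_dm.ids))
        assert got == {self._bruteforce_quartet(quartet_tree_dm)}

    def test_label_permutation_same_topology(self):
        rng = np.random.default_rng(8)
        dm, true_splits = random_binary_tree_metric(rng, 6)
        labels = list(dm.ids)
        perm = [4, 2, 0, 5, 3, 1]
        dm_p = DistanceMatrix(
            dm.data[np.ix_(perm, perm)], [labels[i] for i in perm]
        )
        s1 = tree_nontrivial_splits_from_newick(nj_tree(dm), labels)
        s2 = tree_nontrivial_splits_from_newick(nj_tree(dm_p), labels)
        assert s1 == s2 == true_splits


class TestNexus:
    def _fit(self, seed=0):
        rng = np.random.default_rng(seed)
        dm, _ = planted_circular_metric(["A", "C", "E", "B", "F", "D"], rng)
        return NeighborNet(dm).fit()

    def test_round_trip_identity(self, tmp_path):
        res = self._fit()
        p = write_nexus_splits(res.split_system, tmp_path / "net.nex")
        back = read_nexus_splits(p)
        assert back.taxa == res.split_system.taxa
        assert back.circular_order == res.split_system.circular_order
        a = {(s.side_a, round(s.weight, 8)) for s in res.split_system.splits}
        b = {(s.side_a, round(s.weight, 8)) for s in back.splits}
        assert a == b

    def test_cycle_line_matches_order(self, tmp_path):
        res = self._fit(3)
        p = write_nexus_splits(res.split_system, tmp_path / "net.nex")
        text = p.read_text()
        taxa = res.split_system.taxa
        cycle_line = next(l for l in text.splitlines() if l.startswith("CYCLE"))
        indices = [int(i) for i in cycle_line[len("CYCLE"):].rstrip(";").split()]
        assert tuple(taxa[i - 1] for i in indices) == res.split_system.circular_order

    def test_declared_counts(self, tmp_path, quartet_tree_dm):
        res = NeighborNet(quartet_tree_dm).fit()
        p = write_nexus_splits(res.split_system, tmp_path / "net.nex")
        text = p.read_text()
        assert f"nsplits={res.nsplits}" in text
        assert "ntax=4" in text
        # quartet tree: 4 trivial + 1 internal split
        assert res.nsplits == 5


class TestResultsObject:
    def test_summary_and_residual(self, quartet_tree_dm):
        res = NeighborNet(quartet_tree_dm).fit()
        assert res.residual_norm < 1e-8
        text = res.summary()
        assert "taxa" in text and "residual" in text
        fitted = res.fitted()
        np.testing.assert_allclose(
            fitted.filter(quartet_tree_dm.ids).data, quartet_tree_dm.data, atol=1e-8
        )
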