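"""Distances, UPGMA, calibration and Robinson-Foulds comparison."""

import itertools

import numpy as np
import pytest
from conftest import random_distance_matrix

from phyloepi import (
    CalibrationSpec,
    DistanceMatrix,
    MultipleAlignment,
    TreeError,
    build_both_trees,
    calibrate,
    classify_alignment,
    p_distance,
    parse_newick,
    percent_identity,
    rf_distance,
    upgma,
)


def _aln(rows):
    taxa = tuple(f"t{i}" for i in range(len(rows)))
    return MultipleAlignment(taxa=taxa, rows=tuple(rows))


def _clade_heights(tree):
    """{frozenset(leaf labels): height} for every internal node."""
    heights = tree.heights()
    out = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        leaves = frozenset(l.name for l in tree.leaves() if _is_under(node, l))
        out[leaves] = heights[node]
    return out


def _is_under(ancestor, node):
    stack = [ancestor]
    while stack:
        cur = stack.pop()
        if cur is node:
            return True
        stack.extend(cur.children)
    return False


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACTT", 0.25),
            ("AC-T", "ACGT", 0.0),  # gap column excluded
            ("ACNT", "ACGT", 0.0),  # N column excluded
        ],
    )
    def test_pairwise_values(self, a, b, expected):
        assert p_distance(_aln([a, b])).values[0, 1] == pytest.approx(expected)

    def test_count_gaps_scores_indel_columns(self):
        d = p_distance(_aln(["AC-T", "ACGT"]), count_gaps=True)
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_no_comparable_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="t0.*t1"):
            p_distance(_aln(["--AT", "AT--"]))


class TestPercentIdentity:
    def test_identical_rows_are_100(self):
        pid = percent_identity(_aln(["ACGT", "ACGT"]))
        assert pid.values[0, 1] == pytest.approx(100.0)

    def test_three_quarters_identity(self):
        pid = percent_identity(_aln(["ACGT", "ACTT"]))
        assert pid.values[0, 1] == pytest.approx(75.0)

    def test_symmetric_with_100_diagonal(self):
        pid = percent_identity(_aln(["ACGTAC", "ACTTAC", "GCGTAA"]))
        assert np.allclose(pid.values, pid.values.T)
        assert np.allclose(np.diag(pid.values), 100.0)


def upgma_oracle(taxa, matrix):
    """Brute-force UPGMA recomputing cluster means from the original matrix.

    Independent of the production implementation: cluster distances are
    re-averaged over all original leaf pairs at every step.
    """
    clusters = [frozenset([i]) for i in range(len(taxa))]
    heights = {c: 0.0 for c in clusters}
    internal = {}
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = clusters[a], clusters[b]
            d = np.mean([matrix[i][j] for i in ca for j in cb])
            if d < best_d:
                best_d, best = d, (a, b)
        a, b = best
        merged = clusters[a] | clusters[b]
        h = best_d / 2.0
        heights[merged] = h
        internal[frozenset(taxa[i] for i in merged)] = h
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return internal


class TestUpgma:
    def test_hand_worked_three_taxon_example(self):
        dm = DistanceMatrix(
            taxa=("A", "B", "C"),
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
        )
        ch = _clade_heights(upgma(dm))
        assert ch[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert ch[frozenset({"A", "B", "C"})] == pytest.approx(2.0)

    def test_two_taxa_root_at_half_distance(self):
        dm = DistanceMatrix(
            taxa=("A", "B"), values=np.array([[0, 0.5], [0.5, 0]], float)
        )
        ch = _clade_heights(upgma(dm))
        assert ch[frozenset({"A", "B"})] == pytest.approx(0.25)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            taxa = tuple(f"t{i}" for i in range(n))
            v = random_distance_matrix(rng, n)
            mine = _clade_heights(upgma(DistanceMatrix(taxa=taxa, values=v)))
            oracle = upgma_oracle(taxa, v)
            assert set(mine) == set(oracle)
            for clade in oracle:
                assert mine[clade] == pytest.approx(oracle[clade], abs=1e-9)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            taxa = tuple(f"t{i}" for i in range(n))
            v = random_distance_matrix(rng, n)
            mine = _clade_heights(upgma(DistanceMatrix(taxa=taxa, values=v)))
            merge_heights = sorted(linkage(squareform(v), "average")[:, 2] / 2)
            assert np.allclose(sorted(mine.values()), merge_heights, atol=1e-9)

    def test_taxon_order_invariance_with_distinct_distances(self):
        rng = np.random.default_rng(9)
        n = 6
        taxa = tuple(f"t{i}" for i in range(n))
        v = random_distance_matrix(rng, n)
        ref = _clade_heights(upgma(DistanceMatrix(taxa=taxa, values=v)))
        perm = rng.permutation(n)
        ch = _clade_heights(
            upgma(
                DistanceMatrix(
                    taxa=tuple(taxa[i] for i in perm), values=v[np.ix_(perm, perm)]
                )
            )
        )
        assert ref == pytest.approx(ch)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            dm = DistanceMatrix(
                taxa=tuple(f"t{i}" for i in range(n)),
                values=random_distance_matrix(rng, n),
            )
            assert upgma(dm).is_ultrametric(tol=1e-9)

    def test_invalid_entries_rejected(self):
        bad = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="finite"):
            upgma(DistanceMatrix(taxa=("A", "B"), values=bad))

    def test_zero_matrix_collapses_to_star(self):
        dm = DistanceMatrix(taxa=("A", "B", "C"), values=np.zeros((3, 3)))
        tree = upgma(dm)
        assert len(tree.root.children) == 3
        assert all(h == 0 for h in tree.heights().values())


class TestCalibrate:
    def test_scale_factor_applied_to_all_heights(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        cal = calibrate(tree, CalibrationSpec("A", "B", 1.7))
        ch = _clade_heights(cal)
        assert ch[frozenset({"A", "B"})] == pytest.approx(1.7)
        assert ch[frozenset({"A", "B", "C"})] == pytest.approx(3.4)

    def test_tiny_heights_large_factor(self):
        tree = parse_newick("((A:0.0034,B:0.0034):0.0034,C:0.0068);")
        cal = calibrate(tree, CalibrationSpec("A", "B", 1.7))
        assert _clade_heights(cal)[frozenset({"A", "B"})] == pytest.approx(1.7)

    def test_recalibration_is_identity(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        spec = CalibrationSpec("A", "B", 1.7)
        once = calibrate(tree, spec)
        twice = calibrate(once, spec)
        assert _clade_heights(once) == pytest.approx(_clade_heights(twice))

    def test_height_ratios_preserved(self):
        tree = parse_newick("(((A:1,B:1):2,C:3):1,D:4);")
        cal = calibrate(tree, CalibrationSpec("A", "B", 1.7))
        h0, h1 = _clade_heights(tree), _clade_heights(cal)
        base = frozenset({"A", "B"})
        for clade in h0:
            assert h1[clade] / h1[base] == pytest.approx(h0[clade] / h0[base])

    def test_zero_height_node_rejected(self):
        tree = parse_newick("((A:0,B:0):1,C:1);")
        with pytest.raises(TreeError, match="zero-height"):
            calibrate(tree, CalibrationSpec("A", "B", 1.7))

    def test_missing_taxon_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(TreeError, match="not in tree"):
            calibrate(tree, CalibrationSpec("A", "Z", 1.7))


class TestRfDistance:
    def test_identical_topologies(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((D:2,C:2):2,(B:2,A:2):2);")
        assert rf_distance(t1, t2) == 0

    def test_conflicting_quartets(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_star_vs_resolved(self):
        star = parse_newick("(A:1,B:1,C:1,D:1);")
        resolved = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(star, resolved) == 1

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(TreeError, match="leaf sets"):
            rf_distance(parse_newick("(A:1,B:1);"), parse_newick("(A:1,C:1);"))


class TestBuildBothTrees:
    def test_one_variable_recoded_column_gives_two_clusters(self):
        aln = _aln(["CGCG", "CGTG", "CGTG"])
        sc = classify_alignment(aln)
        _, t_epi = build_both_trees(aln, sc)
        ch = _clade_heights(t_epi)
        assert frozenset({"t1", "t2"}) in ch

    def test_calibration_applied_to_both(self):
        aln = _aln(["CGCGAT", "CGTGAT", "TGTGGC"])
        sc = classify_alignment(aln)
        spec = CalibrationSpec("t0", "t1", 1.7)
        t_gen, t_epi = build_both_trees(aln, sc, calibration=spec)
        for t in (t_gen, t_epi):
            assert _clade_heights(t)[frozenset({"t0", "t1"})] == pytest.approx(1.7)
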