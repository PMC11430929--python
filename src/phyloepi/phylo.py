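"""Distance matrices, UPGMA, divergence-time calibration, tree comparison.

UPGMA is implemented from scratch: iteratively merge the closest pair of
clusters, place the new node at half the merge distance, and update
distances by the size-weighted arithmetic mean (UPGMA proper, not
WPGMA).  Under the molecular-clock assumption the result is ultrametric,
so a single known divergence age (here typically the chimpanzee–bonobo
split) rescales the whole tree to absolute time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from dendropy.calculate import treecompare

from .io_align import MultipleAlignment, Tree, TreeError, TreeNode
from .recode import RecodedAlignment


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise matrix; ``kind`` is 'distance' or 'similarity'."""

    taxa: tuple[str, ...]
    values: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T, atol=1e-12, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if self.kind == "distance":
            if not np.allclose(np.diag(v), 0.0):
                raise ValueError("distance matrix diagonal must be zero")
        elif self.kind != "similarity":
            raise ValueError(f"unknown matrix kind {self.kind!r}")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path, decimals: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for taxon, row in zip(self.taxa, self.values):
                fh.write(
                    taxon + "\t" + "\t".join(f"{x:.{decimals}f}" for x in row) + "\n"
                )


@dataclass(frozen=True)
class CalibrationSpec:
    """Pin the divergence of two named taxa to a known age (in My)."""

    taxon_a: str
    taxon_b: str
    age: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("calibration age must be positive")
        if self.taxon_a == self.taxon_b:
            raise ValueError("calibration taxa must differ")


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _rows_of(x: MultipleAlignment | RecodedAlignment) -> tuple[tuple[str, ...], tuple[str, ...]]:
    return tuple(x.taxa), tuple(x.rows)


def _pair_counts(
    a: np.ndarray, b: np.ndarray, count_gaps: bool
) -> tuple[int, int]:
    """(mismatches, comparable columns) for two uint8-coded rows."""
    gap, nn = ord("-"), ord("N")
    ok_a = (a != gap) & (a != nn)
    ok_b = (b != gap) & (b != nn)
    both = ok_a & ok_b
    mism = int(np.sum(a[both] != b[both]))
    comp = int(np.sum(both))
    if count_gaps:
        # a gap opposite a residue scores as a difference; N and gap/gap stay out
        half = ((a == gap) & ok_b) | ((b == gap) & ok_a)
        mism += int(np.sum(half))
        comp += int(np.sum(half))
    return mism, comp


def p_distance(
    x: MultipleAlignment | RecodedAlignment, count_gaps: bool = False
) -> DistanceMatrix:
    """Proportion of differing sites over comparable columns, per pair."""
    taxa, rows = _rows_of(x)
    coded = [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in rows]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism, comp = _pair_counts(coded[i], coded[j], count_gaps)
            if comp == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            d[i, j] = d[j, i] = mism / comp
    return DistanceMatrix(taxa=taxa, values=d, kind="distance")


def percent_identity(
    aln: MultipleAlignment, count_gaps: bool = False
) -> DistanceMatrix:
    """Pairwise percent identity (similarity matrix, diagonal 100)."""
    pd = p_distance(aln, count_gaps=count_gaps)
    vals = 100.0 * (1.0 - pd.values)
    np.fill_diagonal(vals, 100.0)
    return DistanceMatrix(taxa=pd.taxa, values=vals, kind="similarity")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> Tree:
    """Agglomerative UPGMA: ultrametric tree with node height = d_min / 2.

    Ties on the minimum distance break on the lexicographically smallest
    cluster-index pair, where clusters are numbered in order of creation
    (leaves first, in input taxon order), making the result deterministic.
    Internal edges of exactly zero length are collapsed, so an all-zero
    matrix yields a star tree at height zero.
    """
    if dm.kind != "distance":
        raise ValueError("upgma requires a distance matrix, not a similarity")
    v = dm.values
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("distance matrix entries must be finite and non-negative")
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("upgma needs at least 2 taxa")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=dm.taxa[i]) for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(v[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active: list[int] = list(range(n))
    next_id = n

    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = math.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = dist[(i, j)]
                if dij < best_d or (dij == best_d and best is not None and (i, j) < best):
                    best_d = dij
                    best = (i, j)
        assert best is not None
        i, j = best
        h = best_d / 2.0
        children = []
        for cid in (i, j):
            child = nodes[cid]
            length = h - heights[cid]
            if length < -1e-12:
                raise TreeError("UPGMA produced a negative branch length")
            child.length = max(length, 0.0)
            children.append(child)
        new = TreeNode(children=children)
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            merged = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(k, next_id), max(k, next_id))] = merged
        nodes[next_id] = new
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    tree = Tree(root=nodes[active[0]])
    _collapse_zero_internal_edges(tree.root)
    return tree


def _collapse_zero_internal_edges(node: TreeNode) -> None:
    """Fold zero-length internal edges into their parent (multifurcation)."""
    new_children: list[TreeNode] = []
    for child in node.children:
        _collapse_zero_internal_edges(child)
        if not child.is_leaf and child.length == 0.0:
            new_children.extend(child.children)
        else:
            new_children.append(child)
    node.children = new_children


# ---------------------------------------------------------------------------
# Calibration and comparison
# ---------------------------------------------------------------------------

def calibrate(tree: Tree, spec: CalibrationSpec) -> Tree:
    """Rescale node heights so MRCA(taxon_a, taxon_b) sits at ``spec.age``."""
    heights = tree.heights()  # raises TreeError if not ultrametric
    mrca = tree.mrca([spec.taxon_a, spec.taxon_b])
    h = heights[mrca]
    if h <= 0:
        raise TreeError(
            f"zero-height calibration node for ({spec.taxon_a}, {spec.taxon_b})"
        )
    return tree.scaled(spec.age / h)


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Unrooted Robinson–Foulds symmetric difference of bipartitions."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise TreeError("trees have different leaf sets")
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(
        data=t1.newick(), schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    d2 = dendropy.Tree.get(
        data=t2.newick(), schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )
    return int(treecompare.symmetric_difference(d1, d2))


def build_both_trees(
    aln: MultipleAlignment,
    sc,
    calibration: CalibrationSpec | None = None,
    count_gaps: bool = False,
    include_consistent: bool = True,
) -> tuple[Tree, Tree]:
    """(genetic tree, phylo-epigenetic tree) from one alignment.

    The genetic tree is UPGMA on p-distances over the full alignment; the
    phylo-epigenetic tree is UPGMA on p-distances over the A/T recoded
    CpG matrix.  If a calibration is given, both trees are rescaled with it.
    """
    from .recode import recode_alignment  # local import avoids cycle at import time

    t_gen = upgma(p_distance(aln, count_gaps=count_gaps))
    ra = recode_alignment(sc, include_consistent=include_consistent)
    t_epi = upgma(p_distance(ra))
    if calibration is not None:
        t_gen = calibrate(t_gen, calibration)
        t_epi = calibrate(t_epi, calibration)
    return t_gen, t_epi
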