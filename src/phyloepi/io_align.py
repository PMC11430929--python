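"""Alignment, region-map and tree containers plus FASTA/Newick I/O.

Coordinates are 0-based, half-open, in aligned-column space throughout.
The only gap character is ``-``; ``.`` is rejected loudly so that a
mixed-dialect alignment fails instead of being silently misread.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("phyloepi")

ALPHABET = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Raised when input records do not form a valid multiple alignment."""


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length aligned sequences over {A,C,G,T,N,-} with unique taxa.

    Taxon order is preserved from the input file and used downstream for
    deterministic tie-breaking.
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa/rows length mismatch")
        if len(self.taxa) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if any(not t for t in self.taxa):
            raise AlignmentError("empty taxon label")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                "not an alignment: rows have unequal lengths %s" % sorted(lengths)
            )
        if self.n_cols < 2:
            raise AlignmentError("alignment must have at least 2 columns")
        for t, r in zip(self.taxa, self.rows):
            bad = set(r) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"row {t!r} contains characters outside ACGTN-: {sorted(bad)}"
                )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, col: int) -> tuple[str, ...]:
        return tuple(r[col] for r in self.rows)


def _normalize_residues(raw: str, label: str) -> str:
    """Uppercase, map U->T, reject '.', map other aliens to N (warned)."""
    s = raw.upper().replace("U", "T")
    if "." in s:
        raise AlignmentError(
            f"record {label!r} uses '.' as a gap; only '-' is accepted"
        )
    bad = set(s) - ALPHABET
    if bad:
        log.warning(
            "record %r: %d character(s) outside ACGTN- mapped to N (%s)",
            label,
            sum(s.count(c) for c in bad),
            "".join(sorted(bad)),
        )
        s = "".join(c if c in ALPHABET else "N" for c in s)
    return s


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned multi-FASTA file into a :class:`MultipleAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise AlignmentError(f"{path}: an alignment needs at least 2 records")
    taxa: list[str] = []
    rows: list[str] = []
    for rec in records:
        if rec.id in taxa:
            raise AlignmentError(f"{path}: duplicate taxon label {rec.id!r}")
        taxa.append(rec.id)
        rows.append(_normalize_residues(str(rec.seq), rec.id))
    return MultipleAlignment(taxa=tuple(taxa), rows=tuple(rows))


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Region map (island name -> aligned-column interval)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Named, sorted, non-overlapping half-open column intervals."""

    entries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        prev_end = 0
        for name, start, end in self.entries:
            if start < 0 or end <= start:
                raise ValueError(f"region {name!r}: bad interval [{start},{end})")
            if start < prev_end:
                raise ValueError(f"region {name!r} overlaps previous region")
            prev_end = end

    @classmethod
    def from_tsv(cls, path: str | Path, n_cols: int | None = None) -> "RegionMap":
        entries: list[tuple[str, int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, start, end = line.split("\t")[:3]
                entries.append((name, int(start), int(end)))
        entries.sort(key=lambda e: e[1])
        rm = cls(entries=tuple(entries))
        if n_cols is not None and rm.entries and rm.entries[-1][2] > n_cols:
            raise ValueError("region map extends beyond alignment length")
        return rm

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, start, end in self.entries:
                fh.write(f"{name}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """A rooted tree node; ``length`` is the edge length to the parent."""

    __slots__ = ("name", "children", "length")

    def __init__(
        self,
        name: str | None = None,
        children: list["TreeNode"] | None = None,
        length: float | None = None,
    ) -> None:
        self.name = name
        self.children: list[TreeNode] = children if children is not None else []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


@dataclass
class Tree:
    """Rooted tree with per-edge lengths; heights derived when ultrametric."""

    root: TreeNode

    # -- traversal ----------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> tuple[str, ...]:
        names = tuple(n.name or "" for n in self.leaves())
        if len(set(names)) != len(names) or any(not n for n in names):
            raise TreeError("leaf labels must be unique and non-empty")
        return names

    # -- geometry -----------------------------------------------------------
    def depths(self) -> dict[TreeNode, float]:
        """Distance from the root to every node (root edge length ignored)."""
        d: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            for child in node.children:
                if child.length is None:
                    raise TreeError("tree has edges without lengths")
                d[child] = d[node] + child.length
        return d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.depths()
        leaf_depths = [depths[n] for n in self.leaves()]
        return max(leaf_depths) - min(leaf_depths) <= tol

    def heights(self, tol: float = 1e-6) -> dict[TreeNode, float]:
        """Node heights (leaves at ~0); requires an ultrametric tree."""
        depths = self.depths()
        leaf_depths = [depths[n] for n in self.leaves()]
        total = max(leaf_depths)
        if total > 0 and (max(leaf_depths) - min(leaf_depths)) > tol * max(1.0, total):
            raise TreeError("tree is not ultrametric; node heights are undefined")
        return {node: total - depth for node, depth in depths.items()}

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        want = set(labels)
        missing = want - set(self.leaf_names)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name}  # type: ignore[arg-type]
            else:
                below[node] = set().union(*(below[c] for c in node.children))
        candidates = [n for n in self.postorder() if want <= below[n]]
        return candidates[0]  # postorder: first superset is the smallest

    def scaled(self, factor: float) -> "Tree":
        """A copy with every edge length multiplied by ``factor``."""
        t = copy.deepcopy(self)
        for node in t.preorder():
            if node.length is not None:
                node.length = node.length * factor
        return t

    # -- serialization ------------------------------------------------------
    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name or ""
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.length is not None:
                return f"{core}:{node.length:.17g}"
            return core

        return render(self.root) + ";"


def _from_dendropy(dnode: "dendropy.Node") -> TreeNode:
    name = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = TreeNode(name=name, length=dnode.edge.length)
    node.children = [_from_dendropy(c) for c in dnode.child_nodes()]
    return node


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None  # root edge is meaningless here
    return Tree(root=root)


def read_newick(path: str | Path) -> Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: Tree, path: str | Path) -> None:
    """Write Newick with branch lengths; rejects negative edge lengths."""
    for node in tree.preorder():
        if node.length is not None and node.length < 0:
            raise TreeError(
                f"negative branch length {node.length} (ultrametric violation)"
            )
    Path(path).write_text(tree.newick() + "\n")
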