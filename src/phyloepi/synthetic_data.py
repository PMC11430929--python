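"""Sequence-evolution simulator with CpG hypermutability.

Generates gap-free multi-taxon alignments along a known ultrametric tree
so every analysis stage can be tested against planted ground truth.  The
root sequence mimics a concatenated run of CpG islands: GC-rich
background with CpG dinucleotides planted at frame-aligned (even)
offsets at a target density.  Evolution along each branch is an exact
Gillespie simulation of a context-dependent substitution process:

* non-CpG context: HKY-like, total leave rate mu per site, transitions
  favoured over each transversion by kappa;
* CpG context: the C (and, symmetrically on the other strand, the G) of
  a CG dinucleotide undergoes its deamination transition (C->T, G->A) at
  lambda times the context-free transition rate, re-evaluating context
  after every event.

With lambda = 1 the process reduces exactly to the context-free model.
No indels are simulated, so columns are homologous by construction and
the planted CpG site set is exact ground truth at divergence zero.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_align import MultipleAlignment, Tree, TreeNode, parse_newick

log = logging.getLogger("phyloepi")

_BASES = "ACGT"
_A, _C, _G, _T = 0, 1, 2, 3
_TRANSITION = {_A: _G, _G: _A, _C: _T, _T: _C}

#: 7-taxon hominid topology with node ages in My.
HOMINID_TREE = (
    "((((human:0.65,(neanderthal:0.43,denisovan:0.43):0.22):4.35,"
    "(chimp:1.7,bonobo:1.7):3.3):3.0,gorilla:8.0):6.0,orangutan:14.0);"
)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    tree
        Newick with branch lengths; here interpreted in My.
    seq_length
        Alignment length (even; default emulates ~27 kb of islands).
    cpg_fraction
        Target fraction of frame-aligned dinucleotide positions that are
        CpG at the root (default 0.18 ~ 2495/13530).
    base_rate
        mu, substitutions/site/unit branch length in non-CpG context.
    cpg_multiplier
        lambda >= 1, fold excess of the CpG deamination transition over
        the context-free transition rate (mechanistic range 10-50).
    kappa
        Transition/transversion rate ratio outside CpG context.
    seed
        Master seed; the root sequence and every branch draw independent
        substreams from it, keyed by the branch's leaf set, so adding
        taxa does not perturb existing branches.
    """

    tree: str
    seq_length: int = 27000
    cpg_fraction: float = 0.18
    base_rate: float = 3.6e-4
    cpg_multiplier: float = 20.0
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 2 or self.seq_length % 2:
            raise ValueError("seq_length must be even and >= 2")
        if not 0 <= self.cpg_fraction < 0.5:
            raise ValueError("cpg_fraction must be in [0, 0.5)")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        if self.base_rate <= 0 or self.kappa <= 0:
            raise ValueError("base_rate and kappa must be positive")

    def as_dict(self) -> dict[str, object]:
        return {
            "tree": self.tree,
            "seq_length": self.seq_length,
            "cpg_fraction": self.cpg_fraction,
            "base_rate": self.base_rate,
            "cpg_multiplier": self.cpg_multiplier,
            "kappa": self.kappa,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SimEvent:
    """One substitution: branch key, site, bases, CpG-deamination flag."""

    branch: str
    site: int
    from_base: str
    to_base: str
    cpg_context: bool


@dataclass(frozen=True)
class SimResult:
    alignment: MultipleAlignment
    true_tree: Tree
    event_log: tuple[SimEvent, ...]
    planted_cpg_starts: tuple[int, ...]
    root_sequence: str


def hominid_preset(seed: int = 0) -> SimConfig:
    """Seven hominids with literature node ages (nea-den 0.43, human 0.65,
    chimp-bonobo 1.7, human-chimp 5, gorilla 8, orangutan 14 My)."""
    return SimConfig(tree=HOMINID_TREE, seed=seed)


# ---------------------------------------------------------------------------
# Root sequence
# ---------------------------------------------------------------------------

def _rng_for(seed: int, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def generate_root(cfg: SimConfig) -> tuple[str, tuple[int, ...]]:
    """GC-rich root with CpGs planted at even offsets; returns (seq, starts).

    The fill forbids incidental C->G adjacencies, so the planted CpGs are
    the only CG dinucleotides in the root and form exact ground truth.
    """
    rng = _rng_for(cfg.seed, "root")
    n = cfg.seq_length
    n_dinuc = n // 2
    n_cpg = int(np.floor(n_dinuc * cfg.cpg_fraction))
    if n_cpg > n_dinuc:
        raise ValueError("cpg_fraction unreachable for this seq_length")
    starts = np.sort(rng.choice(n_dinuc, size=n_cpg, replace=False)) * 2
    planted = set(int(s) for s in starts)

    # CpG-island-like background: 60% GC
    probs = np.array([0.2, 0.3, 0.3, 0.2])
    seq = rng.choice(4, size=n, p=probs).astype(np.int8)
    for s in planted:
        seq[s] = _C
        seq[s + 1] = _G
    planted_cols = planted | {s + 1 for s in planted}
    # left-to-right sweep removing accidental CG pairs in the fill
    for i in range(1, n):
        if i in planted_cols:
            continue
        if seq[i] == _G and seq[i - 1] == _C:
            seq[i] = int(rng.choice([_A, _C, _T], p=[0.2 / 0.7, 0.3 / 0.7, 0.2 / 0.7]))
    sequence = "".join(_BASES[b] for b in seq)
    assert all(sequence[s : s + 2] == "CG" for s in planted)
    return sequence, tuple(sorted(planted))


# ---------------------------------------------------------------------------
# Gillespie evolution
# ---------------------------------------------------------------------------

def _site_rate(seq: np.ndarray, i: int, mu: float, kappa: float, lam: float) -> float:
    extra = (lam - 1.0) * mu * kappa / (kappa + 2.0)
    r = mu
    n = len(seq)
    if seq[i] == _C and i + 1 < n and seq[i + 1] == _G:
        r += extra
    elif seq[i] == _G and i > 0 and seq[i - 1] == _C:
        r += extra
    return r


def _evolve_branch(
    parent_seq: np.ndarray,
    branch_len: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    branch_key: str,
    events: list[SimEvent],
) -> np.ndarray:
    mu, kappa, lam = cfg.base_rate, cfg.kappa, cfg.cpg_multiplier
    seq = parent_seq.copy()
    n = len(seq)
    rates = np.array(
        [_site_rate(seq, i, mu, kappa, lam) for i in range(n)], dtype=float
    )
    t = 0.0
    trans_w = mu * kappa / (kappa + 2.0)
    tv_w = mu / (kappa + 2.0)
    while True:
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t > branch_len:
            break
        u = rng.random() * total
        i = int(np.searchsorted(np.cumsum(rates), u, side="right"))
        i = min(i, n - 1)
        b = int(seq[i])
        is_cpg_c = b == _C and i + 1 < n and seq[i + 1] == _G
        is_cpg_g = b == _G and i > 0 and seq[i - 1] == _C
        targets = [x for x in range(4) if x != b]
        weights = []
        for x in targets:
            if x == _TRANSITION[b]:
                w = trans_w
                if is_cpg_c or is_cpg_g:
                    w *= lam
            else:
                w = tv_w
            weights.append(w)
        weights = np.asarray(weights)
        new = targets[int(rng.choice(3, p=weights / weights.sum()))]
        deam = (is_cpg_c and new == _T) or (is_cpg_g and new == _A)
        events.append(
            SimEvent(
                branch=branch_key,
                site=i,
                from_base=_BASES[b],
                to_base=_BASES[new],
                cpg_context=bool(deam),
            )
        )
        seq[i] = new
        for k in (i - 1, i, i + 1):
            if 0 <= k < n:
                rates[k] = _site_rate(seq, k, mu, kappa, lam)
    return seq


def _clade_key(node: TreeNode) -> str:
    leaves = sorted(
        n.name or "" for n in _iter_leaves(node)
    )
    return "|".join(leaves)


def _iter_leaves(node: TreeNode):
    if node.is_leaf:
        yield node
    else:
        for c in node.children:
            yield from _iter_leaves(c)


def evolve(cfg: SimConfig) -> SimResult:
    """Simulate the full tree; returns alignment, truth, and event log."""
    tree = parse_newick(cfg.tree)
    root_seq_str, planted = generate_root(cfg)
    root_seq = np.frombuffer(
        root_seq_str.encode("ascii"), dtype=np.uint8
    ).copy()
    lookup = np.zeros(128, dtype=np.int8)
    for idx, base in enumerate(_BASES):
        lookup[ord(base)] = idx
    root_codes = lookup[root_seq]

    events: list[SimEvent] = []
    leaf_rows: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            if child.length is None or child.length < 0:
                raise ValueError("simulation tree needs non-negative branch lengths")
            key = _clade_key(child)
            rng = _rng_for(cfg.seed, "branch:" + key)
            child_seq = _evolve_branch(seq, child.length, cfg, rng, key, events)
            if child.is_leaf:
                leaf_rows[child.name] = "".join(_BASES[b] for b in child_seq)
            else:
                descend(child, child_seq)

    descend(tree.root, root_codes)
    taxa = tree.leaf_names
    aln = MultipleAlignment(
        taxa=taxa, rows=tuple(leaf_rows[t] for t in taxa)
    )
    n_events = len(events)
    log.debug("simulated %d substitution events over %d taxa", n_events, len(taxa))
    return SimResult(
        alignment=aln,
        true_tree=tree,
        event_log=tuple(events),
        planted_cpg_starts=planted,
        root_sequence=root_seq_str,
    )


def replay_events(result: SimResult) -> dict[str, str]:
    """Re-derive every leaf sequence by replaying the event log from the root.

    Serves as a conservation check: the returned rows must equal the
    simulated alignment exactly.
    """
    by_branch: dict[str, list[SimEvent]] = {}
    for ev in result.event_log:
        by_branch.setdefault(ev.branch, []).append(ev)

    tree = result.true_tree
    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: list[str]) -> None:
        for child in node.children:
            child_seq = list(seq)
            for ev in by_branch.get(_clade_key(child), []):
                if child_seq[ev.site] != ev.from_base:
                    raise ValueError("event log inconsistent with parent sequence")
                child_seq[ev.site] = ev.to_base
            if child.is_leaf:
                out[child.name] = "".join(child_seq)
            else:
                descend(child, child_seq)

    descend(tree.root, list(result.root_sequence))
    return out


# ---------------------------------------------------------------------------
# Output helpers (simulate CLI)
# ---------------------------------------------------------------------------

def write_event_log(result: SimResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tsite\tfrom_base\tto_base\tcpg_context\n")
        for ev in result.event_log:
            fh.write(
                f"{ev.branch}\t{ev.site}\t{ev.from_base}\t{ev.to_base}\t"
                f"{int(ev.cpg_context)}\n"
            )
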