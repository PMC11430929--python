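"""Dinucleotide-site enumeration and CpG consistency classification.

The alignment is read as a sequence of dinucleotide sites.  In the default
``nonoverlapping`` frame the columns are paired (0,1), (2,3), ... — the
"divide the alignment by two" accounting — while the ``overlapping`` frame
considers every adjacent column pair, since the frame anchor is biologically
arbitrary.  Each site is classified by the CpG states of all taxa:

* ``CONSISTENT_CPG`` — every taxon reads CG;
* ``VARIABLE_CPG`` — at least one, but not all, taxa read CG;
* ``NONCPG_VARIABLE`` — no CG anywhere, but >= 2 distinct states;
* ``NONCPG_INVARIANT`` — no CG, all states identical;
* ``GAPPED`` — any taxon carries a gap or N (excluded from all counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from .io_align import MultipleAlignment

_STATE_ALPHABET = frozenset("ACGTN-")


class SiteClass(str, Enum):
    CONSISTENT_CPG = "CONSISTENT_CPG"
    VARIABLE_CPG = "VARIABLE_CPG"
    NONCPG_VARIABLE = "NONCPG_VARIABLE"
    NONCPG_INVARIANT = "NONCPG_INVARIANT"
    GAPPED = "GAPPED"


@dataclass(frozen=True)
class Site:
    """One dinucleotide site: start column, per-taxon 2-mers, class label."""

    start_col: int
    states: tuple[str, ...]
    label: SiteClass


@dataclass(frozen=True)
class SiteCounts:
    n_dinuc_sites: int
    n_cpg_sites: int
    n_consistent_cpg: int
    n_variable_cpg: int
    n_noncpg_variable: int
    n_noncpg_invariant: int
    n_gapped: int
    n_noncpg_snp_columns: int

    def __post_init__(self) -> None:
        if self.n_cpg_sites != self.n_consistent_cpg + self.n_variable_cpg:
            raise ValueError("n_cpg_sites must equal consistent + variable CpG")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_dinuc_sites": self.n_dinuc_sites,
            "n_cpg_sites": self.n_cpg_sites,
            "n_consistent_cpg": self.n_consistent_cpg,
            "n_variable_cpg": self.n_variable_cpg,
            "n_noncpg_variable": self.n_noncpg_variable,
            "n_noncpg_invariant": self.n_noncpg_invariant,
            "n_gapped": self.n_gapped,
            "n_noncpg_snp_columns": self.n_noncpg_snp_columns,
        }


@dataclass(frozen=True)
class SiteClassification:
    """Full per-site classification of an alignment plus aggregate counts."""

    taxa: tuple[str, ...]
    frame_mode: str
    sites: tuple[Site, ...]
    counts: SiteCounts


def enumerate_sites(
    aln: MultipleAlignment, frame_mode: str = "nonoverlapping"
) -> Iterator[tuple[int, tuple[str, ...]]]:
    """Yield (start_col, per-taxon dinucleotide states) for every site."""
    if frame_mode not in ("nonoverlapping", "overlapping"):
        raise ValueError(f"unknown frame_mode {frame_mode!r}")
    step = 2 if frame_mode == "nonoverlapping" else 1
    for start in range(0, aln.n_cols - 1, step):
        yield start, tuple(row[start : start + 2] for row in aln.rows)


def classify_site(states: Iterable[str]) -> SiteClass:
    """Classify one dinucleotide site from its per-taxon 2-mers."""
    states = tuple(states)
    for s in states:
        if len(s) != 2 or not set(s) <= _STATE_ALPHABET:
            raise ValueError(f"invalid dinucleotide state {s!r}")
    if any("-" in s or "N" in s for s in states):
        return SiteClass.GAPPED
    if all(s == "CG" for s in states):
        return SiteClass.CONSISTENT_CPG
    if any(s == "CG" for s in states):
        return SiteClass.VARIABLE_CPG
    if len(set(states)) >= 2:
        return SiteClass.NONCPG_VARIABLE
    return SiteClass.NONCPG_INVARIANT


def classify_alignment(
    aln: MultipleAlignment, frame_mode: str = "nonoverlapping"
) -> SiteClassification:
    """Classify every dinucleotide site and tally SNP columns outside CpGs."""
    sites: list[Site] = []
    tally = {c: 0 for c in SiteClass}
    cpg_columns: set[int] = set()
    for start, states in enumerate_sites(aln, frame_mode):
        label = classify_site(states)
        sites.append(Site(start_col=start, states=states, label=label))
        tally[label] += 1
        if label in (SiteClass.CONSISTENT_CPG, SiteClass.VARIABLE_CPG):
            cpg_columns.update((start, start + 1))

    # Single columns variable outside every CpG-class site: the conventional
    # SNP count the CpG signal is contrasted against.
    n_snp_cols = 0
    for col in range(aln.n_cols):
        if col in cpg_columns:
            continue
        residues = {row[col] for row in aln.rows if row[col] in "ACGT"}
        if len(residues) >= 2:
            n_snp_cols += 1

    counts = SiteCounts(
        n_dinuc_sites=len(sites),
        n_cpg_sites=tally[SiteClass.CONSISTENT_CPG] + tally[SiteClass.VARIABLE_CPG],
        n_consistent_cpg=tally[SiteClass.CONSISTENT_CPG],
        n_variable_cpg=tally[SiteClass.VARIABLE_CPG],
        n_noncpg_variable=tally[SiteClass.NONCPG_VARIABLE],
        n_noncpg_invariant=tally[SiteClass.NONCPG_INVARIANT],
        n_gapped=tally[SiteClass.GAPPED],
        n_noncpg_snp_columns=n_snp_cols,
    )
    return SiteClassification(
        taxa=aln.taxa, frame_mode=frame_mode, sites=tuple(sites), counts=counts
    )


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as in the reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_fractions(sc: SiteClassification | SiteCounts) -> dict[str, object]:
    """Headline percentages: CpG alteration rate and dinucleotide-level rates.

    ``percent_cpg_altered`` is reported rounded to the nearest integer with
    the exact value retained alongside; the dinucleotide-level percentages
    are reported to one decimal.  With no CpG sites the CpG alteration rate
    is undefined and reported as None (NA).
    """
    counts: SiteCounts = sc.counts if isinstance(sc, SiteClassification) else sc
    if counts.n_cpg_sites > 0:
        exact = 100.0 * counts.n_variable_cpg / counts.n_cpg_sites
        pct_alt: float | None = round_half_up(exact)
        pct_alt_exact: float | None = exact
    else:
        pct_alt = pct_alt_exact = None
    n_dinuc = counts.n_dinuc_sites
    return {
        "percent_cpg_altered": pct_alt,
        "percent_cpg_altered_exact": pct_alt_exact,
        "percent_dinuc_cpg_variable": round_half_up(
            100.0 * counts.n_variable_cpg / n_dinuc, 1
        )
        if n_dinuc
        else None,
        "percent_dinuc_noncpg_variable": round_half_up(
            100.0 * counts.n_noncpg_variable / n_dinuc, 1
        )
        if n_dinuc
        else None,
    }


def write_site_report(sc: SiteClassification, path: str | Path) -> None:
    """TSV site report: start_col, class, per-taxon states."""
    with open(path, "w") as fh:
        fh.write("start_col\tclass\t" + "\t".join(sc.taxa) + "\n")
        for site in sc.sites:
            fh.write(
                f"{site.start_col}\t{site.label.value}\t"
                + "\t".join(site.states)
                + "\n"
            )


def write_summary_json(sc: SiteClassification, path: str | Path) -> None:
    payload = {
        "frame_mode": sc.frame_mode,
        **sc.counts.as_dict(),
        **summarize_fractions(sc),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
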