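"""CpG mutation-spectrum counting over variable CpG sites.

Events are tallied per *distinct* non-CG state value per site, not per
taxon: several taxa sharing the same derived dinucleotide count once.
States one substitution away from CG fall into the six canonical classes
(CG->TG, CG->CA, CG->GG, CG->CC, CG->CT, CG->AG); doubly substituted
states go to an explicit ``other`` bin.  No ancestral reconstruction is
attempted — CG is taken as ancestral wherever any taxon retains it, a
deliberate simplification of the deamination-dominated regime.

The per-taxon "perspective" count asks, for each taxon, at how many sites
it still reads CG while at least one other taxon reads TG or CA (the two
strands' deamination products).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .cpg_classify import SiteClass, SiteClassification, round_half_up

#: Canonical single-substitution derived states, in conventional report order.
CLASS_ORDER: tuple[str, ...] = ("TG", "CA", "GG", "CC", "CT", "AG")

#: Deamination products of a methylated CpG (one per strand).
DEAMINATION_STATES: frozenset[str] = frozenset({"TG", "CA"})


def _class_of(state: str) -> str | None:
    """Map a derived dinucleotide to its CG->XY class, or None for 'other'."""
    diffs = sum(a != b for a, b in zip(state, "CG"))
    return state if diffs == 1 else None


@dataclass(frozen=True)
class MutationSpectrum:
    """Counts of CpG mutation classes plus per-taxon perspective counts."""

    class_counts: dict[str, int]
    other: int
    denominator: int
    perspective_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def class_percents(self) -> dict[str, float]:
        """Each class as a half-up one-decimal percent of all CpG sites."""
        if self.denominator == 0:
            return {k: 0.0 for k in self.class_counts}
        return {
            k: round_half_up(100.0 * v / self.denominator, 1)
            for k, v in self.class_counts.items()
        }


def count_classes(sc: SiteClassification) -> MutationSpectrum:
    """Bin every distinct derived state at each variable CpG site."""
    counts = {k: 0 for k in CLASS_ORDER}
    other = 0
    for site in sc.sites:
        if site.label is not SiteClass.VARIABLE_CPG:
            continue
        for state in sorted(set(site.states) - {"CG"}):
            cls = _class_of(state)
            if cls is not None and cls in counts:
                counts[cls] += 1
            else:
                other += 1
    return MutationSpectrum(
        class_counts=counts,
        other=other,
        denominator=sc.counts.n_cpg_sites,
        perspective_counts=perspective_counts(sc),
    )


def perspective_counts(sc: SiteClassification) -> dict[str, int]:
    """Per taxon: sites where it reads CG while another taxon reads TG/CA."""
    out = {t: 0 for t in sc.taxa}
    for site in sc.sites:
        if site.label is not SiteClass.VARIABLE_CPG:
            continue
        has_deamination = {s for s in site.states} & DEAMINATION_STATES
        if not has_deamination:
            continue
        for taxon, state in zip(sc.taxa, site.states):
            if state == "CG":
                out[taxon] += 1
    return out


def spectrum_to_dict(ms: MutationSpectrum) -> dict[str, object]:
    percents = ms.class_percents
    return {
        "denominator_cpg_sites": ms.denominator,
        "classes": [
            {
                "mutation_class": f"CG->{k}",
                "count": ms.class_counts[k],
                "percent_of_cpg_sites": percents[k],
            }
            for k in CLASS_ORDER
        ],
        "other": ms.other,
        "total_events": ms.total + ms.other,
        "perspective_counts": dict(ms.perspective_counts),
    }


def write_spectrum_json(ms: MutationSpectrum, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spectrum_to_dict(ms), indent=2) + "\n")


def write_spectrum_tsv(ms: MutationSpectrum, path: str | Path) -> None:
    """Deterministic TSV: the six classes in report order, then 'other'."""
    percents = ms.class_percents
    with open(path, "w") as fh:
        fh.write("mutation_class\tcount\tpercent_of_cpg_sites\n")
        for k in CLASS_ORDER:
            fh.write(f"CG->{k}\t{ms.class_counts[k]}\t{percents[k]:.1f}\n")
        fh.write(f"other\t{ms.other}\t\n")
        fh.write(f"# denominator_cpg_sites\t{ms.denominator}\t\n")
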