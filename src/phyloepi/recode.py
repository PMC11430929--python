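"""Binary A/T recoding of CpG-class sites (the phylo-epigenetic matrix).

Every gap-free dinucleotide site where at least one taxon reads CG emits
one binary character: per taxon, ``A`` if that taxon's state is CG and
``T`` otherwise.  Sites consistently CG in all taxa therefore become
invariant all-A columns; they are retained by default because the
distance between two recoded rows is deliberately diluted by the
conserved CpG background (dropping them rescales every p-distance and
hence every pre-calibration branch length).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cpg_classify import SiteClass, SiteClassification


@dataclass(frozen=True)
class RecodedAlignment:
    """A/T presence-absence matrix over CpG-class sites.

    ``site_index[j]`` is the original aligned start column of recoded
    column ``j``.
    """

    taxa: tuple[str, ...]
    chars: tuple[str, ...]
    site_index: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.chars):
            raise ValueError("taxa/chars length mismatch")
        for row in self.chars:
            if len(row) != len(self.site_index):
                raise ValueError("recoded row length != site_index length")
            if set(row) - {"A", "T"}:
                raise ValueError("recoded rows must contain only A/T")

    @property
    def n_cols(self) -> int:
        return len(self.site_index)

    # phylo.p_distance duck-types on .rows
    @property
    def rows(self) -> tuple[str, ...]:
        return self.chars


def recode_alignment(
    sc: SiteClassification, include_consistent: bool = True
) -> RecodedAlignment:
    """Build the A/T matrix from a site classification.

    ``include_consistent=False`` drops the invariant all-A columns from
    consistently conserved CpGs, keeping only variable sites.
    """
    keep = {SiteClass.VARIABLE_CPG}
    if include_consistent:
        keep.add(SiteClass.CONSISTENT_CPG)
    cols: list[tuple[str, ...]] = []
    index: list[int] = []
    for site in sc.sites:
        if site.label not in keep:
            continue
        cols.append(tuple("A" if s == "CG" else "T" for s in site.states))
        index.append(site.start_col)
    chars = tuple("".join(col[i] for col in cols) for i in range(len(sc.taxa)))
    return RecodedAlignment(taxa=sc.taxa, chars=chars, site_index=tuple(index))


def write_recoded_fasta(
    ra: RecodedAlignment, path: str | Path, map_path: str | Path | None = None
) -> None:
    """Write the A/T matrix as multi-FASTA plus a column-map sidecar TSV."""
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(ra.taxa, ra.chars)
    ]
    SeqIO.write(records, str(path), "fasta")
    if map_path is None:
        map_path = str(path) + ".columns.tsv"
    with open(map_path, "w") as fh:
        fh.write("recoded_col\taligned_start_col\n")
        for j, start in enumerate(ra.site_index):
            fh.write(f"{j}\t{start}\n")


def read_recoded_fasta(path: str | Path, map_path: str | Path) -> RecodedAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    index: list[int] = []
    with open(map_path) as fh:
        next(fh)  # header
        for line in fh:
            index.append(int(line.split("\t")[1]))
    return RecodedAlignment(
        taxa=tuple(r.id for r in records),
        chars=tuple(str(r.seq).upper() for r in records),
        site_index=tuple(index),
    )
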