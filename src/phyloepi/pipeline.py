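"""End-to-end orchestration: classify -> spectrum -> recode -> trees -> compare.

All products are computed in memory first and only written once every
stage has succeeded, so a failing run leaves no partial output behind.
Logging goes to stderr; data products only to files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import cpg_classify, phylo, recode, spectrum
from .io_align import MultipleAlignment, read_alignment, write_newick
from .phylo import CalibrationSpec

log = logging.getLogger("phyloepi")

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage-named failure of the end-to-end run."""


@dataclass(frozen=True)
class RunConfig:
    alignment_path: str | Path
    out_dir: str | Path
    frame_mode: str = "nonoverlapping"
    count_gaps: bool = False
    calibration: CalibrationSpec | None = None
    include_consistent: bool = True


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_all(cfg: RunConfig) -> dict[str, object]:
    """Run the whole analysis and write the report bundle; returns summary."""
    aln = _stage("read_alignment")(read_alignment)(cfg.alignment_path)
    sc = _stage("classify")(cpg_classify.classify_alignment)(aln, cfg.frame_mode)
    fractions = cpg_classify.summarize_fractions(sc)
    ms = _stage("spectrum")(spectrum.count_classes)(sc)
    if ms.total + ms.other < sc.counts.n_variable_cpg:
        raise PipelineError(
            "stage 'spectrum' failed: fewer mutation events than variable CpG "
            "sites (every variable site must contribute at least one event)"
        )
    ra = _stage("recode")(recode.recode_alignment)(
        sc, include_consistent=cfg.include_consistent
    )

    dm_full = _stage("dist_full")(phylo.p_distance)(aln, count_gaps=cfg.count_gaps)
    pid = _stage("identity")(phylo.percent_identity)(aln)
    dm_rec = _stage("dist_recoded")(phylo.p_distance)(ra)
    t_gen = _stage("upgma_genetic")(phylo.upgma)(dm_full)
    t_epi = _stage("upgma_epigenetic")(phylo.upgma)(dm_rec)

    t_gen_cal = t_epi_cal = None
    if cfg.calibration is not None:
        t_gen_cal = _stage("calibrate_genetic")(phylo.calibrate)(
            t_gen, cfg.calibration
        )
        t_epi_cal = _stage("calibrate_epigenetic")(phylo.calibrate)(
            t_epi, cfg.calibration
        )
    rf = _stage("compare")(phylo.rf_distance)(t_gen, t_epi)

    summary: dict[str, object] = {
        "schema_version": SCHEMA_VERSION,
        "n_taxa": aln.n_taxa,
        "n_cols": aln.n_cols,
        "frame_mode": sc.frame_mode,
        "counts": sc.counts.as_dict(),
        "fractions": fractions,
        "spectrum": spectrum.spectrum_to_dict(ms),
        "rf_genetic_vs_epigenetic": rf,
        "calibration": (
            {
                "taxon_a": cfg.calibration.taxon_a,
                "taxon_b": cfg.calibration.taxon_b,
                "age": cfg.calibration.age,
            }
            if cfg.calibration
            else None
        ),
    }

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cpg_classify.write_site_report(sc, out / "sites.tsv")
    cpg_classify.write_summary_json(sc, out / "classification.json")
    spectrum.write_spectrum_tsv(ms, out / "spectrum.tsv")
    spectrum.write_spectrum_json(ms, out / "spectrum.json")
    pid.to_tsv(out / "identity_matrix.tsv", decimals=2)
    dm_full.to_tsv(out / "distance_full.tsv")
    dm_rec.to_tsv(out / "distance_recoded.tsv")
    recode.write_recoded_fasta(
        ra, out / "recoded.fasta", out / "recoded_columns.tsv"
    )
    write_newick(t_gen, out / "tree_genetic.nwk")
    write_newick(t_epi, out / "tree_epigenetic.nwk")
    if t_gen_cal is not None and t_epi_cal is not None:
        write_newick(t_gen_cal, out / "tree_genetic_calibrated.nwk")
        write_newick(t_epi_cal, out / "tree_epigenetic_calibrated.nwk")
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log.info("report bundle written to %s", out)
    return summary
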