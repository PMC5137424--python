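"""End-to-end orchestration: scoring + classification, peak calling and
profile contrast from one :class:`~occupre.config.AnalysisConfig`.

Re-running with identical inputs, config and seed is bit-identical: no
wall-clock timestamps enter any output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .dependence import PREDependenceModel, PREDependenceResults, QCError
from .peaks import write_peaks
from .profiles import PeakProfileModel, PeakProfileResults
from .intervals import read_bed
from .tracks import read_bedgraph

logger = logging.getLogger(__name__)


def _load_tracks(paths, chrom: str):
    tracks = []
    for p in paths:
        d = read_bedgraph(p)
        if chrom not in d:
            raise ValueError(f"track {p} lacks chromosome {chrom}")
        tracks.append(d[chrom])
    return tracks


def _pad_to_common_length(track_groups: dict) -> None:
    """Zero-pad all tracks to the longest loaded track (bedGraph carries
    no chromosome length, so trailing zero coverage may be implicit)."""
    all_tracks = [t for ts in track_groups.values() for t in ts]
    target = max(len(t) for t in all_tracks)
    for t in all_tracks:
        if len(t) < target:
            t.values = np.concatenate(
                [t.values, np.zeros(target - len(t))]
            )


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run scoring, classification, peak calling and profiles; write the
    report bundle into ``config.outdir`` and return the result objects."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = read_bed(config.catalog_bed)
    if not catalog:
        raise ValueError(f"empty catalog {config.catalog_bed}")
    chroms = sorted({iv.chrom for iv in catalog})
    if len(chroms) != 1:
        raise NotImplementedError("run_pipeline handles one chromosome per run")
    chrom = chroms[0]

    chip = {
        "control": _load_tracks(config.chip_control, chrom),
        "mutant": _load_tracks(config.chip_mutant, chrom),
    }
    inputs = None
    if config.input_control and config.input_mutant:
        inputs = {
            "control": _load_tracks(config.input_control, chrom),
            "mutant": _load_tracks(config.input_mutant, chrom),
        }
    _pad_to_common_length(
        {**{f"chip_{g}": ts for g, ts in chip.items()},
         **({f"input_{g}": ts for g, ts in inputs.items()} if inputs else {})}
    )
    exclusions = read_bed(config.exclusions_bed) if config.exclusions_bed else []

    dep_model = PREDependenceModel(
        catalog,
        chip,
        inputs,
        exclusions=exclusions,
        window=config.window,
        scale=config.scale,
        qc_gate=config.qc_gate,
        dependent_below=config.dependent_below,
        independent_above=config.independent_above,
        weak_fraction=config.weak_fraction,
        weak_mode=config.weak_mode,
    )
    dep_res = dep_model.fit(enforce_qc=not config.force)

    prof_model = PeakProfileModel(
        chip["control"],
        chip["mutant"],
        control_inputs=inputs["control"] if inputs else (),
        mutant_inputs=inputs["mutant"] if inputs else (),
        flank=config.flank,
        bin_width=config.bin_width,
        profile_span=config.profile_span,
        diff_span=config.diff_span,
        n_points=config.n_points,
        k_sd=config.k_sd,
        max_gap=config.max_gap,
        summit_window=config.window,
        isolation_distance=config.isolation_distance,
        n_background_bins=config.n_background_bins,
        diff_scale=config.diff_scale,
    )
    prof_res = prof_model.fit(seed=config.seed)

    write_report(config, dep_res, prof_res, outdir)
    return {"dependence": dep_res, "profiles": prof_res}


def write_report(
    config: AnalysisConfig,
    dep_res: PREDependenceResults,
    prof_res: PeakProfileResults,
    outdir: Path,
) -> None:
    outdir = Path(outdir)
    dep_res.table.to_csv(outdir / "scores.tsv", sep="\t", index=False,
                         float_format="%.6g")
    summary = {
        "classes": dep_res.class_summary(),
        "concordance": dep_res.concordance,
        "qc_passed": dep_res.qc_passed(),
        "rd_formula": dep_res.rd_formula,
        "median_RD": float(dep_res.classified["RD"].median()),
        "median_ratio": float(dep_res.classified["ratio"].median()),
        "wilcoxon_chip_vs_input": dep_res.wilcoxon,
        "n_peaks": len(prof_res.peaks),
        "n_isolated_peaks": len(prof_res.isolated),
        "background": prof_res.background,
        "distal_vs_summit": prof_res.distal_vs_summit(),
        "seed": config.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_peaks(prof_res.peaks, outdir / "peaks.bed")
    for name, pm in prof_res.profiles.items():
        pm.to_frame().to_csv(outdir / f"profile_{name}.tsv", sep="\t",
                             float_format="%.6g")
    prof_res.curves_frame().to_csv(outdir / "curves.tsv", sep="\t", index=False,
                                   float_format="%.6g")
    config.to_yaml(outdir / "config_echo.yaml")
    _write_run_log(config, dep_res, prof_res, outdir / "run_log.txt")
    logger.info("report bundle written to %s", outdir)


def _write_run_log(config, dep_res, prof_res, path) -> None:
    import occupre

    filtered = dep_res.table["filtered_reason"].value_counts().to_dict()
    lines = [
        f"occupre {occupre.__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {config.seed}",
        "",
        dep_res.summary(),
        "",
        f"filter decisions: {json.dumps(filtered, sort_keys=True)}",
        "",
        prof_res.summary(),
        "",
    ]
    Path(path).write_text("\n".join(lines))
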