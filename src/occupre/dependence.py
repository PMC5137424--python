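"""Element-level PRC-dependence analysis as a model/results pair.

:class:`PREDependenceModel` scores a catalog of ~1 kb elements on ChIP
coverage tracks from two genotypes (control and mutant), and its
:meth:`~PREDependenceModel.fit` returns :class:`PREDependenceResults`
holding per-element scores, relative differences, ratios, dependence
classes, replicate-concordance QC, and the Wilcoxon comparison of the
ChIP RD distribution against the matched input RD distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .scoring import (
    CLASSES,
    classify_pre,
    compare_distributions,
    filter_pres,
    normalize_score,
    relative_difference,
    replicate_concordance,
    score_ratio,
    top_window_mean,
)
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)


class QCError(RuntimeError):
    """Raised when replicate concordance fails the QC gate."""


class PREDependenceModel:
    """Comparative occupancy model over a fixed element catalog.

    Parameters
    ----------
    catalog : sequence of GenomicInterval
        Candidate elements (~1 kb each).
    chip_tracks : mapping genotype -> sequence of CoverageTrack
        Replicate ChIP coverage per genotype; must contain the
        ``control`` and ``mutant`` keys.
    input_tracks : mapping, optional
        Matched input libraries in the same layout; enables the
        input-control RD distribution and the Wilcoxon contrast.
    exclusions : sequence of GenomicInterval
        Regions whose overlapping elements are removed (e.g. a deletion
        present in the mutant genotype).
    window : int
        Length of the top-scoring window statistic (consecutive positions).
    scale : float
        Depth-normalization scale (reads per ``scale`` mapped reads).
    qc_gate : float
        Minimum replicate Pearson correlation.
    """

    def __init__(
        self,
        catalog: Sequence[GenomicInterval],
        chip_tracks: Mapping[str, Sequence[CoverageTrack]],
        input_tracks: Mapping[str, Sequence[CoverageTrack]] | None = None,
        exclusions: Sequence[GenomicInterval] = (),
        window: int = 6,
        scale: float = 1e6,
        qc_gate: float = 0.90,
        dependent_below: float = -1.0,
        independent_above: float = -0.5,
        weak_fraction: float = 0.30,
        weak_mode: str = "range",
        control_key: str = "control",
        mutant_key: str = "mutant",
    ) -> None:
        if not catalog:
            raise ValueError("empty element catalog")
        for key in (control_key, mutant_key):
            if key not in chip_tracks:
                raise ValueError(f"chip_tracks must contain {key!r}")
        self.catalog = list(catalog)
        self.chip_tracks = {g: list(ts) for g, ts in chip_tracks.items()}
        self.input_tracks = (
            {g: list(ts) for g, ts in input_tracks.items()} if input_tracks else None
        )
        self.exclusions = list(exclusions)
        self.window = window
        self.scale = scale
        self.qc_gate = qc_gate
        self.dependent_below = dependent_below
        self.independent_above = independent_above
        self.weak_fraction = weak_fraction
        self.weak_mode = weak_mode
        self.control_key = control_key
        self.mutant_key = mutant_key

    @classmethod
    def from_files(
        cls,
        catalog_bed,
        chip_bedgraphs: Mapping[str, Sequence],
        input_bedgraphs: Mapping[str, Sequence] | None = None,
        exclusions_bed=None,
        **kwargs,
    ) -> "PREDependenceModel":
        """Build the model from a BED catalog and bedGraph track files.

        Each bedGraph may cover several chromosomes; tracks are matched to
        catalog chromosomes at scoring time.
        """
        from .intervals import read_bed
        from .tracks import read_bedgraph

        catalog = read_bed(catalog_bed)
        exclusions = read_bed(exclusions_bed) if exclusions_bed else []

        def load(paths_by_genotype):
            return {
                g: [read_bedgraph(p) for p in paths]
                for g, paths in paths_by_genotype.items()
            }

        chip = load(chip_bedgraphs)
        inputs = load(input_bedgraphs) if input_bedgraphs else None
        chroms = {iv.chrom for iv in catalog}

        def flatten(loaded):
            out = {}
            for g, dicts in loaded.items():
                tracks = []
                for d in dicts:
                    missing = chroms - set(d)
                    if missing:
                        raise ValueError(
                            f"track set for {g!r} lacks chromosomes {sorted(missing)}"
                        )
                    if len(chroms) == 1:
                        tracks.append(d[next(iter(chroms))])
                    else:
                        raise NotImplementedError(
                            "multi-chromosome catalogs: score per chromosome "
                            "and concatenate"
                        )
                out[g] = tracks
            return out

        model = cls(catalog, flatten(chip),
                    flatten(inputs) if inputs else None,
                    exclusions=exclusions, **kwargs)
        return model

    # -- scoring ------------------------------------------------------------

    def _score_library(self, track: CoverageTrack) -> tuple[np.ndarray, np.ndarray]:
        raw = np.array(
            [
                top_window_mean(track.segment(iv.start, iv.end), self.window)
                for iv in self.catalog
            ]
        )
        norm = np.array([normalize_score(r, track.depth, self.scale) for r in raw])
        return raw, norm

    def fit(self, enforce_qc: bool = False) -> "PREDependenceResults":
        """Score, QC, filter, contrast and classify the catalog."""
        raw_scores: dict[str, np.ndarray] = {}
        norm_scores: dict[str, np.ndarray] = {}
        for genotype, tracks in self.chip_tracks.items():
            for i, tr in enumerate(tracks, start=1):
                raw, norm = self._score_library(tr)
                raw_scores[f"{genotype}_rep{i}"] = raw
                norm_scores[f"{genotype}_rep{i}"] = norm

        concordance: dict[str, float] = {}
        for genotype, tracks in self.chip_tracks.items():
            keys = [f"{genotype}_rep{i}" for i in range(1, len(tracks) + 1)]
            for a in range(len(keys)):
                for b in range(a + 1, len(keys)):
                    r = replicate_concordance(norm_scores[keys[a]], norm_scores[keys[b]])
                    concordance[f"{keys[a]}:{keys[b]}"] = r
        failing = {pair: r for pair, r in concordance.items() if r <= self.qc_gate}
        if failing:
            msg = ", ".join(f"{p} (r={r:.3f})" for p, r in failing.items())
            if enforce_qc:
                raise QCError(f"replicate concordance below gate {self.qc_gate}: {msg}")
            logger.warning("replicate concordance below gate: %s", msg)

        def genotype_mean(genotype: str, scores: dict[str, np.ndarray]) -> np.ndarray:
            keys = [k for k in scores if k.startswith(f"{genotype}_rep")]
            return np.mean([scores[k] for k in keys], axis=0)

        ctrl_mean = genotype_mean(self.control_key, norm_scores)
        mut_mean = genotype_mean(self.mutant_key, norm_scores)

        kept, reasons = filter_pres(
            self.catalog, ctrl_mean, self.exclusions,
            weak_fraction=self.weak_fraction, weak_mode=self.weak_mode,
        )
        kept_set = set(kept)

        n = len(self.catalog)
        rd = np.full(n, np.nan)
        ratio = np.full(n, np.nan)
        dep_class: list[str | None] = [None] * n
        for i in kept:
            rd[i] = relative_difference(mut_mean[i], ctrl_mean[i])
            ratio[i] = score_ratio(mut_mean[i], ctrl_mean[i])
            dep_class[i] = classify_pre(
                rd[i], self.dependent_below, self.independent_above
            )

        table = pd.DataFrame(
            {
                "name": [iv.name or f"pre_{i + 1}" for i, iv in enumerate(self.catalog)],
                "chrom": [iv.chrom for iv in self.catalog],
                "start": [iv.start for iv in self.catalog],
                "end": [iv.end for iv in self.catalog],
                **{f"raw_{k}": v for k, v in raw_scores.items()},
                **{f"norm_{k}": v for k, v in norm_scores.items()},
                "control_mean": ctrl_mean,
                "mutant_mean": mut_mean,
                "RD": rd,
                "ratio": ratio,
                "dep_class": dep_class,
                "filtered_reason": [reasons.get(i) for i in range(n)],
            }
        )

        input_rd = None
        wilcoxon = None
        if self.input_tracks is not None:
            inp_norm: dict[str, np.ndarray] = {}
            for genotype, tracks in self.input_tracks.items():
                for i, tr in enumerate(tracks, start=1):
                    _, normv = self._score_library(tr)
                    inp_norm[f"{genotype}_rep{i}"] = normv
            inp_ctrl = genotype_mean(self.control_key, inp_norm)
            inp_mut = genotype_mean(self.mutant_key, inp_norm)
            input_rd = np.full(n, np.nan)
            for i in kept:
                input_rd[i] = relative_difference(inp_mut[i], inp_ctrl[i])
            table["input_RD"] = input_rd
            wilcoxon = compare_distributions(rd[kept], input_rd[kept])

        logger.info(
            "scored %d elements, kept %d; class counts: %s",
            n, len(kept),
            table.loc[list(kept_set), "dep_class"].value_counts().to_dict(),
        )
        return PREDependenceResults(
            model=self,
            table=table,
            concordance=concordance,
            wilcoxon=wilcoxon,
            rd_formula="RD = 2*(mutant - control)/(mutant + control)",
        )


@dataclass
class PREDependenceResults:
    """Per-element dependence estimates and cohort-level statistics."""

    model: PREDependenceModel
    table: pd.DataFrame
    concordance: dict[str, float]
    wilcoxon: dict | None = None
    rd_formula: str = "RD = 2*(mutant - control)/(mutant + control)"

    @property
    def classified(self) -> pd.DataFrame:
        """Rows that passed filtering and carry a class."""
        return self.table[self.table["dep_class"].notna()]

    def class_summary(self) -> dict:
        return summarize_classes(self.classified)

    def qc_passed(self) -> bool:
        return all(r > self.model.qc_gate for r in self.concordance.values())

    def summary(self) -> str:
        cs = self.class_summary()
        cls = self.classified
        lines = [
            "Element dependence analysis",
            "=" * 52,
            f"catalog size:        {len(self.table)}",
            f"classified:          {cs['n_total']}"
            f"   (filtered out: {len(self.table) - cs['n_total']})",
            f"scoring window:      {self.model.window} consecutive positions",
            f"RD formula:          {self.rd_formula}",
            f"class thresholds:    dependent RD < {self.model.dependent_below}, "
            f"independent RD > {self.model.independent_above}",
            "",
            "class counts:",
        ]
        for c in CLASSES:
            n_c = cs["n_per_class"].get(c, 0)
            lines.append(f"  {c:<13} {n_c:>5}   ({n_c / cs['n_total']:.1%})")
        lines += [
            "",
            f"fraction independent (RD > {self.model.independent_above}): "
            f"{cs['fraction_independent']:.3f}",
            f"median RD:           {cls['RD'].median():+.3f}",
            f"median ratio:        {cls['ratio'].median():.3f}",
        ]
        lines.append("")
        lines.append("replicate concordance (Pearson r):")
        for pair, r in self.concordance.items():
            flag = "" if r > self.model.qc_gate else "  <-- below QC gate"
            lines.append(f"  {pair:<28} {r:.4f}{flag}")
        if self.wilcoxon is not None:
            w = self.wilcoxon
            lines += [
                "",
                "ChIP RD vs input RD (Wilcoxon rank sum, two-sided):",
                f"  median ChIP RD  = {w['median_a']:+.3f}",
                f"  median input RD = {w['median_b']:+.3f}",
                f"  W = {w['statistic']:.1f}, p = {w['pvalue']:.3e}",
            ]
        return "\n".join(lines)

    def plot_rd_distribution(self, ax=None, bins: int = 30):
        """Histogram of RD with the input-control RD density overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        cls = self.classified
        ax.hist(cls["RD"], bins=bins, density=True, alpha=0.6, color="grey",
                label="ChIP RD")
        if "input_RD" in cls:
            ax.hist(cls["input_RD"], bins=bins, density=True, histtype="step",
                    linestyle="--", color="k", label="input RD")
        for thr in (self.model.dependent_below, self.model.independent_above):
            ax.axvline(thr, color="tab:red", lw=0.8, linestyle=":")
        ax.set_xlabel("relative difference (RD)")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        return ax


def summarize_classes(records: pd.DataFrame) -> dict:
    """Counts and fractions per dependence class.

    ``fraction_independent`` is the fraction of classified elements whose
    RD exceeds the independence threshold (i.e. class == independent).
    """
    if len(records) == 0:
        raise ValueError("no classified records to summarize")
    counts = records["dep_class"].value_counts().to_dict()
    n_total = int(len(records))
    return {
        "n_total": n_total,
        "n_per_class": {c: int(counts.get(c, 0)) for c in CLASSES},
        "fraction_per_class": {
            c: counts.get(c, 0) / n_total for c in CLASSES
        },
        "fraction_independent": counts.get("independent", 0) / n_total,
    }
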