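"""Element-level occupancy statistics and dependence classification.

The element score is the mean read density of the ``window`` (default 6)
consecutive positions with the highest read counts inside the element —
a window-maximum statistic that is robust to where exactly within a ~1 kb
element the binding summit falls.  Scores are depth-normalized per library
(reads-per-million by default; any constant scale cancels in the relative
difference), averaged across replicates per genotype, and contrasted
between mutant and control genotypes as

    RD = 2 (m - c) / (m + c),        ratio = m / c,

the symmetric relative difference, bounded in (-2, 2), with RD = -2 at
total loss.  Elements are classified by RD thresholds: RD < -1.0 is
"dependent" (signal collapses in the mutant), RD > -0.5 "independent",
anything between "intermediate".
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

CLASS_DEPENDENT = "dependent"
CLASS_INTERMEDIATE = "intermediate"
CLASS_INDEPENDENT = "independent"
CLASSES = (CLASS_DEPENDENT, CLASS_INTERMEDIATE, CLASS_INDEPENDENT)

REASON_DELETION = "deletion_overlap"
REASON_WEAK = "weak_signal"


def top_window_mean(segment, window: int = 6) -> float:
    """Mean of the contiguous ``window`` positions with the highest total
    read count, i.e. max over all length-``window`` windows of the window
    mean."""
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1:
        raise ValueError("segment must be 1-D")
    if window < 1:
        raise ValueError("window must be >= 1")
    if seg.size < window:
        raise ValueError(
            f"segment length {seg.size} shorter than window {window}"
        )
    sums = np.convolve(seg, np.ones(window), mode="valid")
    return float(sums.max() / window)


def normalize_score(raw: float, total_depth: float, scale: float = 1e6) -> float:
    """Depth-normalize a raw score: raw x scale / total_depth."""
    if total_depth <= 0:
        raise ValueError(f"total_depth must be > 0, got {total_depth}")
    return float(raw) * scale / float(total_depth)


def replicate_concordance(scores_rep1, scores_rep2) -> float:
    """Pearson correlation between per-element score vectors of two
    replicate libraries (QC gate: pipelines require r > 0.90)."""
    a = np.asarray(scores_rep1, dtype=float)
    b = np.asarray(scores_rep2, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("replicate score vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("replicate correlation undefined: zero variance")
    r, _ = stats.pearsonr(a, b)
    return float(r)


def relative_difference(mutant_mean: float, control_mean: float) -> float:
    """Symmetric relative difference RD = 2(m - c)/(m + c), in (-2, 2)."""
    m, c = float(mutant_mean), float(control_mean)
    if m < 0 or c < 0:
        raise ValueError("scores must be non-negative")
    if m + c == 0:
        raise ValueError("relative difference undefined: both means are zero")
    return 2.0 * (m - c) / (m + c)


def score_ratio(mutant_mean: float, control_mean: float) -> float:
    """Companion ratio m/c (inf when c == 0)."""
    if control_mean == 0:
        return float("inf")
    return float(mutant_mean) / float(control_mean)


def classify_pre(rd: float, dependent_below: float = -1.0,
                 independent_above: float = -0.5) -> str:
    """Map an RD value to a dependence class by threshold."""
    if not np.isfinite(rd):
        raise ValueError(f"RD must be finite, got {rd}")
    if rd < dependent_below:
        return CLASS_DEPENDENT
    if rd > independent_above:
        return CLASS_INDEPENDENT
    return CLASS_INTERMEDIATE


def weak_signal_threshold(scores, fraction: float = 0.30,
                          mode: str = "range") -> float:
    """Threshold below which control signal counts as weak.

    mode="range": min + fraction x (max - min) of the score dynamic range
    (the default reading of "lower 30% of signal dynamic range");
    mode="quantile": the ``fraction`` quantile of the scores.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no scores")
    if mode == "range":
        lo, hi = s.min(), s.max()
        if hi == lo:
            warnings.warn(
                "score dynamic range is zero; weak-signal filter disabled",
                stacklevel=2,
            )
            return -np.inf
        return float(lo + fraction * (hi - lo))
    if mode == "quantile":
        return float(np.quantile(s, fraction))
    raise ValueError(f"unknown weak-signal mode {mode!r}")


def filter_pres(
    catalog: Sequence,
    control_scores,
    exclusion_intervals: Sequence = (),
    weak_fraction: float = 0.30,
    weak_mode: str = "range",
) -> tuple[list[int], dict[int, str]]:
    """Filter a PRE catalog.

    Removes elements overlapping an exclusion interval by >= 1 bp, then
    elements whose control score falls below the weak-signal threshold
    (computed over the elements surviving the exclusion step).

    Returns (kept catalog indices, {removed index: reason}).
    """
    from .intervals import overlaps_any

    scores = np.asarray(control_scores, dtype=float)
    if len(catalog) != scores.size:
        raise ValueError("catalog and score lengths differ")
    reasons: dict[int, str] = {}
    surviving = []
    for i, iv in enumerate(catalog):
        if exclusion_intervals and overlaps_any(iv, exclusion_intervals):
            reasons[i] = REASON_DELETION
        else:
            surviving.append(i)
    if surviving:
        thr = weak_signal_threshold(scores[surviving], weak_fraction, weak_mode)
        for i in list(surviving):
            if scores[i] < thr:
                reasons[i] = REASON_WEAK
                surviving.remove(i)
    if not surviving:
        raise ValueError(
            "no elements left after filtering; review exclusion intervals "
            "and weak-signal parameters"
        )
    logger.info(
        "filtered catalog: kept %d / %d (%d deletion_overlap, %d weak_signal)",
        len(surviving),
        len(catalog),
        sum(r == REASON_DELETION for r in reasons.values()),
        sum(r == REASON_WEAK for r in reasons.values()),
    )
    return surviving, reasons


def compare_distributions(values_a, values_b) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two score distributions.

    Uses the exact null distribution for small untied samples and the
    normal approximation with continuity and tie correction otherwise
    (mirroring R's ``wilcox.test`` defaults).  Returns both medians, the
    rank-sum statistic and the p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
    }
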