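"""Cumulative occupancy profiles around isolated peak summits.

The 10 kb regions centered on peak summits are divided into 100 bp bins;
per-bin average read densities are computed per replicate, averaged across
replicates, and averaged over peaks.  The peak-averaged profile is
smoothed with loess (span 0.1).  Two genotypes are contrasted by
evaluating both fitted curves at 50 evenly spaced offsets, subtracting
(mutant - control) and loess-smoothing the differences with span 0.2.  A
randomized genomic background level is estimated from 999 randomly placed
100 bp bins that do not overlap any bound region.

The headline readout is *distal preferential loss*: when the flanking
("tail") signal is attenuated more than the summit signal, the smoothed
difference of summit-scaled curves is larger in magnitude at 2-5 kb
offsets than at the summit itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .loess import FittedCurve, loess_fit
from .peaks import PeakCall, call_peaks, isolated_peaks
from .tracks import CoverageTrack

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Peaks x bins matrix of average density around summits.

    ``matrix[i, j]`` is the replicate-averaged mean per-base density of bin
    ``j`` around summit ``i``; ``layers`` keeps the per-replicate matrices.
    ``bin_centers`` are bp offsets of bin midpoints relative to the summit.
    """

    matrix: np.ndarray
    bin_centers: np.ndarray
    bin_width: int
    flank: int
    layers: list[np.ndarray] = field(default_factory=list)
    summits: list[int] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def mean_profile(self) -> np.ndarray:
        """Per-bin mean over peaks."""
        return self.matrix.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            columns=[f"{int(c)}" for c in self.bin_centers],
            index=[f"peak_{i + 1}" for i in range(self.n_peaks)],
        )


def build_profile(
    tracks: Sequence[CoverageTrack],
    peaks: Sequence[PeakCall],
    flank: int = 5000,
    bin_width: int = 100,
) -> ProfileMatrix:
    """Bin replicate tracks around peak summits and average replicates.

    Each replicate track is binned separately over ``summit +/- flank``;
    the per-replicate matrices are then averaged element-wise.  Peaks whose
    window leaves the track are dropped with a warning.
    """
    if not peaks:
        raise ValueError("no peaks to profile")
    if not tracks:
        raise ValueError("no tracks to profile")
    if 2 * flank % bin_width:
        raise ValueError("2*flank must be a multiple of bin_width")
    n_bins = 2 * flank // bin_width
    track_len = len(tracks[0])
    origin = tracks[0].origin
    usable = []
    for p in peaks:
        if p.summit - flank >= origin and p.summit + flank <= origin + track_len:
            usable.append(p)
        else:
            logger.warning(
                "dropping peak at %s:%d: +/-%d bp window leaves the track",
                p.region.chrom, p.summit, flank,
            )
    if not usable:
        raise ValueError("no peak window fits inside the track")
    layers = []
    for tr in tracks:
        mat = np.empty((len(usable), n_bins))
        for i, p in enumerate(usable):
            seg = tr.segment(p.summit - flank, p.summit + flank)
            mat[i] = seg.reshape(n_bins, bin_width).mean(axis=1)
        layers.append(mat)
    matrix = np.mean(layers, axis=0)
    bin_centers = -flank + bin_width / 2.0 + bin_width * np.arange(n_bins)
    return ProfileMatrix(
        matrix=matrix,
        bin_centers=bin_centers,
        bin_width=bin_width,
        flank=flank,
        layers=layers,
        summits=[p.summit for p in usable],
    )


def fit_profile_curve(
    profile: ProfileMatrix,
    span: float = 0.1,
    degree: int = 2,
    ci: bool = False,
    n_boot: int = 500,
    seed: int | None = None,
) -> FittedCurve:
    """Loess-smooth the peak-averaged profile; optional pointwise 95%
    percentile-bootstrap band over peaks (``n_boot`` resamples)."""
    x = profile.bin_centers
    curve = loess_fit(x, profile.mean_profile(), span=span, degree=degree)
    if ci:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, x.size))
        n = profile.n_peaks
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = loess_fit(x, profile.matrix[idx].mean(axis=0),
                                 span=span, degree=degree).y
        lo = np.percentile(boots, 2.5, axis=0)
        hi = np.percentile(boots, 97.5, axis=0)
        curve.ci95 = (lo, hi)
    return curve


def profile_difference(
    curve_mut: FittedCurve,
    curve_ctrl: FittedCurve,
    n_points: int = 50,
    smooth_span: float = 0.2,
    degree: int = 2,
    scale: str = "summit",
    background_mut: float = 0.0,
    background_ctrl: float = 0.0,
) -> FittedCurve:
    """Smoothed difference (mutant - control) between two fitted profiles.

    Both curves are evaluated at ``n_points`` evenly spaced offsets over
    their common range, subtracted, and the differences loess-smoothed with
    ``smooth_span``.  With ``scale="summit"`` (default) each curve is first
    background-subtracted and divided by its own summit excess (fitted
    value at offset 0 minus background), so the difference reads as a
    fraction of the genotype's summit signal and the preferential-loss
    comparison is not confounded by the flat sequencing background;
    ``scale="none"`` differs the depth-normalized densities directly.
    """
    lo_m, hi_m = curve_mut.x.min(), curve_mut.x.max()
    lo_c, hi_c = curve_ctrl.x.min(), curve_ctrl.x.max()
    if not (np.isclose(lo_m, lo_c) and np.isclose(hi_m, hi_c)):
        raise ValueError(
            f"curve ranges differ: [{lo_m}, {hi_m}] vs [{lo_c}, {hi_c}]"
        )
    xq = np.linspace(lo_m, hi_m, n_points)
    ym = curve_mut(xq)
    yc = curve_ctrl(xq)
    if scale == "summit":
        sm = float(curve_mut(0.0)) - background_mut
        sc = float(curve_ctrl(0.0)) - background_ctrl
        if sm <= 0 or sc <= 0:
            raise ValueError("summit excess must be positive for summit scaling")
        ym = (ym - background_mut) / sm
        yc = (yc - background_ctrl) / sc
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    diff = ym - yc
    return loess_fit(xq, diff, span=smooth_span, degree=degree, xout=xq)


def background_level(
    track: CoverageTrack,
    excluded: Sequence = (),
    n_bins: int = 999,
    bin_width: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    disjoint: bool = False,
) -> float:
    """Mean of average read counts in randomly placed bins avoiding bound
    regions.

    ``n_bins`` bins of ``bin_width`` bp are placed uniformly at random
    among all positions where the bin has zero overlap with any excluded
    region.  Bins may overlap one another unless ``disjoint=True``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    vals = track.values
    L = vals.size
    excl_mask = np.zeros(L + 1, dtype=float)
    for region in excluded:
        start = getattr(region, "start", None)
        end = getattr(region, "end", None)
        if start is None:
            start, end = region
        s = max(int(start) - track.origin, 0)
        e = min(int(end) - track.origin, L)
        if e > s:
            excl_mask[s] += 1
            excl_mask[e] -= 1
    excl = np.cumsum(excl_mask[:-1]) > 0
    cum = np.concatenate(([0.0], np.cumsum(excl)))
    starts = np.arange(L - bin_width + 1)
    valid = starts[(cum[starts + bin_width] - cum[starts]) == 0]
    if valid.size == 0 or (disjoint and valid.size < n_bins):
        raise ValueError(
            f"insufficient territory for {n_bins} bins of {bin_width} bp: "
            f"{valid.size * 1 if not disjoint else valid.size} candidate "
            f"positions ({int((~excl).sum())} bp unexcluded)"
        )
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    if disjoint:
        chosen: list[int] = []
        taken = np.zeros(L, dtype=bool)
        pool = rng.permutation(valid)
        for s in pool:
            if not taken[s : s + bin_width].any():
                chosen.append(s)
                taken[s : s + bin_width] = True
                if len(chosen) == n_bins:
                    break
        if len(chosen) < n_bins:
            raise ValueError(
                f"insufficient territory for {n_bins} disjoint bins: "
                f"placed only {len(chosen)}"
            )
        sel = np.array(chosen)
    else:
        sel = rng.choice(valid, size=n_bins, replace=True)
    bin_means = (csum[sel + bin_width] - csum[sel]) / bin_width
    return float(bin_means.mean())


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class PeakProfileModel:
    """Contrast of occupancy profiles around shared peak summits.

    Peaks are called (threshold-and-cluster) on the replicate-averaged,
    depth-normalized control track, restricted to isolated peaks, and
    profiles of both genotypes are built around the same summits.

    Parameters
    ----------
    control_tracks, mutant_tracks : sequence of CoverageTrack
        Replicate ChIP tracks per genotype.
    control_inputs, mutant_inputs : sequence of CoverageTrack, optional
        Matched input (non-immunoprecipitated chromatin) tracks.
    peaks : sequence of PeakCall, optional
        Pre-computed peaks; when omitted, called from the control tracks.
    """

    def __init__(
        self,
        control_tracks: Sequence[CoverageTrack],
        mutant_tracks: Sequence[CoverageTrack],
        control_inputs: Sequence[CoverageTrack] = (),
        mutant_inputs: Sequence[CoverageTrack] = (),
        peaks: Sequence[PeakCall] | None = None,
        flank: int = 5000,
        bin_width: int = 100,
        profile_span: float = 0.1,
        diff_span: float = 0.2,
        n_points: int = 50,
        k_sd: float = 3.0,
        max_gap: int = 500,
        summit_window: int = 6,
        isolation_distance: int = 10_000,
        n_background_bins: int = 999,
        diff_scale: str = "summit",
        ci: bool = False,
        n_boot: int = 500,
        normalize: bool = True,
    ) -> None:
        self.control_tracks = list(control_tracks)
        self.mutant_tracks = list(mutant_tracks)
        self.control_inputs = list(control_inputs)
        self.mutant_inputs = list(mutant_inputs)
        self.peaks = list(peaks) if peaks is not None else None
        self.flank = flank
        self.bin_width = bin_width
        self.profile_span = profile_span
        self.diff_span = diff_span
        self.n_points = n_points
        self.k_sd = k_sd
        self.max_gap = max_gap
        self.summit_window = summit_window
        self.isolation_distance = isolation_distance
        self.n_background_bins = n_background_bins
        self.diff_scale = diff_scale
        self.ci = ci
        self.n_boot = n_boot
        self.normalize = normalize

    def _norm(self, tracks: Sequence[CoverageTrack]) -> list[CoverageTrack]:
        return [t.normalized() if self.normalize else t for t in tracks]

    def fit(self, seed: int | None = None) -> "PeakProfileResults":
        from .tracks import average_tracks

        ctrl = self._norm(self.control_tracks)
        mut = self._norm(self.mutant_tracks)
        if self.peaks is None:
            ctrl_avg = average_tracks(ctrl)
            all_peaks = call_peaks(
                ctrl_avg,
                k_sd=self.k_sd,
                max_gap=self.max_gap,
                window=self.summit_window,
                isolation_distance=self.isolation_distance,
            )
        else:
            all_peaks = list(self.peaks)
        iso = isolated_peaks(all_peaks, min_distance=self.isolation_distance)
        if not iso:
            raise ValueError("no isolated peaks to profile")
        profiles = {
            "control": build_profile(ctrl, iso, self.flank, self.bin_width),
            "mutant": build_profile(mut, iso, self.flank, self.bin_width),
        }
        rng = np.random.default_rng(seed)
        boot_seed = int(rng.integers(0, 2**31 - 1))
        curves = {
            g: fit_profile_curve(
                pm, span=self.profile_span, ci=self.ci,
                n_boot=self.n_boot, seed=boot_seed,
            )
            for g, pm in profiles.items()
        }
        for name, tracks in (("control_input", self.control_inputs),
                             ("mutant_input", self.mutant_inputs)):
            if tracks:
                pm = build_profile(self._norm(tracks), iso, self.flank, self.bin_width)
                profiles[name] = pm
                curves[name] = fit_profile_curve(pm, span=self.profile_span)
        excluded = [p.region for p in all_peaks]
        background = {
            "control": background_level(
                average_tracks(ctrl), excluded,
                n_bins=self.n_background_bins, bin_width=self.bin_width,
                rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))),
            ),
            "mutant": background_level(
                average_tracks(mut), excluded,
                n_bins=self.n_background_bins, bin_width=self.bin_width,
                rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))),
            ),
        }
        difference = profile_difference(
            curves["mutant"], curves["control"],
            n_points=self.n_points, smooth_span=self.diff_span,
            scale=self.diff_scale,
            background_mut=background["mutant"],
            background_ctrl=background["control"],
        )
        return PeakProfileResults(
            model=self,
            peaks=all_peaks,
            isolated=iso,
            profiles=profiles,
            curves=curves,
            difference=difference,
            background=background,
        )


@dataclass
class PeakProfileResults:
    """Fitted profile contrast: curves, difference and background levels."""

    model: PeakProfileModel
    peaks: list[PeakCall]
    isolated: list[PeakCall]
    profiles: dict[str, ProfileMatrix]
    curves: dict[str, FittedCurve]
    difference: FittedCurve
    background: dict[str, float]

    def distal_vs_summit(self, distal_range: tuple[float, float] = (2000.0, 5000.0)
                         ) -> dict[str, float]:
        """Mean |difference| over the distal offset band vs |difference|
        at offset 0 (the distal-preferential-loss readout)."""
        lo, hi = distal_range
        x, y = self.difference.x, self.difference.y
        band = (np.abs(x) >= lo) & (np.abs(x) <= hi)
        at_summit = float(np.abs(np.interp(0.0, x, y)))
        distal = float(np.abs(y[band]).mean())
        return {
            "distal_mean_abs": distal,
            "summit_abs": at_summit,
            "ratio": distal / at_summit if at_summit > 0 else float("inf"),
        }

    def summary(self) -> str:
        d = self.distal_vs_summit()
        lines = [
            "Peak profile contrast",
            "=" * 44,
            f"peaks called:            {len(self.peaks)}",
            f"isolated peaks profiled: {len(self.isolated)}",
            f"flank / bin:             {self.model.flank} / {self.model.bin_width} bp",
            f"loess spans:             {self.model.profile_span} (profiles), "
            f"{self.model.diff_span} (difference)",
            f"difference scale:        {self.model.diff_scale}",
            f"background (control):    {self.background['control']:.4f}",
            f"background (mutant):     {self.background['mutant']:.4f}",
            f"|diff| at summit:        {d['summit_abs']:.4f}",
            f"mean |diff| 2-5 kb:      {d['distal_mean_abs']:.4f}",
        ]
        return "\n".join(lines)

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in self.curves.items():
            df = pd.DataFrame({"offset": c.x, "fitted": c.y, "curve": name})
            if c.ci95 is not None:
                df["ci_lo"], df["ci_hi"] = c.ci95
            rows.append(df)
        rows.append(
            pd.DataFrame(
                {"offset": self.difference.x, "fitted": self.difference.y,
                 "curve": "difference"}
            )
        )
        return pd.concat(rows, ignore_index=True)

    def plot(self, ax=None):
        """Plot fitted genotype curves with background reference lines and
        the smoothed difference curve on a twin panel."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        colors = {"control": "tab:red", "mutant": "tab:blue",
                  "control_input": "darkred", "mutant_input": "darkblue"}
        for name, c in self.curves.items():
            ax.plot(c.x, c.y, label=name, color=colors.get(name),
                    linestyle="--" if "input" in name else "-")
            if c.ci95 is not None:
                ax.fill_between(c.x, *c.ci95, alpha=0.2, color=colors.get(name))
        for name, level in self.background.items():
            ax.axhline(level, linestyle=":", color=colors.get(name), lw=1)
        ax.set_xlabel("offset from summit (bp)")
        ax.set_ylabel("mean read density")
        ax.legend(fontsize=8)
        return ax
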