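"""Synthetic ChIP-seq coverage generator with known ground truth.

Emulates the statistical structure the comparative occupancy analysis
assumes: a flat sequencing background, localized element enrichment in the
control genotype, genotype-specific attenuation of that enrichment by
element class, a distance-decaying flank ("tail") signal produced by
looping contacts of element-anchored complexes with surrounding chromatin,
replicate sampling noise, and unequal library depths.  Matched input
tracks carry background only.

Generative model, per base x and library with depth factor d:

    control rate   d * b * [1 + (A_i - 1) * (c_i(x) + t_i(x))]
    mutant  rate   d * b * [1 + (A_i*a_s - 1) * c_i(x) + (A_i - 1) * a_t * t_i(x)]
    input   rate   d * b

where b is the background rate (reads/bp), A_i the element's control
summit fold enrichment (log-normal around ``summit_amplitude_control``
with coefficient of variation ``amplitude_cv``, since real elements span
a wide range of binding strengths — this is what makes replicate score
vectors correlate).  c_i(x) is the element's *core* envelope: a 200 bp
plateau centered in the element plus a fragment-pileup shoulder stepping down
to ``shoulder_fraction`` of the plateau excess immediately outside the
protein footprint and decaying exponentially with half-life
``shoulder_halflife`` (~150 bp, the scale set by sonicated fragment
sizes) — real summit shapes have a pointed apex, not a flat ridge.  t_i(x) is the
looping *tail* envelope: zero inside the nucleosome-depleted element
itself, then ``tail_fraction`` of the plateau excess at the element
boundary (tails are low-level crosslinking, an order of magnitude weaker
than summit binding) decaying with half-life ``tail_halflife`` out to
``tail_extent`` beyond the element — the kb-scale spread of repressive
domains around their anchor.  a_s is the per-class summit attenuation
(mutant summit coverage = control summit coverage x a_s; it scales the
whole core envelope) and a_t the tail attenuation (mutant tail excess
over background = a_t x control tail excess).  When no tail attenuation
is given, a_t defaults per element to (A_i a_s - 1)/(A_i - 1), the
retention under which the mutant element excess is a uniformly scaled
copy of the control — i.e. signal loss with no distance preference; an
explicit ``tail_attenuation_by_class`` below that value models
preferential loss at a distance.  Counts are Poisson by default; a negative-binomial option
models the overdispersion of real coverage.

The simulated chromosome stands for a window of a larger genome: each
track's ``total_depth`` is the notional genome-wide library size
``depth_factor * background_rate * genome_size``, so depth normalization
behaves as for real libraries, where reads inside binding sites are a
negligible fraction of the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, write_bed
from .scoring import CLASSES
from .tracks import CoverageTrack, write_bedgraph

logger = logging.getLogger(__name__)

PLATEAU_WIDTH = 200  # bp; gives a well-defined top-6-window maximum

DEFAULT_ATTENUATION = {"dependent": 0.1, "intermediate": 0.4, "independent": 0.9}
DEFAULT_DEPTH_FACTORS = {"control": (1.0, 1.3), "mutant": (0.8, 1.1)}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the analysis is designed for:
    a 2 Mb chromosome carrying 60 elements of 1 kb, one third per
    dependence class, 20-fold control summit enrichment over a 0.5
    reads/bp background, per-class summit attenuations 0.1/0.4/0.9 in the
    mutant, 1 kb tail half-life out to 5 kb, two replicates per genotype
    with unequal library depths.
    """

    chrom: str = "chrSim"
    chrom_length: int = 2_000_000
    n_pres: int = 60
    pre_width: int = 1000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 / 3.0 for c in CLASSES}
    )
    background_rate: float = 0.5
    summit_amplitude_control: float = 20.0
    amplitude_cv: float = 0.4
    genome_size: float = 120_000_000.0
    attenuation_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    tail_attenuation_by_class: Mapping[str, float] | None = None
    shoulder_fraction: float = 0.85
    shoulder_halflife: float = 150.0
    tail_fraction: float = 0.15
    tail_halflife: float = 2000.0
    tail_extent: int = 5000
    min_spacing: int = 25_000
    n_replicates: int = 2
    depth_factors: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {g: list(v) for g, v in DEFAULT_DEPTH_FACTORS.items()}
    )
    noise_model: str = "poisson"
    nb_dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        for name, v in (
            ("background_rate", self.background_rate),
            ("summit_amplitude_control", self.summit_amplitude_control),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(a < 0 for a in self.attenuation_by_class.values()):
            raise ValueError("attenuations must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if not 0 <= self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in [0, 1]")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be > 0")
        if self.noise_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for g in ("control", "mutant"):
            if len(self.depth_factors[g]) != self.n_replicates:
                raise ValueError(
                    f"depth_factors[{g!r}] must list {self.n_replicates} values"
                )

    def tail_attenuation_for(self, label: str, amplitude: float) -> float:
        """Tail retention for one element.

        Defaults to uniform proportional loss of the element excess,
        (A a_s - 1)/(A - 1), clipped to [0, 1]; an explicit
        ``tail_attenuation_by_class`` overrides it.
        """
        if self.tail_attenuation_by_class is not None:
            return float(self.tail_attenuation_by_class[label])
        a_s = self.attenuation_by_class[label]
        if amplitude <= 1.0:
            return a_s
        return float(np.clip((amplitude * a_s - 1.0) / (amplitude - 1.0), 0.0, 1.0))


@dataclass
class SimulationResult:
    """Tracks, ground truth and element catalog from one simulation."""

    config: SimulationConfig
    chip_tracks: dict[str, list[CoverageTrack]]
    input_tracks: dict[str, list[CoverageTrack]]
    truth: pd.DataFrame
    catalog: list[GenomicInterval]

    def write(self, outdir) -> None:
        """Write bedGraph tracks, BED catalog, truth TSV and config YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for kind, groups in (("chip", self.chip_tracks), ("input", self.input_tracks)):
            for genotype, tracks in groups.items():
                for i, tr in enumerate(tracks, start=1):
                    write_bedgraph(
                        tr,
                        outdir / f"{kind}_{genotype}_rep{i}.bedgraph",
                        write_zero_runs=True,  # keep chromosome length explicit
                    )
        write_bed(self.catalog, outdir / "catalog.bed")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        cfg["class_fractions"] = dict(cfg["class_fractions"])
        with open(outdir / "simulation_config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        logger.info("wrote simulation bundle to %s", outdir)


def _place_elements(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Element center coordinates with pairwise spacing >= min_spacing and
    a margin keeping summit +/- tail_extent inside the chromosome."""
    margin = config.tail_extent + config.pre_width
    span = config.chrom_length - 2 * margin
    slack = span - (config.n_pres - 1) * config.min_spacing
    if config.n_pres < 1 or slack < 0:
        raise ValueError(
            f"cannot place {config.n_pres} elements with min_spacing "
            f"{config.min_spacing} bp on a {config.chrom_length} bp chromosome "
            f"(margin {margin} bp per side)"
        )
    offsets = np.sort(rng.uniform(0.0, slack, size=config.n_pres))
    centers = margin + offsets + np.arange(config.n_pres) * config.min_spacing
    return centers.astype(int)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    counts = {c: int(np.floor(config.class_fractions.get(c, 0.0) * config.n_pres))
              for c in CLASSES}
    labels = [c for c in CLASSES for _ in range(counts[c])]
    frac_order = sorted(
        CLASSES, key=lambda c: config.class_fractions.get(c, 0.0), reverse=True
    )
    i = 0
    while len(labels) < config.n_pres:
        labels.append(frac_order[i % len(frac_order)])
        i += 1
    rng.shuffle(labels)
    return labels


def _element_envelope(config: SimulationConfig, center: int
                      ) -> tuple[slice, np.ndarray, np.ndarray]:
    """Core (plateau + fragment shoulder) and tail envelopes of one
    element, as a chromosome slice plus two local arrays.

    The shoulder decays from the plateau edge; the tail starts at the
    element boundary (the core itself is nucleosome depleted) and decays
    out to ``tail_extent`` beyond it.
    """
    L = config.chrom_length
    half_plateau = PLATEAU_WIDTH // 2
    half_element = config.pre_width // 2
    reach = half_element + config.tail_extent
    lo = max(center - reach, 0)
    hi = min(center + reach, L)
    x = np.arange(lo, hi)
    center_dist = np.abs(x - center)
    plateau_dist = np.maximum(center_dist - half_plateau, 0)
    core = np.where(
        plateau_dist == 0,
        1.0,
        config.shoulder_fraction
        * np.power(2.0, -plateau_dist / config.shoulder_halflife),
    )
    element_dist = np.maximum(center_dist - half_element, 0)
    tail = np.where(
        element_dist > 0,
        config.tail_fraction * np.power(2.0, -element_dist / config.tail_halflife),
        0.0,
    )
    return slice(lo, hi), core, tail


def _draw_counts(rate: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(rate).astype(float)
    # negative binomial via gamma-poisson mixture: var = mu + disp * mu^2
    disp = config.nb_dispersion
    if disp <= 0:
        raise ValueError("nb_dispersion must be > 0 for negative_binomial noise")
    shape = 1.0 / disp
    lam = rng.gamma(shape, rate * disp)
    return rng.poisson(lam).astype(float)


def simulate_tracks(config: SimulationConfig) -> SimulationResult:
    """Generate coverage tracks, the truth table and the element catalog.

    Identical config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    centers = _place_elements(config, rng)
    labels = _assign_classes(config, rng)

    b = config.background_rate
    A = config.summit_amplitude_control
    if config.amplitude_cv > 0 and A > 0:
        # log-normal with mean A and coefficient of variation amplitude_cv
        sigma2 = np.log(1.0 + config.amplitude_cv**2)
        amplitudes = rng.lognormal(
            np.log(A) - sigma2 / 2.0, np.sqrt(sigma2), size=config.n_pres
        )
    else:
        amplitudes = np.full(config.n_pres, float(A))

    ctrl_rate = np.full(config.chrom_length, b)
    mut_rate = np.full(config.chrom_length, b)
    tail_atts = [
        config.tail_attenuation_for(label, A_i)
        for label, A_i in zip(labels, amplitudes)
    ]
    for center, label, A_i, a_t in zip(centers, labels, amplitudes, tail_atts):
        a_s = config.attenuation_by_class[label]
        seg, core, tail = _element_envelope(config, int(center))
        ctrl_rate[seg] = b * (1.0 + (A_i - 1.0) * (core + tail))
        mut_rate[seg] = b * (
            1.0 + (A_i * a_s - 1.0) * core + (A_i - 1.0) * a_t * tail
        )
    base_rates = {"control": ctrl_rate, "mutant": mut_rate}

    # notional genome-wide library size: the simulated chromosome is a
    # window of a genome_size genome whose reads are background-dominated
    chip_tracks: dict[str, list[CoverageTrack]] = {}
    input_tracks: dict[str, list[CoverageTrack]] = {}
    for genotype in ("control", "mutant"):
        chip_tracks[genotype] = []
        input_tracks[genotype] = []
        for rep in range(config.n_replicates):
            d = float(config.depth_factors[genotype][rep])
            depth = d * b * config.genome_size
            chip_vals = _draw_counts(d * base_rates[genotype], config, rng)
            input_vals = _draw_counts(np.full(config.chrom_length, d * b), config, rng)
            chip_tracks[genotype].append(
                CoverageTrack(chrom=config.chrom, values=chip_vals, total_depth=depth)
            )
            input_tracks[genotype].append(
                CoverageTrack(chrom=config.chrom, values=input_vals, total_depth=depth)
            )

    half_width = config.pre_width // 2
    catalog = [
        GenomicInterval(
            chrom=config.chrom,
            start=int(c) - half_width,
            end=int(c) + half_width,
            name=f"pre_{i + 1}",
        )
        for i, c in enumerate(centers)
    ]
    truth = pd.DataFrame(
        {
            "name": [iv.name for iv in catalog],
            "chrom": config.chrom,
            "start": [iv.start for iv in catalog],
            "end": [iv.end for iv in catalog],
            "center": centers,
            "dep_class": labels,
            "control_amplitude": amplitudes,
            "mutant_amplitude": [
                a * config.attenuation_by_class[l]
                for a, l in zip(amplitudes, labels)
            ],
            "summit_attenuation": [config.attenuation_by_class[l] for l in labels],
            "tail_attenuation": tail_atts,
            "tail_halflife": config.tail_halflife,
            "tail_extent": config.tail_extent,
        }
    )
    logger.info(
        "simulated %d elements on %s (%d bp), classes: %s",
        config.n_pres, config.chrom, config.chrom_length,
        truth["dep_class"].value_counts().to_dict(),
    )
    return SimulationResult(
        config=config,
        chip_tracks=chip_tracks,
        input_tracks=input_tracks,
        truth=truth,
        catalog=catalog,
    )
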