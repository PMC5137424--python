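"""Analysis configuration: one dataclass holding every tunable, with the
published defaults (window 6, 3 SD, 500 bp gap, RD thresholds -1.0/-0.5,
5 kb flank, 100 bp bins, loess spans 0.1/0.2, 50 difference points, 999
background bins, QC gate 0.90, 10 kb isolation), YAML round-trip, and
bounds checking."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # inputs
    catalog_bed: str | None = None
    chip_control: list[str] = field(default_factory=list)
    chip_mutant: list[str] = field(default_factory=list)
    input_control: list[str] = field(default_factory=list)
    input_mutant: list[str] = field(default_factory=list)
    exclusions_bed: str | None = None
    outdir: str = "occupre_out"

    # scoring
    window: int = 6
    scale: float = 1e6
    qc_gate: float = 0.90
    dependent_below: float = -1.0
    independent_above: float = -0.5
    weak_fraction: float = 0.30
    weak_mode: str = "range"

    # peak calling
    k_sd: float = 3.0
    max_gap: int = 500
    isolation_distance: int = 10_000

    # profiles
    flank: int = 5000
    bin_width: int = 100
    profile_span: float = 0.1
    diff_span: float = 0.2
    n_points: int = 50
    n_background_bins: int = 999
    diff_scale: str = "summit"

    seed: int = 0
    force: bool = False  # proceed despite a QC-gate failure

    def __post_init__(self) -> None:
        checks = [
            (self.window >= 1, "window must be >= 1"),
            (self.scale > 0, "scale must be > 0"),
            (-1 <= self.qc_gate <= 1, "qc_gate must be a correlation"),
            (self.dependent_below <= self.independent_above,
             "dependent_below must not exceed independent_above"),
            (0 <= self.weak_fraction <= 1, "weak_fraction must be in [0, 1]"),
            (self.k_sd >= 0, "k_sd must be >= 0"),
            (self.max_gap >= 0, "max_gap must be >= 0"),
            (self.flank > 0 and self.bin_width > 0, "flank/bin_width must be > 0"),
            (2 * self.flank % self.bin_width == 0,
             "2*flank must be a multiple of bin_width"),
            (0 < self.profile_span <= 1, "profile_span must be in (0, 1]"),
            (0 < self.diff_span <= 1, "diff_span must be in (0, 1]"),
            (self.n_points >= 10, "n_points must be >= 10"),
            (self.n_background_bins >= 1, "n_background_bins must be >= 1"),
            (self.isolation_distance >= 0, "isolation_distance must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def updated(self, **kwargs) -> "AnalysisConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return AnalysisConfig(**data)
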