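"""Pipeline configuration with the study's default constants.

The defaults reproduce the acquisition and analysis conventions: 500 Hz
sampling, 1-50 Hz broadband filtering, 4 s epochs (29 per subject), five
canonical bands, 5% beamformer regularization, BIC-selected MVAR order
capped at 10, and the printed classifier grids.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import DEFAULT_BANDS

DEFAULT_BAND_SPECS = [
    {"name": b.name, "low_hz": b.low_hz, "high_hz": b.high_hz}
    for b in DEFAULT_BANDS
]


@dataclass
class PipelineConfig:
    seed: int = 0
    # cohort simulation
    n_per_group: int = 22
    duration_s: float = 180.0
    n_sensors: int = 64
    snr_db: float = 20.0
    # sampling / filtering
    fs: float = 500.0
    filter_low: float = 1.0
    filter_high: float = 50.0
    filter_order: int = 4
    # epoching
    epoch_seconds: float = 4.0
    epoch_count: int = 29
    epoch_selection: str = "first"
    # bands
    bands: list = field(default_factory=lambda: [dict(b) for b in
                                                 DEFAULT_BAND_SPECS])
    # beamformer
    beamformer_regularization: float = 0.05
    # MVAR / PDC ("auto" = BIC selection over 2..mvar_max_order)
    mvar_order: object = 5
    mvar_max_order: int = 10
    pdc_squared: bool = False
    # OMST
    omst_max_rounds: int | None = None
    # classification
    c_grid: list = field(default_factory=lambda: [0.1, 1.0, 10.0])
    scale_grid: list = field(default_factory=lambda: [0.01, 0.1, 1.0, "auto"])
    k_grid: list = field(default_factory=lambda: [20, 50, 100])
    inner_folds: int = 5
    relief_k_neighbors: int = 3
    # stats
    alpha_connectivity: float = 0.01
    alpha_laterality: float = 0.05
    # io
    save_recordings: bool = False
    save_epochs: bool = False

    def validate(self) -> "PipelineConfig":
        known = {b["name"] for b in DEFAULT_BAND_SPECS}
        for b in self.bands:
            if b["name"] not in known:
                raise ValueError(f"unknown band name {b['name']!r}")
            if not (0 <= b["low_hz"] < b["high_hz"] <= self.fs / 2):
                raise ValueError(f"invalid band edges for {b['name']!r}")
        if not (0 < self.filter_low < self.filter_high < self.fs / 2):
            raise ValueError("invalid broadband filter edges")
        if self.epoch_seconds <= 0 or self.epoch_count < 1:
            raise ValueError("invalid epoching parameters")
        if self.epoch_selection not in ("first", "random"):
            raise ValueError("epoch selection must be 'first' or 'random'")
        if self.beamformer_regularization < 0:
            raise ValueError("beamformer regularization must be >= 0")
        if self.mvar_order != "auto" and int(self.mvar_order) < 1:
            raise ValueError("mvar order must be 'auto' or >= 1")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        need = self.epoch_seconds * self.epoch_count
        if self.duration_s < need:
            raise ValueError(
                f"duration {self.duration_s}s too short for "
                f"{self.epoch_count} epochs of {self.epoch_seconds}s"
            )
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d).validate()

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
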