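"""Run configuration: a flat, YAML-round-trippable record of every knob.

All times are minutes (the 4-second snapshot is entered as 0.0667) and
all genomic lengths are kbp; keeping a single unit per axis prevents
second/minute mixing from leaking into the pipeline.  The defaults
reproduce the reference simulation setup (N = 1024 chromatids, 2 kbp/min
forks, snapshots 4 s .. 120 min).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..band_model import ChromosomeModel, SpeedMode, build_paper_int, read_model
from ..initiation_scenarios import InitiationScenario
from ..pattern_stats import DEFAULT_BIN_WIDTH, DEFAULT_SNAPSHOT_TIMES_MIN
from ..synthetic_observations import NoiseModel

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Complete, reproducible description of one pipeline run."""

    model_table: str | None = None  # None -> built-in default fragment
    black_flank_kbp: float = 100.0
    speed_mode: str = "dna"
    temporal_mode: str = "synchronous"
    window_min: float = 0.0
    spatial_mode: str = "dispersed"
    locus_kbp: float | None = None
    n_chromatids: int = 1024
    fork_speed_kbp_per_min: float = 2.0
    snapshot_times_min: tuple[float, ...] = DEFAULT_SNAPSHOT_TIMES_MIN
    bin_width: float = DEFAULT_BIN_WIDTH
    p_detect: float = 0.8
    jitter_sd_axial: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "snapshot_times_min", tuple(float(t) for t in self.snapshot_times_min)
        )
        SpeedMode(self.speed_mode)  # validate early

    # -- factories for the pipeline objects -------------------------------

    def build_model(self) -> ChromosomeModel:
        if self.model_table is not None:
            return read_model(self.model_table, self.speed_mode)
        return build_paper_int(self.black_flank_kbp, self.speed_mode)

    def build_scenario(self) -> InitiationScenario:
        return InitiationScenario(
            temporal_mode=self.temporal_mode,
            window_min=self.window_min,
            spatial_mode=self.spatial_mode,
            locus_kbp=self.locus_kbp,
        )

    def build_noise(self) -> NoiseModel:
        return NoiseModel(self.p_detect, self.jitter_sd_axial, self.seed)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snapshot_times_min"] = list(self.snapshot_times_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.dumps())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(d)

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    def content_hash(self) -> str:
        return hashlib.sha256(self.dumps().encode()).hexdigest()[:16]
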