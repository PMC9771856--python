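"""Per-chromatid origin sampling under the four temporal scenarios.

Each chromatid fires exactly one origin.  The spatial law is either
*dispersed* (uniform over the concatenated interband DNA of the INT,
which makes each equal-sized interband equally likely) or *fixed locus*
(every chromatid fires at the same interband position).  The temporal
law is either *synchronous* (all at t = 0) or a *uniform window*
(activation times i.i.d. uniform on [0, T] minutes).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .band_model import ChromosomeModel, SegmentKind

__all__ = [
    "TemporalMode",
    "SpatialMode",
    "InitiationScenario",
    "OriginEvent",
    "ScenarioError",
    "sample_origins",
    "paper_scenarios",
]


class TemporalMode(str, Enum):
    SYNCHRONOUS = "synchronous"
    UNIFORM_WINDOW = "uniform_window"


class SpatialMode(str, Enum):
    DISPERSED = "dispersed"
    FIXED_LOCUS = "fixed_locus"


class ScenarioError(ValueError):
    """Inconsistent scenario parameters or scenario/model mismatch."""


@dataclass(frozen=True)
class InitiationScenario:
    """Temporal + spatial law for origin activation.

    Invariants: ``temporal_mode`` is synchronous iff ``window_min == 0``;
    ``fixed_locus`` requires a ``locus_kbp`` (validated against the model
    at sampling time — it must fall inside an interband).
    """

    temporal_mode: TemporalMode = TemporalMode.SYNCHRONOUS
    window_min: float = 0.0
    spatial_mode: SpatialMode = SpatialMode.DISPERSED
    locus_kbp: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "temporal_mode", TemporalMode(self.temporal_mode))
        object.__setattr__(self, "spatial_mode", SpatialMode(self.spatial_mode))
        if self.temporal_mode is TemporalMode.SYNCHRONOUS and self.window_min != 0:
            raise ScenarioError("synchronous scenario requires window_min == 0")
        if self.temporal_mode is TemporalMode.UNIFORM_WINDOW and not self.window_min > 0:
            raise ScenarioError("uniform_window scenario requires window_min > 0")
        if self.spatial_mode is SpatialMode.FIXED_LOCUS and self.locus_kbp is None:
            raise ScenarioError("fixed_locus scenario requires locus_kbp")

    @classmethod
    def synchronous(cls, **kw) -> "InitiationScenario":
        return cls(TemporalMode.SYNCHRONOUS, 0.0, **kw)

    @classmethod
    def uniform_window(cls, window_min: float, **kw) -> "InitiationScenario":
        return cls(TemporalMode.UNIFORM_WINDOW, window_min, **kw)

    @property
    def label(self) -> str:
        if self.temporal_mode is TemporalMode.SYNCHRONOUS:
            base = "synchronous"
        else:
            base = f"window{self.window_min:g}"
        if self.spatial_mode is SpatialMode.FIXED_LOCUS:
            base += f"_fixed{self.locus_kbp:g}"
        return base


def paper_scenarios() -> tuple[InitiationScenario, ...]:
    """The four default temporal scenarios: synchronous and uniform
    activation windows of 10, 30 and 60 minutes (dispersed origins)."""
    return (
        InitiationScenario.synchronous(),
        InitiationScenario.uniform_window(10.0),
        InitiationScenario.uniform_window(30.0),
        InitiationScenario.uniform_window(60.0),
    )


@dataclass(frozen=True)
class OriginEvent:
    """One origin firing: position (kbp) and activation time (min)."""

    chromatid_id: int
    genomic_pos: float
    activation_time: float


def _check_locus(model: ChromosomeModel, locus_kbp: float) -> None:
    if not 0 <= locus_kbp <= model.total_genomic_kbp:
        raise ScenarioError(f"locus_kbp={locus_kbp} outside model")
    idx = int(model.segment_index(locus_kbp))
    if model.segments[idx].kind is not SegmentKind.INTERBAND:
        raise ScenarioError(
            f"fixed locus {locus_kbp} kbp falls in a "
            f"{model.segments[idx].kind.value} segment, not an interband"
        )


def sample_origins(
    model: ChromosomeModel,
    scenario: InitiationScenario,
    n_chromatids: int,
    seed: int | np.random.Generator,
) -> list[OriginEvent]:
    """Sample one :class:`OriginEvent` per chromatid.

    Positions in dispersed mode are uniform over the concatenated
    interband DNA inside the INT span, weighted by interband DNA content
    (so unequal interbands generalize correctly).  All random values are
    drawn from a single stream in chromatid order (position, then
    activation time, per chromatid), so results do not depend on any
    parallelization of downstream stages.
    """
    if n_chromatids < 1:
        raise ScenarioError("n_chromatids must be >= 1")
    rng = np.random.default_rng(seed)
    # one row per chromatid: (position u, time u)
    u = rng.random((n_chromatids, 2))

    if scenario.spatial_mode is SpatialMode.FIXED_LOCUS:
        _check_locus(model, scenario.locus_kbp)
        positions = np.full(n_chromatids, float(scenario.locus_kbp))
    else:
        intervals = model.interband_intervals()
        if not intervals:
            raise ScenarioError("model has no interband segments inside the INT")
        starts = np.array([a for a, _ in intervals])
        lengths = np.array([b - a for a, b in intervals])
        offsets = np.concatenate([[0.0], np.cumsum(lengths)])
        flat = u[:, 0] * offsets[-1]  # position along concatenated interband DNA
        which = np.clip(np.searchsorted(offsets, flat, side="right") - 1, 0, len(intervals) - 1)
        positions = starts[which] + (flat - offsets[which])

    if scenario.temporal_mode is TemporalMode.SYNCHRONOUS:
        times = np.zeros(n_chromatids)
    else:
        times = u[:, 1] * scenario.window_min

    return [
        OriginEvent(i, float(positions[i]), float(times[i]))
        for i in range(n_chromatids)
    ]
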