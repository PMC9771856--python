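"""Event-driven bidirectional fork propagation through the segment model.

Each origin launches two divergent forks.  Within a segment the fork's
genomic speed is constant, so the full trajectory is a piecewise-linear
curve whose knots are the segment-boundary crossing times; positions and
crossing times are therefore closed-form.  A brute-force explicit
time-stepper is shipped alongside as an independent oracle.

Speed interpretation (see :class:`~polyrep.band_model.SpeedMode`):

* ``dna`` — constant genomic speed (default 2 kbp/min) in every segment.
* ``stated`` — axial speed fixed per segment kind at factors
  (1, 1/5, 1/20, 1/50) of the interband axial speed ``V``, where
  ``V = speed_kbp_per_min / interband density`` (1 width/min for
  2 kbp/min forks and 2-kbp unit-width interbands); genomic speed
  follows from each segment's density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_model import ChromosomeModel, ModelError, SegmentKind, SpeedMode
from .initiation_scenarios import InitiationScenario, OriginEvent, sample_origins

__all__ = [
    "AXIAL_SPEED_FACTORS",
    "ForkTrajectory",
    "ChromatidRecord",
    "segment_speeds",
    "make_record",
    "make_fork",
    "simulate",
    "completion_time",
    "edu_pulse_intervals",
    "fork_position_stepper",
]

#: Relative axial speed per segment kind in ``stated`` mode.
AXIAL_SPEED_FACTORS = {
    SegmentKind.INTERBAND: 1.0,
    SegmentKind.GRAY: 1.0 / 5.0,
    SegmentKind.MIDDLE_GRAY: 1.0 / 20.0,
    SegmentKind.BLACK: 1.0 / 50.0,
}

DEFAULT_FORK_SPEED_KBP_PER_MIN = 2.0


def segment_speeds(
    model: ChromosomeModel,
    speed_kbp_per_min: float = DEFAULT_FORK_SPEED_KBP_PER_MIN,
) -> np.ndarray:
    """Per-segment genomic fork speed (kbp/min) under the model's speed mode."""
    if not speed_kbp_per_min > 0:
        raise ValueError("fork speed must be > 0")
    if model.speed_mode is SpeedMode.DNA:
        return np.full(model.n_segments, float(speed_kbp_per_min))
    ib = model.segments_of_kind(SegmentKind.INTERBAND)
    if not ib:
        raise ModelError("stated speed mode needs an interband to define V")
    v_axial = speed_kbp_per_min / model.segments[ib[0]].density  # widths/min
    return np.array(
        [v_axial * AXIAL_SPEED_FACTORS[s.kind] * s.density for s in model.segments]
    )


@dataclass(frozen=True)
class ForkTrajectory:
    """Closed-form trajectory of one fork.

    ``time_knots``/``pos_knots`` start at (activation, origin) and list
    every segment-boundary crossing out to the model end; position at any
    time in between is linear interpolation.  The fork stops (and is no
    longer rendered) when it reaches the model end.
    """

    origin: OriginEvent
    direction: int  # +1 right, -1 left
    speed_kbp_per_min: float
    time_knots: np.ndarray
    pos_knots: np.ndarray

    @property
    def activation_time(self) -> float:
        return self.origin.activation_time

    @property
    def stop_time(self) -> float:
        """Time the fork reaches the model end."""
        return float(self.time_knots[-1])

    @property
    def segment_exit_times(self) -> np.ndarray:
        """Times at which the fork crosses each successive boundary."""
        return self.time_knots[1:]

    def position(self, t) -> float:
        """Genomic position at time ``t`` (clamped at the model end).

        ``t`` may be a scalar or array; every value must be at or after
        activation.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < self.activation_time - 1e-12):
            raise ValueError(
                f"fork does not exist before activation at {self.activation_time}"
            )
        out = np.interp(t, self.time_knots, self.pos_knots)
        return float(out) if out.ndim == 0 else out

    def time_to_reach(self, g: float) -> float:
        """Earliest time the fork is at genomic position ``g``.

        ``g`` must lie between the origin and the model end in the fork's
        direction of travel (inclusive).
        """
        lo = min(self.pos_knots[0], self.pos_knots[-1])
        hi = max(self.pos_knots[0], self.pos_knots[-1])
        if not lo - 1e-12 <= g <= hi + 1e-12:
            raise ValueError(
                f"position {g} not on this fork's path [{lo}, {hi}]"
            )
        if self.direction > 0:
            return float(np.interp(g, self.pos_knots, self.time_knots))
        return float(np.interp(g, self.pos_knots[::-1], self.time_knots[::-1]))


def _build_trajectory(
    model: ChromosomeModel,
    origin: OriginEvent,
    direction: int,
    speeds: np.ndarray,
    speed_kbp_per_min: float,
) -> ForkTrajectory:
    g0 = origin.genomic_pos
    breaks = model.genomic_breaks
    if direction > 0:
        k0 = int(model.segment_index(g0, side="right"))
        bounds = breaks[k0 + 1 :]
        segs = np.arange(k0, model.n_segments)
    else:
        k0 = int(model.segment_index(g0, side="left"))
        bounds = breaks[k0::-1]
        segs = np.arange(k0, -1, -1)
    dists = np.abs(np.diff(np.concatenate([[g0], bounds])))
    durations = dists / speeds[segs]
    time_knots = origin.activation_time + np.concatenate([[0.0], np.cumsum(durations)])
    pos_knots = np.concatenate([[g0], bounds])
    return ForkTrajectory(origin, direction, speed_kbp_per_min, time_knots, pos_knots)


def make_fork(
    model: ChromosomeModel,
    origin: OriginEvent,
    direction: int,
    speed_kbp_per_min: float = DEFAULT_FORK_SPEED_KBP_PER_MIN,
) -> ForkTrajectory:
    """Build a single fork trajectory (direction +1 right, -1 left)."""
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    speeds = segment_speeds(model, speed_kbp_per_min)
    return _build_trajectory(model, origin, direction, speeds, speed_kbp_per_min)


@dataclass(frozen=True)
class ChromatidRecord:
    """Both fork trajectories of one chromatid plus its INT completion time."""

    origin: OriginEvent
    left_fork: ForkTrajectory
    right_fork: ForkTrajectory
    int_completion_time: float

    @property
    def chromatid_id(self) -> int:
        return self.origin.chromatid_id


def make_record(
    model: ChromosomeModel,
    origin: OriginEvent,
    speeds: np.ndarray,
    speed_kbp_per_min: float,
) -> ChromatidRecord:
    left = _build_trajectory(model, origin, -1, speeds, speed_kbp_per_min)
    right = _build_trajectory(model, origin, +1, speeds, speed_kbp_per_min)
    lo, hi = model.int_span
    completion = max(left.time_to_reach(lo), right.time_to_reach(hi))
    return ChromatidRecord(origin, left, right, completion)


def simulate(
    model: ChromosomeModel,
    scenario: InitiationScenario,
    n_chromatids: int = 1024,
    speed_kbp_per_min: float = DEFAULT_FORK_SPEED_KBP_PER_MIN,
    seed: int | np.random.Generator = 0,
) -> list[ChromatidRecord]:
    """Run the full per-chromatid simulation; deterministic given ``seed``."""
    origins = sample_origins(model, scenario, n_chromatids, seed)
    speeds = segment_speeds(model, speed_kbp_per_min)
    return [make_record(model, o, speeds, speed_kbp_per_min) for o in origins]


def completion_time(record: ChromatidRecord, region: tuple[float, float]) -> float:
    """Earliest time the whole genomic ``region`` is replicated.

    The region must contain the origin: with a single origin per
    chromatid a region strictly on one side can never be fully
    replicated from inside it.
    """
    lo, hi = region
    if lo > hi:
        raise ValueError("region start must be <= end")
    g0 = record.origin.genomic_pos
    if not lo <= g0 <= hi:
        raise ValueError(
            f"region [{lo}, {hi}] does not contain the origin at {g0}"
        )
    return max(record.left_fork.time_to_reach(lo), record.right_fork.time_to_reach(hi))


def edu_pulse_intervals(
    record: ChromatidRecord, t_start: float, duration: float
) -> list[tuple[float, float]]:
    """Genomic intervals replicated during ``[t_start, t_start+duration]``.

    Up to two disjoint intervals, one per fork; empty if the origin
    activates at or after the pulse end or both forks stopped before the
    pulse started.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    a = record.origin.activation_time
    t_end = t_start + duration
    if t_end <= a:
        return []
    t0 = max(t_start, a)
    out = []
    for fork in (record.left_fork, record.right_fork):
        p0 = fork.position(t0)
        p1 = fork.position(t_end)
        lo, hi = min(p0, p1), max(p0, p1)
        if hi > lo:
            out.append((lo, hi))
    return out


def fork_position_stepper(
    model: ChromosomeModel,
    origin_g,
    activation,
    direction,
    t,
    speed_kbp_per_min: float = DEFAULT_FORK_SPEED_KBP_PER_MIN,
    dt: float = 1e-3,
) -> np.ndarray:
    """Brute-force explicit time-stepping oracle for fork positions.

    Advances each fork from its origin with step ``dt``, looking up the
    current segment's speed at every step.  Deliberately independent of
    the event-driven closed form; accurate to O(dt * max speed).  All
    per-fork arguments broadcast to a common batch shape.
    """
    origin_g, activation, direction, t = np.broadcast_arrays(
        np.asarray(origin_g, dtype=float),
        np.asarray(activation, dtype=float),
        np.asarray(direction, dtype=float),
        np.asarray(t, dtype=float),
    )
    if np.any(t < activation):
        raise ValueError("t before activation")
    speeds = segment_speeds(model, speed_kbp_per_min)
    breaks = model.genomic_breaks
    g = origin_g.astype(float).copy().ravel()
    a = activation.ravel()
    d = direction.ravel()
    tt = t.ravel()
    now = a.copy()
    right = d > 0
    n_steps = int(np.ceil(np.max(tt - a) / dt)) + 1
    for _ in range(n_steps):
        remaining = tt - now
        if np.all(remaining <= 0):
            break
        step = np.clip(remaining, 0.0, dt)
        k = np.empty(g.shape, dtype=int)
        # boundary points: a rightward fork is entering the right segment,
        # a leftward fork the left segment
        k[right] = np.clip(np.searchsorted(breaks, g[right], side="right") - 1, 0, model.n_segments - 1)
        k[~right] = np.clip(np.searchsorted(breaks, g[~right], side="left") - 1, 0, model.n_segments - 1)
        g += d * speeds[k] * step
        np.clip(g, 0.0, model.total_genomic_kbp, out=g)
        now += step
    return g.reshape(t.shape)
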