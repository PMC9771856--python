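"""Synthetic microscope-level readout: detection dropout + axial jitter.

Turns ideal simulated dot patterns into noisy observed patterns so the
scenario-recovery stage can be tested without any real image.  Each dot
survives detection with probability ``p_detect``; surviving dots get
Gaussian localization error in axial (microscope) space — that is where
the error physically arises — and are clamped to the model extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_model import ChromosomeModel
from .fork_dynamics import simulate
from .initiation_scenarios import InitiationScenario
from .pattern_stats import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_CLASSIFY_TIMES_MIN,
    DensityProfile,
    Snapshot,
    density_profile,
    snapshot,
)

__all__ = ["NoiseModel", "ObservedPattern", "degrade", "make_labeled_dataset"]


@dataclass(frozen=True)
class NoiseModel:
    """Detection dropout probability and axial localization jitter."""

    p_detect: float = 0.8
    jitter_sd_axial: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_detect <= 1:
            raise ValueError("p_detect must be in (0, 1]")
        if self.jitter_sd_axial < 0:
            raise ValueError("jitter_sd_axial must be >= 0")


@dataclass(frozen=True)
class ObservedPattern:
    """Noisy profiles at several time points, with generating label.

    ``provenance`` records the scenario label that produced the pattern;
    it exists purely for the recovery test harness.
    """

    time_points: tuple[float, ...]
    profiles: tuple[DensityProfile, ...]
    provenance: str

    def __post_init__(self) -> None:
        edges = self.profiles[0].bin_edges
        for p in self.profiles[1:]:
            if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
                raise ValueError("profiles of one pattern must share bin edges")


def degrade(
    snap: Snapshot,
    model: ChromosomeModel,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> Snapshot:
    """Apply dropout and axial jitter to a snapshot.

    With ``p_detect=1`` and ``jitter_sd_axial=0`` this is the identity on
    the dot multiset.  Reproducible from ``noise.seed`` when no generator
    is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    n = snap.n_dots
    keep = rng.random(n) < noise.p_detect
    x = snap.axial_pos[keep].copy()
    if noise.jitter_sd_axial > 0:
        x += rng.normal(0.0, noise.jitter_sd_axial, size=len(x))
        np.clip(x, 0.0, model.total_axial_width, out=x)
    g = model.axial_to_genomic(x) if len(x) else np.empty(0)
    kinds = tuple(
        model.segments[i].kind for i in np.atleast_1d(model.segment_index(np.asarray(g)))
    ) if len(x) else ()
    return Snapshot(snap.time_min, snap.chromatid_ids[keep], np.asarray(g), x, kinds)


def make_labeled_dataset(
    model: ChromosomeModel,
    scenarios: list[InitiationScenario],
    n_patterns_per_scenario: int,
    noise: NoiseModel,
    seed: int,
    times: tuple[float, ...] = DEFAULT_CLASSIFY_TIMES_MIN,
    n_chromatids: int = 1024,
    speed_kbp_per_min: float = 2.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> list[ObservedPattern]:
    """Balanced, seeded dataset of noisy patterns for recovery experiments.

    Each pattern gets its own spawned random stream covering both the
    simulation and the noise, so patterns are mutually independent and
    the whole dataset is a pure function of ``seed``.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    if n_patterns_per_scenario < 1:
        raise ValueError("n_patterns_per_scenario must be >= 1")
    children = np.random.SeedSequence(seed).spawn(
        len(scenarios) * n_patterns_per_scenario
    )
    out: list[ObservedPattern] = []
    k = 0
    for scen in scenarios:
        for _ in range(n_patterns_per_scenario):
            rng = np.random.default_rng(children[k])
            k += 1
            records = simulate(model, scen, n_chromatids, speed_kbp_per_min, rng)
            profiles = []
            for t in times:
                noisy = degrade(snapshot(records, model, t), model, noise, rng)
                profiles.append(
                    density_profile(noisy, model, bin_width, n_chromatids)
                )
            out.append(ObservedPattern(tuple(times), tuple(profiles), scen.label))
    return out
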