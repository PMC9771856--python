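"""Snapshot dot patterns, axial density profiles and scenario recovery.

A snapshot is the set of "red dots" — active fork positions — at one
time point; a density profile is its binned axial histogram.  The
classifier compares an observed set of profiles against averaged
reference profiles simulated per candidate scenario and returns the
nearest candidate by summed Euclidean distance across time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .band_model import ChromosomeModel, SegmentKind
from .fork_dynamics import ChromatidRecord, simulate
from .initiation_scenarios import InitiationScenario

__all__ = [
    "Snapshot",
    "DensityProfile",
    "ProfileMismatchError",
    "DEFAULT_SNAPSHOT_TIMES_MIN",
    "DEFAULT_CLASSIFY_TIMES_MIN",
    "DEFAULT_BIN_WIDTH",
    "snapshot",
    "density_profile",
    "edge_concentration_index",
    "fraction_initiated",
    "classify_scenario",
]

#: Default rendering times in minutes (4 s then 1..120 min).
DEFAULT_SNAPSHOT_TIMES_MIN = (0.0667, 1.0, 5.0, 20.0, 30.0, 60.0, 120.0)

#: Times used for classification.  The early points separate synchronous
#: from gradual initiation; the 60-min point is required to separate the
#: 30- and 60-min windows, whose normalized profiles are identical in
#: expectation at any earlier time (activated-origin ages are uniform on
#: [0, t] in both whenever t is below both windows).
DEFAULT_CLASSIFY_TIMES_MIN = (1.0, 5.0, 20.0, 30.0, 60.0)

DEFAULT_BIN_WIDTH = 0.1


class ProfileMismatchError(ValueError):
    """Observed and reference profiles have incompatible bins or times."""


@dataclass(frozen=True)
class Snapshot:
    """Active fork dots at one time point.

    Arrays are parallel; a chromatid contributes at most two dots
    (none before activation, none for forks that already reached the
    model end).
    """

    time_min: float
    chromatid_ids: np.ndarray
    genomic_pos: np.ndarray
    axial_pos: np.ndarray
    segment_kinds: tuple[SegmentKind, ...]

    @property
    def n_dots(self) -> int:
        return len(self.genomic_pos)


@dataclass(frozen=True)
class DensityProfile:
    """Binned axial histogram of one snapshot."""

    bin_edges: np.ndarray
    counts: np.ndarray
    time_min: float
    n_chromatids: int

    @property
    def n_dots(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Counts as fractions of the snapshot's dots (zeros if empty)."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def snapshot(
    records: list[ChromatidRecord], model: ChromosomeModel, t: float
) -> Snapshot:
    """Render every active fork at time ``t`` as a dot.

    A fork is active iff its chromatid activated at or before ``t`` and
    the fork has not yet reached the model end (``stop_time > t``).
    Segment membership uses half-open intervals.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    ids: list[int] = []
    gs: list[float] = []
    for rec in records:
        for fork in (rec.left_fork, rec.right_fork):
            if fork.activation_time <= t < fork.stop_time:
                ids.append(rec.chromatid_id)
                gs.append(fork.position(t))
    g = np.asarray(gs, dtype=float)
    x = model.genomic_to_axial(g) if len(g) else np.empty(0)
    kinds = tuple(
        model.segments[i].kind for i in np.atleast_1d(model.segment_index(g))
    ) if len(g) else ()
    return Snapshot(float(t), np.asarray(ids, dtype=int), g, np.asarray(x), kinds)


def density_profile(
    snap: Snapshot,
    model: ChromosomeModel,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_chromatids: int = 0,
) -> DensityProfile:
    """Histogram the snapshot's axial dot positions over the whole model.

    Bins are half-open on the right except the last, which also includes
    the model's far end (dots clamped there still count).
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    total = model.total_axial_width
    n_bins = max(1, int(np.ceil(total / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], total)
    counts, _ = np.histogram(snap.axial_pos, bins=edges)
    return DensityProfile(edges, counts, snap.time_min, n_chromatids)


def edge_concentration_index(
    snap: Snapshot, model: ChromosomeModel, margin_kbp: float
) -> float:
    """Fraction of dots sitting in the flanking black bands within
    ``margin_kbp`` (genomic) of the black/INT boundary.

    Returns 0.0 for an empty snapshot.  Rises as forks pour into the
    black flanks and falls again once they travel past the margin.
    """
    if margin_kbp < 0:
        raise ValueError("margin_kbp must be >= 0")
    if snap.n_dots == 0:
        return 0.0
    lo = 0
    while lo < model.n_segments and model.segments[lo].kind is SegmentKind.BLACK:
        lo += 1
    hi = model.n_segments
    while hi > lo and model.segments[hi - 1].kind is SegmentKind.BLACK:
        hi -= 1
    g = snap.genomic_pos
    inside = np.zeros(len(g), dtype=bool)
    if lo > 0:  # leading black run, boundary at its right end
        b = model.genomic_breaks[lo]
        inside |= (g >= b - margin_kbp) & (g < b)
    if hi < model.n_segments:  # trailing black run, boundary at its left end
        b = model.genomic_breaks[hi]
        inside |= (g >= b) & (g <= b + margin_kbp)
    return float(inside.mean())


def fraction_initiated(records: list[ChromatidRecord], t: float) -> float:
    """Fraction of chromatids whose origin activated at or before ``t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if not records:
        return 0.0
    n = sum(r.origin.activation_time <= t for r in records)
    return n / len(records)


def _profiles_for_run(
    records, model, times, bin_width, n_chromatids
) -> list[DensityProfile]:
    return [
        density_profile(snapshot(records, model, t), model, bin_width, n_chromatids)
        for t in times
    ]


def classify_scenario(
    observed: list[DensityProfile],
    candidates: list[InitiationScenario],
    model: ChromosomeModel,
    n_reference_sims: int = 5,
    seed: int = 0,
    n_chromatids: int = 1024,
    speed_kbp_per_min: float = 2.0,
) -> tuple[InitiationScenario, dict[str, float]]:
    """Match observed density profiles to the nearest candidate scenario.

    For each candidate, ``n_reference_sims`` fresh simulations are run at
    the observed time points and their normalized profiles averaged; the
    observed pattern is scored by the Euclidean distance between
    normalized profiles, summed across time points.  Returns the argmin
    candidate and the per-candidate distances.  Deterministic given
    ``seed``.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate scenarios")
    if not observed:
        raise ProfileMismatchError("no observed profiles given")
    obs = sorted(observed, key=lambda p: p.time_min)
    times = [p.time_min for p in obs]
    edges = obs[0].bin_edges
    for p in obs:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ProfileMismatchError("observed profiles have differing bin edges")
    bin_width = float(edges[1] - edges[0])

    children = np.random.SeedSequence(seed).spawn(len(candidates))
    obs_norm = [p.normalized() for p in obs]
    distances: dict[str, float] = {}
    best: InitiationScenario | None = None
    for cand, child in zip(candidates, children):
        rng = np.random.default_rng(child)
        acc = [np.zeros(len(edges) - 1) for _ in times]
        for _ in range(n_reference_sims):
            records = simulate(model, cand, n_chromatids, speed_kbp_per_min, rng)
            for j, t in enumerate(times):
                prof = density_profile(
                    snapshot(records, model, t), model, bin_width, n_chromatids
                )
                if len(prof.counts) != len(edges) - 1:
                    raise ProfileMismatchError(
                        "reference profile bins do not match observed bins"
                    )
                acc[j] += prof.normalized()
        dist = 0.0
        for j in range(len(times)):
            ref_mean = acc[j] / n_reference_sims
            dist += float(np.linalg.norm(obs_norm[j] - ref_mean))
        distances[cand.label] = dist
        if best is None or dist < distances[best.label]:
            best = cand
    return best, distances
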