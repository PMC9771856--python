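"""Band/interband geometry of a multi-chromatid chromosome fragment.

A chromosome fragment is an ordered run of segments, each with a DNA
content (kbp) and an axial width (abstract width units).  Because
chromatin compaction differs between segment kinds, the genomic and
axial coordinate systems are related by a piecewise-linear bijection:
within a segment, axial position interpolates proportionally to the
genomic offset.

Conventions
-----------
* Genomic coordinates are real-valued kbp, 0-based.
* Segment intervals are half-open ``[start, end)``; a point exactly on
  a boundary belongs to the right-hand segment.
* Axial coordinates are real-valued width units, 0-based, with the same
  half-open convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SegmentKind",
    "SpeedMode",
    "Segment",
    "ChromosomeModel",
    "ModelError",
    "ModelFormatError",
    "CoordinateRangeError",
    "build_paper_int",
    "read_model",
    "write_model",
]


class SegmentKind(str, Enum):
    """Chromatin compaction class of a segment."""

    INTERBAND = "interband"
    GRAY = "gray"
    MIDDLE_GRAY = "middle_gray"
    BLACK = "black"


class SpeedMode(str, Enum):
    """How fork speed varies across segment kinds.

    ``DNA``
        Constant genomic speed (kbp/min) everywhere; the axial speed then
        falls with compaction automatically.
    ``STATED``
        Axial speed is fixed per segment kind at the printed relative
        factors (1, 1/5, 1/20, 1/50 of the interband axial speed) and the
        genomic speed is derived through each segment's density.
    """

    DNA = "dna"
    STATED = "stated"


class ModelError(ValueError):
    """Invalid chromosome-model structure or parameters."""


class ModelFormatError(ModelError):
    """Malformed segment-table file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CoordinateRangeError(ValueError):
    """Coordinate outside the model's genomic or axial extent."""


@dataclass(frozen=True)
class Segment:
    """One band or interband.

    Parameters
    ----------
    kind
        Compaction class.
    dna_kbp
        DNA content in kbp; must be positive.
    axial_width
        Axial extent in width units; must be positive.
    name
        Optional label used in segment tables.
    """

    kind: SegmentKind
    dna_kbp: float
    axial_width: float
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SegmentKind(self.kind))
        if not (self.dna_kbp > 0 and np.isfinite(self.dna_kbp)):
            raise ModelError(f"dna_kbp must be finite and > 0, got {self.dna_kbp}")
        if not (self.axial_width > 0 and np.isfinite(self.axial_width)):
            raise ModelError(
                f"axial_width must be finite and > 0, got {self.axial_width}"
            )

    @property
    def density(self) -> float:
        """Compaction density in kbp per axial width unit."""
        return self.dna_kbp / self.axial_width


@dataclass(frozen=True)
class ChromosomeModel:
    """Ordered band/interband geometry with derived coordinate maps.

    The genomic and axial break arrays are derived from the segments and
    never stored externally.  ``int_span`` is the genomic interval
    covering all non-black segments between the flanking black runs.
    """

    segments: tuple[Segment, ...]
    speed_mode: SpeedMode = SpeedMode.DNA

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        object.__setattr__(self, "speed_mode", SpeedMode(self.speed_mode))
        if not self.segments:
            raise ModelError("model needs at least one segment")

    # -- derived geometry -------------------------------------------------

    @cached_property
    def genomic_breaks(self) -> np.ndarray:
        """Cumulative genomic boundaries, length ``n_segments + 1``."""
        return np.concatenate(
            [[0.0], np.cumsum([s.dna_kbp for s in self.segments])]
        )

    @cached_property
    def axial_breaks(self) -> np.ndarray:
        """Cumulative axial boundaries, length ``n_segments + 1``."""
        return np.concatenate(
            [[0.0], np.cumsum([s.axial_width for s in self.segments])]
        )

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_genomic_kbp(self) -> float:
        return float(self.genomic_breaks[-1])

    @property
    def total_axial_width(self) -> float:
        return float(self.axial_breaks[-1])

    @cached_property
    def int_span(self) -> tuple[float, float]:
        """Genomic interval of the non-black core between the black flanks.

        Leading and trailing runs of black segments are excluded; if the
        model has no black segments the span is the whole model.
        """
        lo = 0
        while lo < self.n_segments and self.segments[lo].kind is SegmentKind.BLACK:
            lo += 1
        hi = self.n_segments
        while hi > lo and self.segments[hi - 1].kind is SegmentKind.BLACK:
            hi -= 1
        return (float(self.genomic_breaks[lo]), float(self.genomic_breaks[hi]))

    @property
    def int_length_kbp(self) -> float:
        lo, hi = self.int_span
        return hi - lo

    # -- coordinate maps --------------------------------------------------

    def segment_index(self, g, *, side: str = "right"):
        """Index of the segment containing genomic position ``g``.

        ``side='right'`` implements the half-open convention (a boundary
        point belongs to the right-hand segment); ``side='left'`` assigns
        boundary points to the left-hand segment, which is what a
        leftward-moving fork sitting on a boundary is about to enter.
        """
        idx = np.searchsorted(self.genomic_breaks, g, side=side) - 1
        return np.clip(idx, 0, self.n_segments - 1)

    def segment_index_axial(self, x, *, side: str = "right"):
        idx = np.searchsorted(self.axial_breaks, x, side=side) - 1
        return np.clip(idx, 0, self.n_segments - 1)

    def _check_range(self, v, lo: float, hi: float, what: str) -> None:
        v = np.asarray(v, dtype=float)
        if np.any(v < lo) or np.any(v > hi):
            raise CoordinateRangeError(
                f"{what} position outside model range [{lo}, {hi}]"
            )

    def genomic_to_axial(self, g):
        """Map genomic kbp to axial width units (piecewise linear).

        Accepts scalars or arrays; raises :class:`CoordinateRangeError`
        outside ``[0, total_genomic_kbp]``.
        """
        self._check_range(g, 0.0, self.total_genomic_kbp, "genomic")
        out = np.interp(g, self.genomic_breaks, self.axial_breaks)
        return float(out) if np.isscalar(g) else out

    def axial_to_genomic(self, x):
        """Inverse of :meth:`genomic_to_axial` on its range."""
        self._check_range(x, 0.0, self.total_axial_width, "axial")
        out = np.interp(x, self.axial_breaks, self.genomic_breaks)
        return float(out) if np.isscalar(x) else out

    # -- structure helpers ------------------------------------------------

    def segments_of_kind(self, kind: SegmentKind) -> list[int]:
        kind = SegmentKind(kind)
        return [i for i, s in enumerate(self.segments) if s.kind is kind]

    def interband_intervals(self) -> list[tuple[float, float]]:
        """Genomic ``[start, end)`` intervals of interband segments inside
        the INT span."""
        lo, hi = self.int_span
        out = []
        for i in self.segments_of_kind(SegmentKind.INTERBAND):
            a, b = self.genomic_breaks[i], self.genomic_breaks[i + 1]
            if a >= lo and b <= hi:
                out.append((float(a), float(b)))
        return out

    def mirror(self) -> "ChromosomeModel":
        """Model with segment order reversed (same speed mode)."""
        return ChromosomeModel(tuple(reversed(self.segments)), self.speed_mode)

    def content_hash(self) -> str:
        payload = "\n".join(
            f"{s.name}\t{s.kind.value}\t{s.dna_kbp!r}\t{s.axial_width!r}"
            for s in self.segments
        )
        payload += f"\n{self.speed_mode.value}"
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# -- built-in default fragment -------------------------------------------

#: Non-black core composition: 6 interbands of 2 kbp alternating with
#: 4 gray bands of 5 kbp and one 20-kbp middle gray band, 52 kbp total.
_INT_CORE: tuple[tuple[SegmentKind, float], ...] = (
    (SegmentKind.INTERBAND, 2.0),
    (SegmentKind.GRAY, 5.0),
    (SegmentKind.INTERBAND, 2.0),
    (SegmentKind.GRAY, 5.0),
    (SegmentKind.INTERBAND, 2.0),
    (SegmentKind.MIDDLE_GRAY, 20.0),
    (SegmentKind.INTERBAND, 2.0),
    (SegmentKind.GRAY, 5.0),
    (SegmentKind.INTERBAND, 2.0),
    (SegmentKind.GRAY, 5.0),
    (SegmentKind.INTERBAND, 2.0),
)

#: Default compaction density of a flanking black band, kbp per width unit.
BLACK_DENSITY_KBP_PER_WIDTH = 50.0


def build_paper_int(
    black_flank_kbp: float = 100.0,
    speed_mode: SpeedMode | str = SpeedMode.DNA,
    black_axial_width: float | None = None,
) -> ChromosomeModel:
    """Build the default 13-segment fragment: one 52-kbp INT between two
    black flanks.

    The INT core alternates six 2-kbp interbands with four 5-kbp gray
    bands and one 20-kbp middle gray band; every core segment has unit
    axial width.  The black flanks default to 100 kbp of DNA each at a
    density of 50 kbp per width unit (axial width 2.0), both
    configurable.

    Parameters
    ----------
    black_flank_kbp
        DNA content of each flanking black band (kbp, > 0).
    speed_mode
        Speed interpretation stored on the model.
    black_axial_width
        Override for the flanks' axial width; by default derived from
        ``black_flank_kbp / 50``.
    """
    if not black_flank_kbp > 0:
        raise ModelError("black_flank_kbp must be > 0")
    if black_axial_width is None:
        black_axial_width = black_flank_kbp / BLACK_DENSITY_KBP_PER_WIDTH
    flank = dict(dna_kbp=black_flank_kbp, axial_width=black_axial_width)
    segments = [Segment(SegmentKind.BLACK, **flank, name="black_L")]
    counters: dict[SegmentKind, int] = {}
    for kind, dna in _INT_CORE:
        counters[kind] = counters.get(kind, 0) + 1
        short = {"interband": "ib", "gray": "gray", "middle_gray": "mgray"}[kind.value]
        segments.append(
            Segment(kind, dna_kbp=dna, axial_width=1.0, name=f"{short}{counters[kind]}")
        )
    segments.append(Segment(SegmentKind.BLACK, **flank, name="black_R"))
    return ChromosomeModel(tuple(segments), SpeedMode(speed_mode))


# -- segment-table I/O ----------------------------------------------------

_TABLE_HEADER = ("name", "kind", "dna_kbp", "axial_width")


def write_model(model: ChromosomeModel, path: str | Path) -> None:
    """Write a model as a BED-like TSV segment table.

    Columns: ``name  kind  dna_kbp  axial_width``.  Genomic and axial
    break coordinates are derived on read, never stored.
    """
    path = Path(path)
    lines = ["\t".join(_TABLE_HEADER)]
    for s in model.segments:
        lines.append(f"{s.name}\t{s.kind.value}\t{s.dna_kbp!r}\t{s.axial_width!r}")
    path.write_text("\n".join(lines) + "\n")


def read_model(
    path: str | Path, speed_mode: SpeedMode | str = SpeedMode.DNA
) -> ChromosomeModel:
    """Read a segment table written by :func:`write_model`.

    Malformed rows raise :class:`ModelFormatError` carrying the
    1-based line number.  Adjacent segments of the same kind are
    accepted (the table format is more general than the built-in
    default).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ModelFormatError("empty segment table", line=1)
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _TABLE_HEADER:
        raise ModelFormatError(
            f"expected header {'/'.join(_TABLE_HEADER)}, got {lines[0]!r}", line=1
        )
    segments: list[Segment] = []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 4:
            raise ModelFormatError(
                f"expected 4 tab-separated fields, got {len(fields)}", line=ln
            )
        name, kind_tok, dna_tok, width_tok = fields
        try:
            kind = SegmentKind(kind_tok)
        except ValueError:
            raise ModelFormatError(f"unknown kind {kind_tok!r}", line=ln) from None
        try:
            dna = float(dna_tok)
            width = float(width_tok)
        except ValueError as exc:
            raise ModelFormatError(str(exc), line=ln) from None
        try:
            segments.append(Segment(kind, dna, width, name=name))
        except ModelError as exc:
            raise ModelFormatError(str(exc), line=ln) from None
    if not segments:
        raise ModelFormatError("segment table has no data rows", line=1)
    return ChromosomeModel(tuple(segments), SpeedMode(speed_mode))
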