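"""TSV writers/readers for the pipeline's tabular outputs.

All files are headered, tab-separated, written with `repr` floats so
identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..band_model import ChromosomeModel
from ..fork_dynamics import ChromatidRecord
from ..initiation_scenarios import OriginEvent
from ..pattern_stats import DensityProfile, Snapshot

__all__ = [
    "TableFormatError",
    "write_origins",
    "write_records",
    "write_snapshots",
    "read_snapshots",
    "write_profiles",
    "read_profiles",
]


class TableFormatError(ValueError):
    """Malformed tabular input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _write(path: str | Path, header: list[str], rows) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_origins(origins: list[OriginEvent], path: str | Path) -> None:
    _write(
        path,
        ["chromatid_id", "genomic_pos_kbp", "activation_time_min"],
        ((o.chromatid_id, repr(o.genomic_pos), repr(o.activation_time)) for o in origins),
    )


def write_records(records: list[ChromatidRecord], path: str | Path) -> None:
    _write(
        path,
        [
            "chromatid_id",
            "origin_kbp",
            "activation_min",
            "completion_min",
            "left_stop_min",
            "right_stop_min",
        ],
        (
            (
                r.chromatid_id,
                repr(r.origin.genomic_pos),
                repr(r.origin.activation_time),
                repr(r.int_completion_time),
                repr(r.left_fork.stop_time),
                repr(r.right_fork.stop_time),
            )
            for r in records
        ),
    )


_SNAPSHOT_HEADER = ["time_min", "chromatid_id", "genomic_pos_kbp", "axial_pos", "segment_kind"]


def write_snapshots(snapshots: list[Snapshot], path: str | Path) -> None:
    def rows():
        for snap in snapshots:
            for i in range(snap.n_dots):
                yield (
                    repr(snap.time_min),
                    snap.chromatid_ids[i],
                    repr(float(snap.genomic_pos[i])),
                    repr(float(snap.axial_pos[i])),
                    snap.segment_kinds[i].value,
                )

    _write(path, _SNAPSHOT_HEADER, rows())


def read_snapshots(path: str | Path, model: ChromosomeModel) -> list[Snapshot]:
    """Rebuild snapshots (grouped by time) from a snapshots TSV."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _SNAPSHOT_HEADER:
        raise TableFormatError("bad or missing snapshots header", line=1)
    by_time: dict[float, list[tuple[int, float, float]]] = {}
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 5:
            raise TableFormatError(f"expected 5 fields, got {len(fields)}", line=ln)
        try:
            t = float(fields[0])
            cid = int(fields[1])
            g = float(fields[2])
            x = float(fields[3])
        except ValueError as exc:
            raise TableFormatError(str(exc), line=ln) from None
        by_time.setdefault(t, []).append((cid, g, x))
    out = []
    for t in sorted(by_time):
        rows = by_time[t]
        g = np.array([r[1] for r in rows])
        kinds = tuple(model.segments[i].kind for i in np.atleast_1d(model.segment_index(g)))
        out.append(
            Snapshot(
                t,
                np.array([r[0] for r in rows], dtype=int),
                g,
                np.array([r[2] for r in rows]),
                kinds,
            )
        )
    return out


_PROFILE_HEADER = ["time_min", "bin_index", "bin_left", "bin_right", "count", "n_chromatids"]


def write_profiles(profiles: list[DensityProfile], path: str | Path) -> None:
    def rows():
        for prof in profiles:
            for i, c in enumerate(prof.counts):
                yield (
                    repr(prof.time_min),
                    i,
                    repr(float(prof.bin_edges[i])),
                    repr(float(prof.bin_edges[i + 1])),
                    int(c),
                    prof.n_chromatids,
                )

    _write(path, _PROFILE_HEADER, rows())


def read_profiles(path: str | Path) -> list[DensityProfile]:
    """Read a profiles TSV back into per-time :class:`DensityProfile`.

    Validates contiguous bins and dense 0..n-1 bin indices per time
    point; problems raise :class:`TableFormatError` with a line number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _PROFILE_HEADER:
        raise TableFormatError("bad or missing profiles header", line=1)
    by_time: dict[float, list[tuple[int, float, float, int, int, int]]] = {}
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 6:
            raise TableFormatError(f"expected 6 fields, got {len(fields)}", line=ln)
        try:
            t = float(fields[0])
            idx = int(fields[1])
            left = float(fields[2])
            right = float(fields[3])
            count = int(fields[4])
            n_chromatids = int(fields[5])
        except ValueError as exc:
            raise TableFormatError(str(exc), line=ln) from None
        if count < 0:
            raise TableFormatError("negative count", line=ln)
        by_time.setdefault(t, []).append((idx, left, right, count, n_chromatids, ln))
    if not by_time:
        raise TableFormatError("profiles table has no data rows", line=1)
    out = []
    for t in sorted(by_time):
        rows = sorted(by_time[t])
        for want, row in enumerate(rows):
            if row[0] != want:
                raise TableFormatError(
                    f"bin indices for time {t} are not dense (missing {want})",
                    line=row[5],
                )
        edges = [rows[0][1]] + [r[2] for r in rows]
        for k in range(1, len(rows)):
            if abs(rows[k][1] - edges[k]) > 1e-9:
                raise TableFormatError(
                    f"bins for time {t} are not contiguous", line=rows[k][5]
                )
        out.append(
            DensityProfile(
                np.array(edges),
                np.array([r[3] for r in rows], dtype=int),
                t,
                rows[0][4],
            )
        )
    return out
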