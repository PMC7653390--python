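"""Flat-table trajectory files.

Tab-separated, header ``timeStep pedestrianId x y selfCategory``, frame
indices starting at 1, coordinates in metres.  Coordinates are printed with
six decimals when that is lossless and otherwise at full precision, so a
write -> read -> write round trip is byte-identical.  Experiment-style
four-column files (without the selfCategory column) are accepted on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .engine import TRAJECTORY_COLUMNS, Trajectory

__all__ = ["ParseError", "read_trajectories", "write_trajectories"]

HEADER5 = TRAJECTORY_COLUMNS
HEADER4 = TRAJECTORY_COLUMNS[:4]


class ParseError(ValueError):
    """Malformed trajectory file; the message names the offending line."""


def _format_coord(x: float) -> str:
    s = f"{x:.6f}"
    return s if float(s) == x else repr(x)


def write_trajectories(path: str | Path, trajectory: Trajectory) -> None:
    """Write one multi-agent trajectory table (canonical serialisation)."""
    df = trajectory.records
    with_categories = df["selfCategory"].notna().any()
    lines = ["\t".join(HEADER5 if with_categories else HEADER4)]
    for row in df.itertuples(index=False):
        fields = [
            str(int(row.timeStep)),
            str(int(row.pedestrianId)),
            _format_coord(float(row.x)),
            _format_coord(float(row.y)),
        ]
        if with_categories:
            fields.append("" if row.selfCategory is None else str(row.selfCategory))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trajectories(path: str | Path, frame_interval: float) -> Trajectory:
    """Read a trajectory table; tolerates files without selfCategory.

    Raises :class:`ParseError` with a line number for a malformed header,
    non-integer frame or agent ids, bad coordinates, wrong field counts or
    duplicate (timeStep, pedestrianId) pairs.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header == HEADER5:
        ncols = 5
    elif header == HEADER4:
        ncols = 4
    else:
        raise ParseError(f"{path}:1: malformed header {lines[0]!r}")

    rows: list[tuple] = []
    seen: set[tuple[int, int]] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncols:
            raise ParseError(
                f"{path}:{lineno}: expected {ncols} fields, got {len(fields)}"
            )
        try:
            step = int(fields[0])
            pid = int(fields[1])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-integer timeStep/pedestrianId"
            ) from None
        try:
            x = float(fields[2])
            y = float(fields[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad coordinate") from None
        key = (step, pid)
        if key in seen:
            raise ParseError(
                f"{path}:{lineno}: duplicate (timeStep, pedestrianId) = {key}"
            )
        seen.add(key)
        category: Optional[str] = None
        if ncols == 5 and fields[4] != "":
            category = fields[4]
        rows.append((step, pid, x, y, category))

    if not rows:
        raise ParseError(f"{path}: no records")
    return Trajectory(
        frame_interval=frame_interval,
        records=pd.DataFrame(rows, columns=HEADER5),
    )
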