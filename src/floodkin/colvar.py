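"""COLVAR-dialect whitespace text files.

Header line ``#! FIELDS time cv bias`` followed by one row per recorded
step.  Comment lines start with ``#``.  Files produced by restarted runs
may repeat the header mid-file; the reader merges them by keeping the
monotone-time prefix of each segment.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .engine import Trajectory
from .errors import FormatError

log = logging.getLogger(__name__)

HEADER_PREFIX = "#! FIELDS"


def write_colvar_arrays(path, times, cv_values, bias_values) -> None:
    path = Path(path)
    times = np.asarray(times, dtype=float)
    cv = np.asarray(cv_values, dtype=float)
    bias = np.asarray(bias_values, dtype=float)
    with path.open("w") as fh:
        fh.write(f"{HEADER_PREFIX} time cv bias\n")
        for t, y, v in zip(times, cv, bias):
            fh.write(f"{t:.10g} {y:.10g} {v:.10g}\n")


def write_colvar(path, trajectory: Trajectory) -> None:
    """Write a trajectory in the COLVAR dialect."""
    write_colvar_arrays(path, trajectory.times, trajectory.cv_values, trajectory.bias_values)


def read_colvar(path, cv_name: str = "cv", escaped: bool = True) -> Trajectory:
    """Parse a COLVAR-dialect file into a Trajectory.

    The ``time`` column and a CV column named ``cv_name`` are required; a
    missing ``bias`` column defaults to zero with a logged warning.  The
    returned trajectory is marked escaped by default (fixture and
    production files end at the escape step); pass ``escaped=False`` for
    truncated runs.
    """
    path = Path(path)
    columns: list[str] | None = None
    rows: list[list[float]] = []
    last_time = -np.inf
    restart_merged = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(HEADER_PREFIX):
                fields = line[len(HEADER_PREFIX):].split()
                if columns is None:
                    columns = fields
                elif fields != columns:
                    raise FormatError(f"{path}:{lineno}: restart header changes the fields")
                else:
                    restart_merged = True
                continue
            if line.startswith("#"):
                continue
            if columns is None:
                raise FormatError(f"{path}: data before the '#! FIELDS' header")
            values = [float(x) for x in line.split()]
            if len(values) != len(columns):
                raise FormatError(f"{path}:{lineno}: expected {len(columns)} columns")
            rows.append(values)

    if columns is None:
        raise FormatError(f"{path}: missing '{HEADER_PREFIX}' header")
    for required in ("time", cv_name):
        if required not in columns:
            raise FormatError(
                f"{path}: missing required column {required!r} (have {columns}); "
                "use the cv-name alias flag if the CV column is named differently"
            )
    data = np.asarray(rows, dtype=float)
    t_idx = columns.index("time")
    cv_idx = columns.index(cv_name)
    if restart_merged:
        keep = np.zeros(len(data), dtype=bool)
        last_time = -np.inf
        for i, t in enumerate(data[:, t_idx]):
            if t > last_time:
                keep[i] = True
                last_time = t
        data = data[keep]
    times = data[:, t_idx]
    if np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: non-monotone time column after restart merge")
    if "bias" in columns:
        bias = data[:, columns.index("bias")]
    else:
        log.warning("%s: no bias column, assuming an unbiased run (bias = 0)", path)
        bias = np.zeros(len(data))
    return Trajectory(
        times=times,
        cv_values=data[:, cv_idx],
        bias_values=bias,
        seed=-1,
        escaped=escaped,
        escape_step=len(times) - 1 if escaped else None,
    )
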