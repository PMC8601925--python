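"""Plain-text trajectory I/O (TSV with a fixed, diffable column order)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "TRAJECTORY_HEADER"]

TRAJECTORY_HEADER = (
    "time", "time_scale", "x1", "x2", "x3", "x4", "x", "p1", "p2", "D", "p_A", "H",
)


def _fmt(v: float) -> str:
    return f"{v:.10g}"


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as TSV, floats at 10 significant digits."""
    frame = traj.frame
    with open(path, "w") as fh:
        fh.write("\t".join(TRAJECTORY_HEADER) + "\n")
        for row in frame.itertuples(index=False):
            values = [
                _fmt(row.time), traj.time_scale,
                _fmt(row.x1), _fmt(row.x2), _fmt(row.x3), _fmt(row.x4),
                _fmt(row.x), _fmt(row.p1), _fmt(row.p2),
                _fmt(row.D), _fmt(row.p_A), _fmt(row.H),
            ]
            fh.write("\t".join(values) + "\n")


def read_trajectory(path) -> Trajectory:
    """Read a TSV written by :func:`write_trajectory`."""
    raw = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_HEADER) - set(raw.columns)
    if missing:
        raise ValueError(f"trajectory file is missing columns {sorted(missing)}")
    scales = raw["time_scale"].unique()
    if len(scales) != 1:
        raise ValueError(f"trajectory file mixes time scales: {scales}")
    frame = raw.drop(columns=["time_scale"]).astype(float)
    return Trajectory(frame=frame, time_scale=str(scales[0]))
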