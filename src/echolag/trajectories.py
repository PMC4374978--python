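"""Data model, I/O, smoothing and kinematics for uniformly sampled paired 2-D trajectories.

A :class:`Trajectory` holds the raw positions of one bat on a uniform time
grid (default 20 ms).  Positions are smoothed with a centred moving average
(half-window ``w``) before headings and speeds are derived by central
differences; the ``w + 1`` boundary samples on each side carry no kinematics.
Times are handled internally as integer sample indices on the grid
``t = t0 + k * dt`` so that the (t, tau) lattice of the delay maps never
accumulates floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "PairedTrajectory",
    "TrajectoryError",
    "smooth",
    "kinematics",
    "wrap_angle",
    "read_trajectories",
    "write_trajectories",
]


class TrajectoryError(ValueError):
    """Invalid trajectory input (shape, time grid, or pairing)."""


def wrap_angle(a):
    """Wrap angles to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def smooth(positions: np.ndarray, w: int) -> np.ndarray:
    """Centred moving average over ``2w + 1`` samples per coordinate.

    Returns an array of the same shape; the first and last ``w`` samples are
    NaN, flagging them as excluded from downstream kinematics.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise TrajectoryError("positions must have shape (n, 2)")
    n = positions.shape[0]
    if w < 0:
        raise TrajectoryError("smoothing half-window w must be >= 0")
    if n < 2 * w + 1:
        raise TrajectoryError(
            f"need at least {2 * w + 1} samples for half-window w={w}, got {n}"
        )
    if w == 0:
        return positions.copy()
    kernel = np.full(2 * w + 1, 1.0 / (2 * w + 1))
    out = np.full_like(positions, np.nan)
    for c in range(2):
        out[w : n - w, c] = np.convolve(positions[:, c], kernel, mode="valid")
    return out


@dataclass
class Trajectory:
    """Uniformly sampled 2-D path of one bat with derived kinematics."""

    bat_id: str
    t0: float
    dt: float
    positions: np.ndarray  # (n, 2) metres
    smoothed_positions: np.ndarray | None = None  # NaN-padded at the edges
    headings: np.ndarray | None = None  # (n,) radians in (-pi, pi], NaN at edges
    speeds: np.ndarray | None = None  # (n,) m/s, NaN at edges

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise TrajectoryError("positions must have shape (n, 2)")
        if not self.dt > 0:
            raise TrajectoryError("dt must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def copy(self) -> "Trajectory":
        return Trajectory(
            bat_id=self.bat_id,
            t0=self.t0,
            dt=self.dt,
            positions=self.positions.copy(),
            smoothed_positions=None
            if self.smoothed_positions is None
            else self.smoothed_positions.copy(),
            headings=None if self.headings is None else self.headings.copy(),
            speeds=None if self.speeds is None else self.speeds.copy(),
        )


def kinematics(traj: Trajectory, w: int = 2) -> Trajectory:
    """Fill smoothed positions, headings and speeds of ``traj`` (returns a copy).

    Velocity at sample k is the central difference
    ``(p[k+1] - p[k-1]) / (2 dt)`` of the smoothed positions; heading is its
    atan2 angle and speed its norm.  Samples where either neighbour is
    undefined, or where the speed vanishes, carry NaN.
    """
    n = len(traj)
    if n < max(3, 2 * w + 2):
        raise TrajectoryError(
            f"need at least {max(3, 2 * w + 2)} samples for kinematics with w={w}"
        )
    out = traj.copy()
    out.smoothed_positions = smooth(traj.positions, w)
    vel = np.full((n, 2), np.nan)
    vel[1:-1] = (out.smoothed_positions[2:] - out.smoothed_positions[:-2]) / (2.0 * traj.dt)
    speeds = np.hypot(vel[:, 0], vel[:, 1])
    headings = np.full(n, np.nan)
    ok = np.isfinite(speeds) & (speeds > 0.0)
    headings[ok] = np.arctan2(vel[ok, 1], vel[ok, 0])
    headings[ok] = wrap_angle(headings[ok])
    out.headings = headings
    out.speeds = speeds
    return out


@dataclass
class PairedTrajectory:
    """Two trajectories of one bat pair on an identical time grid."""

    pair_id: str
    a: Trajectory
    b: Trajectory

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise TrajectoryError(
                f"pair {self.pair_id!r}: members have different lengths "
                f"({len(self.a)} vs {len(self.b)})"
            )
        if not np.isclose(self.a.dt, self.b.dt):
            raise TrajectoryError(f"pair {self.pair_id!r}: members have different dt")
        if not np.isclose(self.a.t0, self.b.t0):
            raise TrajectoryError(f"pair {self.pair_id!r}: members have different t0")

    @property
    def dt(self) -> float:
        return self.a.dt

    @property
    def t0(self) -> float:
        return self.a.t0

    def __len__(self) -> int:
        return len(self.a)

    def with_kinematics(self, w: int = 2) -> "PairedTrajectory":
        return PairedTrajectory(self.pair_id, kinematics(self.a, w), kinematics(self.b, w))


def _check_uniform_grid(t: np.ndarray, pair_id: str, bat_id: str) -> tuple[float, float]:
    """Validate a uniform time grid; return (t0, dt)."""
    if len(t) < 2:
        raise TrajectoryError(f"pair {pair_id!r}, bat {bat_id!r}: fewer than 2 samples")
    diffs = np.diff(t)
    dt = float(np.median(diffs))
    if dt <= 0:
        raise TrajectoryError(f"pair {pair_id!r}, bat {bat_id!r}: non-increasing times")
    bad = np.where(~np.isclose(diffs, dt, rtol=1e-6, atol=1e-9))[0]
    if bad.size:
        k = bad[0]
        raise TrajectoryError(
            f"pair {pair_id!r}, bat {bat_id!r}: non-uniform time grid at "
            f"t={t[k]:.6g} -> {t[k + 1]:.6g} (expected step {dt:.6g})"
        )
    return float(t[0]), dt


def read_trajectories(path: str | Path) -> list[PairedTrajectory]:
    """Read paired trajectories from a delimited text table.

    The table must have a header row with columns ``pair_id,bat_id,t,x,y``
    (comma- or tab-separated); t in seconds, x/y in metres.  Rows are grouped
    by pair; each pair must contain exactly two bats sharing an identical
    uniform time grid.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing so written trajectories read back bit-identically
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except (pd.errors.EmptyDataError, StopIteration):
        raise TrajectoryError(f"{path}: empty trajectory file") from None
    required = {"pair_id", "bat_id", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryError(f"{path}: missing columns {sorted(missing)}")
    pairs: list[PairedTrajectory] = []
    for pair_id, grp in df.groupby("pair_id", sort=False):
        bat_ids = list(dict.fromkeys(grp["bat_id"]))
        if len(bat_ids) != 2:
            raise TrajectoryError(
                f"pair {pair_id!r}: expected exactly 2 bat ids, found {len(bat_ids)}"
            )
        members = []
        grids = []
        for bat_id in bat_ids:
            sub = grp[grp["bat_id"] == bat_id].sort_values("t")
            t = sub["t"].to_numpy(dtype=float)
            t0, dt = _check_uniform_grid(t, str(pair_id), str(bat_id))
            grids.append((t0, dt, len(t)))
            members.append(
                Trajectory(
                    bat_id=str(bat_id),
                    t0=t0,
                    dt=dt,
                    positions=np.column_stack([sub["x"].to_numpy(float), sub["y"].to_numpy(float)]),
                )
            )
        if not (
            np.isclose(grids[0][0], grids[1][0])
            and np.isclose(grids[0][1], grids[1][1])
            and grids[0][2] == grids[1][2]
        ):
            raise TrajectoryError(f"pair {pair_id!r}: members do not share a common time grid")
        pairs.append(PairedTrajectory(str(pair_id), members[0], members[1]))
    if not pairs:
        raise TrajectoryError(f"{path}: no trajectory rows")
    return pairs


def write_trajectories(
    pairs: Iterable[PairedTrajectory],
    path: str | Path,
    include_kinematics: bool = False,
    sep: str = ",",
) -> None:
    """Write paired trajectories in the delimited input format.

    With ``include_kinematics`` the audited ``heading`` and ``speed`` columns
    are appended (NaN where undefined).
    """
    rows = []
    for pair in pairs:
        for traj in (pair.a, pair.b):
            rec = {
                "pair_id": pair.pair_id,
                "bat_id": traj.bat_id,
                "t": traj.t,
                "x": traj.positions[:, 0],
                "y": traj.positions[:, 1],
            }
            if include_kinematics:
                n = len(traj)
                rec["heading"] = traj.headings if traj.headings is not None else np.full(n, np.nan)
                rec["speed"] = traj.speeds if traj.speeds is not None else np.full(n, np.nan)
            rows.append(pd.DataFrame(rec))
    pd.concat(rows, ignore_index=True).to_csv(path, sep=sep, index=False)
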