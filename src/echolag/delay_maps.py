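"""Delayed directional-correlation and delayed-separation maps on the (t, tau) lattice.

For a bat pair (i, j) the directional correlation at time t and delay tau is
the normalised scalar product of i's velocity at t with j's velocity at
t + tau; its window mean over ``2w + 1`` consecutive samples is the
time-dependent delayed directional correlation (TDDC).  The analogous window
mean of the Euclidean distance between i at t and j at t + tau is the
time-dependent delayed separation (TDDS).  A lattice cell (t, tau) is defined
only when every sample of both windows lies inside the recording and carries
defined kinematics; undefined cells are NaN, never zero, so that path
extraction cannot score them.

Both maps are computed from the smoothed coordinates.  The tau lattice step
equals dt and the tau range is the maximal one for which the domain is
nonempty; with this convention the sharp domain boundaries are the lines
``t + tau = const`` at the two ends of the recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajectories import PairedTrajectory

__all__ = ["DelayMap", "directional_correlation", "tddc", "tdds"]


@dataclass
class DelayMap:
    """Dense map over the (t, tau) lattice; NaN marks undefined cells."""

    kind: str  # "correlation" | "separation"
    pair_id: str
    i_id: str
    j_id: str
    t0: float
    dt: float
    t_idx: np.ndarray  # integer sample indices into the trajectories
    tau_idx: np.ndarray  # integer delays in samples (negative and positive)
    values: np.ndarray  # (n_t, n_tau)
    w: int

    @property
    def t_values(self) -> np.ndarray:
        return self.t0 + self.dt * self.t_idx

    @property
    def tau_values(self) -> np.ndarray:
        return self.dt * self.tau_idx

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell(self, t_index: int, tau_index: int) -> float:
        """Value at trajectory sample index ``t_index`` and lattice delay ``tau_index``."""
        n = int(np.searchsorted(self.t_idx, t_index))
        m = int(np.searchsorted(self.tau_idx, tau_index))
        if (
            n >= len(self.t_idx)
            or m >= len(self.tau_idx)
            or self.t_idx[n] != t_index
            or self.tau_idx[m] != tau_index
        ):
            return float("nan")
        return float(self.values[n, m])

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        """Dense matrix with a t header row and tau header column + JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("tau" + sep + sep.join(f"{t:.6g}" for t in self.t_values) + "\n")
            for m, tau in enumerate(self.tau_values):
                fh.write(
                    f"{tau:.6g}" + sep + sep.join(f"{v:.8g}" for v in self.values[:, m]) + "\n"
                )
        sidecar = {
            "kind": self.kind,
            "pair_id": self.pair_id,
            "i_id": self.i_id,
            "j_id": self.j_id,
            "t0": self.t0,
            "dt": self.dt,
            "w": self.w,
            "t_idx_start": int(self.t_idx[0]),
            "tau_idx_start": int(self.tau_idx[0]),
            "n_t": int(len(self.t_idx)),
            "n_tau": int(len(self.tau_idx)),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    def plot(self, ax=None, levels=None, **kwargs):
        """Filled contour rendering of the map (t on x, tau on y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cs = ax.contourf(self.t_values, self.tau_values, self.values.T, levels=levels, **kwargs)
        ax.set_xlabel("t (s)")
        ax.set_ylabel("tau (s)")
        ax.set_title(f"{self.kind} map, pair {self.pair_id}")
        return ax, cs


def _ensure_kinematics(pair: PairedTrajectory, w: int) -> PairedTrajectory:
    if pair.a.headings is None or pair.b.headings is None:
        return pair.with_kinematics(w)
    return pair


def _unit_velocities(traj) -> np.ndarray:
    """Unit heading vectors per sample, NaN where kinematics are undefined."""
    u = np.full((len(traj), 2), np.nan)
    ok = np.isfinite(traj.headings)
    u[ok, 0] = np.cos(traj.headings[ok])
    u[ok, 1] = np.sin(traj.headings[ok])
    return u


def directional_correlation(pair: PairedTrajectory, t_index: int, tau_index: int, w: int = 2):
    """Instantaneous correlation nu(t, tau) between i's velocity at t and j's at t + tau.

    Returns NaN (the undefined-cell marker) when either velocity is undefined
    or either sample falls outside the recording.
    """
    pair = _ensure_kinematics(pair, w)
    n = len(pair)
    k = t_index + tau_index
    if not (0 <= t_index < n and 0 <= k < n):
        return float("nan")
    ha = pair.a.headings[t_index]
    hb = pair.b.headings[k]
    if not (np.isfinite(ha) and np.isfinite(hb)):
        return float("nan")
    return float(np.cos(ha - hb))


def _window_mean_lattice(xa: np.ndarray, xb: np.ndarray, w: int, combine):
    """Shared lattice machinery: window-mean of combine(xa[t], xb[t+tau]) over k in [-w, w].

    ``xa``/``xb`` are full-length per-sample arrays (rows may be vectors) with
    NaN marking undefined samples; NaN propagates through the window mean,
    which implements the all-samples-defined domain rule.
    """
    n = xa.shape[0]
    t_lo, t_hi = 2 * w + 1, n - 2 * w - 2  # inclusive; velocity valid on [w+1, n-w-2]
    if t_hi < t_lo:
        raise ValueError(f"trajectory too short for delay map with w={w}")
    t_idx = np.arange(t_lo, t_hi + 1)
    m_max = t_hi - t_lo
    tau_idx = np.arange(-m_max, m_max + 1)
    kernel = np.full(2 * w + 1, 1.0 / (2 * w + 1))
    values = np.full((len(t_idx), len(tau_idx)), np.nan)
    for col, m in enumerate(tau_idx):
        # overlap of [0, n) for t and t+m
        lo = max(0, -m)
        hi = min(n, n - m)
        if hi - lo < 2 * w + 1:
            continue
        prod = combine(xa[lo:hi], xb[lo + m : hi + m])
        sm = np.convolve(prod, kernel, mode="valid")  # centres lo+w .. hi-1-w
        centres = np.arange(lo + w, hi - w)
        keep = (centres >= t_lo) & (centres <= t_hi)
        values[centres[keep] - t_lo, col] = sm[keep]
    return t_idx, tau_idx, values


def tddc(pair: PairedTrajectory, w: int = 2) -> DelayMap:
    """Time-dependent delayed directional correlation map C_ij(t, tau)."""
    pair = _ensure_kinematics(pair, w)
    ua = _unit_velocities(pair.a)
    ub = _unit_velocities(pair.b)
    t_idx, tau_idx, values = _window_mean_lattice(
        ua, ub, w, lambda x, y: np.einsum("ij,ij->i", x, y)
    )
    np.clip(values, -1.0, 1.0, out=values)
    return DelayMap(
        kind="correlation",
        pair_id=pair.pair_id,
        i_id=pair.a.bat_id,
        j_id=pair.b.bat_id,
        t0=pair.t0,
        dt=pair.dt,
        t_idx=t_idx,
        tau_idx=tau_idx,
        values=values,
        w=w,
    )


def tdds(pair: PairedTrajectory, w: int = 2) -> DelayMap:
    """Time-dependent delayed separation map R_ij(t, tau) in metres."""
    pair = _ensure_kinematics(pair, w)
    n = len(pair)
    # share the correlation map's definedness: restrict to samples that also
    # carry kinematics, so both maps have the identical Eq.-domain lattice
    valid = np.zeros(n, dtype=bool)
    valid[w + 1 : n - w - 1] = True
    pa = np.where(valid[:, None], pair.a.smoothed_positions, np.nan)
    pb = np.where(valid[:, None], pair.b.smoothed_positions, np.nan)
    t_idx, tau_idx, values = _window_mean_lattice(
        pa, pb, w, lambda x, y: np.hypot(x[:, 0] - y[:, 0], x[:, 1] - y[:, 1])
    )
    return DelayMap(
        kind="separation",
        pair_id=pair.pair_id,
        i_id=pair.a.bat_id,
        j_id=pair.b.bat_id,
        t0=pair.t0,
        dt=pair.dt,
        t_idx=t_idx,
        tau_idx=tau_idx,
        values=values,
        w=w,
    )
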