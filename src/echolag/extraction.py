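"""Time-ordered interaction-path extraction from TDDC/TDDS maps.

The extracted path assigns one delay tau(t) per time step.  Reactions must be
ordered in time (delay may decrease by at most dt per step), super-threshold
cells contribute their correlation to the path score, a fixed penalty q is
charged whenever the delay changes, and sub-threshold or undefined cells are
traversed at zero contribution.  Chase paths minimise the delayed separation
over cells that are simultaneously well correlated (C >= v_c) and spatially
coincident in the delayed frame (R <= d_c); when a chase path exists the
coordinated path is constrained to coincide with it.

Delay uncertainties are the contiguous super-threshold tau intervals
containing the path, tightened by propagating slope −1 lines forward from
per-time minima and backward from per-time maxima — the time-ordering
constraint applied to the interval bounds themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dp import best_path
from .delay_maps import DelayMap

__all__ = [
    "ExtractionConfig",
    "InteractionPath",
    "extract_coordinated_path",
    "extract_chase_path",
    "delay_uncertainty",
    "threshold_relative_heading_deg",
]

KIND_NONE = 0
KIND_COORDINATED = 1
KIND_CHASE = 2
_KIND_NAMES = np.array(["none", "coordinated", "chase"])

_CHASE_BONUS = 1.0e6  # dominates any separation sum; maximises chase-cell coverage first


@dataclass
class ExtractionConfig:
    """Thresholds of the behavioural classifier.

    v_c : correlation threshold (headings within arccos(v_c) of each other)
    d_c : chase separation threshold in metres (below the bat's wingspan)
    q   : penalty subtracted from the path score at every delay change
    w   : smoothing/averaging half-window in samples
    """

    v_c: float = 0.95
    d_c: float = 0.15
    q: float = 0.02
    w: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.v_c <= 1.0:
            raise ValueError("v_c must be in (0, 1]")
        if not self.d_c > 0:
            raise ValueError("d_c must be positive")
        if self.q < 0:
            raise ValueError("q must be non-negative")
        if self.w < 0:
            raise ValueError("w must be non-negative")


def threshold_relative_heading_deg(v_c: float = 0.95) -> float:
    """Relative-heading magnitude (degrees) at the correlation threshold.

    Two headings correlate at exactly v_c when they differ by arccos(v_c);
    the default threshold 0.95 therefore admits headings within ~18.2 deg.
    """
    return float(np.degrees(np.arccos(v_c)))


@dataclass
class InteractionPath:
    """Extracted delay per time step with uncertainty bounds and labels."""

    pair_id: str
    t0: float
    dt: float
    t_idx: np.ndarray  # integer sample indices (shared with the maps)
    tau_steps: np.ndarray  # integer delay per time step
    kind: np.ndarray  # int8 per time step: 0 none, 1 coordinated, 2 chase
    score: float
    n_changes: int = 0
    tau_lo_steps: np.ndarray | None = None
    tau_hi_steps: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau_lo_steps is None:
            self.tau_lo_steps = self.tau_steps.copy()
        if self.tau_hi_steps is None:
            self.tau_hi_steps = self.tau_steps.copy()

    @property
    def t_values(self) -> np.ndarray:
        return self.t0 + self.dt * self.t_idx

    @property
    def tau(self) -> np.ndarray:
        return self.dt * self.tau_steps

    @property
    def tau_lo(self) -> np.ndarray:
        return self.dt * self.tau_lo_steps

    @property
    def tau_hi(self) -> np.ndarray:
        return self.dt * self.tau_hi_steps

    @property
    def segment_kind(self) -> np.ndarray:
        return _KIND_NAMES[self.kind]

    @property
    def n_classified(self) -> int:
        return int(np.count_nonzero(self.kind))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t_values,
                "tau": self.tau,
                "tau_lo": self.tau_lo,
                "tau_hi": self.tau_hi,
                "kind": self.segment_kind,
            }
        )


def _scored_mask(values: np.ndarray, v_c: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return values >= v_c


def _run_dp(con_same, con_change, allowed, tau_idx):
    tau_abs = np.abs(tau_idx).astype(float)
    cols, score, n_changes = best_path(
        np.ascontiguousarray(con_same, dtype=float),
        np.ascontiguousarray(con_change, dtype=float),
        np.ascontiguousarray(allowed, dtype=np.bool_),
        tau_abs,
    )
    return cols, score, int(n_changes)


def extract_coordinated_path(
    c_map: DelayMap, cfg: ExtractionConfig, anchor: InteractionPath | None = None
) -> InteractionPath:
    """Maximum-correlation time-ordered path through the TDDC map.

    If ``anchor`` (a chase path) is given, the returned path coincides with it
    on every chase-labelled sample; those samples keep the chase label.
    """
    if c_map.kind != "correlation":
        raise ValueError("extract_coordinated_path requires a correlation map")
    vals = c_map.values
    scored = _scored_mask(vals, cfg.v_c)
    con_same = np.where(scored, vals, 0.0)
    con_change = np.where(scored, vals - cfg.q, 0.0)
    allowed = np.ones(vals.shape, dtype=bool)
    if anchor is not None:
        if not np.array_equal(anchor.t_idx, c_map.t_idx):
            raise ValueError("anchor path and map do not share a time lattice")
        for n in np.flatnonzero(anchor.kind == KIND_CHASE):
            j = int(anchor.tau_steps[n] - c_map.tau_idx[0])
            allowed[n, :] = False
            allowed[n, j] = True
    cols, _, n_changes = _run_dp(con_same, con_change, allowed, c_map.tau_idx)
    tau_steps = c_map.tau_idx[cols]
    on_path_scored = scored[np.arange(len(cols)), cols]
    kind = np.where(on_path_scored, KIND_COORDINATED, KIND_NONE).astype(np.int8)
    if anchor is not None:
        kind[anchor.kind == KIND_CHASE] = KIND_CHASE
    # Eq.-style score: correlation summed over scored cells, minus q per change
    score = float(np.sum(vals[np.arange(len(cols)), cols][on_path_scored]))
    changed = np.zeros(len(cols), dtype=bool)
    changed[1:] = np.diff(tau_steps) != 0
    score -= cfg.q * float(np.count_nonzero(changed & on_path_scored))
    return InteractionPath(
        pair_id=c_map.pair_id,
        t0=c_map.t0,
        dt=c_map.dt,
        t_idx=c_map.t_idx.copy(),
        tau_steps=tau_steps.astype(np.int64),
        kind=kind,
        score=score,
        n_changes=n_changes,
    )


def extract_chase_path(
    c_map: DelayMap, r_map: DelayMap, cfg: ExtractionConfig
) -> InteractionPath:
    """Minimum delayed-separation time-ordered path over chase-qualifying cells.

    Qualifying cells satisfy C >= v_c and R <= d_c.  The path maximises the
    number of qualifying cells visited and, among such paths, minimises the
    cumulative delayed separation with the change penalty q.  With no
    qualifying cells an empty path (all labels "none") is returned.
    """
    if r_map.kind != "separation":
        raise ValueError("extract_chase_path requires a separation map")
    if not (
        np.array_equal(c_map.t_idx, r_map.t_idx)
        and np.array_equal(c_map.tau_idx, r_map.tau_idx)
    ):
        raise ValueError("correlation and separation maps do not share a lattice")
    with np.errstate(invalid="ignore"):
        qual = (c_map.values >= cfg.v_c) & (r_map.values <= cfg.d_c)
    empty = InteractionPath(
        pair_id=c_map.pair_id,
        t0=c_map.t0,
        dt=c_map.dt,
        t_idx=c_map.t_idx.copy(),
        tau_steps=np.zeros(len(c_map.t_idx), dtype=np.int64),
        kind=np.zeros(len(c_map.t_idx), dtype=np.int8),
        score=0.0,
    )
    if not qual.any():
        return empty
    r = np.where(np.isfinite(r_map.values), r_map.values, 0.0)
    con_same = np.where(qual, _CHASE_BONUS - r, 0.0)
    con_change = np.where(qual, _CHASE_BONUS - r - cfg.q, 0.0)
    allowed = np.ones(qual.shape, dtype=bool)
    cols, _, n_changes = _run_dp(con_same, con_change, allowed, c_map.tau_idx)
    rows = np.arange(len(cols))
    on_chase = qual[rows, cols]
    kind = np.where(on_chase, KIND_CHASE, KIND_NONE).astype(np.int8)
    score = float(np.sum(r_map.values[rows, cols][on_chase]))
    return InteractionPath(
        pair_id=c_map.pair_id,
        t0=c_map.t0,
        dt=c_map.dt,
        t_idx=c_map.t_idx.copy(),
        tau_steps=c_map.tau_idx[cols].astype(np.int64),
        kind=kind,
        score=score,
        n_changes=n_changes,
    )


def _contiguous_interval(mask_row: np.ndarray, j: int) -> tuple[int, int]:
    """Bounds (inclusive column indices) of the True run of ``mask_row`` containing j."""
    lo = j
    while lo > 0 and mask_row[lo - 1]:
        lo -= 1
    hi = j
    while hi < len(mask_row) - 1 and mask_row[hi + 1]:
        hi += 1
    return lo, hi


def delay_uncertainty(
    c_map: DelayMap,
    path: InteractionPath,
    cfg: ExtractionConfig,
    r_map: DelayMap | None = None,
) -> InteractionPath:
    """Fill asymmetric delay bounds tau_lo/tau_hi on a copy of ``path``.

    Coordinated samples: the contiguous super-threshold tau interval
    containing the path, tightened by slope −1 lines propagated forward from
    per-time minima and backward from per-time maxima.  Chase samples: the
    (small) contiguous tau window with C >= v_c and R <= d_c.  Unclassified
    samples keep degenerate bounds equal to the extracted delay.
    """
    scored = _scored_mask(c_map.values, cfg.v_c)
    qual = None
    if r_map is not None:
        with np.errstate(invalid="ignore"):
            qual = scored & (r_map.values <= cfg.d_c)
    T = len(path.t_idx)
    lo = np.full(T, np.iinfo(np.int64).min, dtype=np.int64)
    hi = np.full(T, np.iinfo(np.int64).min, dtype=np.int64)
    defined = np.zeros(T, dtype=bool)
    cols = (path.tau_steps - c_map.tau_idx[0]).astype(np.int64)
    for n in range(T):
        k = path.kind[n]
        if k == KIND_NONE:
            continue
        if k == KIND_CHASE:
            if qual is None:
                raise ValueError("chase samples present: delay_uncertainty needs the r_map")
            row = qual[n]
        else:
            row = scored[n]
        if not row[cols[n]]:
            continue
        a, b = _contiguous_interval(row, int(cols[n]))
        lo[n], hi[n] = a, b
        defined[n] = True

    # slope −1 propagation: lower bounds forward, upper bounds backward
    lo_t = lo.astype(float)
    hi_t = hi.astype(float)
    run = -np.inf
    for n in range(T):
        run -= 1.0
        if defined[n]:
            if lo_t[n] > run:
                run = lo_t[n]
            else:
                lo_t[n] = run
    run = np.inf
    for n in range(T - 1, -1, -1):
        run += 1.0
        if defined[n]:
            if hi_t[n] < run:
                run = hi_t[n]
            else:
                hi_t[n] = run

    out = InteractionPath(
        pair_id=path.pair_id,
        t0=path.t0,
        dt=path.dt,
        t_idx=path.t_idx.copy(),
        tau_steps=path.tau_steps.copy(),
        kind=path.kind.copy(),
        score=path.score,
        n_changes=path.n_changes,
    )
    out.tau_lo_steps = path.tau_steps.copy()
    out.tau_hi_steps = path.tau_steps.copy()
    sel = defined
    out.tau_lo_steps[sel] = c_map.tau_idx[0] + lo_t[sel].astype(np.int64)
    out.tau_hi_steps[sel] = c_map.tau_idx[0] + hi_t[sel].astype(np.int64)
    return out
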