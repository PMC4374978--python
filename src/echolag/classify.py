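"""Behaviour segmentation of bat pairs and actor–reactor role assignment.

Each time sample of a pair is labelled unclassified, coordinated or chase by
running the full chain: delay maps -> chase path -> coordinated path anchored
to it -> delay uncertainty.  The sign of the extracted delay assigns roles:
tau > 0 means bat j copies bat i's past headings, so i is the actor; tau < 0
swaps the roles; tau = 0 leaves the roles unresolved.  Chase takes precedence
over coordinated where both apply (chases are a sub-category of coordinated
flight: every chase sample also satisfies the correlation criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .delay_maps import DelayMap, tddc, tdds
from .extraction import (
    KIND_CHASE,
    KIND_COORDINATED,
    KIND_NONE,
    ExtractionConfig,
    InteractionPath,
    delay_uncertainty,
    extract_chase_path,
    extract_coordinated_path,
)
from .sound_field import SonarParams, max_range
from .trajectories import PairedTrajectory, Trajectory

__all__ = [
    "ClassifiedPair",
    "classify",
    "sensitivity_sweep",
    "randomized_pairing_null",
]


@dataclass
class ClassifiedPair:
    """Per-time behaviour labels, roles and delays for one pair."""

    pair_id: str
    pair: PairedTrajectory  # with kinematics filled
    c_map: DelayMap
    r_map: DelayMap
    path: InteractionPath  # merged (chase takes precedence), with bounds
    flagged_out_of_range: bool = False

    @property
    def t_idx(self) -> np.ndarray:
        return self.path.t_idx

    @property
    def labels(self) -> np.ndarray:
        return self.path.segment_kind

    @property
    def tau(self) -> np.ndarray:
        """Extracted delay (s); NaN on unclassified samples."""
        tau = self.path.tau.astype(float).copy()
        tau[self.path.kind == KIND_NONE] = np.nan
        return tau

    def roles(self) -> tuple[np.ndarray, np.ndarray]:
        """(actor, reactor) id per sample; None when unclassified or tau = 0."""
        n = len(self.path.t_idx)
        actor = np.full(n, None, dtype=object)
        reactor = np.full(n, None, dtype=object)
        a_id, b_id = self.pair.a.bat_id, self.pair.b.bat_id
        classified = self.path.kind != KIND_NONE
        pos = classified & (self.path.tau_steps > 0)
        neg = classified & (self.path.tau_steps < 0)
        actor[pos], reactor[pos] = a_id, b_id
        actor[neg], reactor[neg] = b_id, a_id
        return actor, reactor

    def summary(self) -> dict:
        kind = self.path.kind
        n = len(kind)
        return {
            "pair_id": self.pair_id,
            "n_samples": int(n),
            "fraction_unclassified": float(np.mean(kind == KIND_NONE)),
            "fraction_coordinated": float(np.mean(kind == KIND_COORDINATED)),
            "fraction_chase": float(np.mean(kind == KIND_CHASE)),
            "fraction_interacting": float(np.mean(kind != KIND_NONE)),
            "flagged_out_of_range": bool(self.flagged_out_of_range),
        }

    def to_frame(self) -> pd.DataFrame:
        actor, reactor = self.roles()
        tau = self.tau
        lo = self.path.tau_lo.astype(float).copy()
        hi = self.path.tau_hi.astype(float).copy()
        lo[np.isnan(tau)] = np.nan
        hi[np.isnan(tau)] = np.nan
        return pd.DataFrame(
            {
                "t": self.path.t_values,
                "label": self.labels,
                "actor": actor,
                "reactor": reactor,
                "tau": tau,
                "tau_lo": lo,
                "tau_hi": hi,
            }
        )


def _classify_from_maps(
    pair: PairedTrajectory, c_map: DelayMap, r_map: DelayMap, cfg: ExtractionConfig
) -> InteractionPath:
    chase = extract_chase_path(c_map, r_map, cfg)
    anchor = chase if np.any(chase.kind == KIND_CHASE) else None
    coord = extract_coordinated_path(c_map, cfg, anchor=anchor)
    return delay_uncertainty(c_map, coord, cfg, r_map=r_map)


def classify(
    pair: PairedTrajectory,
    cfg: ExtractionConfig | None = None,
    sonar: SonarParams | None = None,
) -> ClassifiedPair:
    """Run the full classification chain on one pair.

    ``sonar`` is only used to flag pairs whose members never come within the
    0 dB echo range of each other (candidate outliers); flagged pairs are not
    discarded here.
    """
    cfg = cfg or ExtractionConfig()
    pk = pair.with_kinematics(cfg.w)
    c_map = tddc(pk, cfg.w)
    r_map = tdds(pk, cfg.w)
    if not np.isfinite(c_map.values).any():
        warnings.warn(
            f"pair {pair.pair_id!r}: delay map entirely undefined; all samples unclassified",
            stacklevel=2,
        )
        path = InteractionPath(
            pair_id=pair.pair_id,
            t0=c_map.t0,
            dt=c_map.dt,
            t_idx=c_map.t_idx.copy(),
            tau_steps=np.zeros(len(c_map.t_idx), dtype=np.int64),
            kind=np.zeros(len(c_map.t_idx), dtype=np.int8),
            score=0.0,
        )
    else:
        path = _classify_from_maps(pk, c_map, r_map, cfg)
    sonar = sonar or SonarParams()
    sep = np.hypot(
        *(pk.a.positions - pk.b.positions).T
    )
    flagged = bool(np.nanmin(sep) > max_range(sonar, level=0.0))
    return ClassifiedPair(
        pair_id=pair.pair_id,
        pair=pk,
        c_map=c_map,
        r_map=r_map,
        path=path,
        flagged_out_of_range=flagged,
    )


def sensitivity_sweep(
    pairs: list[PairedTrajectory],
    v_c_values,
    cfg: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Interacting fraction per pair for each correlation threshold.

    The delay maps are computed once per pair and re-thresholded, mirroring
    how the threshold choice is audited: a stricter v_c can only shrink the
    super-threshold region, so the interacting fraction is non-increasing.
    Returns a tidy frame (pair_id, v_c, fraction_interacting) plus pooled rows
    with pair_id "pooled".
    """
    cfg = cfg or ExtractionConfig()
    if not pairs:
        raise ValueError("sensitivity_sweep needs at least one pair")
    rows = []
    pooled: dict[float, list[float]] = {float(v): [0, 0] for v in v_c_values}
    for pair in pairs:
        pk = pair.with_kinematics(cfg.w)
        c_map = tddc(pk, cfg.w)
        r_map = tdds(pk, cfg.w)
        for v_c in v_c_values:
            cfg_v = ExtractionConfig(v_c=float(v_c), d_c=cfg.d_c, q=cfg.q, w=cfg.w)
            path = _classify_from_maps(pk, c_map, r_map, cfg_v)
            frac = float(np.mean(path.kind != KIND_NONE))
            rows.append(
                {"pair_id": pair.pair_id, "v_c": float(v_c), "fraction_interacting": frac}
            )
            pooled[float(v_c)][0] += path.n_classified
            pooled[float(v_c)][1] += len(path.kind)
    for v_c, (k, n) in pooled.items():
        rows.append(
            {"pair_id": "pooled", "v_c": v_c, "fraction_interacting": k / n if n else np.nan}
        )
    return pd.DataFrame(rows)


def randomized_pairing_null(
    trajectories: list[Trajectory],
    n_draws: int,
    seed: int | np.random.Generator,
    bin_edges: np.ndarray,
) -> np.ndarray:
    """Null separation histogram from randomised re-pairing of trajectories.

    Draws ``n_draws`` pairs of distinct trajectories uniformly at random,
    aligns their time grids at a common origin, and accumulates same-time
    separations into ``bin_edges``.  Returns the bin counts.
    """
    if len(trajectories) < 2:
        raise ValueError("randomized pairing needs at least two trajectories")
    dts = {round(tr.dt, 12) for tr in trajectories}
    if len(dts) != 1:
        raise ValueError("trajectories must share a sampling interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.zeros(len(bin_edges) - 1, dtype=float)
    for _ in range(int(n_draws)):
        i, j = rng.choice(len(trajectories), size=2, replace=False)
        a, b = trajectories[i], trajectories[j]
        n = min(len(a), len(b))
        if n == 0:
            raise ValueError("trajectories have no overlapping samples")
        d = np.hypot(*(a.positions[:n] - b.positions[:n]).T)
        h, _ = np.histogram(d, bins=bin_edges)
        counts += h
    return counts
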