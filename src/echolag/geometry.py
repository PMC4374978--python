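"""Reactor-centred relative geometry of co-flying pairs.

Each labelled time sample yields a relative sample: the actor's same-time
position expressed in the reactor's frame (reactor at the origin, heading
along +y), the separation distance d, the relative heading phi_rel (angular
difference of the two velocity vectors) and the exposure angle theta_exp (the
signed angular position of the actor with respect to the reactor's heading,
zero straight ahead, pi directly behind).  The extracted delay enters only
through the role assignment; the geometry itself is instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import KIND_NONE
from .trajectories import PairedTrajectory, wrap_angle

__all__ = ["RelativeSample", "relative_sample", "collect_samples", "histogram_set"]


@dataclass
class RelativeSample:
    """Geometry of one (actor, reactor) pair at one time sample."""

    pair_id: str
    t: float
    label: str
    d: float  # separation (m)
    phi_rel: float  # relative heading (rad, (-pi, pi])
    theta_exp: float  # exposure angle (rad, (-pi, pi])
    rel_x: float  # actor position in the reactor frame (m)
    rel_y: float


def _to_frame(delta: np.ndarray, reactor_heading: float) -> tuple[float, float]:
    """World-frame offset -> reactor frame with heading along +y."""
    h = reactor_heading
    rel_x = delta[0] * np.sin(h) - delta[1] * np.cos(h)
    rel_y = delta[0] * np.cos(h) + delta[1] * np.sin(h)
    return float(rel_x), float(rel_y)


def relative_sample(
    pair: PairedTrajectory,
    t_index: int,
    actor_id: str,
    label: str = "unclassified",
) -> RelativeSample | None:
    """Relative sample at trajectory index ``t_index`` with the given actor.

    The other member of the pair is the reactor.  Returns None when either
    heading is undefined at that sample.
    """
    if pair.a.bat_id == actor_id:
        actor, reactor = pair.a, pair.b
    elif pair.b.bat_id == actor_id:
        actor, reactor = pair.b, pair.a
    else:
        raise ValueError(f"unknown actor id {actor_id!r} for pair {pair.pair_id!r}")
    if actor.headings is None or reactor.headings is None:
        raise ValueError("relative_sample requires kinematics; call with_kinematics first")
    ha = actor.headings[t_index]
    hr = reactor.headings[t_index]
    if not (np.isfinite(ha) and np.isfinite(hr)):
        return None
    delta = actor.positions[t_index] - reactor.positions[t_index]
    rel_x, rel_y = _to_frame(delta, float(hr))
    return RelativeSample(
        pair_id=pair.pair_id,
        t=float(pair.t0 + pair.dt * t_index),
        label=label,
        d=float(np.hypot(rel_x, rel_y)),
        phi_rel=float(wrap_angle(ha - hr)),
        theta_exp=float(np.arctan2(rel_x, rel_y)) if (rel_x, rel_y) != (0.0, 0.0) else 0.0,
        rel_x=rel_x,
        rel_y=rel_y,
    )


def collect_samples(classified_pairs, rng=None) -> pd.DataFrame:
    """Relative samples for every map time sample of every classified pair.

    Labelled samples use the extracted actor/reactor roles; unclassified
    samples (and classified samples with unresolved roles at tau = 0) centre a
    randomly picked member of the pair, drawn once per pair with ``rng``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    records = []
    for cp in classified_pairs:
        actor, _ = cp.roles()
        labels = cp.labels
        random_actor = cp.pair.a.bat_id if rng.random() < 0.5 else cp.pair.b.bat_id
        for n, t_index in enumerate(cp.t_idx):
            a_id = actor[n]
            label = labels[n]
            if a_id is None:
                a_id = random_actor
                if cp.path.kind[n] == KIND_NONE:
                    label = "unclassified"
            rs = relative_sample(cp.pair, int(t_index), a_id, label=label)
            if rs is not None:
                records.append(rs.__dict__)
    return pd.DataFrame.from_records(records)


def histogram_set(
    samples: pd.DataFrame,
    d_bins: np.ndarray | int = 20,
    angle_bins: int = 18,
) -> dict:
    """Normalised histograms of d, |phi_rel| and theta_exp per label.

    Angular histograms span the wrapped ranges ([0, pi] for the folded
    relative heading, (-pi, pi] for the exposure angle).  Each histogram's bar
    masses sum to one within its label.
    """
    if samples.empty:
        raise ValueError("histogram_set needs a nonempty sample set")
    if isinstance(d_bins, int):
        d_bins = np.linspace(0.0, float(samples["d"].max()) or 1.0, d_bins + 1)
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for label, grp in samples.groupby("label"):
        n = len(grp)
        hists = {}
        h, e = np.histogram(grp["d"], bins=d_bins)
        hists["d"] = (h / n, e)
        h, e = np.histogram(np.abs(grp["phi_rel"]), bins=angle_bins, range=(0.0, np.pi))
        hists["abs_phi_rel"] = (h / n, e)
        h, e = np.histogram(grp["theta_exp"], bins=angle_bins, range=(-np.pi, np.pi))
        hists["theta_exp"] = (h / n, e)
        out[str(label)] = hists
    return out


def plot_relative_positions(samples: pd.DataFrame, sonar=None, levels=(-40, -20, 0, 10), ax=None):
    """Scatter of actor positions in the reactor frame with optional sound-field contours."""
    import matplotlib.pyplot as plt

    from .sound_field import isocontour

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    colors = {"chase": "tab:blue", "coordinated": "tab:green", "unclassified": "0.6"}
    for label, grp in samples.groupby("label"):
        ax.scatter(
            grp["rel_x"], grp["rel_y"], s=4, alpha=0.5,
            color=colors.get(str(label), "k"), label=str(label),
        )
    if sonar is not None:
        for level in levels:
            poly = isocontour(sonar, level)
            ax.plot(poly[:, 0], poly[:, 1], color="tab:red", lw=0.8)
    ax.set_xlabel("x rel. to reactor (m)")
    ax.set_ylabel("y rel. to reactor (m)")
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    return ax
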