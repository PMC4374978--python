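"""Agent-based biosonar movement-interaction simulator for bat pairs.

Two bats perform correlated random walks in continuous 2-D space and discrete
20 ms time.  Per step each bat draws its speed from a Rician distribution,
chooses a desired heading from a von Mises distribution — centred on its own
previous heading when independent (kappa = 557), or on the circular midpoint
of its previous heading and the partner heading a reaction delay tau in the
past when interacting (kappa = 2473) — and turns towards it no faster than
the aerodynamic limit a_c / v per unit time (maximum lateral acceleration of
4 g).  Every five steps (100 ms) both bats echolocate along their headings; a
conspecific whose returning echo reaches the hearing threshold B triggers the
interacting state from one reaction delay later, a missed detection restores
independence, and an interacting bat may spontaneously escape to independence
with probability 0.05 per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sound_field import SonarParams, echo_amplitude
from .trajectories import PairedTrajectory, Trajectory, wrap_angle

__all__ = [
    "SimConfig",
    "BatState",
    "draw_speed",
    "desired_heading_independent",
    "desired_heading_interacting",
    "circular_midpoint",
    "turn_clamp",
    "escape_update",
    "emit_calls",
    "echolocation_update",
    "step",
    "simulate_pair",
    "simulate_ensemble",
]

G = 9.81


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the observed/fitted values."""

    dt: float = 0.02
    duration: float = 10.0
    call_interval_steps: int = 5  # one call every 100 ms
    kappa_indep: float = 557.0
    kappa_inter: float = 2473.0
    rician_nu: float = 4.81  # m/s, non-centrality of the speed distribution
    rician_sigma: float = 2.18  # m/s, scale of the speed distribution
    a_c: float = 4.0 * G  # m/s^2, maximum lateral acceleration
    escape_prob: float = 0.05  # per 20 ms step
    tau: float = 0.3  # s, reaction delay (multiple of dt)
    arena: float = 30.0  # m, side of the initial-placement square
    sonar: SonarParams = field(default_factory=SonarParams)

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("reaction delay tau must be >= 0")
        steps = self.tau / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError(f"tau={self.tau} must be a multiple of dt={self.dt}")
        if not 0.0 <= self.escape_prob <= 1.0:
            raise ValueError("escape_prob must be in [0, 1]")

    @property
    def tau_steps(self) -> int:
        return int(round(self.tau / self.dt))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class BatState:
    """Mutable per-bat state during a simulation run."""

    position: np.ndarray  # (2,)
    heading: float
    speed: float = 0.0
    interacting: bool = False
    partner_heading_lagged: float = 0.0  # partner heading stored at the effective call
    # per-call history: (step index, detected, partner heading at that call)
    call_steps: list = field(default_factory=list)
    call_detected: list = field(default_factory=list)
    call_partner_heading: list = field(default_factory=list)


def draw_speed(cfg: SimConfig, rng: np.random.Generator) -> float:
    """Rician speed draw via the norm of a bivariate normal offset by (nu, 0)."""
    return float(
        np.hypot(
            rng.normal(cfg.rician_nu, cfg.rician_sigma),
            rng.normal(0.0, cfg.rician_sigma),
        )
    )


def circular_midpoint(a: float, b: float) -> float:
    """Shortest-arc midpoint of two angles (unit-vector mean direction)."""
    sx = np.cos(a) + np.cos(b)
    sy = np.sin(a) + np.sin(b)
    if abs(sx) < 1e-12 and abs(sy) < 1e-12:
        # antipodal headings: midpoint ill-defined, pick a + pi/2 deterministically
        return float(wrap_angle(a + 0.5 * np.pi))
    return float(np.arctan2(sy, sx))


def desired_heading_independent(state: BatState, cfg: SimConfig, rng) -> float:
    """Von Mises draw centred on the bat's previous heading (broad turning)."""
    return float(wrap_angle(rng.vonmises(state.heading, cfg.kappa_indep)))


def desired_heading_interacting(
    state: BatState, partner_heading_lagged: float, cfg: SimConfig, rng
) -> float:
    """Von Mises draw centred midway between own heading and the lagged partner heading."""
    centre = circular_midpoint(state.heading, partner_heading_lagged)
    return float(wrap_angle(rng.vonmises(centre, cfg.kappa_inter)))


def turn_clamp(heading_prev: float, gamma: float, v: float, cfg: SimConfig) -> float:
    """New heading after clamping the desired turn to the aerodynamic limit."""
    beta_dt = cfg.a_c / v * cfg.dt
    d = wrap_angle(gamma - heading_prev)
    if abs(d) <= beta_dt:
        return float(wrap_angle(gamma))
    return float(wrap_angle(heading_prev + np.sign(d) * beta_dt))


def escape_update(state: BatState, cfg: SimConfig, rng) -> BatState:
    """Interacting bats spontaneously revert to independence with escape_prob."""
    if state.interacting and rng.random() < cfg.escape_prob:
        state.interacting = False
    return state


def emit_calls(states: tuple[BatState, BatState], cfg: SimConfig, n: int) -> None:
    """At a call step, both bats echolocate along their headings.

    Each bat evaluates the echo returning from its partner at the current
    range and off-axis angle and records the outcome together with the
    partner's current heading (the information a positive detection delivers).
    """
    if n % cfg.call_interval_steps != 0:
        return
    a, b = states
    d = float(np.hypot(*(b.position - a.position)))
    for me, other in ((a, b), (b, a)):
        bearing = np.arctan2(
            other.position[1] - me.position[1], other.position[0] - me.position[0]
        )
        zeta = abs(wrap_angle(bearing - me.heading))
        det = echo_amplitude(cfg.sonar, max(d, 1e-9), zeta) >= cfg.sonar.B
        me.call_steps.append(n)
        me.call_detected.append(bool(det))
        me.call_partner_heading.append(other.heading)


def echolocation_update(
    states: tuple[BatState, BatState], cfg: SimConfig, n: int
) -> tuple[BatState, BatState]:
    """Apply the call outcome whose delayed effect lands at step ``n``.

    The call emitted at step c takes effect at step c + tau/dt (at least one
    step after emission): a positive detection puts the bat in the
    interacting state, storing that call's partner heading, a negative one
    makes it independent.  Between effective calls the last outcome persists.
    """
    lag = max(cfg.tau_steps, 1)  # information can act at the earliest one step later
    eff = n - lag
    if eff >= 0 and eff % cfg.call_interval_steps == 0:
        k = eff // cfg.call_interval_steps
        for me in states:
            if k < len(me.call_steps):
                me.interacting = me.call_detected[k]
                me.partner_heading_lagged = me.call_partner_heading[k]
    return states


def step(
    states: tuple[BatState, BatState], cfg: SimConfig, rng: np.random.Generator, n: int
) -> tuple[BatState, BatState]:
    """Advance both bats by one time step.

    Order within the step: delayed call outcomes land, interacting bats may
    escape, both bats move, then (on the call schedule) both echolocate from
    their new positions.
    """
    states = echolocation_update(states, cfg, n)
    for me in states:
        me = escape_update(me, cfg, rng)
        if me.interacting:
            gamma = desired_heading_interacting(me, me.partner_heading_lagged, cfg, rng)
        else:
            gamma = desired_heading_independent(me, cfg, rng)
        v = draw_speed(cfg, rng)
        me.heading = turn_clamp(me.heading, gamma, v, cfg)
        me.speed = v
        me.position = me.position + v * cfg.dt * np.array(
            [np.cos(me.heading), np.sin(me.heading)]
        )
    emit_calls(states, cfg, n)
    return states


def simulate_pair(
    cfg: SimConfig, rng: np.random.Generator, pair_id: str = "sim"
) -> tuple[PairedTrajectory, dict]:
    """Simulate one pair; returns the trajectories and a per-step state log."""
    n_steps = cfg.n_steps
    states = tuple(
        BatState(
            position=rng.uniform(0.0, cfg.arena, size=2),
            heading=float(rng.uniform(-np.pi, np.pi)),
        )
        for _ in range(2)
    )
    pos = np.empty((n_steps, 2, 2))
    interacting = np.zeros((n_steps, 2), dtype=bool)
    speeds = np.full((n_steps, 2), np.nan)
    headings = np.full((n_steps, 2), np.nan)
    pos[0, 0], pos[0, 1] = states[0].position, states[1].position
    headings[0] = [states[0].heading, states[1].heading]
    emit_calls(states, cfg, 0)
    for n in range(1, n_steps):
        states = step(states, cfg, rng, n)
        for i, s in enumerate(states):
            pos[n, i] = s.position
            interacting[n, i] = s.interacting
            speeds[n, i] = s.speed
            headings[n, i] = s.heading
    a = Trajectory(bat_id="1", t0=0.0, dt=cfg.dt, positions=pos[:, 0])
    b = Trajectory(bat_id="2", t0=0.0, dt=cfg.dt, positions=pos[:, 1])
    log = {"interacting": interacting, "speeds": speeds, "headings": headings}
    return PairedTrajectory(pair_id, a, b), log


def simulate_ensemble(
    cfg: SimConfig, n_pairs: int, seed: int | np.random.SeedSequence
) -> tuple[list[PairedTrajectory], list[dict]]:
    """Independent replicate pairs with per-pair RNG substreams.

    Substreams are spawned from the seed so that increasing ``n_pairs`` adds
    pairs without perturbing earlier ones; the same seed reproduces the
    ensemble bit for bit.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pairs = []
    logs = []
    for k, child in enumerate(ss.spawn(n_pairs)):
        pair, log = simulate_pair(cfg, np.random.default_rng(child), pair_id=f"sim{k:04d}")
        pairs.append(pair)
        logs.append(log)
    return pairs, logs
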