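"""Time integration of the velocity Langevin dynamics.

Each cell's velocity obeys

    dv_i/dt = −α v_i + β Σ_{j∈N(i)} (v_j − v_i) + Σ_{j∈N(i)} f(x_j − x_i) + σ_i η_i

with N(i) the sector neighbors, f the central pair force and η_i a
two-component Ornstein–Uhlenbeck process of correlation time τ and unit
stationary variance per component. Positions follow overdamped kinematics
x ← x + v·dt. Integration is explicit Euler for v and x with an exact
(stationarity-preserving) OU sub-step for η.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .forces import pair_force
from .geometry import Box, hex_lattice
from .neighbors import NeighborGraph, find_neighbors, local_density

KIND_BULK = 0
KIND_LEADER = 1


@dataclass
class ParticleState:
    """Vectorized per-cell state."""

    ids: np.ndarray        # (N,) int
    pos: np.ndarray        # (N, 2) µm
    vel: np.ndarray        # (N, 2) µm/h
    eta: np.ndarray        # (N, 2) OU state, dimensionless
    kind: np.ndarray       # (N,) KIND_BULK | KIND_LEADER
    leader_v: np.ndarray   # (N, 2) µm/h, nan for non-leaders
    alive: np.ndarray      # (N,) bool

    @classmethod
    def make(cls, pos: np.ndarray, rng: np.random.Generator | None = None):
        n = len(pos)
        eta = rng.standard_normal((n, 2)) if rng is not None else np.zeros((n, 2))
        return cls(
            ids=np.arange(n),
            pos=np.asarray(pos, dtype=float).copy(),
            vel=np.zeros((n, 2)),
            eta=eta,
            kind=np.zeros(n, dtype=np.int8),
            leader_v=np.full((n, 2), np.nan),
            alive=np.ones(n, dtype=bool),
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_leader(self) -> np.ndarray:
        return self.kind == KIND_LEADER


@dataclass
class Trajectory:
    """Snapshots of a run: times plus per-snapshot state arrays."""

    times: np.ndarray                 # (T,) h, strictly increasing
    positions: list = field(default_factory=list)   # (N_t, 2) per snapshot
    velocities: list = field(default_factory=list)
    ids: list = field(default_factory=list)
    kinds: list = field(default_factory=list)
    config: SimConfig | None = None
    seed: int | None = None

    @property
    def n_snapshots(self) -> int:
        return len(self.times)


def ou_step(eta: np.ndarray, dt: float, tau: float,
            rng: np.random.Generator) -> np.ndarray:
    """Exact OU update preserving the unit stationary variance."""
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be positive")
    decay = np.exp(-dt / tau)
    return eta * decay + np.sqrt(1.0 - decay ** 2) * rng.standard_normal(eta.shape)


def noise_amplitude(d: np.ndarray, config: SimConfig) -> np.ndarray:
    """σ_i: constant, or increasing linearly as density falls below d0."""
    d = np.asarray(d, dtype=float)
    if not config.density_noise:
        return np.full_like(d, config.sigma0)
    return config.sigma0 * (1.0 + config.kappa * np.maximum(0.0, 1.0 - d / config.d0))


def velocity_step(state: ParticleState, graph: NeighborGraph,
                  config: SimConfig, dt: float,
                  sigma: np.ndarray | None = None,
                  extra_force: np.ndarray | None = None) -> None:
    """One explicit-Euler velocity update (in place). Leaders are skipped."""
    n = state.n
    src, dst, vec, _ = graph.edges()
    align = np.zeros((n, 2))
    np.add.at(align, src, state.vel[dst])
    deg = np.bincount(src, minlength=n).astype(float)
    align -= deg[:, None] * state.vel
    if config.align_mean:
        align /= np.maximum(deg, 1.0)[:, None]
    F = np.zeros((n, 2))
    if config.potential.A_rep > 0 or config.potential.A_att > 0:
        np.add.at(F, src, pair_force(vec, config.potential))
    if extra_force is not None:
        F += extra_force
    if sigma is None:
        sigma = np.full(n, config.sigma0)
    dv = dt * (-config.alpha * state.vel + config.beta * align + F
               + sigma[:, None] * state.eta)
    leaders = state.is_leader()
    dv[leaders] = 0.0
    state.vel += dv
    if not np.all(np.isfinite(state.vel)):
        raise RuntimeError(
            "non-finite velocity after step: integration unstable (dt too large)")


def position_step(state: ParticleState, dt: float, box: Box) -> None:
    """Overdamped kinematics with periodic wrapping."""
    state.pos += state.vel * dt
    state.pos = box.wrap(state.pos)


def simulate_bulk(config: SimConfig, n_particles: int, t_end: float,
                  snapshot_every: float = 0.1,
                  init_jitter: float = 1.0) -> Trajectory:
    """Bulk sheet in a periodic box: jittered hexagonal start, full update loop.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pos = hex_lattice(config.box, n_particles, rng=rng, jitter=init_jitter)
    state = ParticleState.make(pos, rng=rng)
    n_steps = int(round(t_end / config.dt))
    every = max(1, int(round(snapshot_every / config.dt)))
    times, P, V, I, K = [], [], [], [], []

    def record(t):
        times.append(t)
        P.append(state.pos.copy())
        V.append(state.vel.copy())
        I.append(state.ids.copy())
        K.append(state.kind.copy())

    graph = None
    record(0.0)
    for step in range(n_steps):
        if graph is None or step % config.graph_refresh_every == 0:
            graph = find_neighbors(state.pos, config.neighbor_cutoff, config.box,
                                   symmetrize=config.symmetrize_graph)
        d = local_density(graph)
        sigma = noise_amplitude(d, config)
        state.eta = ou_step(state.eta, config.dt, config.tau, rng)
        velocity_step(state, graph, config, config.dt, sigma=sigma)
        position_step(state, config.dt, config.box)
        if (step + 1) % every == 0:
            record((step + 1) * config.dt)

    traj = Trajectory(times=np.asarray(times), positions=P, velocities=V,
                      ids=I, kinds=K, config=config, seed=config.seed)
    return traj
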