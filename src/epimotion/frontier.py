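"""Band geometry with a free surface: leaders, surface damage, division, border.

The epithelium initially occupies a band x ∈ [−W, 0], periodic in y. The
unexplored surface (x > 0) is covered by a static grid of surface particles
that repel normal cells (gaussian kernel) and carry a scalar damage variable

    dw_s/dt = −w_s/τ_w + Σ_{cells within R} |f(cell on s)|

with removal once w_s reaches a threshold. Leader cells — created near the
border at a given rate per border length, with +x velocity of gaussian
modulus — damage surface particles with a much larger amplitude and feel no
surface force. A leader keeps its initial velocity while it has at least 4
neighbors; with fewer it takes the mean neighbor velocity (speed-capped).
Bulk cells divide with doubling time T_div, a division being rolled back if
it would raise the local density above the initial density d0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import BandParams, DivisionParams, LeaderParams, SimConfig, SurfaceParams
from .dynamics import (KIND_BULK, KIND_LEADER, ParticleState, noise_amplitude,
                       ou_step, position_step, velocity_step)
from .geometry import BAND, Box, hex_lattice
from .neighbors import NeighborGraph, find_neighbors, local_density

log = logging.getLogger(__name__)


@dataclass
class SurfaceField:
    """Static grid of surface particles with damage state."""

    pos: np.ndarray      # (M, 2) µm
    w: np.ndarray        # (M,) damage, µm·h⁻¹
    alive: np.ndarray    # (M,) bool
    params: SurfaceParams

    @classmethod
    def grid(cls, free_width_x: float, Ly: float, params: SurfaceParams):
        gs = params.grid_spacing
        nx = int(round(free_width_x / gs))
        ny = int(round(Ly / gs))
        xs = (np.arange(nx) + 0.5) * gs
        ys = (np.arange(ny) + 0.5) * gs
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pos = np.column_stack([X.ravel(), Y.ravel()])
        return cls(pos=pos, w=np.zeros(len(pos)), alive=np.ones(len(pos), bool),
                   params=params)


@dataclass
class LeaderEvent:
    t: float
    id: int
    x: float
    y: float
    speed: float


@dataclass
class BandResult:
    """Output of a band run: snapshots, border series and leader log."""

    times: np.ndarray
    positions: list
    velocities: list
    ids: list
    kinds: list
    border_times: np.ndarray        # per step
    border_mean: np.ndarray         # mean border position per step
    leader_log: list                # LeaderEvent
    surface: SurfaceField
    config: SimConfig | None = None
    band: BandParams | None = None
    n_cells: np.ndarray | None = None


def _cross_pairs(query_pos: np.ndarray, target_pos: np.ndarray, r: float,
                 box: Box):
    """Directed pairs (iq, it, vec, dist) with |vec| <= r, periodic-aware.

    ``vec`` points from the query point to the target point.
    """
    if len(query_pos) == 0 or len(target_pos) == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros((0, 2)), np.zeros(0)
    aug, srcmap = box.with_ghosts(box.wrap(target_pos), r)
    tree = cKDTree(aug)
    lists = tree.query_ball_point(box.wrap(query_pos), r)
    iq, it, vec = [], [], []
    wq = box.wrap(query_pos)
    for k, cand in enumerate(lists):
        if not cand:
            continue
        cand = np.asarray(cand, dtype=np.int64)
        iq.append(np.full(len(cand), k, dtype=np.int64))
        it.append(srcmap[cand])
        vec.append(aug[cand] - wq[k])
    if not iq:
        z = np.zeros(0, dtype=np.int64)
        return z, z, np.zeros((0, 2)), np.zeros(0)
    iq = np.concatenate(iq)
    it = np.concatenate(it)
    vec = np.concatenate(vec)
    return iq, it, vec, np.hypot(vec[:, 0], vec[:, 1])


def detect_border(positions: np.ndarray, Ly: float, band_width: float = 20.0,
                  alive: np.ndarray | None = None):
    """Border polyline: per y-band maximal x; empty bands linearly interpolated.

    Returns ``(band_centers, x_border, mean_x)``.
    """
    pos = np.asarray(positions, dtype=float)
    if alive is not None:
        pos = pos[alive]
    if len(pos) == 0:
        raise ValueError("no particles: border undefined")
    nb = max(1, int(round(Ly / band_width)))
    idx = np.clip((pos[:, 1] % Ly) / (Ly / nb), 0, nb - 1e-9).astype(int)
    xb = np.full(nb, -np.inf)
    np.maximum.at(xb, idx, pos[:, 0])
    centers = (np.arange(nb) + 0.5) * (Ly / nb)
    filled = np.isfinite(xb)
    if not filled.any():
        raise ValueError("all bands empty")
    if not filled.all():
        # periodic linear interpolation across empty bands
        xp = np.nonzero(filled)[0]
        xb[~filled] = np.interp(np.nonzero(~filled)[0], xp, xb[xp],
                                period=nb)
    return centers, xb, float(xb.mean())


def spawn_leaders(state: ParticleState, border, t: float, dt: float,
                  params: LeaderParams, box: Box,
                  rng: np.random.Generator,
                  log_events: list | None = None) -> int:
    """Poisson leader creation along the border. Returns number created."""
    centers, xb, _ = border
    rate = params.rate_early if t < params.switch_time else params.rate_late
    lam = rate * (box.Ly / 1000.0) * dt  # rate is per mm of border
    n_events = rng.poisson(lam)
    created = 0
    nb = len(centers)
    for _ in range(n_events):
        band_idx = np.clip((state.pos[:, 1] % box.Ly) / (box.Ly / nb),
                           0, nb - 1e-9).astype(int)
        near_border = state.pos[:, 0] >= xb[band_idx] - params.creation_depth
        eligible = state.alive & (state.kind == KIND_BULK) & near_border
        leaders = np.nonzero(state.alive & (state.kind == KIND_LEADER))[0]
        if len(leaders):
            dy = np.abs(state.pos[:, None, 1] - state.pos[None, leaders, 1])
            dy = np.minimum(dy, box.Ly - dy)
            eligible &= (dy >= params.exclusion_dy).all(axis=1)
        cand = np.nonzero(eligible)[0]
        if len(cand) == 0:
            log.info("leader creation event skipped: no eligible candidate")
            continue
        i = int(rng.choice(cand))
        speed = rng.normal(params.v_mean, params.v_sd)
        while speed <= 0.0:
            speed = rng.normal(params.v_mean, params.v_sd)
        state.kind[i] = KIND_LEADER
        state.leader_v[i] = (speed, 0.0)
        state.vel[i] = (speed, 0.0)
        created += 1
        if log_events is not None:
            log_events.append(LeaderEvent(t=t, id=int(state.ids[i]),
                                          x=float(state.pos[i, 0]),
                                          y=float(state.pos[i, 1]),
                                          speed=float(speed)))
    return created


def update_leader(state: ParticleState, graph: NeighborGraph,
                  params: LeaderParams) -> None:
    """Leader feedback: constant velocity with enough followers, else adapt."""
    leaders = np.nonzero(state.is_leader() & state.alive)[0]
    if len(leaders) == 0:
        return
    deg = graph.degree
    src, dst, _, _ = graph.edges()
    vsum = np.zeros((state.n, 2))
    np.add.at(vsum, src, state.vel[dst])
    for i in leaders:
        v0 = state.leader_v[i]
        cap = params.v_cap if params.v_cap is not None else float(np.hypot(*v0))
        if deg[i] >= params.min_followers:
            state.vel[i] = v0
        elif deg[i] >= 1:
            v = vsum[i] / deg[i]
            s = float(np.hypot(*v))
            if s > cap:
                v = v * (cap / s)
            state.vel[i] = v
        else:
            # neighborless leader: previous direction at the capped speed
            v = state.vel[i]
            s = float(np.hypot(*v))
            direction = v / s if s > 1e-12 else v0 / np.hypot(*v0)
            state.vel[i] = cap * direction
            log.info("leader %d has no neighbors; keeping previous direction",
                     int(state.ids[i]))


class _SurfaceCache:
    """Cell↔surface pair geometry, reused between neighbor-graph refreshes.

    Per-step displacements (≲0.1 µm) are far below the kernel widths
    (≥10 µm), so the pair list and distances are effectively constant over a
    refresh interval; only the surface alive mask changes step to step.
    """

    def __init__(self, state: ParticleState, surface: SurfaceField, box: Box):
        p = surface.params
        r = max(3.0 * p.r_surf, p.interaction_radius)
        alive_s = np.nonzero(surface.alive)[0]
        self.n_cells = state.n
        if len(alive_s) == 0:
            self.cell = np.zeros(0, dtype=np.int64)
            self.surf = np.zeros(0, dtype=np.int64)
            self.dist = np.zeros(0)
            self.unit = np.zeros((0, 2))
            return
        iq, it, vec, dist = _cross_pairs(state.pos, surface.pos[alive_s],
                                         r, box)
        self.cell = iq
        self.surf = alive_s[it]
        self.dist = dist
        with np.errstate(invalid="ignore", divide="ignore"):
            self.unit = vec / np.maximum(dist, 1e-12)[:, None]


def surface_force(state: ParticleState, surface: SurfaceField, box: Box,
                  cache: _SurfaceCache | None = None) -> np.ndarray:
    """Repulsion from alive surface particles on non-leader cells."""
    p = surface.params
    F = np.zeros((state.n, 2))
    if cache is None or cache.n_cells != state.n:
        cache = _SurfaceCache(state, surface, box)
    if len(cache.cell) == 0:
        return F
    m = (surface.alive[cache.surf] & (cache.dist <= 3.0 * p.r_surf)
         & ~state.is_leader()[cache.cell] & state.alive[cache.cell])
    if not m.any():
        return F
    mag = p.A_surf_normal * np.exp(-cache.dist[m] ** 2 / (2.0 * p.r_surf ** 2))
    # repulsion: away from the surface particle
    f = -mag[:, None] * cache.unit[m]
    np.add.at(F, cache.cell[m], f)
    return F


def damage_step(surface: SurfaceField, state: ParticleState, dt: float,
                box: Box, cache: _SurfaceCache | None = None) -> None:
    """Advance damage variables and remove particles past the threshold."""
    p = surface.params
    if not surface.alive.any():
        return
    if cache is None or cache.n_cells != state.n:
        cache = _SurfaceCache(state, surface, box)
    gain = np.zeros(len(surface.pos))
    m = (surface.alive[cache.surf] & (cache.dist <= p.interaction_radius)
         & state.alive[cache.cell])
    if m.any():
        is_leader = state.is_leader()[cache.cell[m]]
        A = np.where(is_leader, p.A_surf_leader, p.A_surf_normal)
        rs = np.where(is_leader, p.r_surf_leader, p.r_surf)
        mag = A * np.exp(-cache.dist[m] ** 2 / (2.0 * rs ** 2))
        np.add.at(gain, cache.surf[m], mag)
    alive_s = surface.alive
    leak = 0.0 if np.isinf(p.tau_w) else surface.w[alive_s] / p.tau_w
    surface.w[alive_s] += dt * (gain[alive_s] - leak)
    surface.alive[surface.w >= p.w_threshold] = False


def _density_at(point: np.ndarray, others: np.ndarray, cutoff: float,
                box: Box) -> float:
    """Sector local density of a probe point against a candidate point set."""
    iq, it, vec, dist = _cross_pairs(point[None, :], others, cutoff, box)
    keep = dist > 1e-9
    vec, dist = vec[keep], dist[keep]
    sector_d = np.full(6, cutoff)
    if len(dist):
        ang = np.arctan2(vec[:, 1], vec[:, 0]) % (2 * np.pi)
        sec = np.minimum((ang / (np.pi / 3)).astype(int), 5)
        for s in range(6):
            m = sec == s
            if m.any():
                sector_d[s] = dist[m].min()
    rbar = sector_d.mean()
    return 2.0 / (np.sqrt(3.0) * rbar ** 2)


def divide_cells(state: ParticleState, dt: float, params: DivisionParams,
                 cutoff: float, box: Box, rng: np.random.Generator
                 ) -> ParticleState:
    """Density-capped stochastic division; returns the (possibly grown) state.

    Each bulk cell divides with probability dt·ln2/T_div; the daughter is
    placed at ``daughter_offset`` in a random direction with the parent's
    velocity and OU state. The division is rolled back if the parent's
    post-division local density would exceed the cap. Leaders never divide.
    """
    p_div = dt * np.log(2.0) / params.T_div
    if p_div >= 1.0:
        raise ValueError("dt too large for the division rate")
    bulk = np.nonzero(state.alive & ~state.is_leader())[0]
    draws = rng.random(len(bulk))
    dividers = bulk[draws < p_div]
    if len(dividers) == 0:
        return state
    new_pos, new_vel, new_eta = [], [], []
    pts = state.pos[state.alive]
    for i in dividers:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        offset = params.daughter_offset * np.array([np.cos(theta), np.sin(theta)])
        daughter = box.wrap(state.pos[i] + offset)
        trial = np.vstack([pts] + new_pos + [daughter[None, :]])
        d_parent = _density_at(state.pos[i], trial, cutoff, box)
        d_daughter = _density_at(daughter, trial, cutoff, box)
        if max(d_parent, d_daughter) > params.density_cap:
            continue
        new_pos.append(daughter[None, :])
        new_vel.append(state.vel[i].copy())
        new_eta.append(state.eta[i].copy())
    if not new_pos:
        return state
    m = len(new_pos)
    next_id = int(state.ids.max()) + 1
    return ParticleState(
        ids=np.concatenate([state.ids, next_id + np.arange(m)]),
        pos=np.vstack([state.pos] + new_pos),
        vel=np.vstack([state.vel, np.array(new_vel)]),
        eta=np.vstack([state.eta, np.array(new_eta)]),
        kind=np.concatenate([state.kind, np.zeros(m, dtype=np.int8)]),
        leader_v=np.vstack([state.leader_v, np.full((m, 2), np.nan)]),
        alive=np.concatenate([state.alive, np.ones(m, dtype=bool)]),
    )


def init_band(config: SimConfig, n_particles: int, band: BandParams,
              rng: np.random.Generator | None = None,
              init_jitter: float = 1.0):
    """Cells tile x ∈ [−band_width_x, 0] at d0; surface grid on x > 0."""
    box = config.box
    if box.kind != BAND:
        raise ValueError("band initialization requires a band box")
    pos = hex_lattice(box, n_particles, rng=rng, jitter=init_jitter,
                      x_range=(-band.band_width_x, 0.0))
    state = ParticleState.make(pos, rng=rng)
    surface = (SurfaceField.grid(band.free_width_x, box.Ly, band.surface)
               if band.enable_surface
               else SurfaceField(np.zeros((0, 2)), np.zeros(0),
                                 np.zeros(0, bool), band.surface))
    return state, surface


def simulate_band(config: SimConfig, n_particles: int, band: BandParams,
                  t_end: float, snapshot_every: float = 0.5,
                  init_jitter: float = 1.0) -> BandResult:
    """Full frontier run: bulk dynamics + surface + leaders + division."""
    rng = np.random.default_rng(config.seed)
    state, surface = init_band(config, n_particles, band, rng=rng,
                               init_jitter=init_jitter)
    n_steps = int(round(t_end / config.dt))
    every = max(1, int(round(snapshot_every / config.dt)))
    leader_log: list[LeaderEvent] = []
    times, P, V, I, K, ncells = [], [], [], [], [], []
    bt, bm = [], []

    def record(t):
        times.append(t)
        P.append(state.pos[state.alive].copy())
        V.append(state.vel[state.alive].copy())
        I.append(state.ids[state.alive].copy())
        K.append(state.kind[state.alive].copy())
        ncells.append(int(state.alive.sum()))

    record(0.0)
    graph = None
    cache = None
    for step in range(n_steps):
        t = step * config.dt
        if graph is None or step % config.graph_refresh_every == 0 \
                or graph.n != state.n:
            graph = find_neighbors(state.pos, config.neighbor_cutoff,
                                   config.box,
                                   symmetrize=config.symmetrize_graph)
            cache = _SurfaceCache(state, surface, config.box) \
                if band.enable_surface else None
        border = detect_border(state.pos, config.box.Ly, band.border_band,
                               alive=state.alive)
        bt.append(t)
        bm.append(border[2])
        if band.enable_leaders:
            spawn_leaders(state, border, t, config.dt, band.leaders,
                          config.box, rng, log_events=leader_log)
        d = local_density(graph)
        sigma = noise_amplitude(d, config)
        state.eta = ou_step(state.eta, config.dt, config.tau, rng)
        Fs = surface_force(state, surface, config.box, cache=cache) \
            if band.enable_surface else None
        velocity_step(state, graph, config, config.dt, sigma=sigma,
                      extra_force=Fs)
        update_leader(state, graph, band.leaders)
        position_step(state, config.dt, config.box)
        if band.enable_surface:
            damage_step(surface, state, config.dt, config.box, cache=cache)
        if band.enable_division:
            state = divide_cells(state, config.dt, band.division,
                                 config.neighbor_cutoff, config.box, rng)
        if (step + 1) % every == 0:
            record((step + 1) * config.dt)

    return BandResult(times=np.asarray(times), positions=P, velocities=V,
                      ids=I, kinds=K, border_times=np.asarray(bt),
                      border_mean=np.asarray(bm), leader_log=leader_log,
                      surface=surface, config=config, band=band,
                      n_cells=np.asarray(ncells))
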