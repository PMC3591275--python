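"""Analytically solvable approximation: velocity dynamics on a frozen lattice.

With cell positions pinned to a periodic triangular lattice and pair forces
dropped, the velocity equation becomes linear and diagonalizes in Fourier
modes over the lattice. Each mode relaxes at

    λ_q = α + β Σ_{e ∈ 6 neighbors} (1 − cos(q·e)),

and, driven by OU noise of correlation time τ (rate μ = 1/τ, unit stationary
variance), has stationary autocovariance (per velocity component, σ = 1)

    C_q(T) = e^{−λT} / (2λ(λ+μ)) + [e^{−λT}/(2λ) − e^{−μT}/(λ+μ)] / (μ−λ),

with the analytic λ→μ limit e^{−λT} (1/(2λ²) + T/(2λ)). Equal-time mode
variances 1/(λ_q(λ_q+μ)) give the spatial correlation by an inverse discrete
Fourier sum. Normalized curves do not depend on the noise amplitude.

These closed forms initialize the correlation-function fits and serve as
oracles for the frozen-position simulation; their temporal decay is slower
than the full model's (moving positions decorrelate faster), so they are
never used as ground truth for full-model curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig
from .dynamics import ou_step


@dataclass(frozen=True)
class LatticeSpec:
    """Periodic triangular lattice: spacing and primitive-cell counts."""

    a: float          # µm
    n1: int = 48
    n2: int = 48

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("spacing must be positive")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least 2 cells per direction")

    @property
    def primitive(self) -> np.ndarray:
        return np.array([[self.a, 0.0],
                         [self.a / 2.0, self.a * np.sqrt(3.0) / 2.0]])

    @property
    def neighbor_vectors(self) -> np.ndarray:
        a1, a2 = self.primitive
        return np.array([a1, a2, a2 - a1, -a1, -a2, a1 - a2])

    def sites(self) -> np.ndarray:
        a1, a2 = self.primitive
        i1, i2 = np.meshgrid(np.arange(self.n1), np.arange(self.n2),
                             indexing="ij")
        return i1.ravel()[:, None] * a1 + i2.ravel()[:, None] * a2

    def wavevectors(self) -> np.ndarray:
        A = self.primitive.T                # columns are a1, a2
        B = 2.0 * np.pi * np.linalg.inv(A)  # rows are b1, b2 (a_i·b_j = 2πδ)
        m1, m2 = np.meshgrid(np.arange(self.n1), np.arange(self.n2),
                             indexing="ij")
        return (m1.ravel()[:, None] / self.n1) * B[0] \
            + (m2.ravel()[:, None] / self.n2) * B[1]


@dataclass
class ModeSpectrum:
    q: np.ndarray       # (M, 2)
    rates: np.ndarray   # (M,) λ_q, h⁻¹
    spec: LatticeSpec
    alpha: float
    beta: float

    def variances(self, tau: float) -> np.ndarray:
        """Stationary per-mode velocity variance at unit noise amplitude."""
        return 1.0 / (self.rates * (self.rates + 1.0 / tau))


def mode_rates(spec: LatticeSpec, alpha: float, beta: float) -> ModeSpectrum:
    q = spec.wavevectors()
    lam = alpha + beta * np.sum(1.0 - np.cos(q @ spec.neighbor_vectors.T),
                                axis=1)
    return ModeSpectrum(q=q, rates=lam, spec=spec, alpha=alpha, beta=beta)


def _mode_autocov(lam: np.ndarray, mu: float, t: np.ndarray) -> np.ndarray:
    """Stationary autocovariance (unit σ) of dv/dt = −λv + η_OU(μ)."""
    lam = np.asarray(lam, dtype=float)[:, None]
    t = np.abs(np.asarray(t, dtype=float))[None, :]
    near = np.abs(lam - mu) < 1e-9 * np.maximum(lam, mu)
    lam_safe = np.where(near, mu * (1 + 1e-6), lam)
    gen = (np.exp(-lam_safe * t) / (2 * lam_safe * (lam_safe + mu))
           + (np.exp(-lam_safe * t) / (2 * lam_safe)
              - np.exp(-mu * t) / (lam_safe + mu)) / (mu - lam_safe))
    degen = np.exp(-mu * t) * (1.0 / (2 * mu ** 2) + t / (2 * mu))
    return np.where(near, degen, gen)


def _mode_mask(spectrum: ModeSpectrum, include_uniform: bool) -> np.ndarray:
    if include_uniform:
        return np.ones(len(spectrum.rates), dtype=bool)
    return ~np.all(spectrum.q == 0.0, axis=1)


def analytic_temporal_autocorr(spectrum: ModeSpectrum, tau: float,
                               t: np.ndarray,
                               include_uniform: bool = False) -> np.ndarray:
    """Normalized velocity autocorrelation A(t) of the frozen-lattice model.

    By default the uniform (q = 0) mode is excluded: the empirical
    estimators subtract the instantaneous spatial mean velocity, which
    removes exactly that mode, and it carries a large variance weight
    (its relaxation rate is the bare damping α).
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("lags must be non-negative")
    mu = 1.0 / tau
    m = _mode_mask(spectrum, include_uniform)
    cov = _mode_autocov(spectrum.rates[m], mu, np.asarray(t, dtype=float))
    A = cov.sum(axis=0)
    return A / A[0] if A[0] != 0 else A


def analytic_spatial_corr(spectrum: ModeSpectrum, tau: float,
                          r_vectors: np.ndarray,
                          include_uniform: bool = False) -> np.ndarray:
    """Normalized equal-time correlation C(r) at lattice displacement vectors.

    The uniform mode is excluded by default (see
    ``analytic_temporal_autocorr``); with it included C(r) acquires a
    near-constant offset that mean-removed estimators never show.
    """
    m = _mode_mask(spectrum, include_uniform)
    var = spectrum.variances(tau)[m]
    r = np.atleast_2d(np.asarray(r_vectors, dtype=float))
    C = np.cos(r @ spectrum.q[m].T) @ var
    return C / var.sum()


def analytic_spatial_curve(spectrum: ModeSpectrum, tau: float, dr: float,
                           r_max: float, include_uniform: bool = False):
    """C(r) binned by lattice distance onto a radial grid (centers, values)."""
    spec = spectrum.spec
    a1, a2 = spec.primitive
    kmax = int(np.ceil(r_max / spec.a)) + 1
    i1, i2 = np.meshgrid(np.arange(-kmax, kmax + 1),
                         np.arange(-kmax, kmax + 1), indexing="ij")
    r = i1.ravel()[:, None] * a1 + i2.ravel()[:, None] * a2
    dist = np.linalg.norm(r, axis=1)
    m = dist <= r_max
    r, dist = r[m], dist[m]
    C = analytic_spatial_corr(spectrum, tau, r,
                              include_uniform=include_uniform)
    # the r = 0 point is reported as its own lag-0 bin (value 1), matching
    # the simulation estimator's self-term convention
    origin = dist < 1e-9
    r, dist, C = r[~origin], dist[~origin], C[~origin]
    edges = np.arange(0.0, r_max + dr, dr)
    idx = np.digitize(dist, edges) - 1
    nb = len(edges) - 1
    sums = np.zeros(nb)
    cnts = np.zeros(nb)
    good = (idx >= 0) & (idx < nb)
    np.add.at(sums, idx[good], C[good])
    np.add.at(cnts, idx[good], 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    keep = cnts > 0
    lag = np.concatenate([[0.0], centers[keep]])
    val = np.concatenate([[1.0], sums[keep] / cnts[keep]])
    return lag, val


def frozen_sim(spec: LatticeSpec, config: SimConfig, t_end: float,
               rng: np.random.Generator, burn_in: float | None = None,
               snapshot_every: float = 0.1, dr: float | None = None,
               r_max: float | None = None, max_lag: float = 4.0,
               n_blocks: int = 8, remove_mean: bool = True):
    """Velocity dynamics with pinned positions; empirical C(r) and A(t).

    Returns two ``CorrelationCurve`` objects (spatial, temporal), normalized,
    with standard errors estimated from independent time blocks. The spatial
    correlation is computed exactly over all lattice displacements via FFT
    and binned radially (bin width ``dr``, default half a spacing, which
    isolates the first neighbor shells).
    """
    n = spec.n1 * spec.n2
    nbrs = _neighbor_indices(spec)
    if burn_in is None:
        burn_in = 5.0 * max(config.tau, 1.0 / config.alpha)
    dt = config.dt
    v = np.zeros((n, 2))
    eta = rng.standard_normal((n, 2))
    n_burn = int(round(burn_in / dt))
    n_steps = int(round(t_end / dt))
    every = max(1, int(round(snapshot_every / dt)))
    snaps = []
    for step in range(n_burn + n_steps):
        eta = ou_step(eta, dt, config.tau, rng)
        coupling = v[nbrs].sum(axis=1) - 6.0 * v
        v = v + dt * (-config.alpha * v + config.beta * coupling
                      + config.sigma0 * eta)
        if step >= n_burn and (step - n_burn) % every == 0:
            snaps.append(v[:, 0].copy())  # x component
    V = np.array(snaps)  # (T, n)
    return _frozen_curves(spec, V, snapshot_every, dr=dr, r_max=r_max,
                          max_lag=max_lag, n_blocks=n_blocks,
                          remove_mean=remove_mean)


def _neighbor_indices(spec: LatticeSpec) -> np.ndarray:
    n1, n2 = spec.n1, spec.n2
    i1, i2 = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    i1, i2 = i1.ravel(), i2.ravel()
    offs = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    cols = [((i1 + o1) % n1) * n2 + ((i2 + o2) % n2) for o1, o2 in offs]
    return np.stack(cols, axis=1)


def _frozen_curves(spec: LatticeSpec, V: np.ndarray, snap_dt: float,
                   dr: float | None = None, r_max: float | None = None,
                   max_lag: float = 4.0, n_blocks: int = 8,
                   remove_mean: bool = True):
    """Block-averaged normalized C(r) and A(t) from frozen-lattice snapshots.

    ``V`` is the (T, n1*n2) x-velocity matrix. The spatial autocovariance
    over all lattice displacements is computed exactly per snapshot with a
    2-D FFT, then binned radially; per-snapshot means are removed, matching
    the moving-cell estimators.
    """
    from .stats import CorrelationCurve

    n1, n2 = spec.n1, spec.n2
    if dr is None:
        dr = spec.a / 2.0
    if r_max is None:
        r_max = min(n1, n2) * spec.a / 2.5
    T = V.shape[0]
    U = V - V.mean(axis=1, keepdims=True) if remove_mean else V.copy()
    G = U.reshape(T, n1, n2)
    # displacement distances with torus minimum image
    i1 = np.arange(n1)
    i2 = np.arange(n2)
    i1 = np.where(i1 > n1 // 2, i1 - n1, i1)
    i2 = np.where(i2 > n2 // 2, i2 - n2, i2)
    I1, I2 = np.meshgrid(i1, i2, indexing="ij")
    a1, a2 = spec.primitive
    disp = I1[..., None] * a1 + I2[..., None] * a2
    dist = np.linalg.norm(disp, axis=-1).ravel()
    edges = np.arange(0.0, r_max + dr, dr)
    bin_of = np.digitize(dist, edges) - 1
    origin = dist < 1e-9
    nb = len(edges) - 1
    bin_counts = np.bincount(bin_of[(bin_of >= 0) & (bin_of < nb) & ~origin],
                             minlength=nb)

    blocks = np.array_split(np.arange(T), n_blocks)
    max_lag_steps = min(len(blocks[0]) - 1, int(round(max_lag / snap_dt)))
    C_blocks, A_blocks = [], []
    for blk in blocks:
        g = G[blk]
        F = np.fft.fft2(g, axes=(1, 2))
        S = (F * F.conj()).real.mean(axis=0)
        cov = np.fft.ifft2(S).real / (n1 * n2)   # autocov per displacement
        c0 = cov[0, 0]
        flat = cov.ravel()
        sums = np.bincount(bin_of[(bin_of >= 0) & (bin_of < nb) & ~origin],
                           weights=flat[(bin_of >= 0) & (bin_of < nb) & ~origin],
                           minlength=nb)
        with np.errstate(invalid="ignore"):
            C_blocks.append(np.where(bin_counts > 0,
                                     sums / np.maximum(bin_counts, 1) / c0,
                                     np.nan))
        u = U[blk]
        a0 = (u ** 2).mean()
        A_blocks.append([np.mean(u[: len(blk) - k] * u[k:]) / a0
                         for k in range(max_lag_steps + 1)])
    C_blocks = np.array(C_blocks)
    A_blocks = np.array(A_blocks)
    centers = 0.5 * (edges[1:] + edges[:-1])
    keep = bin_counts > 0
    C = C_blocks.mean(axis=0)
    C_se = C_blocks.std(axis=0, ddof=1) / np.sqrt(len(blocks))
    A = A_blocks.mean(axis=0)
    A_se = A_blocks.std(axis=0, ddof=1) / np.sqrt(len(blocks))
    spatial = CorrelationCurve(
        lag=np.concatenate([[0.0], centers[keep]]),
        value=np.concatenate([[1.0], C[keep]]),
        raw=np.concatenate([[1.0], C[keep]]),
        counts=np.concatenate([[n1 * n2], bin_counts[keep]]),
        se=np.concatenate([[0.0], C_se[keep]]))
    temporal = CorrelationCurve(
        lag=np.arange(max_lag_steps + 1) * snap_dt,
        value=A, raw=A, counts=np.full(max_lag_steps + 1, len(blocks[0])),
        se=A_se)
    return spatial, temporal


def border_estimate(rate_per_mm_h: float, V_L: float, v0: float,
                    ell_corr: float, t: np.ndarray,
                    switch_time: float = 20.0,
                    rate_late: float | None = None) -> np.ndarray:
    """Mean border position from leader-driven entrainment.

    Each leader entrains a border portion of lateral extent ~ the velocity
    correlation length ell_corr (µm) at the leader speed V_L; with leaders
    appearing at a constant rate per border length the border advance is

        x̄(t) = v0·t + ½ · rate · (ell_corr/1000) · (V_L − v0) · t²

    (rate in mm⁻¹h⁻¹). After ``switch_time`` the rate switches to
    ``rate_late`` and the trajectory continues with matched value and slope.
    """
    if min(rate_per_mm_h, V_L, v0, ell_corr) < 0:
        raise ValueError("arguments must be non-negative")
    t = np.asarray(t, dtype=float)
    k_early = 0.5 * rate_per_mm_h * (ell_corr / 1000.0) * (V_L - v0)
    x = v0 * t + k_early * t ** 2
    if rate_late is not None:
        k_late = 0.5 * rate_late * (ell_corr / 1000.0) * (V_L - v0)
        ts = switch_time
        late = t >= ts
        x_ts = v0 * ts + k_early * ts ** 2
        slope_ts = v0 + 2 * k_early * ts
        dtm = t[late] - ts
        x[late] = x_ts + slope_ts * dtm + k_late * dtm ** 2
    return x
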