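"""Velocity-field and structure statistics.

Estimators used to compare simulations with PIV-style experimental data:
velocity histograms, radial distribution of cell centers, neighbor distance
and angle distributions, equal-time spatial velocity correlations, temporal
velocity autocorrelations (Lagrangian and Eulerian), correlation lengths,
gridded velocity fields, border kinetics fits, velocity profiles across the
border and density profiles along fingers.

All correlation curves are normalized by their lag-0 value; component means
are removed per snapshot before correlating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Box
from .neighbors import NeighborGraph

_COMP = {"x": 0, "y": 1}


@dataclass
class Histogram:
    edges: np.ndarray
    counts: np.ndarray
    density: bool = True

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[1:] + self.edges[:-1])

    @property
    def values(self) -> np.ndarray:
        if not self.density:
            return self.counts.astype(float)
        widths = np.diff(self.edges)
        total = self.counts.sum()
        return self.counts / (total * widths) if total else self.counts * 0.0


@dataclass
class CorrelationCurve:
    lag: np.ndarray        # µm or h
    value: np.ndarray      # normalized (value at lag 0 == 1 when present)
    raw: np.ndarray        # unnormalized estimator
    counts: np.ndarray     # samples per bin
    se: np.ndarray | None = None  # standard error of the normalized value


@dataclass
class VelocityField:
    origin: np.ndarray     # (2,)
    step: float            # µm
    mean_v: np.ndarray     # (nx, ny, 2); nan where count == 0
    counts: np.ndarray     # (nx, ny)


def velocity_histograms(velocities: np.ndarray, bin_width: float = 1.0):
    """Density histograms of vx, vy and |v| plus gaussian moments.

    Returns ``(hist_vx, hist_vy, hist_mod, moments)`` with ``moments`` a dict
    of per-component mean and standard deviation.
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 2 or len(v) < 2:
        raise ValueError("need at least 2 velocity samples")
    mod = np.hypot(v[:, 0], v[:, 1])
    lo = min(v.min(), 0.0)
    hi = max(v.max(), mod.max())
    edges = np.arange(np.floor(lo / bin_width) * bin_width,
                      np.ceil(hi / bin_width) * bin_width + bin_width,
                      bin_width)
    if len(edges) < 2:
        edges = np.array([lo - bin_width / 2, lo + bin_width / 2])
    hists = []
    for sample in (v[:, 0], v[:, 1], mod):
        counts, _ = np.histogram(sample, bins=edges)
        hists.append(Histogram(edges=edges, counts=counts))
    moments = {
        "vx_mean": float(v[:, 0].mean()), "vx_sd": float(v[:, 0].std(ddof=1)),
        "vy_mean": float(v[:, 1].mean()), "vy_sd": float(v[:, 1].std(ddof=1)),
        "speed_mean": float(mod.mean()),
    }
    return hists[0], hists[1], hists[2], moments


def _pair_distances(pos: np.ndarray, r_max: float, box: Box):
    """Unordered pair distances up to r_max under periodic boundaries."""
    aug, srcmap = box.with_ghosts(box.wrap(pos), r_max)
    tree = cKDTree(aug)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros(0), np.zeros(0, np.int64), np.zeros(0, np.int64)
    n = len(pos)
    a, b = pairs[:, 0], pairs[:, 1]
    # keep each physical pair once: require the first member to be a real point
    m = a < n
    a, b = a[m], b[m]
    d = np.linalg.norm(aug[b] - aug[a], axis=1)
    i, j = a, srcmap[b]
    keep = i != j
    # real-real pairs appear once in query_pairs; real-ghost pairs appear for
    # both members, so drop the duplicate with i > j when both in range both ways
    dup = (b[keep] >= n) & (i[keep] > j[keep])
    return d[keep][~dup], i[keep][~dup], j[keep][~dup]


def pair_correlation_centers(positions: np.ndarray, box: Box, dr: float = 2.0,
                             r_max: float | None = None) -> CorrelationCurve:
    """Radial distribution function g(r) of cell centers (periodic box)."""
    if dr <= 0:
        raise ValueError("dr must be positive")
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if r_max is None:
        r_max = min(box.Lx, box.Ly) / 4.0
    edges = np.arange(0.0, r_max + dr, dr)
    d, _, _ = _pair_distances(pos, float(edges[-1]), box)
    counts, _ = np.histogram(d, bins=edges)
    rho = n / (box.Lx * box.Ly)
    centers = 0.5 * (edges[1:] + edges[:-1])
    shell = 2.0 * np.pi * centers * dr
    g = (2.0 * counts) / (n * rho * shell)  # ordered-pair normalization
    return CorrelationCurve(lag=centers, value=g, raw=counts.astype(float),
                            counts=counts)


def neighbor_distance_distribution(graph: NeighborGraph,
                                   bin_width: float = 1.0) -> Histogram:
    """Histogram of all (cell, sector-neighbor) distances."""
    d = graph.dist[graph.ids >= 0]
    if len(d) == 0:
        return Histogram(edges=np.array([0.0, bin_width]),
                         counts=np.zeros(1, dtype=int))
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return Histogram(edges=edges, counts=counts)


def spatial_velocity_correlation(positions: np.ndarray, velocities: np.ndarray,
                                 component: str, dr: float, box: Box,
                                 r_max: float | None = None,
                                 remove_mean: bool = True) -> CorrelationCurve:
    """Normalized equal-time spatial correlation of one velocity component.

    C_u(r) = <u_i u_j>_{|x_i-x_j| in bin} / Var(u), the r = 0 bin being the
    self term (== 1 after normalization).
    """
    pos = np.asarray(positions, dtype=float)
    u = np.asarray(velocities, dtype=float)[:, _COMP[component]].copy()
    if len(pos) < 2:
        raise ValueError("need at least 2 particles")
    if remove_mean:
        u -= u.mean()
    var = u.var()
    if var <= 0:
        raise ValueError("zero velocity variance: correlation undefined")
    if r_max is None:
        r_max = min(box.Lx, box.Ly) / 4.0
    edges = np.arange(0.0, r_max + dr, dr)
    d, i, j = _pair_distances(pos, float(edges[-1]), box)
    idx = np.digitize(d, edges) - 1
    nb = len(edges) - 1
    sums = np.zeros(nb)
    cnts = np.zeros(nb, dtype=np.int64)
    good = (idx >= 0) & (idx < nb)
    np.add.at(sums, idx[good], u[i[good]] * u[j[good]])
    np.add.at(cnts, idx[good], 1)
    with np.errstate(invalid="ignore"):
        raw = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    lag = np.concatenate([[0.0], 0.5 * (edges[1:] + edges[:-1])])
    value = np.concatenate([[1.0], raw / var])
    counts = np.concatenate([[len(u)], cnts])
    return CorrelationCurve(lag=lag, value=value,
                            raw=np.concatenate([[var], raw]), counts=counts)


def average_spatial_correlation(trajectory, component: str, dr: float,
                                box: Box, t_min: float = 0.0,
                                r_max: float | None = None,
                                remove_mean: bool = True) -> CorrelationCurve:
    """Snapshot-averaged spatial velocity correlation over t >= t_min."""
    curves = []
    for t, p, v in zip(trajectory.times, trajectory.positions,
                       trajectory.velocities):
        if t < t_min:
            continue
        curves.append(spatial_velocity_correlation(p, v, component, dr, box,
                                                   r_max=r_max,
                                                   remove_mean=remove_mean))
    if not curves:
        raise ValueError("no snapshots past t_min")
    vals = np.array([c.value for c in curves])
    se = vals.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 \
        else np.full(vals.shape[1], np.nan)
    return CorrelationCurve(lag=curves[0].lag, value=vals.mean(axis=0),
                            raw=np.array([c.raw for c in curves]).mean(axis=0),
                            counts=curves[0].counts, se=se)


def _snapshot_matrix(trajectory, component: str):
    """(T, N) component matrix following particle ids across snapshots."""
    c = _COMP[component]
    ref = np.asarray(trajectory.ids[0])
    rows = []
    for ids, vel in zip(trajectory.ids, trajectory.velocities):
        ids = np.asarray(ids)
        if len(ids) != len(ref) or not np.array_equal(ids, ref):
            lookup = {int(i): k for k, i in enumerate(ids)}
            try:
                order = np.array([lookup[int(i)] for i in ref])
            except KeyError as exc:
                raise ValueError("particle ids do not persist across "
                                 "snapshots") from exc
            rows.append(np.asarray(vel)[order, c])
        else:
            rows.append(np.asarray(vel)[:, c])
    return np.array(rows)


def temporal_autocorrelation(trajectory, component: str,
                             mode: str = "lagrangian",
                             grid_step: float = 30.0,
                             box: Box | None = None,
                             t_min: float = 0.0,
                             max_lag: float | None = None,
                             remove_mean: bool = True) -> CorrelationCurve:
    """Velocity autocorrelation vs time lag, normalized at lag 0.

    ``lagrangian`` follows particle identities; ``eulerian`` first bins each
    snapshot to a gridded velocity field and correlates per grid cell.
    """
    keep = np.asarray(trajectory.times) >= t_min
    times = np.asarray(trajectory.times)[keep]
    if len(times) < 2:
        raise ValueError("need at least 2 snapshots")
    dt = float(np.diff(times).mean())
    if mode == "lagrangian":
        U = _snapshot_matrix(trajectory, component)[keep]
    elif mode == "eulerian":
        if box is None:
            raise ValueError("eulerian mode needs the box")
        fields = []
        sel = np.nonzero(keep)[0]
        for k in sel:
            f = grid_velocity_field(trajectory.positions[k],
                                    trajectory.velocities[k], grid_step, box)
            fields.append(f.mean_v[..., _COMP[component]].ravel())
        U = np.array(fields)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if remove_mean:
        U = U - np.nanmean(U, axis=1, keepdims=True)
    T = U.shape[0]
    n_lags = T if max_lag is None else min(T, int(round(max_lag / dt)) + 1)
    raw = np.zeros(n_lags)
    cnt = np.zeros(n_lags, dtype=np.int64)
    for k in range(n_lags):
        prod = U[: T - k] * U[k:]
        raw[k] = np.nanmean(prod)
        cnt[k] = np.isfinite(prod).sum()
    value = raw / raw[0]
    return CorrelationCurve(lag=np.arange(n_lags) * dt, value=value, raw=raw,
                            counts=cnt)


def correlation_length(curve: CorrelationCurve) -> float:
    """First 1/e crossing of a normalized curve, linearly interpolated."""
    target = float(np.exp(-1.0))
    lag = np.asarray(curve.lag, dtype=float)
    val = np.asarray(curve.value, dtype=float)
    ok = np.isfinite(val)
    lag, val = lag[ok], val[ok]
    for k in range(1, len(val)):
        if val[k - 1] >= target > val[k]:
            frac = (val[k - 1] - target) / (val[k - 1] - val[k])
            return float(lag[k - 1] + frac * (lag[k] - lag[k - 1]))
    raise ValueError(
        f"no 1/e crossing in range [{lag[0]:g}, {lag[-1]:g}] "
        f"(min value {val.min():g})")


def grid_velocity_field(positions: np.ndarray, velocities: np.ndarray,
                        grid_step: float, box: Box) -> VelocityField:
    """Mean velocity of the particles inside each square grid cell."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    pos = box.wrap(np.asarray(positions, dtype=float))
    vel = np.asarray(velocities, dtype=float)
    nx = max(1, int(np.ceil(box.Lx / grid_step)))
    ny = max(1, int(np.ceil(box.Ly / grid_step)))
    ix = np.clip((pos[:, 0] / grid_step).astype(int), 0, nx - 1)
    iy = np.clip((pos[:, 1] / grid_step).astype(int), 0, ny - 1)
    flat = ix * ny + iy
    counts = np.bincount(flat, minlength=nx * ny)
    sums = np.zeros((nx * ny, 2))
    np.add.at(sums, flat, vel)
    with np.errstate(invalid="ignore"):
        mean = sums / np.maximum(counts, 1)[:, None]
    mean[counts == 0] = np.nan
    return VelocityField(origin=np.array([grid_step / 2, grid_step / 2]),
                         step=grid_step,
                         mean_v=mean.reshape(nx, ny, 2),
                         counts=counts.reshape(nx, ny))


def border_kinetics(times: np.ndarray, border_mean: np.ndarray,
                    t_crossover: float):
    """Early-quadratic / late-linear fits of the mean border position.

    Early regime (t < t_crossover): least squares x(t) = x(0) + b t + c t².
    Late regime (t >= t_crossover): x(t) = p + q t. Also reports log–log
    slopes of the advance x(t) − x(0) in each regime.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(border_mean, dtype=float)
    early = t < t_crossover
    late = ~early
    if early.sum() < 5 or late.sum() < 5:
        raise ValueError("need at least 5 time points per regime")
    x0 = x[0]
    te, xe = t[early], x[early] - x0
    A = np.column_stack([te, te ** 2])
    (b, c), *_ = np.linalg.lstsq(A, xe, rcond=None)
    tl, xl = t[late], x[late]
    (q, p), *_ = np.linalg.lstsq(np.column_stack([tl, np.ones_like(tl)]), xl,
                                 rcond=None)

    def loglog_slope(tt, xx):
        m = (tt > 0) & (xx > 0)
        if m.sum() < 3:
            return np.nan
        sl, _ = np.polyfit(np.log(tt[m]), np.log(xx[m]), 1)
        return float(sl)

    return {
        "x0": float(x0),
        "quad_linear_coeff": float(b),
        "quad_coeff": float(c),
        "late_slope": float(q),
        "late_intercept": float(p),
        "early_loglog_slope": loglog_slope(te, xe),
        "late_loglog_slope": loglog_slope(tl, xl - x0),
    }


def velocity_profile(trajectory, box: Box, times, bin_width: float = 50.0,
                     border_band: float = 20.0, time_tol: float = 0.5):
    """Mean v_x vs distance to the mean border position, per requested time.

    Snapshots are translated so that the mean border position sits at 0,
    then v_x is averaged in x-bins. Returns {time: (bin_centers, mean_vx)}.
    """
    from .frontier import detect_border

    out = {}
    ts = np.asarray(trajectory.times)
    for t_req in np.atleast_1d(times):
        k = int(np.argmin(np.abs(ts - t_req)))
        if abs(ts[k] - t_req) > time_tol:
            raise ValueError(f"no snapshot within {time_tol} h of t={t_req}")
        pos = np.asarray(trajectory.positions[k])
        vel = np.asarray(trajectory.velocities[k])
        _, _, xb = detect_border(pos, box.Ly, border_band)
        rel = pos[:, 0] - xb
        lo = np.floor(rel.min() / bin_width) * bin_width
        hi = np.ceil(rel.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi, bin_width)
        idx = np.digitize(rel, edges) - 1
        nb = len(edges) - 1
        sums = np.zeros(nb)
        cnts = np.zeros(nb)
        good = (idx >= 0) & (idx < nb)
        np.add.at(sums, idx[good], vel[good, 0])
        np.add.at(cnts, idx[good], 1)
        with np.errstate(invalid="ignore"):
            prof = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out[float(ts[k])] = (0.5 * (edges[1:] + edges[:-1]), prof)
    return out


def finger_density(positions: np.ndarray, densities: np.ndarray, box: Box,
                   arclength_bin: float = 25.0, border_band: float = 20.0):
    """Cell density vs position along the largest finger, base to tip.

    A finger is a contiguous run of y-bands whose border position protrudes
    beyond the baseline border. The baseline is the 25th percentile of the
    per-band border positions — the typical position of the un-protruded
    border, unaffected by the fingers themselves (the mean would be dragged
    outward by them, placing the "base" already inside the sparse finger
    region). Cells inside protruding bands and beyond the baseline are
    binned by their distance from it; model fingers grow normal to the
    initial border, so this distance is the arclength coordinate.
    """
    centers, xb, _ = detect_border_for_fingers(positions, box, border_band)
    mean_x = float(np.percentile(xb, 25.0))
    # protrusions must clear the border's own roughness (its interquartile
    # spread), otherwise a flat noisy border would yield spurious fingers
    iqr = float(np.percentile(xb, 75.0) - mean_x)
    protruding = xb > mean_x + max(2.0 * border_band, 2.0 * iqr)
    if not protruding.any():
        return np.zeros(0), np.zeros(0)
    # largest contiguous protruding run (periodic in band index)
    idx = np.nonzero(protruding)[0]
    runs = np.split(idx, np.nonzero(np.diff(idx) > 1)[0] + 1)
    if protruding[0] and protruding[-1] and len(runs) > 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs = runs[:-1]
    run = max(runs, key=len)
    nb = len(centers)
    band_of = np.clip((positions[:, 1] % box.Ly) / (box.Ly / nb),
                      0, nb - 1e-9).astype(int)
    in_finger = np.isin(band_of, run) & (positions[:, 0] > mean_x)
    if not in_finger.any():
        return np.zeros(0), np.zeros(0)
    s = positions[in_finger, 0] - mean_x  # arclength proxy: distance from base
    d = densities[in_finger]
    edges = np.arange(0.0, s.max() + arclength_bin, arclength_bin)
    idx = np.digitize(s, edges) - 1
    nbins = len(edges) - 1
    sums = np.zeros(nbins)
    cnts = np.zeros(nbins)
    good = (idx >= 0) & (idx < nbins)
    np.add.at(sums, idx[good], d[good])
    np.add.at(cnts, idx[good], 1)
    keep = cnts > 0
    return (0.5 * (edges[1:] + edges[:-1]))[keep], (sums[keep] / cnts[keep])


def detect_border_for_fingers(positions, box, border_band):
    from .frontier import detect_border

    return detect_border(np.asarray(positions), box.Ly, border_band)
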