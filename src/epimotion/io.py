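"""Configuration files, columnar writers/readers, manifests, synthetic PIV.

Configuration is a flat YAML key-value document with a ``schema: 1`` marker;
unknown keys are rejected. All run outputs are columnar text with ``#``
metadata headers, and every CLI run writes a JSON manifest (config echo,
seed, wall time, sha256 of each output file).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import (BandParams, DivisionParams, LeaderParams,
                     PotentialParams, SimConfig, SurfaceParams)
from .geometry import Box
from .stats import CorrelationCurve, Histogram, VelocityField

SCHEMA_VERSION = 1

# flat config keys -> (section, field); sim-level fields have section None
_SIM_KEYS = {f: None for f in (
    "alpha beta tau sigma0 density_noise kappa d0 neighbor_cutoff dt seed "
    "graph_refresh_every symmetrize_graph align_mean".split())}
_POT_KEYS = {f"pot_{f}": f for f in "A_rep r_rep A_att r_att r_cut r_cap".split()}
_BOX_KEYS = {"Lx": "Lx", "Ly": "Ly", "boundary": "kind"}
_LEADER_KEYS = {f"leader_{f}": f for f in (
    "rate_early rate_late switch_time creation_depth exclusion_dy v_mean "
    "v_sd min_followers v_cap".split())}
_DIV_KEYS = {f"div_{f}": f for f in "T_div daughter_offset density_cap".split()}
_SURF_KEYS = {f"surf_{f}": f for f in (
    "tau_w A_surf_normal r_surf A_surf_leader r_surf_leader "
    "interaction_radius w_threshold grid_spacing".split())}
_BAND_KEYS = {f"band_{f}": f for f in (
    "band_width_x free_width_x border_band enable_leaders enable_division "
    "enable_surface".split())}


def config_to_flat(config: SimConfig, band: BandParams | None = None) -> dict:
    out = {"schema": SCHEMA_VERSION}
    for k in _SIM_KEYS:
        out[k] = getattr(config, k)
    for k, f in _POT_KEYS.items():
        out[k] = getattr(config.potential, f)
    for k, f in _BOX_KEYS.items():
        out[k] = getattr(config.box, f)
    if band is not None:
        for k, f in _BAND_KEYS.items():
            out[k] = getattr(band, f)
        for k, f in _LEADER_KEYS.items():
            out[k] = getattr(band.leaders, f)
        for k, f in _DIV_KEYS.items():
            out[k] = getattr(band.division, f)
        for k, f in _SURF_KEYS.items():
            out[k] = getattr(band.surface, f)
    return out


def flat_to_config(flat: dict) -> tuple[SimConfig, BandParams | None]:
    flat = dict(flat)
    schema = flat.pop("schema", None)
    if schema != SCHEMA_VERSION:
        raise ValueError(f"unsupported or missing schema (expected "
                         f"{SCHEMA_VERSION}, got {schema!r})")
    known = (set(_SIM_KEYS) | set(_POT_KEYS) | set(_BOX_KEYS)
             | set(_LEADER_KEYS) | set(_DIV_KEYS) | set(_SURF_KEYS)
             | set(_BAND_KEYS))
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

    def take(keys, cls):
        kw = {f: flat[k] for k, f in keys.items() if k in flat}
        return kw, cls

    pot_kw, _ = take(_POT_KEYS, PotentialParams)
    box_kw, _ = take(_BOX_KEYS, Box)
    sim_kw = {k: flat[k] for k in _SIM_KEYS if k in flat}
    sim = SimConfig(potential=PotentialParams(**pot_kw),
                    box=Box(**box_kw) if box_kw else SimConfig().box,
                    **sim_kw)
    band = None
    band_related = (set(_BAND_KEYS) | set(_LEADER_KEYS) | set(_DIV_KEYS)
                    | set(_SURF_KEYS))
    if band_related & set(flat):
        leader_kw, _ = take(_LEADER_KEYS, LeaderParams)
        div_kw, _ = take(_DIV_KEYS, DivisionParams)
        surf_kw, _ = take(_SURF_KEYS, SurfaceParams)
        band_kw = {f: flat[k] for k, f in _BAND_KEYS.items() if k in flat}
        band = BandParams(leaders=LeaderParams(**leader_kw),
                          division=DivisionParams(**div_kw),
                          surface=SurfaceParams(**surf_kw), **band_kw)
    return sim, band


def load_config(path) -> tuple[SimConfig, BandParams | None]:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    if not isinstance(flat, dict):
        raise ValueError("configuration file must be a key-value document")
    return flat_to_config(flat)


def save_config(path, config: SimConfig, band: BandParams | None = None):
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_flat(config, band), fh, sort_keys=True)


def write_trajectory(path, traj) -> None:
    """Columnar text, one row per (time, id): t,id,x,y,vx,vy,kind."""
    frames = []
    for t, p, v, i, k in zip(traj.times, traj.positions, traj.velocities,
                             traj.ids, traj.kinds):
        frames.append(pd.DataFrame({
            "t": t, "id": np.asarray(i), "x": np.asarray(p)[:, 0],
            "y": np.asarray(p)[:, 1], "vx": np.asarray(v)[:, 0],
            "vy": np.asarray(v)[:, 1], "kind": np.asarray(k)}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


def read_trajectory(path, config: SimConfig | None = None):
    from .dynamics import Trajectory

    df = pd.read_csv(path)
    times, P, V, I, K = [], [], [], [], []
    for t, grp in df.groupby("t", sort=True):
        times.append(float(t))
        P.append(grp[["x", "y"]].to_numpy())
        V.append(grp[["vx", "vy"]].to_numpy())
        I.append(grp["id"].to_numpy())
        K.append(grp["kind"].to_numpy())
    return Trajectory(times=np.asarray(times), positions=P, velocities=V,
                      ids=I, kinds=K, config=config)


def _write_columnar(path, header: dict, columns: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df = pd.DataFrame(columns)
        fh.write(",".join(df.columns) + "\n")
        df.to_csv(fh, index=False, header=False, float_format="%.8g")


def write_curve(path, curve: CorrelationCurve, name: str, **meta) -> None:
    _write_columnar(path, {"estimator": name, **meta},
                    {"lag": curve.lag, "value": curve.value,
                     "count": curve.counts})


def read_curve(path) -> CorrelationCurve:
    df = pd.read_csv(path, comment="#")
    return CorrelationCurve(lag=df["lag"].to_numpy(),
                            value=df["value"].to_numpy(),
                            raw=df["value"].to_numpy(),
                            counts=df["count"].to_numpy())


def write_histogram(path, hist: Histogram, name: str, **meta) -> None:
    _write_columnar(path, {"estimator": name, **meta},
                    {"left": hist.edges[:-1], "right": hist.edges[1:],
                     "count": hist.counts})


def write_velocity_field(path, field: VelocityField, **meta) -> None:
    nx, ny = field.counts.shape
    cx = field.origin[0] + field.step * np.repeat(np.arange(nx), ny)
    cy = field.origin[1] + field.step * np.tile(np.arange(ny), nx)
    _write_columnar(path, {"estimator": "velocity_field",
                           "grid_step": field.step, **meta},
                    {"cx": cx, "cy": cy,
                     "vx": field.mean_v[..., 0].ravel(),
                     "vy": field.mean_v[..., 1].ravel(),
                     "count": field.counts.ravel()})


def write_manifest(path, config: SimConfig, seed, outputs,
                   band: BandParams | None = None, t_start=None) -> None:
    inv = {}
    for f in outputs:
        f = Path(f)
        inv[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "config": config_to_flat(config, band),
        "seed": seed,
        "code_version": _package_version(),
        "wall_time_start": t_start,
        "wall_time_end": time.time(),
        "outputs": inv,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def _package_version() -> str:
    from . import __version__

    return __version__


def make_synthetic_piv(config: SimConfig, grid_step: float = 30.0,
                       measurement_noise: float = 0.0,
                       n_particles: int = 1000, t_end: float = 8.0,
                       snapshot_every: float = 0.1,
                       rng: np.random.Generator | None = None):
    """PIV-style gridded velocity-field series from a bulk simulation.

    Emulates the output of image-based velocimetry: per-snapshot square-grid
    mean velocities with isotropic gaussian measurement noise added. Returns
    ``(times, fields, truth)``; ``truth`` records the generating parameters
    and is the target for parameter-recovery tests.
    """
    from .dynamics import simulate_bulk
    from .stats import grid_velocity_field

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    traj = simulate_bulk(config, n_particles, t_end,
                         snapshot_every=snapshot_every)
    fields = []
    for p, v in zip(traj.positions, traj.velocities):
        f = grid_velocity_field(p, v, grid_step, config.box)
        if measurement_noise > 0:
            noisy = f.mean_v + rng.normal(0.0, measurement_noise,
                                          size=f.mean_v.shape)
            f = VelocityField(origin=f.origin, step=f.step, mean_v=noisy,
                              counts=f.counts)
        fields.append(f)
    truth = {"alpha": config.alpha, "beta": config.beta, "tau": config.tau,
             "sigma0": config.sigma0, "seed": config.seed,
             "grid_step": grid_step, "measurement_noise": measurement_noise,
             "n_particles": n_particles, "t_end": t_end}
    return traj.times, fields, truth
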