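"""Central pair interaction between cells.

The potential is the sum of a repulsive gaussian core,
U_rep(r) = A_rep · exp(−r² / (2 r_rep²)), and a Heaviside-gated attractive
part active on r_att < r ≤ r_cut, U_att(r) = A_att (r − r_att)² / (2 (r_cut − r_att)).
The force is −dU/dr along the pair axis:

    f(r) = A_rep (r / r_rep²) exp(−r²/(2 r_rep²))          (all r ≤ r_cut)
         − A_att (r − r_att) / (r_cut − r_att)              (r_att < r ≤ r_cut)

and identically zero beyond r_cut. The gating makes the force drop from
−A_att to 0 at r_cut (a kink of U); everywhere else it is continuous.
At very short range (r < r_cap, default 0.5 µm, e.g. freshly divided
daughters) the magnitude is capped at its value at r_cap.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import PotentialParams

log = logging.getLogger(__name__)


def force_magnitude(r: np.ndarray, pot: PotentialParams) -> np.ndarray:
    """Signed radial force magnitude (positive = repulsive) at separation r."""
    r = np.asarray(r, dtype=float)
    rep = pot.A_rep * (r / pot.r_rep ** 2) * np.exp(-r ** 2 / (2.0 * pot.r_rep ** 2))
    att = np.where(
        (r > pot.r_att) & (r <= pot.r_cut),
        -pot.A_att * (r - pot.r_att) / (pot.r_cut - pot.r_att),
        0.0,
    )
    return np.where(r <= pot.r_cut, rep + att, 0.0)


def potential_energy(r: np.ndarray, pot: PotentialParams) -> np.ndarray:
    """Pair potential U(r); continuous, with a kink at r_cut."""
    r = np.asarray(r, dtype=float)
    u = pot.A_rep * np.exp(-r ** 2 / (2.0 * pot.r_rep ** 2))
    span = pot.r_cut - pot.r_att
    att = np.where(
        r <= pot.r_att,
        0.0,
        np.where(r <= pot.r_cut,
                 pot.A_att * (r - pot.r_att) ** 2 / (2.0 * span),
                 pot.A_att * span / 2.0),
    )
    return u + att


def pair_force(r_vec: np.ndarray, pot: PotentialParams) -> np.ndarray:
    """Force on the particle at the origin from a particle at ``r_vec``.

    ``r_vec`` may be a single 2-vector or an (..., 2) array. Repulsion
    points away from the other particle (along −r_vec).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    single = r_vec.ndim == 1
    v = np.atleast_2d(r_vec)
    r = np.hypot(v[..., 0], v[..., 1])
    capped = r < pot.r_cap
    if np.any(capped & (r < 1e-12)):
        log.warning("pair_force: coincident particles, capped magnitude applied")
    r_eff = np.where(capped, pot.r_cap, r)
    mag = force_magnitude(r_eff, pot)
    # unit vector away from the other particle; arbitrary fixed axis at r = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[..., None] > 1e-12, -v / np.maximum(r, 1e-12)[..., None],
                        np.array([-1.0, 0.0]))
    out = mag[..., None] * unit
    return out[0] if single else out
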