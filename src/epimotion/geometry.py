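"""Simulation box geometry: periodic wrapping, ghost images, hexagonal packing.

Two box kinds are supported: fully periodic squares/rectangles (bulk runs)
and bands that are periodic in y only, with open x (border-progression runs).
Neighbor queries use ghost-image augmentation: points within ``pad`` of a
periodic boundary are duplicated on the opposite side so that a single
KD-tree query sees all periodic images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PERIODIC = "periodic"
BAND = "band"  # periodic in y only, open in x


@dataclass(frozen=True)
class Box:
    Lx: float
    Ly: float
    kind: str = PERIODIC

    def __post_init__(self) -> None:
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("box dimensions must be positive")
        if self.kind not in (PERIODIC, BAND):
            raise ValueError(f"unknown box kind {self.kind!r}")

    @property
    def periodic_x(self) -> bool:
        return self.kind == PERIODIC

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions into the primary cell (periodic dimensions only)."""
        out = np.array(pos, dtype=float, copy=True)
        if self.periodic_x:
            out[..., 0] %= self.Lx
        out[..., 1] %= self.Ly
        return out

    def min_image(self, dvec: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied to displacement vectors."""
        out = np.array(dvec, dtype=float, copy=True)
        if self.periodic_x:
            out[..., 0] -= self.Lx * np.round(out[..., 0] / self.Lx)
        out[..., 1] -= self.Ly * np.round(out[..., 1] / self.Ly)
        return out

    def with_ghosts(self, pos: np.ndarray, pad: float):
        """Augment ``pos`` (assumed wrapped) with periodic images within ``pad``.

        Returns ``(aug, src)`` where ``aug`` stacks the original points first
        and ``src[k]`` is the original index every augmented point maps to.
        """
        pos = np.asarray(pos, dtype=float)
        n = len(pos)
        shifts = [np.zeros(2)]
        axes = ([0, 1] if self.periodic_x else [1])
        L = (self.Lx, self.Ly)
        base = [np.zeros(2)]
        for ax in axes:
            new = []
            for s in base:
                for k in (-1.0, 0.0, 1.0):
                    sh = s.copy()
                    sh[ax] += k * L[ax]
                    new.append(sh)
            base = new
        shifts = [s for s in base if np.any(s != 0)]
        chunks = [pos]
        srcs = [np.arange(n)]
        for sh in shifts:
            shifted = pos + sh
            # keep only images that can fall within pad of the primary cell
            m = (
                (shifted[:, 0] > -pad)
                & (shifted[:, 0] < self.Lx + pad)
                & (shifted[:, 1] > -pad)
                & (shifted[:, 1] < self.Ly + pad)
            )
            if m.any():
                chunks.append(shifted[m])
                srcs.append(np.nonzero(m)[0])
        return np.concatenate(chunks, axis=0), np.concatenate(srcs)


def hex_lattice(box: Box, n: int, rng=None, jitter: float = 0.0,
                x_range: tuple[float, float] | None = None) -> np.ndarray:
    """Jittered hexagonal packing of exactly ``n`` points.

    The packing fills ``x_range`` (default: the whole box) at the density
    implied by ``n`` over that area; the lattice is commensurate with the
    periodic y-dimension. Surplus lattice sites are removed at random.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    x0, x1 = x_range if x_range is not None else (0.0, box.Lx)
    width = x1 - x0
    area = width * box.Ly
    density = n / area
    a = float(np.sqrt(2.0 / (np.sqrt(3.0) * density)))
    # columns along x at spacing a*sqrt(3)/2, sites along y at spacing a,
    # odd columns shifted by a/2: neighbor bonds point at 30°, 90°, 150°, …,
    # strictly inside the 60° sectors anchored on the +x axis
    dx = a * np.sqrt(3.0) / 2.0
    nr0 = max(2, int(round(box.Ly / a)))
    nc0 = max(1, int(round(width / dx)))
    col_step = 2 if box.periodic_x else 1
    # search nearby grid shapes for a site total as close to n as possible:
    # surplus sites become vacancies, which distort the local packing
    best = None
    for nr in range(max(2, nr0 - 3), nr0 + 4):
        for nc in range(max(col_step, nc0 - 2 - (nc0 % col_step)),
                        nc0 + 3, col_step):
            sites = nr * nc
            if sites < n:
                continue
            key = (sites - n, abs(nr * a - box.Ly))
            if best is None or key < best[0]:
                best = (key, nr, nc)
    n_rows, n_cols = (best[1], best[2]) if best else (nr0 + 3, nc0 + 2)
    ay = box.Ly / n_rows
    dx = width / n_cols
    rows = np.arange(n_rows)
    cols = np.arange(n_cols)
    X = x0 + (cols[None, :] + 0.5) * dx * np.ones((n_rows, 1))
    Y = (rows[:, None] + 0.5 + 0.5 * (cols[None, :] % 2)) * ay
    pts = np.column_stack([X.ravel(), Y.ravel()])
    while len(pts) < n:  # rare: add an extra offset copy
        extra = pts[: n - len(pts)] + np.array([dx / 3.0, ay / 3.0])
        pts = np.vstack([pts, extra])
    if len(pts) > n:
        if rng is None:
            rng = np.random.default_rng(0)
        keep = rng.choice(len(pts), size=n, replace=False)
        pts = pts[np.sort(keep)]
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    pts[:, 1] %= box.Ly
    if box.periodic_x:
        pts[:, 0] %= box.Lx
    return pts
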