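"""Shared fixtures and brute-force oracles for the test suite.

The brute-force helpers deliberately re-implement the geometric rules with
plain Python/numpy loops, independent of the package's KD-tree fast paths.
"""

from __future__ import annotations

import numpy as np
import pytest

from epimotion.geometry import Box


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def hex_lattice_y(a: float, n_cols: int, n_rows: int):
    """Triangular lattice with a neighbor bond along +y.

    Neighbors sit at angles 30°, 90°, 150°, ... — strictly inside the 60°
    sectors anchored on the +x axis, avoiding boundary-angle degeneracies.
    Returns (positions, box) with a commensurate periodic box.
    """
    dx = a * np.sqrt(3.0) / 2.0
    i, j = np.meshgrid(np.arange(n_cols), np.arange(n_rows), indexing="ij")
    x = i * dx
    y = (j + 0.5 * (i % 2)) * a
    pos = np.column_stack([x.ravel(), y.ravel()])
    return pos, Box(n_cols * dx, n_rows * a, "periodic")


def brute_force_sector_neighbors(pos: np.ndarray, cutoff: float, box: Box):
    """All-pairs sector scan: per particle, closest in each 60° sector.

    Ties broken toward the lower particle id, matching the package rule.
    Returns (ids, dist) arrays of shape (N, 6).
    """
    n = len(pos)
    ids = np.full((n, 6), -1, dtype=int)
    dist = np.full((n, 6), np.inf)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = box.min_image(pos[j] - pos[i])
            r = float(np.hypot(*d))
            if r > cutoff:
                continue
            ang = np.arctan2(d[1], d[0]) % (2 * np.pi)
            s = min(int(ang / (np.pi / 3)), 5)
            if r < dist[i, s] or (r == dist[i, s] and j < ids[i, s]):
                ids[i, s] = j
                dist[i, s] = r
    return ids, dist


def brute_force_successive_angles(pos: np.ndarray, cutoff: float, box: Box):
    """Angles between displacement vectors to mutual-neighbor pairs."""
    ids, _ = brute_force_sector_neighbors(pos, cutoff, box)
    adj = set()
    for i in range(len(pos)):
        for j in ids[i]:
            if j >= 0:
                adj.add((min(i, int(j)), max(i, int(j))))
    out = []
    for i in range(len(pos)):
        nb = [int(j) for j in ids[i] if j >= 0]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                j, k = nb[a], nb[b]
                if (min(j, k), max(j, k)) not in adj:
                    continue
                u = box.min_image(pos[j] - pos[i])
                w = box.min_image(pos[k] - pos[i])
                c = np.dot(u, w) / (np.hypot(*u) * np.hypot(*w))
                out.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
    return np.asarray(out)
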