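"""Synthetic electrode layouts and neighbourhood graphs.

Real recordings use a 10-20 cap; the simulator only needs a plausible 2-D
scalp geometry, so electrodes are placed on concentric rings around a vertex
electrode.  Mastoid reference channels (``M1``/``M2``) sit outside the scalp
disc.  Adjacency is a Delaunay triangulation of the planar positions with
implausibly long edges removed, following common sensor-neighbourhood
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay


@dataclass(frozen=True)
class Montage:
    """Planar electrode layout: scalp channels plus two mastoids."""

    names: list[str]
    positions: np.ndarray  # (n_scalp, 2), unit scalp disc
    mastoid_names: tuple[str, str] = ("M1", "M2")

    @property
    def n_scalp(self) -> int:
        return len(self.names)

    @property
    def all_names(self) -> list[str]:
        return self.names + list(self.mastoid_names)


def ring_montage(n_scalp: int = 61) -> Montage:
    """Place ``n_scalp`` electrodes on concentric rings of a unit disc.

    One vertex electrode, then rings of increasing radius holding
    proportionally more electrodes, mimicking the density of an extended
    10-20 cap.
    """
    if n_scalp < 1:
        raise ValueError("n_scalp must be >= 1")
    positions = [(0.0, 0.0)]
    ring = 0
    while len(positions) < n_scalp:
        ring += 1
        n_on_ring = min(6 * ring, n_scalp - len(positions))
        radius = ring
        for k in range(n_on_ring):
            ang = 2 * np.pi * k / n_on_ring + (0.5 * np.pi * ring)
            positions.append((radius * np.cos(ang), radius * np.sin(ang)))
    pos = np.asarray(positions[:n_scalp], dtype=float)
    if ring > 0:
        pos /= ring  # normalise to unit disc
    names = [f"E{i + 1}" for i in range(n_scalp)]
    return Montage(names=names, positions=pos)


def grid_montage(rows: int, cols: int) -> Montage:
    """Rectangular grid layout, handy for small simulation studies."""
    yy, xx = np.mgrid[0:rows, 0:cols]
    pos = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    names = [f"E{i + 1}" for i in range(rows * cols)]
    return Montage(names=names, positions=pos)


def delaunay_adjacency(positions: np.ndarray, prune_factor: float = 1.5) -> np.ndarray:
    """Boolean adjacency from a Delaunay triangulation of 2-D positions.

    Edges longer than ``prune_factor`` times the median edge length are
    removed so that the convex hull does not connect distant sensors.
    Degenerate layouts (< 3 points or collinear) fall back to a chain over
    nearest neighbours.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    adj = np.zeros((n, n), dtype=bool)
    if n <= 1:
        return adj
    if n == 2:
        adj[0, 1] = adj[1, 0] = True
        return adj
    try:
        tri = Delaunay(positions)
    except Exception:  # collinear etc.
        order = np.argsort(positions[:, 0] + 1e-9 * positions[:, 1])
        for a, b in zip(order[:-1], order[1:]):
            adj[a, b] = adj[b, a] = True
        return adj
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    lengths = {e: np.linalg.norm(positions[e[0]] - positions[e[1]]) for e in edges}
    cutoff = prune_factor * np.median(list(lengths.values()))
    for (a, b), length in lengths.items():
        if length <= cutoff:
            adj[a, b] = adj[b, a] = True
    return adj
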