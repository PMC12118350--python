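"""Hexagonal-lattice stepping-stone landscapes.

Demes sit on the vertices of equilateral triangles tiling the plane
(a triangular lattice: each interior vertex has six nearest neighbours at
distance 1).  An approximately circular landscape is cut from the lattice by
taking the ``n_demes`` vertices closest to a central vertex, breaking ties
by polar angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class HexLandscape:
    """64-deme (by default) triangular-lattice landscape.

    ``axial`` holds integer axial coordinates ``(q, r)`` per deme and
    ``coords`` their Euclidean embedding with nearest-neighbour spacing 1.
    """

    axial: np.ndarray
    coords: np.ndarray
    deme_size: int = 1000

    @property
    def n_demes(self) -> int:
        return len(self.coords)

    def distance(self, a: int, b: int) -> float:
        """Euclidean distance in lattice units."""
        return float(np.hypot(*(self.coords[a] - self.coords[b])))

    def distance_matrix(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.hypot(d[..., 0], d[..., 1])

    def hop_distance(self, a: int, b: int) -> float:
        """Lattice-step distance (nearest neighbours = 1, and so on)."""
        return float(self.hop_matrix()[a, b])

    def hop_matrix(self) -> np.ndarray:
        """All-pairs shortest-path lengths over the adjacency graph."""
        if not hasattr(self, "_hops"):
            from collections import deque

            n = self.n_demes
            nbrs = [self.neighbors(i) for i in range(n)]
            hops = np.full((n, n), np.inf)
            for s in range(n):
                hops[s, s] = 0
                queue = deque([s])
                while queue:
                    u = queue.popleft()
                    for v in nbrs[u]:
                        if hops[s, v] == np.inf:
                            hops[s, v] = hops[s, u] + 1
                            queue.append(v)
            object.__setattr__(self, "_hops", hops)
        return self._hops

    def hex_ring(self, center: int, k: int) -> list[int]:
        """Demes in the k-th lattice ring (hex distance k) around *center*."""
        cq, cr = self.axial[center]
        out = []
        for i, (q, r) in enumerate(self.axial):
            dq, dr = q - cq, r - cr
            if (abs(dq) + abs(dr) + abs(dq + dr)) // 2 == k:
                out.append(i)
        return out

    def neighbors(self, deme: int) -> list[int]:
        return self.hex_ring(deme, 1)

    def adjacency(self) -> list[tuple[int, int]]:
        """Directed nearest-neighbour pairs (i, j), i != j."""
        pairs = []
        for i in range(self.n_demes):
            for j in self.neighbors(i):
                pairs.append((i, j))
        return pairs

    def degree(self, deme: int) -> int:
        return len(self.neighbors(deme))


_AXIAL_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


def _xy(q: int, r: int) -> tuple[float, float]:
    return q + 0.5 * r, SQRT3_2 * r


def build_hex_landscape(n_demes: int = 64, deme_size: int = 1000) -> HexLandscape:
    """Cut an approximately circular ``n_demes``-vertex patch from the lattice.

    Complete hexagonal rings around the central vertex are taken first; the
    remainder grows as a compact accretion on the boundary: among lattice
    points adjacent to at least two chosen demes, the one with the most
    chosen neighbours (ties: smallest central distance, then polar angle)
    is added.  This keeps node degrees in 3..6 and, for 64 demes, yields a
    lattice-step (hop) diameter of exactly 9, a Euclidean diameter of ~8.5
    and a radius of ~4.4.  Deterministic throughout.
    """
    if n_demes < 1:
        raise ValueError("n_demes must be positive")
    chosen: list[tuple[int, int]] = []
    ring = 0
    while True:
        pts = [
            (q, r)
            for q in range(-ring, ring + 1)
            for r in range(-ring, ring + 1)
            if (abs(q) + abs(r) + abs(q + r)) // 2 == ring
        ]
        if len(chosen) + len(pts) > n_demes:
            break
        chosen.extend(pts)
        ring += 1
        if len(chosen) == n_demes:
            break
    chosen_set = set(chosen)
    while len(chosen_set) < n_demes:
        candidates = {}
        for p in chosen_set:
            for dq, dr in _AXIAL_NEIGHBORS:
                cand = (p[0] + dq, p[1] + dr)
                if cand in chosen_set or cand in candidates:
                    continue
                deg = sum(
                    1
                    for dq2, dr2 in _AXIAL_NEIGHBORS
                    if (cand[0] + dq2, cand[1] + dr2) in chosen_set
                )
                if deg >= 2:
                    x, y = _xy(*cand)
                    candidates[cand] = (
                        -deg,
                        round(math.hypot(x, y), 9),
                        round(math.atan2(y, x) % (2 * math.pi), 9),
                    )
        best = min(candidates, key=lambda k: candidates[k])
        chosen_set.add(best)
    ordered = sorted(
        chosen_set,
        key=lambda p: (
            round(math.hypot(*_xy(*p)), 9),
            round(math.atan2(_xy(*p)[1], _xy(*p)[0]) % (2 * math.pi), 9),
        ),
    )
    axial = np.array(ordered, dtype=int)
    coords = np.array([_xy(q, r) for q, r in ordered], dtype=float)
    return HexLandscape(axial=axial, coords=coords, deme_size=deme_size)
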