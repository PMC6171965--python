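"""Hexagonal simulation domain.

The cortex patch is modeled as an open regular hexagon centered at the
origin.  Agents that wander outside are re-inserted uniformly at random,
so the only geometric primitives needed are exact point-in-hexagon tests
and uniform area sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HexagonDomain"]

# Vertices at angles 0, 60, ..., 300 degrees; edge normals at 30 + 60k degrees.
_NORMAL_ANGLES = np.deg2rad(30.0 + 60.0 * np.arange(6))
_NORMALS = np.column_stack([np.cos(_NORMAL_ANGLES), np.sin(_NORMAL_ANGLES)])


@dataclass(frozen=True)
class HexagonDomain:
    """Regular hexagon centered at the origin.

    Parameters
    ----------
    circumradius : float
        Center-to-vertex distance in micrometers.
    """

    circumradius: float

    def __post_init__(self) -> None:
        if self.circumradius <= 0:
            raise ValueError("circumradius must be positive")

    @property
    def inradius(self) -> float:
        """Center-to-edge distance, (sqrt(3)/2) * circumradius."""
        return 0.5 * np.sqrt(3.0) * self.circumradius

    @property
    def area(self) -> float:
        """Hexagon area, (3*sqrt(3)/2) * circumradius**2."""
        return 1.5 * np.sqrt(3.0) * self.circumradius**2

    @property
    def vertices(self) -> np.ndarray:
        """(6, 2) vertex coordinates, counter-clockwise from (R, 0)."""
        ang = np.deg2rad(60.0 * np.arange(6))
        return self.circumradius * np.column_stack([np.cos(ang), np.sin(ang)])

    def contains(self, points: np.ndarray) -> np.ndarray | bool:
        """True for points inside or on the boundary.

        The hexagon is the intersection of six half-planes
        ``p . n_k <= inradius``; boundary points are included (with a
        1e-12 relative slack against floating-point rounding).
        """
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        pts = np.atleast_2d(pts)
        proj = pts @ _NORMALS.T
        tol = self.inradius * 1e-12
        inside = np.all(proj <= self.inradius + tol, axis=1)
        return bool(inside[0]) if scalar else inside

    def sample_uniform(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` points uniformly over the hexagon area.

        Decomposes the hexagon into six triangles sharing the center and
        samples each uniformly (fold-over method), so every returned
        point satisfies :meth:`contains` by construction.
        """
        verts = self.vertices
        tri = rng.integers(0, 6, size=n)
        a = verts[tri]
        b = verts[(tri + 1) % 6]
        u = rng.random(n)
        v = rng.random(n)
        fold = u + v > 1.0
        u[fold] = 1.0 - u[fold]
        v[fold] = 1.0 - v[fold]
        pts = u[:, None] * a + v[:, None] * b
        return pts

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the hexagon."""
        r = self.circumradius
        return -r, r, -self.inradius, self.inradius
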