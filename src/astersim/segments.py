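"""Closest-point computations for rod segments.

Filaments are line segments parameterized by center ``c``, unit
direction ``u`` and half-length ``h``; signed coordinates along the rod
lie in [-h, +h] with +h at the plus-end.
"""

from __future__ import annotations

import numpy as np

__all__ = ["point_segment", "segment_segment"]


def point_segment(
    q: np.ndarray, center: np.ndarray, direction: np.ndarray, half_length: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distance from point(s) ``q`` to segment(s), plus the signed foot coordinate.

    All arguments broadcast along the leading dimension.  Returns
    ``(dist, t)`` where ``t`` in [-h, +h] is the signed along-rod
    coordinate of the closest point.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    center = np.atleast_2d(np.asarray(center, dtype=float))
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    h = np.asarray(half_length, dtype=float)
    rel = q - center
    t = np.clip(np.einsum("ij,ij->i", rel, direction), -h, h)
    foot = center + t[:, None] * direction
    dist = np.linalg.norm(q - foot, axis=1)
    return dist, t


def segment_segment(
    c1: np.ndarray,
    u1: np.ndarray,
    h1: float | np.ndarray,
    c2: np.ndarray,
    u2: np.ndarray,
    h2: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum distance between segment pairs and the signed closest coordinates.

    Returns ``(dist, s, t)`` with ``s`` on segment 1 and ``t`` on
    segment 2, both signed about the respective centers.  Uses the
    clamp-and-reproject scheme for the constrained quadratic.
    """
    c1 = np.atleast_2d(np.asarray(c1, dtype=float))
    c2 = np.atleast_2d(np.asarray(c2, dtype=float))
    u1 = np.atleast_2d(np.asarray(u1, dtype=float))
    u2 = np.atleast_2d(np.asarray(u2, dtype=float))
    h1 = np.broadcast_to(np.asarray(h1, dtype=float), c1.shape[0])
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), c2.shape[0])

    p1 = c1 - h1[:, None] * u1
    d1 = 2.0 * h1[:, None] * u1
    p2 = c2 - h2[:, None] * u2
    d2 = 2.0 * h2[:, None] * u2
    r = p1 - p2

    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    cdot = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)

    denom = a * e - b * b
    safe = np.where(denom <= 0, 1.0, denom)
    s = np.clip(np.where(denom > 0, (b * f - cdot * e) / safe, 0.0), 0.0, 1.0)
    e_safe = np.where(e == 0, 1.0, e)
    t_raw = np.where(e > 0, (b * s + f) / e_safe, 0.0)
    t = np.clip(t_raw, 0.0, 1.0)
    # where t was clamped, re-minimize s for the fixed t (exact for the box QP)
    a_safe = np.where(a == 0, 1.0, a)
    s_re = np.clip(np.where(a > 0, (b * t - cdot) / a_safe, 0.0), 0.0, 1.0)
    s = np.where(t_raw != t, s_re, s)

    q1 = p1 + s[:, None] * d1
    q2 = p2 + t[:, None] * d2
    dist = np.linalg.norm(q1 - q2, axis=1)
    s_signed = (s - 0.5) * 2.0 * h1
    t_signed = (t - 0.5) * 2.0 * h2
    return dist, s_signed, t_signed
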