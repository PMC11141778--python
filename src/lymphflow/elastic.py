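"""Discrete elastic energies and their exact gradients.

Shared by the valve leaflets (open chains) and the cell membrane (closed
polygon): linear stretching springs on segments, angular bending springs at
vertices, radial anchor springs to the polygon centroid, and an area
compressibility penalty.  Each routine returns the energy contribution and
accumulates the force ``-dE/dx`` analytically, so that structure forces are
the exact negative gradient of the total elastic energy.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidStateError


def stretch(
    P: np.ndarray, i: np.ndarray, j: np.ndarray, k: float, l0: np.ndarray,
    F: np.ndarray,
) -> float:
    """Hookean springs between node pairs (i, j) with rest lengths l0."""
    d = P[j] - P[i]
    l = np.hypot(d[:, 0], d[:, 1])
    if np.any(l < 1e-14):
        raise InvalidStateError("degenerate zero-length segment")
    t = d / l[:, None]
    s = k * (l - l0)
    np.add.at(F, i, s[:, None] * t)
    np.add.at(F, j, -s[:, None] * t)
    return 0.5 * k * float(np.sum((l - l0) ** 2))


def bend(
    P: np.ndarray,
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    k: float, theta0: np.ndarray,
    F: np.ndarray,
    ghost_a: np.ndarray | None = None,
) -> float:
    """Angular springs on the turning angle at vertex ``b`` of triples (a,b,c).

    The turning angle is ``atan2(u x v, u . v)`` with ``u = b - a`` and
    ``v = c - b``; it is zero for a straight chain and positive for a left
    turn.  ``ghost_a`` optionally supplies fixed (non-force-receiving)
    upstream points in place of ``P[a]`` — used for leaflet base angles
    relative to the wall tangent.
    """
    Pa = ghost_a if ghost_a is not None else P[a]
    u = P[b] - Pa
    v = P[c] - P[b]
    cr = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dt = np.sum(u * v, axis=1)
    denom = cr**2 + dt**2
    if np.any(denom < 1e-28):
        raise InvalidStateError("degenerate bending triple")
    theta = np.arctan2(cr, dt)
    # d(theta)/du and d(theta)/dv
    dth_du = (dt[:, None] * np.stack([v[:, 1], -v[:, 0]], axis=1)
              - cr[:, None] * v) / denom[:, None]
    dth_dv = (dt[:, None] * np.stack([-u[:, 1], u[:, 0]], axis=1)
              - cr[:, None] * u) / denom[:, None]
    m = k * (theta - theta0)
    if ghost_a is None:
        np.add.at(F, a, m[:, None] * dth_du)
    np.add.at(F, b, -m[:, None] * (dth_du - dth_dv))
    np.add.at(F, c, -m[:, None] * dth_dv)
    return 0.5 * k * float(np.sum((theta - theta0) ** 2))


def radial_anchor(P: np.ndarray, k: float, r0: float, F: np.ndarray) -> float:
    """Springs from every vertex to the instantaneous centroid.

    The centroid is the vertex mean; its dependence on the vertices is
    included in the gradient so the force field remains exactly ``-dE/dx``.
    """
    n = len(P)
    c = P.mean(axis=0)
    d = P - c
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r < 1e-14):
        raise InvalidStateError("vertex coincides with centroid")
    u = d / r[:, None]
    s = k * (r - r0)
    F -= s[:, None] * u
    F += np.sum(s[:, None] * u, axis=0) / n
    return 0.5 * k * float(np.sum((r - r0) ** 2))


def polygon_area(P: np.ndarray) -> float:
    x, y = P[:, 0], P[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def area_penalty(P: np.ndarray, k: float, A0: float, F: np.ndarray) -> float:
    """Quadratic penalty on enclosed-area deviation (incompressible interior)."""
    A = polygon_area(P)
    coef = k * (A - A0) / A0
    gx = 0.5 * (np.roll(P[:, 1], -1) - np.roll(P[:, 1], 1))
    gy = 0.5 * (np.roll(P[:, 0], 1) - np.roll(P[:, 0], -1))
    F[:, 0] -= coef * gx
    F[:, 1] -= coef * gy
    return 0.5 * k * (A - A0) ** 2 / A0
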