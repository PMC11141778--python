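"""Immersed-boundary kernel operations.

Regularized 4-point delta function (Peskin) for spreading Lagrangian
structure forces onto the lattice and interpolating lattice fields back to
structure nodes.  Lagrangian positions are in lattice coordinates
``(x, y)``; Eulerian fields are indexed ``[y, x]``.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def delta4(r: np.ndarray) -> np.ndarray:
    """Peskin 4-point regularized delta (support |r| < 2, partition of unity)."""
    r = np.abs(r)
    out = np.zeros_like(r)
    m1 = r < 1.0
    m2 = (r >= 1.0) & (r < 2.0)
    out[m1] = 0.125 * (3.0 - 2.0 * r[m1] + np.sqrt(1.0 + 4.0 * r[m1] - 4.0 * r[m1] ** 2))
    out[m2] = 0.125 * (5.0 - 2.0 * r[m2] - np.sqrt(-7.0 + 12.0 * r[m2] - 4.0 * r[m2] ** 2))
    return out


def _stencil(X: np.ndarray, ny: int, nx: int):
    """4x4 stencil indices and tensor-product weights for points X (n, 2)."""
    if np.any(~np.isfinite(X)):
        raise GeometryError("non-finite Lagrangian coordinates")
    base = np.floor(X).astype(int) - 1
    offs = np.arange(4)
    ix = base[:, 0, None] + offs            # (n, 4)
    iy = base[:, 1, None] + offs
    if ix.min() < 0 or iy.min() < 0 or ix.max() >= nx or iy.max() >= ny:
        raise GeometryError("Lagrangian node stencil leaves the domain")
    wx = delta4(X[:, 0, None] - ix)
    wy = delta4(X[:, 1, None] - iy)
    w = wy[:, :, None] * wx[:, None, :]     # (n, 4y, 4x)
    return ix, iy, w


def spread(
    X: np.ndarray, F: np.ndarray, field: np.ndarray
) -> np.ndarray:
    """Accumulate Lagrangian forces ``F`` (n, 2) into ``field`` (2, ny, nx)."""
    _, ny, nx = field.shape
    ix, iy, w = _stencil(X, ny, nx)
    IY = np.broadcast_to(iy[:, :, None], w.shape)
    IX = np.broadcast_to(ix[:, None, :], w.shape)
    for d in range(2):
        np.add.at(field[d], (IY, IX), F[:, d, None, None] * w)
    return field


def interpolate(field: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Sample an Eulerian field at points X.

    ``field`` may be (ny, nx) -> returns (n,), or (2, ny, nx) -> (n, 2).
    Exact for constant fields (kernel partition of unity).
    """
    if field.ndim == 2:
        ny, nx = field.shape
        ix, iy, w = _stencil(X, ny, nx)
        IY = np.broadcast_to(iy[:, :, None], w.shape)
        IX = np.broadcast_to(ix[:, None, :], w.shape)
        return np.sum(field[IY, IX] * w, axis=(1, 2))
    ny, nx = field.shape[1:]
    ix, iy, w = _stencil(X, ny, nx)
    IY = np.broadcast_to(iy[:, :, None], w.shape)
    IX = np.broadcast_to(ix[:, None, :], w.shape)
    out = np.empty((len(X), 2))
    for d in range(2):
        out[:, d] = np.sum(field[d][IY, IX] * w, axis=(1, 2))
    return out


def contact_forces(
    PA: np.ndarray, PB: np.ndarray, d_c: float, k_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear penalty repulsion between two node sets within range ``d_c``.

    Returns equal-and-opposite force arrays (FA, FB); zero beyond ``d_c``.
    """
    FA = np.zeros_like(PA)
    FB = np.zeros_like(PB)
    d = PA[:, None, :] - PB[None, :, :]          # (nA, nB, 2)
    dist = np.hypot(d[..., 0], d[..., 1])
    mask = dist < d_c
    if not np.any(mask):
        return FA, FB
    dist_safe = np.where(dist > 1e-12, dist, 1e-12)
    mag = np.where(mask, k_c * (d_c - dist), 0.0)
    fx = mag * d[..., 0] / dist_safe
    fy = mag * d[..., 1] / dist_safe
    FA[:, 0] += fx.sum(axis=1)
    FA[:, 1] += fy.sum(axis=1)
    FB[:, 0] -= fx.sum(axis=0)
    FB[:, 1] -= fy.sum(axis=0)
    return FA, FB
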