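"""Ski-slope surface: regular elevation grid, tangent frames, ray intersection.

The slope is represented as a regular grid of elevations interpolated
bilinearly, which gives a continuous (C0) surface.  The grid file dialect is
ESRI-ASCII-like: a single header line ``x0 y0 dx dy ncols nrows`` followed by
``nrows`` rows of ``ncols`` elevation values (row j is the line of constant
``y = y0 + j*dy``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FormatError, RangeError

__all__ = ["SlopeMesh", "elevation", "surface_frame", "ray_intersect",
           "read_mesh", "write_mesh"]


@dataclass
class SlopeMesh:
    """Regular elevation grid.

    ``z[j, i]`` is the elevation at ``(x0 + i*dx, y0 + j*dy)``.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.dx <= 0 or self.dy <= 0:
            raise DataError("grid spacings dx, dy must be positive")
        if self.z.ndim != 2 or min(self.z.shape) < 2:
            raise DataError("elevation matrix must be 2-D with >= 2 nodes per axis")
        if not np.all(np.isfinite(self.z)):
            raise DataError("elevation matrix contains non-finite values")

    @property
    def ny(self) -> int:
        return self.z.shape[0]

    @property
    def nx(self) -> int:
        return self.z.shape[1]

    @property
    def x_max(self) -> float:
        return self.x0 + (self.nx - 1) * self.dx

    @property
    def y_max(self) -> float:
        return self.y0 + (self.ny - 1) * self.dy

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x >= self.x0) & (x <= self.x_max)
                & (y >= self.y0) & (y <= self.y_max))


def _cell(mesh: SlopeMesh, x, y):
    """Cell indices and in-cell fractions for (arrays of) query points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(mesh.contains(x, y)):
        raise RangeError("query point outside mesh bounds")
    fx = (x - mesh.x0) / mesh.dx
    fy = (y - mesh.y0) / mesh.dy
    i = np.clip(np.floor(fx).astype(int), 0, mesh.nx - 2)
    j = np.clip(np.floor(fy).astype(int), 0, mesh.ny - 2)
    return i, j, fx - i, fy - j


def elevation(mesh: SlopeMesh, x, y):
    """Bilinear surface elevation at (x, y); vectorized over arrays."""
    i, j, u, v = _cell(mesh, x, y)
    z = mesh.z
    return (z[j, i] * (1 - u) * (1 - v) + z[j, i + 1] * u * (1 - v)
            + z[j + 1, i] * (1 - u) * v + z[j + 1, i + 1] * u * v)


def _gradient(mesh: SlopeMesh, x, y):
    i, j, u, v = _cell(mesh, x, y)
    z = mesh.z
    dzdx = ((z[j, i + 1] - z[j, i]) * (1 - v)
            + (z[j + 1, i + 1] - z[j + 1, i]) * v) / mesh.dx
    dzdy = ((z[j + 1, i] - z[j, i]) * (1 - u)
            + (z[j + 1, i + 1] - z[j, i + 1]) * u) / mesh.dy
    return dzdx, dzdy


def surface_frame(mesh: SlopeMesh, x, y):
    """Local surface frame at (x, y): (normal, ex, ey), all unit vectors.

    ``normal`` is the upward surface normal; ``ex`` is the tangent-plane
    projection of the site +X axis (the fall-line proxy) and
    ``ey = normal × ex`` completes the right-handed tangent frame.
    Vectorized: scalar inputs give (3,) vectors, array inputs (n, 3).
    """
    dzdx, dzdy = _gradient(mesh, x, y)
    scalar = np.ndim(dzdx) == 0
    dzdx = np.atleast_1d(dzdx)
    dzdy = np.atleast_1d(dzdy)
    n = np.stack([-dzdx, -dzdy, np.ones_like(dzdx)], axis=-1)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    ex = np.zeros_like(n)
    ex[:, 0] = 1.0
    ex -= (ex * n).sum(axis=-1, keepdims=True) * n
    norms = np.linalg.norm(ex, axis=-1, keepdims=True)
    if np.any(norms < 1e-12):
        raise DataError("degenerate (vertical) surface: X axis parallel to normal")
    ex /= norms
    ey = np.cross(n, ex)
    if scalar:
        return n[0], ex[0], ey[0]
    return n, ex, ey


def _heights_above_surface(mesh, pts):
    """z of points minus surface elevation below them; +inf outside the grid."""
    inside = mesh.contains(pts[..., 0], pts[..., 1])
    h = np.full(pts.shape[:-1], np.inf)
    if np.any(inside):
        h[inside] = pts[..., 2][inside] - elevation(
            mesh, pts[..., 0][inside], pts[..., 1][inside])
    return h


def ray_intersect(mesh: SlopeMesh, origin, direction,
                  step: float = 0.1, max_range: float = 1e4,
                  tol: float = 1e-9):
    """First intersection of a downward ray with the bilinear surface.

    Marches along the ray in ``step``-metre increments until the
    height-above-surface changes sign, then bisects to ``|Δz| < tol``.

    Returns ``(point, t)`` with ``t`` the ray parameter in metres.
    """
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if d[2] >= 0:
        raise DataError("ray direction must have a negative Z component")
    h0 = float(origin[2] - elevation(mesh, origin[0], origin[1]))
    if h0 <= 0:
        raise DataError("ray origin must lie above the surface")
    t_lo, h_lo = 0.0, h0
    t = step
    while t <= max_range:
        p = origin + t * d
        if not mesh.contains(p[0], p[1]):
            raise RangeError("ray leaves the mesh before intersecting the surface")
        h = float(p[2] - elevation(mesh, p[0], p[1]))
        if h <= 0:
            break
        t_lo, h_lo = t, h
        t += step
    else:
        raise RangeError("no intersection within max_range")
    t_hi = t
    for _ in range(200):
        tm = 0.5 * (t_lo + t_hi)
        p = origin + tm * d
        h = float(p[2] - elevation(mesh, p[0], p[1]))
        if abs(h) < tol:
            return p, tm
        if h > 0:
            t_lo = tm
        else:
            t_hi = tm
    return origin + t_hi * d, t_hi


def ray_intersect_many(mesh: SlopeMesh, origins, directions,
                       step: float = 0.1, max_range: float = 20.0,
                       tol: float = 1e-9):
    """Vectorized ray/surface intersection for one ray per sample.

    Used by the pendulum estimator where every antenna sample casts a short
    downward ray.  Same contract as :func:`ray_intersect` but batched; rays
    that do not cross within ``max_range`` raise :class:`RangeError`.
    """
    origins = np.asarray(origins, dtype=float)
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(d[:, 2] >= 0):
        raise DataError("all ray directions must point downward")
    n = origins.shape[0]
    ts = np.arange(0.0, max_range + step, step)
    pts = origins[:, None, :] + ts[None, :, None] * d[:, None, :]
    h = _heights_above_surface(mesh, pts)          # (n, n_steps); inf outside
    below = h <= 0
    if not np.all(below.any(axis=1)):
        raise RangeError("some rays do not intersect the surface in range")
    first = below.argmax(axis=1)
    if np.any(first == 0):
        raise DataError("ray origins must lie above the surface")
    t_hi = ts[first]
    t_lo = ts[first - 1]
    # guard: marching may have skipped out-of-grid cells before the crossing
    if np.any(~np.isfinite(h[np.arange(n), first - 1])):
        raise RangeError("ray leaves the mesh before intersecting the surface")
    for _ in range(60):
        tm = 0.5 * (t_lo + t_hi)
        p = origins + tm[:, None] * d
        hm = p[:, 2] - elevation(mesh, p[:, 0], p[:, 1])
        hi = hm <= 0
        t_hi = np.where(hi, tm, t_hi)
        t_lo = np.where(hi, t_lo, tm)
        if np.max(t_hi - t_lo) < tol * 1e-2:
            break
    t = 0.5 * (t_lo + t_hi)
    return origins + t[:, None] * d, t


# ---------------------------------------------------------------------------
# Mesh file I/O
# ---------------------------------------------------------------------------

def read_mesh(path) -> SlopeMesh:
    """Read the ASCII grid dialect (header ``x0 y0 dx dy ncols nrows``)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 6:
            raise FormatError(f"{path}: header must have 6 fields, got {len(header)}")
        try:
            x0, y0, dx, dy = map(float, header[:4])
            ncols, nrows = int(header[4]), int(header[5])
        except ValueError as exc:
            raise FormatError(f"{path}: malformed header") from exc
        z = np.loadtxt(fh, dtype=float)
    z = np.atleast_2d(z)
    if z.shape != (nrows, ncols):
        raise FormatError(
            f"{path}: expected {nrows}x{ncols} values, got {z.shape}")
    return SlopeMesh(x0, y0, dx, dy, z)


def write_mesh(mesh: SlopeMesh, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{mesh.x0:.9f} {mesh.y0:.9f} {mesh.dx:.9f} {mesh.dy:.9f} "
                 f"{mesh.nx} {mesh.ny}\n")
        np.savetxt(fh, mesh.z, fmt="%.9f")
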