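"""Implicit interface representation and transport.

Moving interfaces (valve leaflets, the contracting ventricular wall, static
obstacles) are carried as signed-distance fields :math:`\\phi` sampled at the
cell centres of the Cartesian grid.  The convention throughout the package is

* ``phi > 0`` in the fluid,
* ``phi <= 0`` inside the solid / outside the flow domain,

so the zero contour is the immersed boundary.  Interfaces move by the
advection equation ``phi_t + V . grad(phi) = 0`` with a propagation velocity
``V`` extended off the interface along its normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import cKDTree
from skimage import measure

from .grid import UniformGrid, interp_cc

#: half-width (in cells) of the narrow band used for reinitialization and
#: velocity extension; full-domain distances are only computed at construction.
DEFAULT_BAND = 5


@dataclass
class LevelSetField:
    """Signed-distance scalar field; zero contour is an immersed interface."""

    phi: np.ndarray
    grid: UniformGrid
    label: str = "interface"

    def copy(self) -> "LevelSetField":
        return replace(self, phi=self.phi.copy())

    def fluid_mask(self) -> np.ndarray:
        return self.phi > 0.0

    def zero_contours(self) -> list[np.ndarray]:
        """Extract the zero contour(s) as polylines in physical coordinates."""
        out = []
        for c in measure.find_contours(self.phi, 0.0):
            xy = np.empty_like(c)
            xy[:, 0] = self.grid.x0 + (c[:, 0] + 0.5) * self.grid.h
            xy[:, 1] = self.grid.y0 + (c[:, 1] + 0.5) * self.grid.h
            out.append(xy)
        return out


@dataclass
class PropagationField:
    """Interface propagation velocity ``V`` on the grid (cm/s components)."""

    vx: np.ndarray
    vy: np.ndarray
    grid: UniformGrid

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.vx)) and np.all(np.isfinite(self.vy))):
            raise ValueError("propagation velocity must be finite everywhere")


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment [a_k, b_k] (vectorized)."""
    ab = b - a  # (M,2)
    denom = np.maximum(np.einsum("ij,ij->i", ab, ab), 1e-300)
    out = np.full(len(pts), np.inf)
    # chunk over points to bound memory
    step = max(1, int(4e6 / max(len(a), 1)))
    for s in range(0, len(pts), step):
        p = pts[s : s + step]
        ap = p[:, None, :] - a[None, :, :]  # (n,M,2)
        t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom, 0.0, 1.0)
        d = ap - t[:, :, None] * ab[None, :, :]
        out[s : s + step] = np.sqrt(np.min(np.einsum("nmj,nmj->nm", d, d), axis=1))
    return out


def build_sdf(
    polyline: np.ndarray,
    grid: UniformGrid,
    *,
    label: str = "interface",
    closed: bool = True,
    fluid_side: str = "inside",
    band: float | None = None,
    repair: bool = False,
) -> LevelSetField:
    """Signed Euclidean distance to a polyline, sampled at cell centres.

    Parameters
    ----------
    polyline
        Vertex array (N, 2) in cm.  For ``closed=True`` the last vertex is
        implicitly joined to the first.
    closed
        Whether the polyline bounds a region.  An open polyline cannot carry
        a closed-region (inside/outside) label and is rejected.
    fluid_side
        ``"inside"``: fluid (phi > 0) is the polygon interior — used for the
        chamber wall contour.  ``"outside"``: the polygon is a solid immersed
        body (leaflet, obstacle) and fluid surrounds it.
    band
        If given, exact distances are only computed within ``band`` cm of the
        interface; beyond it phi is clamped to ``+-band`` (sign preserved).
        Used for fast narrow-band rebuilds during coupling.
    """
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or polyline.shape[1] != 2 or len(polyline) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array")
    if not closed:
        raise ValueError(
            f"open polyline cannot define the closed region for label {label!r}"
        )
    ring = shapely.LinearRing(polyline)
    if not ring.is_simple:
        if not repair:
            raise ValueError(f"self-intersecting polyline for label {label!r}")
        # tight offset curves (thin bodies bending at radii below their
        # half-thickness) develop small loops; buffer(0) dissolves them
        poly = shapely.Polygon(polyline).buffer(0)
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda p: p.area)
    else:
        poly = shapely.Polygon(polyline)

    pts = grid.cell_centres()
    inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])

    a = polyline
    b = np.roll(polyline, -1, axis=0)
    if band is None:
        dist = _segment_distance(pts, a, b)
    else:
        # cheap point-sample prefilter, exact distance only near the interface
        dense = _densify(polyline, closed=True, max_len=2.0 * band)
        approx = cKDTree(dense).query(pts, k=1)[0]
        near = approx <= 2.0 * band
        dist = np.minimum(approx, 2.0 * band)
        if np.any(near):
            dist[near] = _segment_distance(pts[near], a, b)
        dist = np.minimum(dist, band)

    sgn = np.where(inside, 1.0, -1.0)
    if fluid_side == "outside":
        sgn = -sgn
    elif fluid_side != "inside":
        raise ValueError("fluid_side must be 'inside' or 'outside'")
    phi = (sgn * dist).reshape(grid.nx, grid.ny)
    return LevelSetField(phi=phi, grid=grid, label=label)


def _densify(polyline: np.ndarray, *, closed: bool, max_len: float) -> np.ndarray:
    """Resample so no segment exceeds max_len; returns vertex array."""
    p = np.asarray(polyline, float)
    if closed:
        p = np.vstack([p, p[:1]])
    out = [p[:1]]
    for k in range(len(p) - 1):
        seg = p[k + 1] - p[k]
        n = max(1, int(np.ceil(np.hypot(*seg) / max_len)))
        t = np.linspace(0, 1, n + 1)[1:, None]
        out.append(p[k] + t * seg)
    return np.vstack(out)


# ---------------------------------------------------------------------------
# advection
# ---------------------------------------------------------------------------


def _pad2(f: np.ndarray) -> np.ndarray:
    """Pad by 2 ghost layers with linear extrapolation (keeps |grad| smooth)."""
    g = np.pad(f, 2, mode="edge")
    g[1, :] = 2 * g[2, :] - g[3, :]
    g[0, :] = 2 * g[1, :] - g[2, :]
    g[-2, :] = 2 * g[-3, :] - g[-4, :]
    g[-1, :] = 2 * g[-2, :] - g[-3, :]
    g[:, 1] = 2 * g[:, 2] - g[:, 3]
    g[:, 0] = 2 * g[:, 1] - g[:, 2]
    g[:, -2] = 2 * g[:, -3] - g[:, -4]
    g[:, -1] = 2 * g[:, -2] - g[:, -3]
    return g


def _minmod(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.where(a * b <= 0, 0.0, np.where(np.abs(a) < np.abs(b), a, b))


def _eno2_gradients(phi: np.ndarray, h: float):
    """One-sided second-order (ENO2) gradients (px_m, px_p, py_m, py_p).

    With 2 ghost layers, phi index i maps to padded index i+2; the second
    difference dxx has one fewer ghost on each side, so phi index i maps to
    dxx row i+1.
    """
    g = _pad2(phi)
    c = slice(2, -2)
    dxx = (g[2:, :] - 2 * g[1:-1, :] + g[:-2, :]) / h**2
    dyy = (g[:, 2:] - 2 * g[:, 1:-1] + g[:, :-2]) / h**2
    px_m = (g[2:-2, c] - g[1:-3, c]) / h + (h / 2) * _minmod(
        dxx[:-2, c], dxx[1:-1, c]
    )
    px_p = (g[3:-1, c] - g[2:-2, c]) / h - (h / 2) * _minmod(
        dxx[1:-1, c], dxx[2:, c]
    )
    py_m = (g[c, 2:-2] - g[c, 1:-3]) / h + (h / 2) * _minmod(
        dyy[c, :-2], dyy[c, 1:-1]
    )
    py_p = (g[c, 3:-1] - g[c, 2:-2]) / h - (h / 2) * _minmod(
        dyy[c, 1:-1], dyy[c, 2:]
    )
    return px_m, px_p, py_m, py_p


def _advect_rhs(phi: np.ndarray, vx: np.ndarray, vy: np.ndarray, h: float) -> np.ndarray:
    px_m, px_p, py_m, py_p = _eno2_gradients(phi, h)
    px = np.where(vx > 0, px_m, px_p)
    py = np.where(vy > 0, py_m, py_p)
    return -(vx * px + vy * py)


def advect(ls: LevelSetField, V: PropagationField, dt: float) -> LevelSetField:
    """Transport phi by ``phi_t + V . grad(phi) = 0`` over one step.

    ENO2 upwind in space, two-stage TVD Runge--Kutta in time.  The step must
    satisfy a CFL condition ``max(|V|) dt / h <= 0.5``; violation raises with
    the limiting cell named.
    """
    h = ls.grid.h
    if dt < 0:
        raise ValueError("dt must be non-negative")
    speed = np.maximum(np.abs(V.vx), np.abs(V.vy))
    cfl = speed * dt / h
    if cfl.max() > 0.5 + 1e-12:
        ij = tuple(int(k) for k in np.unravel_index(np.argmax(cfl), cfl.shape))
        raise ValueError(
            f"CFL violation in advect: CFL={cfl.max():.3f} at cell {ij} "
            f"(|V|={speed[ij]:.4g} cm/s, h={h:.4g} cm, dt={dt:.4g} s)"
        )
    if dt == 0 or cfl.max() == 0:
        return ls.copy()
    phi = ls.phi
    k1 = phi + dt * _advect_rhs(phi, V.vx, V.vy, h)
    k2 = k1 + dt * _advect_rhs(k1, V.vx, V.vy, h)
    return replace(ls, phi=0.5 * (phi + k2))


# ---------------------------------------------------------------------------
# reinitialization
# ---------------------------------------------------------------------------


def gradient_magnitude(ls: LevelSetField) -> np.ndarray:
    """Central-difference |grad phi| (used by the band invariant checks)."""
    g = _pad2(ls.phi)
    px = (g[3:-1, 2:-2] - g[1:-3, 2:-2]) / (2 * ls.grid.h)
    py = (g[2:-2, 3:-1] - g[2:-2, 1:-3]) / (2 * ls.grid.h)
    return np.hypot(px, py)


def reinitialize(
    ls: LevelSetField, *, iterations: int = 20, band: int = DEFAULT_BAND
) -> LevelSetField:
    """Restore the signed-distance property near the zero contour.

    PDE-based reinitialization (pseudo-time relaxation of ``|grad phi| = 1``)
    with the subcell interface fix of Russo & Smereka so the zero contour is
    pinned: an exact signed-distance field is a fixed point to round-off, and
    contour displacement stays well below 0.1 h.  Only the narrow band of
    ``band`` cells is updated.
    """
    h = ls.grid.h
    phi0 = ls.phi.copy()
    phi = ls.phi.copy()

    # interface cells: sign change with a 4-neighbour
    s0 = np.sign(phi0)
    iface = np.zeros_like(phi, dtype=bool)
    iface[:-1, :] |= s0[:-1, :] * s0[1:, :] < 0
    iface[1:, :] |= s0[1:, :] * s0[:-1, :] < 0
    iface[:, :-1] |= s0[:, :-1] * s0[:, 1:] < 0
    iface[:, 1:] |= s0[:, 1:] * s0[:, :-1] < 0

    # target distance in interface cells from the initial field
    g = _pad2(phi0)
    dx_c = (g[3:-1, 2:-2] - g[1:-3, 2:-2]) / 2.0
    dy_c = (g[2:-2, 3:-1] - g[2:-2, 1:-3]) / 2.0
    denom = np.maximum(np.hypot(dx_c, dy_c) / h, 1e-12)
    D = phi0 / denom

    bandmask = np.abs(phi0) <= (band + 2) * h * np.maximum(denom, 1.0)
    sgn = phi0 / np.sqrt(phi0**2 + h**2)
    dtau = 0.45 * h

    for _ in range(iterations):
        gpad = _pad2(phi)
        a = (gpad[2:-2, 2:-2] - gpad[1:-3, 2:-2]) / h  # D-x
        b = (gpad[3:-1, 2:-2] - gpad[2:-2, 2:-2]) / h  # D+x
        c = (gpad[2:-2, 2:-2] - gpad[2:-2, 1:-3]) / h  # D-y
        d = (gpad[2:-2, 3:-1] - gpad[2:-2, 2:-2]) / h  # D+y
        ap, am = np.maximum(a, 0), np.minimum(a, 0)
        bp, bm = np.maximum(b, 0), np.minimum(b, 0)
        cp, cm = np.maximum(c, 0), np.minimum(c, 0)
        dp, dm = np.maximum(d, 0), np.minimum(d, 0)
        gpos = np.sqrt(np.maximum(ap**2, bm**2) + np.maximum(cp**2, dm**2))
        gneg = np.sqrt(np.maximum(am**2, bp**2) + np.maximum(cm**2, dp**2))
        grad = np.where(phi0 > 0, gpos, gneg)
        upd = -dtau * sgn * (grad - 1.0)
        # Russo-Smereka fix at the interface
        upd_if = -(dtau / h) * (np.sign(phi0) * np.abs(phi) - D)
        new = phi + np.where(iface, upd_if, upd)
        phi = np.where(bandmask, new, phi)
    return replace(ls, phi=phi)


# ---------------------------------------------------------------------------
# velocity extension
# ---------------------------------------------------------------------------


def extend_velocity(
    ls: LevelSetField,
    sample_points: np.ndarray,
    sample_velocities: np.ndarray,
    *,
    band: int | None = None,
) -> PropagationField:
    """Extend interface velocity samples off the interface along its normals.

    Each grid point takes the velocity of its nearest interface sample (the
    foot of the normal for dense samples), which makes ``V`` constant along
    characteristics normal to the interface: ``grad(V) . grad(phi) ~ 0``.
    Extension uses only the samples supplied for *this* field's label; fields
    of other interfaces are extended from their own samples.
    """
    sp = np.atleast_2d(np.asarray(sample_points, float))
    sv = np.atleast_2d(np.asarray(sample_velocities, float))
    if len(sp) == 0:
        raise ValueError(f"empty interface sample set for label {ls.label!r}")
    if sv.shape != sp.shape:
        raise ValueError("sample_velocities must match sample_points shape")
    pts = ls.grid.cell_centres()
    idx = cKDTree(sp).query(pts, k=1)[1]
    vx = sv[idx, 0].reshape(ls.grid.nx, ls.grid.ny)
    vy = sv[idx, 1].reshape(ls.grid.nx, ls.grid.ny)
    return PropagationField(vx=vx, vy=vy, grid=ls.grid)


def combined_fluid_mask(fields: list[LevelSetField]) -> np.ndarray:
    """Effective fluid mask: cells where every interface field is positive."""
    if not fields:
        raise ValueError("need at least one level-set field")
    m = fields[0].fluid_mask()
    for f in fields[1:]:
        m &= f.fluid_mask()
    return m


def combined_phi(fields: list[LevelSetField]) -> np.ndarray:
    """Pointwise minimum of the phi fields (fluid where positive)."""
    phi = fields[0].phi.copy()
    for f in fields[1:]:
        np.minimum(phi, f.phi, out=phi)
    return phi
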