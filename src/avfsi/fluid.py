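"""Incompressible Navier--Stokes on a fixed Cartesian grid with immersed
boundaries.

A staggered (MAC) projection scheme: Adams--Bashforth convection with
Crank--Nicolson (semi-implicit) diffusion in the predictor, a pressure
Poisson solve restricted to fluid cells (cells where every level-set field
is positive), then a velocity correction.  Immersed interfaces are treated
sharply at the face level: faces whose level-set value is non-positive, or
that touch a solid cell, are forced to the local interface velocity (the
extended propagation field), which imposes no-slip/no-penetration and feeds
the volume displaced by moving boundaries into the flow.  The aortic outflow
is a prescribed plug profile whose flux equals the instantaneous displaced
volume rate, so global mass is closed to round-off every step.

Internals are SI (m, s, Pa); the grid object keeps the package-wide cm
coordinates and is converted where needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import label as nd_label
from scipy.sparse.linalg import splu

from .grid import UniformGrid, interp_cc
from .levelset import LevelSetField, PropagationField, combined_phi

CM = 1e-2


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa s).

    Defaults reproduce the printed stenotic-jet Reynolds number of ~10^4
    from a mean velocity of ~1 m/s in a 3.3 cm aorta.
    """

    rho: float = 1060.0
    mu: float = 3.5e-3

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.mu > 0):
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class OutletSpec:
    """Plug outflow on the top boundary over x in [xa, xb] (cm); flux in
    m^2/s per unit depth (positive = out of the domain)."""

    xa: float
    xb: float
    flux: float = 0.0


@dataclass
class BoundaryConditions:
    periodic_x: bool = False
    periodic_y: bool = False
    outlet: OutletSpec | None = None
    #: tangential wall speeds (m/s) for Couette-type setups
    wall_u_top: float = 0.0
    wall_u_bottom: float = 0.0
    #: body force per unit mass (m/s^2), e.g. a mean pressure gradient
    body_force: tuple[float, float] = (0.0, 0.0)


@dataclass
class FluidState:
    """MAC velocity (m/s), cell pressure (Pa) and phase masks on the grid."""

    grid: UniformGrid
    props: FluidProperties
    u: np.ndarray = None  # type: ignore[assignment]
    v: np.ndarray = None  # type: ignore[assignment]
    p: np.ndarray = None  # type: ignore[assignment]
    t: float = 0.0
    mask: np.ndarray = None  # type: ignore[assignment]
    scheme: str = "upwind2"
    conv_prev: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        nx, ny = self.grid.nx, self.grid.ny
        if self.u is None:
            self.u = np.zeros((nx + 1, ny))
        if self.v is None:
            self.v = np.zeros((nx, ny + 1))
        if self.p is None:
            self.p = np.zeros((nx, ny))
        if self.mask is None:
            self.mask = np.ones((nx, ny), dtype=bool)

    def copy(self) -> "FluidState":
        return FluidState(
            self.grid, self.props, self.u.copy(), self.v.copy(),
            self.p.copy(), self.t, self.mask.copy(), self.scheme,
            None if self.conv_prev is None
            else (self.conv_prev[0].copy(), self.conv_prev[1].copy()),
        )

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max(), 0.0))


# ---------------------------------------------------------------------------
# padding helpers (2 ghost layers, honouring periodicity / wall reflection)
# ---------------------------------------------------------------------------


def _pad_u(u: np.ndarray, bc: BoundaryConditions) -> np.ndarray:
    g = np.pad(u, 2, mode="edge")
    if bc.periodic_x:
        g[0, 2:-2] = u[-3, :]
        g[1, 2:-2] = u[-2, :]
        g[-2, 2:-2] = u[1, :]
        g[-1, 2:-2] = u[2, :]
    else:
        g[1, 2:-2] = -u[1, :]  # antisymmetric about the boundary face
        g[0, 2:-2] = -u[2, :]
        g[-2, 2:-2] = -u[-2, :]
        g[-1, 2:-2] = -u[-3, :]
    if bc.periodic_y:
        g[:, 0] = g[:, -4]
        g[:, 1] = g[:, -3]
        g[:, -2] = g[:, 2]
        g[:, -1] = g[:, 3]
    else:
        g[:, 1] = 2 * bc.wall_u_bottom - g[:, 2]
        g[:, 0] = g[:, 1]
        g[:, -2] = 2 * bc.wall_u_top - g[:, -3]
        g[:, -1] = g[:, -2]
    return g


def _pad_v(v: np.ndarray, bc: BoundaryConditions) -> np.ndarray:
    g = np.pad(v, 2, mode="edge")
    if bc.periodic_y:
        g[2:-2, 0] = v[:, -3]
        g[2:-2, 1] = v[:, -2]
        g[2:-2, -2] = v[:, 1]
        g[2:-2, -1] = v[:, 2]
    else:
        g[2:-2, 1] = -v[:, 1]
        g[2:-2, 0] = -v[:, 2]
        g[2:-2, -2] = -v[:, -2]
        g[2:-2, -1] = -v[:, -3]
    if bc.periodic_x:
        g[0, :] = g[-4, :]
        g[1, :] = g[-3, :]
        g[-2, :] = g[2, :]
        g[-1, :] = g[3, :]
    else:
        g[1, :] = -g[2, :]  # no-slip stationary side walls
        g[0, :] = g[1, :]
        g[-2, :] = -g[-3, :]
        g[-1, :] = g[-2, :]
    return g


def _ddx_upwind2(gq: np.ndarray, adv: np.ndarray, h: float, axis: int):
    """Second-order upwind derivative of padded field gq along axis."""

    def sl(k):
        idx = [slice(2, -2), slice(2, -2)]
        idx[axis] = slice(2 + k, (-2 + k) or None)
        return gq[tuple(idx)]

    minus = (3 * sl(0) - 4 * sl(-1) + sl(-2)) / (2 * h)
    plus = (-3 * sl(0) + 4 * sl(1) - sl(2)) / (2 * h)
    return np.where(adv > 0, minus, plus)


def _ddx_central(gq: np.ndarray, h: float, axis: int):
    def sl(k):
        idx = [slice(2, -2), slice(2, -2)]
        idx[axis] = slice(2 + k, (-2 + k) or None)
        return gq[tuple(idx)]

    return (sl(1) - sl(-1)) / (2 * h)


def _laplace(gq: np.ndarray, h: float):
    c = gq[2:-2, 2:-2]
    return (
        gq[3:-1, 2:-2] + gq[1:-3, 2:-2] + gq[2:-2, 3:-1] + gq[2:-2, 1:-3] - 4 * c
    ) / h**2


# ---------------------------------------------------------------------------
# face classification
# ---------------------------------------------------------------------------


def _face_phi(phi: np.ndarray):
    """Level-set values at u- and v-faces by averaging adjacent cells."""
    nx, ny = phi.shape
    phi_u = np.empty((nx + 1, ny))
    phi_u[1:-1] = 0.5 * (phi[:-1] + phi[1:])
    phi_u[0] = phi[0]
    phi_u[-1] = phi[-1]
    phi_v = np.empty((nx, ny + 1))
    phi_v[:, 1:-1] = 0.5 * (phi[:, :-1] + phi[:, 1:])
    phi_v[:, 0] = phi[:, 0]
    phi_v[:, -1] = phi[:, -1]
    return phi_u, phi_v


def _classify(mask: np.ndarray, phi_u, phi_v, bc: BoundaryConditions):
    """Projected ('interior') faces: both neighbour cells fluid, face wet."""
    nx, ny = mask.shape
    u_int = np.zeros((nx + 1, ny), dtype=bool)
    u_int[1:-1] = mask[:-1] & mask[1:] & (phi_u[1:-1] > 0)
    if bc.periodic_x:
        wrap = mask[-1] & mask[0]
        u_int[0] = wrap
        u_int[-1] = False  # duplicate face, slaved to u[0]
    v_int = np.zeros((nx, ny + 1), dtype=bool)
    v_int[:, 1:-1] = mask[:, :-1] & mask[:, 1:] & (phi_v[:, 1:-1] > 0)
    if bc.periodic_y:
        wrap = mask[:, -1] & mask[:, 0]
        v_int[:, 0] = wrap
        v_int[:, -1] = False
    return u_int, v_int


def _outlet_faces(grid: UniformGrid, outlet: OutletSpec) -> np.ndarray:
    xc = grid.xc
    sel = (xc >= outlet.xa - 1e-12) & (xc <= outlet.xb + 1e-12)
    if not sel.any():
        raise ValueError("outlet segment has zero length on this grid")
    return sel


# ---------------------------------------------------------------------------
# cached implicit operators
# ---------------------------------------------------------------------------


class _OperatorCache:
    """LU factorizations of the Helmholtz (momentum) and Poisson systems,
    rebuilt only when the phase masks, BCs or dt change."""

    def __init__(self):
        self.key = None
        self.data = None

    def get(self, mask, u_int, v_int, bc: BoundaryConditions, a: float):
        key = (mask.tobytes(), u_int.tobytes(), v_int.tobytes(),
               bc.periodic_x, bc.periodic_y, bc.wall_u_top, bc.wall_u_bottom,
               round(a, 14))
        if self.key == key:
            return self.data
        nx, ny = mask.shape
        lu_u, rc_u = _build_helmholtz_u(nx, ny, u_int, bc, a)
        lu_v, rc_v = _build_helmholtz_v(nx, ny, v_int, bc, a)
        lu_p, index, anchors, labels = _build_poisson(mask, u_int, v_int, bc)
        self.key = key
        self.data = (lu_u, rc_u, lu_v, rc_v, lu_p, index, anchors, labels)
        return self.data


_OPS = _OperatorCache()


def _build_helmholtz_u(nx, ny, u_int, bc, a):
    """(I - a*L) on u-faces; non-projected faces get identity rows."""
    N = (nx + 1) * ny
    fid = lambda i, j: i * ny + j
    I, J = np.meshgrid(np.arange(nx + 1), np.arange(ny), indexing="ij")
    rows_c = fid(I, J).ravel()
    interior = u_int.ravel()
    diag = np.ones(N)
    diag[interior] = 1.0 + 4.0 * a
    rows, cols, vals = [rows_c[interior]], [rows_c[interior]], [diag[interior]]
    rows.append(rows_c[~interior])
    cols.append(rows_c[~interior])
    vals.append(np.ones(int((~interior).sum())))
    rhs_const = np.zeros(N)
    diag_adj = np.zeros(N)

    Ii, Jj = I.ravel(), J.ravel()
    sel = interior

    def couple(di, dj):
        ii = Ii[sel] + di
        jj = Jj[sel] + dj
        rr = rows_c[sel]
        ok = np.ones(len(ii), dtype=bool)
        if di != 0:
            if bc.periodic_x:
                ii = np.where(ii < 0, nx - 1, ii)  # u[-1] == u[nx-1]
                # face nx exists as a slaved duplicate of u[0]
            else:
                ok &= (ii >= 0) & (ii <= nx)
        if dj != 0:
            if bc.periodic_y:
                jj = jj % ny
            else:
                ghost_lo = jj < 0
                ghost_hi = jj >= ny
                wall_val = np.where(ghost_lo, bc.wall_u_bottom, bc.wall_u_top)
                gm = ghost_lo | ghost_hi
                # ghost = 2*u_wall - u_self: fold into diagonal and rhs
                np.add.at(diag_adj, rr[gm], a)
                np.add.at(rhs_const, rr[gm], 2.0 * a * wall_val[gm])
                ok &= ~gm
        rows.append(rr[ok])
        cols.append(fid(ii[ok], jj[ok]))
        vals.append(-a * np.ones(int(ok.sum())))

    couple(1, 0)
    couple(-1, 0)
    couple(0, 1)
    couple(0, -1)
    rows.append(rows_c[interior])
    cols.append(rows_c[interior])
    vals.append(diag_adj[rows_c[interior]])
    if bc.periodic_x:
        # slave rows: u[nx, j] - u[0, j] = 0  (identity part already added)
        r = fid(np.full(ny, nx), np.arange(ny))
        rows.append(r)
        cols.append(fid(np.zeros(ny, int), np.arange(ny)))
        vals.append(-np.ones(ny))
    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return splu(A), rhs_const


def _build_helmholtz_v(nx, ny, v_int, bc, a):
    N = nx * (ny + 1)
    fid = lambda i, j: i * (ny + 1) + j
    I, J = np.meshgrid(np.arange(nx), np.arange(ny + 1), indexing="ij")
    rows_c = fid(I, J).ravel()
    interior = v_int.ravel()
    diag = np.ones(N)
    diag[interior] = 1.0 + 4.0 * a
    rows, cols, vals = [rows_c[interior]], [rows_c[interior]], [diag[interior]]
    rows.append(rows_c[~interior])
    cols.append(rows_c[~interior])
    vals.append(np.ones(int((~interior).sum())))
    rhs_const = np.zeros(N)
    diag_adj = np.zeros(N)
    Ii, Jj = I.ravel(), J.ravel()
    sel = interior

    def couple(di, dj):
        ii = Ii[sel] + di
        jj = Jj[sel] + dj
        rr = rows_c[sel]
        ok = np.ones(len(ii), dtype=bool)
        if dj != 0:
            if bc.periodic_y:
                jj = np.where(jj < 0, ny - 1, jj)
            else:
                ok &= (jj >= 0) & (jj <= ny)
        if di != 0:
            if bc.periodic_x:
                ii = ii % nx
            else:
                gm = (ii < 0) | (ii >= nx)
                # no-slip stationary side walls: ghost = -v_self
                np.add.at(diag_adj, rr[gm], a)
                ok &= ~gm
        rows.append(rr[ok])
        cols.append(fid(ii[ok], jj[ok]))
        vals.append(-a * np.ones(int(ok.sum())))

    couple(1, 0)
    couple(-1, 0)
    couple(0, 1)
    couple(0, -1)
    rows.append(rows_c[interior])
    cols.append(rows_c[interior])
    vals.append(diag_adj[rows_c[interior]])
    if bc.periodic_y:
        r = fid(np.arange(nx), np.full(nx, ny))
        rows.append(r)
        cols.append(fid(np.arange(nx), np.zeros(nx, int)))
        vals.append(-np.ones(nx))
    A = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return splu(A), rhs_const


def _build_poisson(mask, u_int, v_int, bc):
    nx, ny = mask.shape
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, ncomp = nd_label(mask, structure=structure)
    n = int(mask.sum())
    index = -np.ones((nx, ny), dtype=int)
    index[mask] = np.arange(n)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    ii, jj = np.nonzero(mask)
    me = index[ii, jj]

    def couple(di, dj, through):
        nb = index[(ii + di) % nx, (jj + dj) % ny]
        m = through & (nb >= 0)
        rows.append(me[m])
        cols.append(nb[m])
        vals.append(-np.ones(int(m.sum())))
        diag[me[m]] += 1.0

    ueast = u_int[ii + 1, jj].copy()
    if bc.periodic_x:
        ueast |= (ii == nx - 1) & u_int[0, jj]
    couple(1, 0, ueast)
    uwest = u_int[ii, jj]
    couple(-1, 0, uwest)
    vnorth = v_int[ii, jj + 1].copy()
    if bc.periodic_y:
        vnorth |= (jj == ny - 1) & v_int[ii, 0]
    couple(0, 1, vnorth)
    vsouth = v_int[ii, jj]
    couple(0, -1, vsouth)

    rows.append(me)
    cols.append(me)
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tolil()
    anchors = []
    for c in range(1, ncomp + 1):
        cells = np.nonzero(labels == c)
        a = index[cells[0][0], cells[1][0]]
        anchors.append((a, cells[0][0], cells[1][0]))
        A[a, :] = 0.0
        A[a, a] = 1.0
    return splu(sp.csc_matrix(A)), index, anchors, labels


# ---------------------------------------------------------------------------
# time step
# ---------------------------------------------------------------------------


def step_fluid(
    state: FluidState,
    levelsets: list[LevelSetField] | None,
    propagation: PropagationField | None,
    bc: BoundaryConditions,
    dt: float,
) -> FluidState:
    """Advance one projection step; returns a new state.

    ``levelsets`` carry the immersed interfaces (may be None/empty for pure
    channel problems); ``propagation`` is the combined extended interface
    velocity (cm/s) used to force faces inside or touching solids.  Raises
    on convective CFL violation (limit 0.5; diffusion is implicit) and on a
    broken pressure solve.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = state.grid
    h = g.h * CM
    nu = state.props.nu
    nx, ny = g.nx, g.ny

    umax = state.max_speed()
    if propagation is not None:
        umax = max(umax, float(np.abs(propagation.vx).max() * CM),
                   float(np.abs(propagation.vy).max() * CM))
    cfl_c = umax * dt / h
    if cfl_c > 0.5 + 1e-12:
        raise ValueError(f"convective CFL {cfl_c:.3f} exceeds 0.5 "
                         f"(|u|max={umax:.3g} m/s, h={h:.3g} m, dt={dt:.3g} s)")

    if levelsets:
        phi = combined_phi(levelsets)
        mask = phi > 0.0
        phi_u, phi_v = _face_phi(phi)
    else:
        mask = np.ones((nx, ny), dtype=bool)
        phi_u = np.ones((nx + 1, ny))
        phi_v = np.ones((nx, ny + 1))

    u = state.u.copy()
    v = state.v.copy()
    fresh = mask & ~state.mask
    if fresh.any():
        _fill_fresh(u, v, fresh, mask)

    u_int, v_int = _classify(mask, phi_u, phi_v, bc)

    # interface velocity at faces (m/s); propagation field is cm/s
    u_if = np.zeros_like(u)
    v_if = np.zeros_like(v)
    if propagation is not None:
        u_if[1:-1] = 0.5 * (propagation.vx[:-1, :] + propagation.vx[1:, :]) * CM
        v_if[:, 1:-1] = 0.5 * (propagation.vy[:, :-1] + propagation.vy[:, 1:]) * CM
        if levelsets:
            # ghost-fluid values on near-band solid faces: mirror the fluid
            # velocity across the zero contour so the no-slip condition is
            # imposed at the sub-cell interface position (the forcing then
            # varies continuously as the interface moves through the grid,
            # which the strongly-coupled sub-iterations rely on)
            _apply_mirror_ghosts(g, phi, u, v, u_if, v_if, u_int, v_int)

    # ---- predictor: AB2 convection + CN diffusion ------------------------
    gu = _pad_u(u, bc)
    gv = _pad_v(v, bc)
    v_at_u = 0.25 * (gv[1:-2, 2:-3] + gv[2:-1, 2:-3] + gv[1:-2, 3:-2] + gv[2:-1, 3:-2])
    u_at_v = 0.25 * (gu[2:-3, 1:-2] + gu[3:-2, 1:-2] + gu[2:-3, 2:-1] + gu[3:-2, 2:-1])

    if state.scheme == "upwind2":
        conv_u = u * _ddx_upwind2(gu, u, h, 0) + v_at_u * _ddx_upwind2(gu, v_at_u, h, 1)
        conv_v = u_at_v * _ddx_upwind2(gv, u_at_v, h, 0) + v * _ddx_upwind2(gv, v, h, 1)
    elif state.scheme == "central":
        conv_u = u * _ddx_central(gu, h, 0) + v_at_u * _ddx_central(gu, h, 1)
        conv_v = u_at_v * _ddx_central(gv, h, 0) + v * _ddx_central(gv, h, 1)
    else:
        raise ValueError(f"unknown convection scheme {state.scheme!r}")

    if state.conv_prev is not None:
        cu = 1.5 * conv_u - 0.5 * state.conv_prev[0]
        cv = 1.5 * conv_v - 0.5 * state.conv_prev[1]
    else:
        cu, cv = conv_u, conv_v

    a = 0.5 * nu * dt / h**2
    lu_u, rc_u, lu_v, rc_v, lu_p, index, anchors, labels = _OPS.get(
        mask, u_int, v_int, bc, a
    )

    rhs_u = u + dt * (-cu + 0.5 * nu * _laplace(gu, h) + bc.body_force[0])
    rhs_v = v + dt * (-cv + 0.5 * nu * _laplace(gv, h) + bc.body_force[1])
    rhs_u = rhs_u.ravel() + rc_u
    rhs_v = rhs_v.ravel() + rc_v

    # forced faces carry their prescribed values through identity rows
    forced_u = ~u_int
    forced_v = ~v_int
    ru = rhs_u.reshape(nx + 1, ny)
    rv = rhs_v.reshape(nx, ny + 1)
    ru[forced_u] = u_if[forced_u]
    rv[forced_v] = v_if[forced_v]
    out_sel = None
    if bc.outlet is not None:
        out_sel = _outlet_faces(g, bc.outlet)
        width = out_sel.sum() * h
        rv[out_sel, -1] = bc.outlet.flux / width
        rv[~out_sel, -1] = 0.0
    if bc.periodic_x:
        ru[-1] = 0.0  # slave row u[nx] - u[0] = 0
    if bc.periodic_y:
        rv[:, -1] = 0.0

    us = lu_u.solve(rhs_u).reshape(nx + 1, ny)
    vs = lu_v.solve(rhs_v).reshape(nx, ny + 1)

    # ---- exact discrete mass closure per connected component -------------
    _close_mass(us, vs, mask, u_int, v_int, labels, out_sel, h)
    div = np.zeros((nx, ny))
    div[mask] = (
        us[1:, :][mask] - us[:-1, :][mask] + vs[:, 1:][mask] - vs[:, :-1][mask]
    ) / h

    # ---- pressure Poisson -------------------------------------------------
    rhs = np.zeros(int(mask.sum()))
    rhs[index[mask]] = -state.props.rho / dt * div[mask] * h**2
    for anc, ai, aj in anchors:
        rhs[anc] = state.p[ai, aj]
    pvec = lu_p.solve(rhs)
    if not np.all(np.isfinite(pvec)):
        raise RuntimeError("pressure Poisson solve produced non-finite values")
    p = np.zeros((nx, ny))
    p[mask] = pvec[index[mask]]

    # ---- corrector --------------------------------------------------------
    un, vn = us, vs
    dpx = np.zeros_like(us)
    dpx[1:-1] = (p[1:, :] - p[:-1, :]) / h
    if bc.periodic_x:
        dpx[0] = (p[0, :] - p[-1, :]) / h
    dpy = np.zeros_like(vs)
    dpy[:, 1:-1] = (p[:, 1:] - p[:, :-1]) / h
    if bc.periodic_y:
        dpy[:, 0] = (p[:, 0] - p[:, -1]) / h
    un[u_int] -= dt / state.props.rho * dpx[u_int]
    vn[v_int] -= dt / state.props.rho * dpy[v_int]
    if bc.periodic_x:
        un[-1] = un[0]
    if bc.periodic_y:
        vn[:, -1] = vn[:, 0]

    if out_sel is not None:
        p = p - p[out_sel, -1].mean()
    p[~mask] = 0.0

    new = state.copy()
    new.u, new.v, new.p = un, vn, p
    new.mask = mask
    new.t = state.t + dt
    new.conv_prev = (conv_u, conv_v)
    return new


def divergence(state: FluidState) -> np.ndarray:
    """Discrete divergence (1/s) on fluid cells, zero elsewhere."""
    h = state.grid.h * CM
    d = (np.diff(state.u, axis=0) + np.diff(state.v, axis=1)) / h
    d[~state.mask] = 0.0
    return d


def _bilerp(arr: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    nx, ny = arr.shape
    gx = np.clip(gx, 0.0, nx - 1.0)
    gy = np.clip(gy, 0.0, ny - 1.0)
    i0 = np.clip(np.floor(gx).astype(int), 0, max(nx - 2, 0))
    j0 = np.clip(np.floor(gy).astype(int), 0, max(ny - 2, 0))
    tx = gx - i0
    ty = gy - j0
    i1 = np.minimum(i0 + 1, nx - 1)
    j1 = np.minimum(j0 + 1, ny - 1)
    return (arr[i0, j0] * (1 - tx) * (1 - ty) + arr[i1, j0] * tx * (1 - ty)
            + arr[i0, j1] * (1 - tx) * ty + arr[i1, j1] * tx * ty)


def _apply_mirror_ghosts(g, phi, u, v, u_if, v_if, u_int, v_int):
    """Second-order ghost values on solid faces near the interface:
    ``u_ghost = 2 u_interface - u(mirror point)``."""
    h = g.h
    nx, ny = phi.shape
    gxc, gyc = np.gradient(phi, h)
    phi_u, phi_v = _face_phi(phi)

    # u-faces (interior index range 1..nx-1)
    fu = np.zeros_like(u_if, dtype=bool)
    fu[1:-1] = (~u_int[1:-1]) & (phi_u[1:-1] <= 0) & (phi_u[1:-1] > -1.5 * h)
    ii, jj = np.nonzero(fu)
    if len(ii):
        nxv = 0.5 * (gxc[ii - 1, jj] + gxc[np.minimum(ii, nx - 1), jj])
        nyv = 0.5 * (gyc[ii - 1, jj] + gyc[np.minimum(ii, nx - 1), jj])
        nn = np.maximum(np.hypot(nxv, nyv), 1e-12)
        nxv /= nn
        nyv /= nn
        xf = g.x0 + ii * h
        yf = g.y0 + (jj + 0.5) * h
        d = -2.0 * phi_u[ii, jj]
        xm = xf + d * nxv
        ym = yf + d * nyv
        phi_m = _bilerp(phi, (xm - g.x0) / h - 0.5, (ym - g.y0) / h - 0.5)
        ok = phi_m > 0.25 * h  # mirror must land in resolved fluid
        um = _bilerp(u, (xm - g.x0) / h, (ym - g.y0) / h - 0.5)
        vals = 2.0 * u_if[ii, jj] - um
        sel = np.zeros(len(ii), dtype=bool)
        sel[:] = ok
        u_if[ii[sel], jj[sel]] = vals[sel]

    fv = np.zeros_like(v_if, dtype=bool)
    fv[:, 1:-1] = (~v_int[:, 1:-1]) & (phi_v[:, 1:-1] <= 0) \
        & (phi_v[:, 1:-1] > -1.5 * h)
    ii, jj = np.nonzero(fv)
    if len(ii):
        nxv = 0.5 * (gxc[ii, jj - 1] + gxc[ii, np.minimum(jj, ny - 1)])
        nyv = 0.5 * (gyc[ii, jj - 1] + gyc[ii, np.minimum(jj, ny - 1)])
        nn = np.maximum(np.hypot(nxv, nyv), 1e-12)
        nxv /= nn
        nyv /= nn
        xf = g.x0 + (ii + 0.5) * h
        yf = g.y0 + jj * h
        d = -2.0 * phi_v[ii, jj]
        xm = xf + d * nxv
        ym = yf + d * nyv
        phi_m = _bilerp(phi, (xm - g.x0) / h - 0.5, (ym - g.y0) / h - 0.5)
        ok = phi_m > 0.25 * h
        vm = _bilerp(v, (xm - g.x0) / h - 0.5, (ym - g.y0) / h)
        vals = 2.0 * v_if[ii, jj] - vm
        v_if[ii[ok], jj[ok]] = vals[ok]


def _fill_fresh(u, v, fresh, mask):
    ii, jj = np.nonzero(fresh)
    uc = 0.5 * (u[:-1, :] + u[1:, :])
    vc = 0.5 * (v[:, :-1] + v[:, 1:])
    nx, ny = mask.shape
    for i, j in zip(ii, jj):
        vals_u, vals_v = [], []
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and mask[a, b] and not fresh[a, b]:
                vals_u.append(uc[a, b])
                vals_v.append(vc[a, b])
        if vals_u:
            u[i, j] = u[i + 1, j] = np.mean(vals_u)
            v[i, j] = v[i, j + 1] = np.mean(vals_v)


def _close_mass(us, vs, mask, u_int, v_int, labels, out_sel, h):
    """Distribute each component's net boundary-flux mismatch onto its
    forced interface faces (never the outlet, whose flux is the prescribed
    displaced-volume rate)."""
    nx, ny = mask.shape
    div = (np.diff(us, axis=0) + np.diff(vs, axis=1)) / h
    false_col = np.zeros((1, ny), dtype=bool)
    false_row = np.zeros((nx, 1), dtype=bool)
    for c in range(1, int(labels.max()) + 1):
        cmm = labels == c
        m2 = float(div[cmm].sum()) * h * h
        scale = max(np.abs(us).max(), np.abs(vs).max(), 1e-30) * h
        if abs(m2) <= 1e-13 * scale:
            continue
        uL = np.vstack([false_col, cmm])  # (nx+1, ny): left cell in component
        uR = np.vstack([cmm, false_col])
        bu = (~u_int) & (uL ^ uR)
        su = np.where(uL, 1.0, -1.0)
        vD = np.hstack([false_row, cmm])  # (nx, ny+1): lower cell in comp.
        vU = np.hstack([cmm, false_row])
        bv = (~v_int) & (vD ^ vU)
        if out_sel is not None:
            bv[out_sel, -1] = False
        sv = np.where(vD, 1.0, -1.0)
        nfaces = int(bu.sum() + bv.sum())
        if nfaces == 0:
            continue
        dv = -m2 / (nfaces * h)
        us[bu] += su[bu] * dv
        vs[bv] += sv[bv] * dv


# ---------------------------------------------------------------------------
# interface traction and displaced-volume outflow
# ---------------------------------------------------------------------------


def interface_traction(
    state: FluidState, ls: LevelSetField, markers: np.ndarray
) -> np.ndarray:
    """Fluid traction (Pa) at interface markers: ``(-p I + 2 mu S) . n``.

    ``n`` is the unit normal along ``grad(phi)`` (pointing into the fluid),
    so for a hydrostatic field the traction is ``-p n`` — the load the fluid
    presses onto the solid surface.  Pressure and velocity gradients are
    sampled one grid spacing into the fluid (one-sided, sharp interface).
    Markers further than h from the zero contour are rejected.
    """
    markers = np.atleast_2d(np.asarray(markers, float))
    g = state.grid
    h = g.h
    phi_m = interp_cc(g, ls.phi, markers)
    if np.any(np.abs(phi_m) > h):
        k = int(np.argmax(np.abs(phi_m)))
        raise ValueError(
            f"marker {k} at {markers[k]} is {abs(phi_m[k]):.3g} cm from the "
            f"zero contour (> h = {h:.3g} cm)"
        )
    eps = h
    nx_ = (interp_cc(g, ls.phi, markers + [[eps, 0]]) -
           interp_cc(g, ls.phi, markers - [[eps, 0]])) / (2 * eps)
    ny_ = (interp_cc(g, ls.phi, markers + [[0, eps]]) -
           interp_cc(g, ls.phi, markers - [[0, eps]])) / (2 * eps)
    nrm = np.column_stack([nx_, ny_])
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-30)

    # one-sided sampling: fields are first extended into solid cells from
    # the nearest fluid cell, so marker-point interpolation never mixes in
    # undefined solid values (important in thin near-coaptation films,
    # where reaching a full h along the normal would cross the gap)
    uc, vc = state.cell_velocity()
    hm = h * CM
    fill = _nearest_fluid_fill(state.mask)
    p_f = fill(state.p)
    dudx = fill(np.gradient(uc, hm, axis=0))
    dudy = fill(np.gradient(uc, hm, axis=1))
    dvdx = fill(np.gradient(vc, hm, axis=0))
    dvdy = fill(np.gradient(vc, hm, axis=1))
    mu = state.props.mu
    sample = markers + 0.25 * h * nrm
    p_s = interp_cc(g, p_f, sample)
    t_xx = -p_s + 2 * mu * interp_cc(g, dudx, sample)
    t_yy = -p_s + 2 * mu * interp_cc(g, dvdy, sample)
    t_xy = mu * (interp_cc(g, dudy, sample) + interp_cc(g, dvdx, sample))
    tx = t_xx * nrm[:, 0] + t_xy * nrm[:, 1]
    ty = t_xy * nrm[:, 0] + t_yy * nrm[:, 1]
    return np.column_stack([tx, ty])


def _nearest_fluid_fill(mask: np.ndarray):
    """Returns a filler replacing solid-cell values by the nearest fluid
    cell's value (constant extrapolation across the interface)."""
    from scipy.ndimage import distance_transform_edt

    if mask.all():
        return lambda f: f
    _, (ii, jj) = distance_transform_edt(~mask, return_indices=True)

    def fill(f):
        out = f.copy()
        out[~mask] = f[ii[~mask], jj[~mask]]
        return out

    return fill


def polygon_area_rate(polyline: np.ndarray, velocities: np.ndarray) -> float:
    """d/dt of the shoelace area of a moving polygon (cm^2/s, cm inputs)."""
    x = np.asarray(polyline, float)
    vel = np.asarray(velocities, float)
    xn = np.roll(x, -1, axis=0)
    vn = np.roll(vel, -1, axis=0)
    cross = lambda a, b: a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return float(0.5 * np.sum(cross(vel, xn) + cross(x, vn)))


def outflow_bc(
    wall: tuple[np.ndarray, np.ndarray] | None,
    obstacles: list[tuple[np.ndarray, np.ndarray]] = (),
) -> float:
    """Outlet flux (cm^2/s per unit depth) balancing interface motion.

    ``wall`` is the closed flow-domain contour (vertices, vertex velocities);
    ``obstacles`` are closed solid contours immersed in the fluid (leaflets).
    The fluid area is the wall polygon minus the obstacle polygons, so the
    required outflow is ``-dA_wall/dt + sum dA_obs/dt``.
    """
    q = 0.0
    if wall is not None:
        q -= polygon_area_rate(*wall)
    for poly, vel in obstacles:
        q += polygon_area_rate(poly, vel)
    return q
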