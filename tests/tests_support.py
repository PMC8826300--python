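"""Shared verification helpers used by the unit and acceptance suites."""

import numpy as np

from avfsi import fluid as fl
from avfsi import solid
from avfsi.grid import UniformGrid
from avfsi.solid import CM, _assembler


def run_poiseuille(n=64, steps=800, dt=2e-3):
    """Body-force driven periodic channel, marched to steady state."""
    H = 0.01  # m
    g = UniformGrid(4, n, 100 * H / n)
    props = fl.FluidProperties(rho=1000.0, mu=1.0)
    vbar = 0.01
    bc = fl.BoundaryConditions(
        periodic_x=True, body_force=(12 * props.nu * vbar / H**2, 0.0))
    st = fl.FluidState(g, props)
    for _ in range(steps):
        st = fl.step_fluid(st, None, None, bc, dt)
    return st, vbar, H, props


def _taylor_green_state(n, scheme="central", nu=0.01):
    L = 2 * np.pi
    g = UniformGrid(n, n, 100 * L / n)
    st = fl.FluidState(g, fl.FluidProperties(rho=1.0, mu=nu), scheme=scheme)
    xf, yc = np.meshgrid(g.xf * fl.CM, g.yc * fl.CM, indexing="ij")
    st.u = np.cos(xf) * np.sin(yc)
    xc, yf = np.meshgrid(g.xc * fl.CM, g.yf * fl.CM, indexing="ij")
    st.v = -np.sin(xc) * np.cos(yf)
    return g, st


def taylor_green_decay(n=64, T=2.0, nu=0.01):
    """Kinetic-energy ratio after time T vs the analytic exp(-4 nu T)."""
    g, st = _taylor_green_state(n, nu=nu)
    ke0 = np.sum(st.u[:-1] ** 2) + np.sum(st.v[:, :-1] ** 2)
    dt = 0.2 * 2 * np.pi / n
    ns = int(round(T / dt))
    bc = fl.BoundaryConditions(True, True)
    for _ in range(ns):
        st = fl.step_fluid(st, None, None, bc, T / ns)
    ke = np.sum(st.u[:-1] ** 2) + np.sum(st.v[:, :-1] ** 2)
    return float(ke / ke0), float(np.exp(-4 * nu * T))


def taylor_green_error(n, T=0.5, nu=0.01):
    """L2 velocity error vs the analytic solution at time T."""
    g, st = _taylor_green_state(n, nu=nu)
    dt = 0.2 * 2 * np.pi / n
    ns = int(round(T / dt))
    bc = fl.BoundaryConditions(True, True)
    for _ in range(ns):
        st = fl.step_fluid(st, None, None, bc, T / ns)
    xf, yc = np.meshgrid(g.xf * fl.CM, g.yc * fl.CM, indexing="ij")
    xc, yf = np.meshgrid(g.xc * fl.CM, g.yf * fl.CM, indexing="ij")
    dec = np.exp(-2 * nu * T)
    ue = np.cos(xf) * np.sin(yc) * dec
    ve = -np.sin(xc) * np.cos(yf) * dec
    return float(np.sqrt(np.mean(
        (st.u[:-1] - ue[:-1]) ** 2 + (st.v[:, :-1] - ve[:, :-1]) ** 2)))


def poiseuille_analytic_state(n=64, vbar=0.01, H=0.01, mu=1.0, nx=6):
    """Analytic parabolic profile loaded into a FluidState (for metrics)."""
    g = UniformGrid(nx, n, 100 * H / n)
    st = fl.FluidState(g, fl.FluidProperties(rho=1000.0, mu=mu))
    y = g.yc * fl.CM
    st.u[:, :] = 6.0 * vbar * y * (H - y) / H**2
    return st, g, vbar, H, mu


def static_solve(mesh, f_ext, tol=1e-12, max_iter=40):
    """Quasi-static Newton solve; returns nodal displacement in metres."""
    asm = _assembler(mesh)
    free = ~mesh.fixed.reshape(-1)
    d = np.zeros(mesh.n_dof)
    fe = np.asarray(f_ext).reshape(-1)
    for _ in range(max_iter):
        fi, K = asm.internal_forces(d.reshape(-1, 2) / CM, with_tangent=True)
        R = fi.reshape(-1) - fe
        if np.abs(R[free]).max() <= tol * max(np.abs(fe).max(), 1e-30) + 1e-30:
            break
        d[free] -= np.linalg.solve(K[np.ix_(free, free)], R[free])
    return d.reshape(-1, 2)


def patch_residual():
    """Constant-strain patch test: interior residual over force scale."""
    mat = solid.isotropic_fung_constants(100.0, 0.3)
    nodes = np.array([[0, 0], [2, 0], [2, 1], [0, 1], [0.6, 0.4],
                      [1.5, 0.3], [1.4, 0.7], [0.5, 0.65]], float)
    elems = np.array([[0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6],
                      [3, 0, 4, 7], [4, 5, 6, 7]])
    mesh = solid.LeafletMesh(nodes, elems, mat)
    exx, eyy, gxy = 1e-3, -5e-4, 8e-4
    mesh.disp = np.column_stack([
        exx * nodes[:, 0] + 0.5 * gxy * nodes[:, 1],
        eyy * nodes[:, 1] + 0.5 * gxy * nodes[:, 0],
    ])
    f = solid.assemble_internal_forces(mesh)
    return float(np.abs(f[4:]).max() / np.abs(f).max())


def cantilever_ratios():
    """Slender-cantilever tip deflection over Euler-Bernoulli, per element."""
    L, t = 10.0, 0.1  # cm; length/thickness = 100
    mat = solid.isotropic_fung_constants(100.0, 0.0)
    E_pa = 100.0e3
    I = (t * CM) ** 3 / 12.0
    P = 1e-7 * 3 * E_pa * I / (L * CM) ** 3
    exact = P * (L * CM) ** 3 / (3 * E_pa * I)
    out = {}
    for etype in ("eas", "q4"):
        m = solid.rectangular_mesh(L, t, 20, 1, mat, element_type=etype)
        m.fixed[np.isclose(m.nodes[:, 0], 0.0)] = True
        fext = np.zeros_like(m.nodes)
        tip = np.isclose(m.nodes[:, 0], L)
        fext[tip, 1] = P / tip.sum()
        d = static_solve(m, fext)
        out[etype] = float(d[tip, 1].mean() / exact)
    return out
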