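"""Haemodynamic evaluation suite.

Pure post-processing of flow fields and leaflet level sets: valve orifice
(gap and a circular pseudo-area surrogate for the clinical AVA),
transvalvular pressure gradient (LVOT minus ascending aorta, mmHg), peak
systolic velocity, wall shear stress, Q-criterion vortex identification,
the viscous dissipation function ``Phi = 2 mu S:S`` and the Reynolds number
``Re = rho V D / mu``.  Re-running the suite on saved fields reproduces the
report bitwise — nothing here mutates solver state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluid import CM, FluidProperties, FluidState
from .grid import UniformGrid, interp_cc
from .levelset import LevelSetField

MMHG = 133.322  # Pa per mmHg


def reynolds(v_mean: float, d: float, props: FluidProperties) -> float:
    """Re = rho V D / mu (V in m/s, D in m)."""
    if v_mean < 0 or d <= 0:
        raise ValueError("velocity must be >= 0 and diameter > 0")
    return props.rho * v_mean * d / props.mu


def orifice_area(
    leaflet_levelsets: list[LevelSetField],
    valve_plane_y: float,
    *,
    x_limits: tuple[float, float] | None = None,
    n_samples: int = 2000,
) -> tuple[float, float]:
    """Open gap (cm) between leaflet zero contours on the valve plane and
    the circular pseudo-area pi (gap/2)^2 (cm^2).

    The pseudo-area is a 2D-derived surrogate for the clinical aortic valve
    area: it is the area of the circle whose diameter equals the measured
    gap, reported for qualitative comparison only.

    The gap is the contiguous open run of the valve plane that contains the
    root centreline — fluid in the sinus recesses *behind* the leaflets is
    not orifice.
    """
    if not leaflet_levelsets:
        raise ValueError("need at least one leaflet level set")
    g = leaflet_levelsets[0].grid
    if not (g.y0 < valve_plane_y < g.y0 + g.ly):
        raise ValueError("valve plane misses the computational domain")
    xa, xb = x_limits if x_limits else (g.x0, g.x0 + g.lx)
    xs = np.linspace(xa, xb, n_samples)
    pts = np.column_stack([xs, np.full(n_samples, valve_plane_y)])
    phi = np.min(
        [interp_cc(g, ls.phi, pts) for ls in leaflet_levelsets], axis=0
    )
    dx = xs[1] - xs[0]
    open_ = phi > 0.0
    mid = int(np.argmin(np.abs(xs - 0.5 * (xa + xb))))
    if not open_[mid]:
        gap = 0.0
    else:
        lo = mid
        while lo > 0 and open_[lo - 1]:
            lo -= 1
        hi = mid
        while hi < len(xs) - 1 and open_[hi + 1]:
            hi += 1
        gap = float((hi - lo + 1) * dx)
    return gap, float(np.pi * (gap / 2.0) ** 2)


def transvalvular_gradient(
    state: FluidState,
    lvot_box: tuple[float, float, float, float],
    aao_box: tuple[float, float, float, float],
) -> float:
    """Area-averaged p(LVOT box) - p(AAo box) in mmHg.

    Boxes are (xa, xb, ya, yb) in cm and must contain fluid cells.
    """

    def box_mean(box):
        xa, xb, ya, yb = box
        g = state.grid
        X, Y = np.meshgrid(g.xc, g.yc, indexing="ij")
        sel = (X >= xa) & (X <= xb) & (Y >= ya) & (Y <= yb) & state.mask
        if not sel.any():
            raise ValueError(f"probe box {box} contains no fluid cells")
        return float(state.p[sel].mean())

    return (box_mean(lvot_box) - box_mean(aao_box)) / MMHG


def wall_shear_stress(
    state: FluidState,
    wall_ls: LevelSetField,
    markers: np.ndarray,
) -> np.ndarray:
    """WSS (Pa) at stationary wall markers: ``tau = mu du_t/dn`` one-sided.

    The tangential velocity is sampled at one and two grid spacings along
    the inward (fluid) normal; a second-order one-sided difference with the
    no-slip wall value (zero) gives the normal gradient.
    """
    markers = np.atleast_2d(np.asarray(markers, float))
    g = state.grid
    h = g.h
    eps = h
    nx_ = (interp_cc(g, wall_ls.phi, markers + [[eps, 0]]) -
           interp_cc(g, wall_ls.phi, markers - [[eps, 0]])) / (2 * eps)
    ny_ = (interp_cc(g, wall_ls.phi, markers + [[0, eps]]) -
           interp_cc(g, wall_ls.phi, markers - [[0, eps]])) / (2 * eps)
    nrm = np.column_stack([nx_, ny_])
    nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-30)
    tang = np.column_stack([-nrm[:, 1], nrm[:, 0]])

    uc, vc = state.cell_velocity()
    out = np.empty(len(markers))
    hm = h * CM
    for k, (m, n, tg) in enumerate(zip(markers, nrm, tang)):
        p1 = m + h * n
        p2 = m + 2 * h * n
        ut1 = interp_cc(g, uc, [p1])[0] * tg[0] + interp_cc(g, vc, [p1])[0] * tg[1]
        ut2 = interp_cc(g, uc, [p2])[0] * tg[0] + interp_cc(g, vc, [p2])[0] * tg[1]
        out[k] = state.props.mu * (4.0 * ut1 - ut2) / (2.0 * hm)
    return out


def _gradients(state: FluidState):
    uc, vc = state.cell_velocity()
    hm = state.grid.h * CM
    dudx = np.gradient(uc, hm, axis=0)
    dudy = np.gradient(uc, hm, axis=1)
    dvdx = np.gradient(vc, hm, axis=0)
    dvdy = np.gradient(vc, hm, axis=1)
    return dudx, dudy, dvdx, dvdy


def q_criterion(state: FluidState) -> np.ndarray:
    """Q = (|Omega|_F^2 - |S|_F^2)/2 (1/s^2) at cell centres.

    Positive where rotation dominates strain: zero for pure shear and
    uniform flow, Omega^2 for solid-body rotation at rate Omega.
    """
    dudx, dudy, dvdx, dvdy = _gradients(state)
    s12 = 0.5 * (dudy + dvdx)
    w12 = 0.5 * (dudy - dvdx)
    normS2 = dudx**2 + dvdy**2 + 2.0 * s12**2
    normW2 = 2.0 * w12**2
    q = 0.5 * (normW2 - normS2)
    q[~state.mask] = 0.0
    return q


def viscous_dissipation(
    state: FluidState, region: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Pointwise ``Phi = 2 mu S:S`` (W/m^3) and its integral over the fluid
    area (W per metre of depth); ``region`` restricts the integral (e.g. to
    the ascending aorta, where the comparative evaluation reports energy
    loss)."""
    dudx, dudy, dvdx, dvdy = _gradients(state)
    s12 = 0.5 * (dudy + dvdx)
    phi = 2.0 * state.props.mu * (dudx**2 + dvdy**2 + 2.0 * s12**2)
    phi[~state.mask] = 0.0
    sel = phi if region is None else np.where(region, phi, 0.0)
    total = float(sel.sum() * (state.grid.h * CM) ** 2)
    return phi, total


def kinetic_energy(state: FluidState) -> float:
    """J per metre of depth, over fluid cells."""
    uc, vc = state.cell_velocity()
    ke = 0.5 * state.props.rho * (uc**2 + vc**2)
    ke[~state.mask] = 0.0
    return float(ke.sum() * (state.grid.h * CM) ** 2)


def peak_velocity(state: FluidState, region: np.ndarray | None = None) -> float:
    """Max |u| (m/s) over fluid cells, optionally within a region (the
    clinical peak systolic velocity is read in the ascending aorta)."""
    uc, vc = state.cell_velocity()
    sp = np.hypot(uc, vc)
    sp[~state.mask] = 0.0
    if region is not None:
        sp = np.where(region, sp, 0.0)
    return float(sp.max())


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-run haemodynamic time series and summary scalars."""

    time: list[float] = field(default_factory=list)
    gap: list[float] = field(default_factory=list)  # cm
    pseudo_ava: list[float] = field(default_factory=list)  # cm^2
    delta_p: list[float] = field(default_factory=list)  # mmHg
    peak_velocity: list[float] = field(default_factory=list)  # m/s
    wss_max: list[float] = field(default_factory=list)  # Pa
    q_max: list[float] = field(default_factory=list)  # 1/s^2
    dissipation_total: list[float] = field(default_factory=list)  # W/m depth
    re_aao: float = 0.0
    config: str = ""

    def summary(self) -> dict:
        t = np.asarray(self.time)

        def arr(x):
            return np.asarray(x) if len(x) else np.zeros(1)

        def robust(x):
            # reject single-sample solver transients before taking peaks
            x = arr(x)
            if len(x) < 3:
                return x
            from scipy.signal import medfilt

            return medfilt(x, 3)

        gap = robust(self.gap)
        vel = robust(self.peak_velocity)
        out = {
            "config": self.config,
            "gap_max_cm": float(gap.max()),
            "pseudo_ava_max_cm2": float(robust(self.pseudo_ava).max()),
            "delta_p_peak_mmhg": float(robust(self.delta_p).max()),
            "peak_velocity_ms": float(vel.max()),
            "wss_max_pa": float(robust(self.wss_max).max()),
            "dissipation_integral_j_per_m": float(
                np.trapezoid(arr(self.dissipation_total), t)
            ) if len(t) > 1 else 0.0,
            "re_aao": self.re_aao,
        }
        if len(t):
            out["t_gap_max_ms"] = float(t[int(gap.argmax())] * 1e3)
            out["t_velocity_peak_ms"] = float(t[int(vel.argmax())] * 1e3)
        return out

    def to_csv(self, path) -> None:
        cols = ["time", "gap", "pseudo_ava", "delta_p", "peak_velocity",
                "wss_max", "q_max", "dissipation_total"]
        data = np.column_stack([np.asarray(getattr(self, c)) for c in cols])
        header = ",".join(cols)
        np.savetxt(path, data, delimiter=",", header=header, comments="")


def comparative_report(runs: dict[str, MetricsReport]) -> dict:
    """Ranking table over the SAV/NAV/TAVR comparative experiment.

    Requires all three configurations (same anatomy and driver — enforced
    upstream) and emits the summary metrics per valve plus ordinal flags
    for the directional findings: the stenosed valve opens less, jets
    faster, carries a larger transvalvular gradient, dissipates more energy
    and loads the aortic wall with higher WSS than the de-calcified valve,
    with the prosthesis in between on opening.
    """
    for cfg in ("SAV", "NAV", "TAVR"):
        if cfg not in runs:
            raise ValueError(f"missing run for configuration {cfg}")
    s = {cfg: runs[cfg].summary() for cfg in ("SAV", "NAV", "TAVR")}

    def flag(key, a="SAV", b="NAV", sense=1):
        va, vb = s[a][key], s[b][key]
        if va == vb:
            return "tie"
        return "yes" if (va - vb) * sense > 0 else "no"

    flags = {
        "sav_smaller_orifice": flag("gap_max_cm", sense=-1),
        "sav_higher_peak_velocity": flag("peak_velocity_ms"),
        "sav_higher_gradient": flag("delta_p_peak_mmhg"),
        "sav_higher_dissipation": flag("dissipation_integral_j_per_m"),
        "sav_higher_wss": flag("wss_max_pa"),
        "tavr_orifice_between": (
            "tie"
            if s["SAV"]["gap_max_cm"] == s["NAV"]["gap_max_cm"]
            else (
                "yes"
                if s["SAV"]["gap_max_cm"]
                <= s["TAVR"]["gap_max_cm"]
                <= s["NAV"]["gap_max_cm"]
                else "no"
            )
        ),
    }
    return {"summaries": s, "flags": flags}
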