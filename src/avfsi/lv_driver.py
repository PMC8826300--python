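"""Prescribed left-ventricular wall contraction.

The spatial contraction rate along the LV wall is a product of Gaussians,
one per active coordinate,

.. math:: f(x, t) = a \\, e^{-(x - b)^2 / (2 c^2)} \\Big|_{x, z}

with centre/width constants ``b = (-1.4, -1.6, -2.6)`` and
``c = (0.58, 0.5, 0.8)`` per (x, y, z); in the 2D mid-plane the y entry is
inactive.  The amplitude ``a`` (cm/s) is calibrated so the wall sweeps the
prescribed end-diastolic-to-end-systolic area difference over one systole
(1/3 of the cardiac cycle at the configured heart rate).  A half-sine
temporal envelope ramps the rate from zero at systole onset to a mid-systolic
peak and back, avoiding impulsive starts.

Wall kinematics: septal markers move strictly along the inward normal;
lateral markers additionally carry a longitudinal (toward-base) component.
Markers on the LVOT, sinus and aorta are stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fluid import polygon_area_rate


@dataclass
class LVDriverParams:
    a: float = 1.0  # cm/s contraction-rate scale (calibrated)
    b: tuple[float, float, float] = (-1.4, -1.6, -2.6)
    c: tuple[float, float, float] = (0.58, 0.5, 0.8)
    heart_rate: float = 70.0  # bpm
    systole_fraction: float = 1.0 / 3.0
    #: 2D stroke: swept area per unit depth over one systole.  Chosen so
    #: desk-grid valve films see jets in the 0.1-1 m/s range (the 3D
    #: patient stroke has no direct 2D equivalent; comparisons between
    #: valve configurations are ordinal and unaffected by the scale).
    edv_to_esv_delta: float = 4.0  # cm^2 swept per unit depth (2D)
    lateral_long_frac: float = 0.3  # longitudinal share of lateral motion
    envelope: str = "half_sine"

    def __post_init__(self) -> None:
        if not all(ci > 0 for ci in self.c):
            raise ValueError("Gaussian width constants must be positive")
        if not 0 < self.systole_fraction <= 1:
            raise ValueError("systole_fraction must lie in (0, 1]")

    @property
    def systolic_duration(self) -> float:
        """Seconds: 60/heart_rate * systole_fraction."""
        return 60.0 / self.heart_rate * self.systole_fraction


def envelope(t: float, params: LVDriverParams) -> float:
    """Temporal envelope in [0, 1]; zero outside systole."""
    T = params.systolic_duration
    if t < 0 or t > T:
        return 0.0
    if params.envelope == "half_sine":
        return float(np.sin(np.pi * t / T))
    if params.envelope == "constant":
        return 1.0
    raise ValueError(f"unknown envelope {params.envelope!r}")


def contraction_rate(
    xnorm: np.ndarray, t: float, params: LVDriverParams
) -> np.ndarray:
    """Contraction-rate magnitude f (cm/s) at normalized wall coordinates.

    ``xnorm`` has shape (N, 2): the (x, z) entries of the normalized frame
    (the y entry is inactive in 2D).  Pure function of its arguments.
    """
    xn = np.atleast_2d(np.asarray(xnorm, float))
    bx, _, bz = params.b
    cx, _, cz = params.c
    gx = np.exp(-((xn[:, 0] - bx) ** 2) / (2.0 * cx**2))
    gz = np.exp(-((xn[:, 1] - bz) ** 2) / (2.0 * cz**2))
    return params.a * gx * gz * envelope(t, params)


def normalized_coords(bundle) -> np.ndarray:
    """Map LV wall vertices into the Gaussian frame.

    The transverse position (x over the LV semi-axis) and the longitudinal
    fraction zeta (0 at base, 1 at apex) are scaled into the frame so that
    the Gaussian peak sits at the mid-ventricular free wall: x_hat = b_x +
    sqrt(2) c_x xi and z_hat = b_z + sqrt(2) c_z (2 zeta - 1).  The absolute
    frame of the printed constants is not fully determined by the formula;
    this mapping is the package's documented choice and is config-free.
    """
    from .geometry import GeometryBundle  # cycle guard

    p = bundle.params
    xi = bundle.wall_contour[:, 0] / (p.lv_short_axis / 2.0)
    zeta = bundle.wall_zeta
    bx, _, bz = bundle_driver_b(bundle)
    cx, _, cz = bundle_driver_c(bundle)
    xhat = bx + np.sqrt(2.0) * cx * xi
    zhat = bz + np.sqrt(2.0) * cz * (2.0 * zeta - 1.0)
    return np.column_stack([xhat, zhat])


def bundle_driver_b(bundle):
    return getattr(bundle, "driver_b", (-1.4, -1.6, -2.6))


def bundle_driver_c(bundle):
    return getattr(bundle, "driver_c", (0.58, 0.5, 0.8))


def _inward_normals(contour: np.ndarray) -> np.ndarray:
    """Unit normals pointing into a CCW polygon at each vertex."""
    nxt = np.roll(contour, -1, axis=0)
    prv = np.roll(contour, 1, axis=0)
    tang = nxt - prv
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-30)
    # CCW polygon: interior is to the left of the tangent
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def wall_velocity_field(
    bundle, t: float, params: LVDriverParams, contour: np.ndarray | None = None
) -> np.ndarray:
    """Velocity (cm/s) of every wall-contour vertex at time t.

    ``contour`` may be the current (deformed) contour; labels and normalized
    coordinates stay attached to the reference vertices.  Septal markers
    move along the inward normal with magnitude f; lateral markers get the
    full vector form (normal plus longitudinal toward-base component);
    everything else is stationary.  Raises on unlabelled markers.
    """
    labels = bundle.wall_labels
    if any(lab not in ("septal", "lateral", "fixed", "outlet") for lab in labels):
        bad = next(l for l in labels if l not in ("septal", "lateral", "fixed", "outlet"))
        raise ValueError(f"unlabelled wall marker kind {bad!r}")
    cur = bundle.wall_contour if contour is None else contour
    nrm = _inward_normals(cur)
    f = contraction_rate(normalized_coords(bundle), t, params)
    vel = np.zeros_like(cur)
    septal = np.array([lab == "septal" for lab in labels])
    lateral = np.array([lab == "lateral" for lab in labels])
    vel[septal] = f[septal, None] * nrm[septal]
    vel[lateral] = f[lateral, None] * nrm[lateral]
    vel[lateral, 1] += params.lateral_long_frac * f[lateral]  # toward base (+y)
    return vel


def sweep_contour(
    bundle, params: LVDriverParams, n_steps: int = 64
):
    """Integrate the wall motion over one systole (explicit midpoint).

    Returns (contour at end systole, swept area in cm^2).
    """
    T = params.systolic_duration
    dt = T / n_steps
    cur = bundle.wall_contour.copy()
    a0 = _polygon_area(cur)
    for k in range(n_steps):
        t = k * dt
        v1 = wall_velocity_field(bundle, t, params, cur)
        mid = cur + 0.5 * dt * v1
        v2 = wall_velocity_field(bundle, t + 0.5 * dt, params, mid)
        cur = cur + dt * v2
    return cur, a0 - _polygon_area(cur)


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def calibrate_amplitude(
    bundle, params: LVDriverParams, *, rel_tol: float = 1e-3, n_steps: int = 64
) -> float:
    """Find the rate scale ``a`` whose systolic sweep equals the target.

    Bisection to 0.1 % of ``edv_to_esv_delta``; raises if the bracket cannot
    be established (e.g. the wall cannot sweep that much area).
    """
    target = params.edv_to_esv_delta
    if target == 0:
        return 0.0
    if target < 0:
        raise ValueError("edv_to_esv_delta must be non-negative")
    chamber = _polygon_area(bundle.wall_contour)
    if target >= 0.9 * chamber:
        raise RuntimeError(
            f"calibration bracket not found: target sweep {target} cm^2 "
            f"approaches the whole chamber area {chamber:.1f} cm^2")

    def sweep(a):
        return sweep_contour(bundle, replace(params, a=a), n_steps)[1]

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if sweep(hi) >= target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("calibration bracket not found: wall cannot sweep "
                           f"{target} cm^2")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        s = sweep(mid)
        if abs(s - target) <= rel_tol * target:
            return mid
        if s < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def displaced_volume_rate(bundle, t, params, contour=None) -> float:
    """Instantaneous fluid-volume displacement rate by the LV wall
    (cm^2/s per unit depth) — the driver-side half of the mass-consistency
    check against the outflow bookkeeping."""
    cur = bundle.wall_contour if contour is None else contour
    vel = wall_velocity_field(bundle, t, params, cur)
    return -polygon_area_rate(cur, vel)
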