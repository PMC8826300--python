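"""Parameterized 2D LV-LVOT-sinus-aorta anatomy with valve leaflets.

A long-axis mid-plane reduction of the aortic-root anatomy, standing in for
CT-derived patient geometry: an idealized left ventricle (closed at the
mitral side — the mitral valve is taken fully closed during systolic
ejection), a straight outflow tract, a sinus-of-Valsalva bulge (a smooth
cosine-type widening, needed for the retro-leaflet vortex to form), and a
straight ascending aorta whose top edge is the single outlet.

Three valve configurations share the identical wall contour and outlet, so
downstream comparisons isolate valve effects:

* ``NAV`` — de-calcified native valve: two flexible leaflets (circular-arc
  reference shape) attached at the annulus edges, nearly coapted.
* ``SAV`` — stenosed valve: same leaflets with the Fung stress scale ``c``
  multiplied 10-fold uniformly (calcific stiffening).
* ``TAVR`` — a 23 mm-class prosthesis: new (pericardial) leaflets attached
  to a ring of ``tavr_ring_diameter``, with the pushed-aside native
  leaflets frozen as static no-slip obstacles between ring and sinus wall.

All coordinates in cm; the valve (annulus) plane is y = 0 and the LV lies
below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
from scipy.interpolate import PchipInterpolator

from .solid import FungMaterial, LeafletMesh, strip_mesh

CONFIGS = ("SAV", "NAV", "TAVR")

#: native-leaflet exponential material.  The exponent constants are
#: literature-scale for aortic leaflet tissue; the stress scale and the 2D
#: strip thickness are chosen so the strip's bending rigidity stands in
#: for the 3D leaflet's combined bending + membrane + commissural support
#: (a thin 2D strip at tissue-test moduli would flutter freely, which a
#: supported 3D leaflet does not).
NATIVE_MATERIAL = FungMaterial(
    c=8.0, A=(40.0, 40.0, 20.0, 20.0, 0.0, 0.0), thickness=0.08, rho_s=1100.0
)
#: bovine-pericardium-class TAVR leaflet set (stiffer, slightly thinner)
TAVR_MATERIAL = FungMaterial(
    c=12.0, A=(40.0, 40.0, 20.0, 20.0, 0.0, 0.0), thickness=0.07, rho_s=1100.0
)


@dataclass
class AnatomyParams:
    """Geometric parameters (cm).  Defaults give a 3.3 cm ascending aorta
    (the patient-averaged diameter the evaluation metrics are anchored to);
    a mildly dilated 3.6 cm variant is a single-parameter change."""

    lv_long_axis: float = 7.0
    lv_short_axis: float = 4.6
    lvot_width: float = 2.2
    aorta_diameter: float = 3.3
    sinus_bulge_depth: float = 0.7
    aorta_length: float = 3.5
    leaflet_length: float = 1.7
    leaflet_thickness: float = 0.08
    config: str = "NAV"
    tavr_ring_diameter: float = 2.3
    seed: int = 0
    # secondary shape parameters (config-exposed, not patient targets)
    lvot_length: float = 1.2
    sinus_length_frac: float = 0.55  # sinus length / aorta diameter
    initial_gap_frac: float = 0.02  # leaflet coaptation gap / aorta diameter
    tavr_ring_height: float = 0.35  # ring anchor height above the annulus
    tavr_leaflet_length: float | None = None
    contour_noise: float = 0.0  # optional seeded wall perturbation (cm)
    ds: float = 0.06  # wall sampling interval (cm)
    leaflet_elements: int = 24  # elements along each leaflet
    leaflet_thickness_elements: int = 1

    def __post_init__(self) -> None:
        for name in ("lv_long_axis", "lv_short_axis", "lvot_width",
                     "aorta_diameter", "sinus_bulge_depth", "aorta_length",
                     "leaflet_length", "leaflet_thickness"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.config not in CONFIGS:
            raise ValueError(f"config must be one of {CONFIGS}")
        if self.leaflet_length >= self.aorta_diameter:
            raise ValueError("leaflets longer than the aortic root")
        if self.config == "TAVR" and self.tavr_ring_diameter > self.aorta_diameter:
            raise ValueError("TAVR ring wider than the aorta")
        if self.lvot_width >= self.lv_short_axis:
            raise ValueError("LVOT wider than the ventricle")


@dataclass
class GeometryBundle:
    """Closed flow domain with labelled wall markers and valve structures."""

    params: AnatomyParams
    wall_contour: np.ndarray  # (N,2) closed CCW polyline, cm
    wall_labels: list[str]  # per vertex: septal/lateral/fixed/outlet
    wall_zeta: np.ndarray  # longitudinal fraction (LV only; 0 elsewhere)
    outlet_segment: np.ndarray  # (2,2): endpoints of the outlet edge
    leaflets: list[LeafletMesh]
    leaflet_centerlines: list[np.ndarray]
    static_obstacles: list[np.ndarray] = field(default_factory=list)
    valve_y: float = 0.0
    leaflet_rise: float = 0.0

    def lv_wall_segment(self) -> np.ndarray:
        sel = [lab in ("septal", "lateral") for lab in self.wall_labels]
        return self.wall_contour[np.array(sel)]

    def outlet_width(self) -> float:
        return float(abs(self.outlet_segment[1, 0] - self.outlet_segment[0, 0]))

    def bounding_box(self, margin: float = 0.0):
        lo = self.wall_contour.min(axis=0) - margin
        hi = self.wall_contour.max(axis=0) + margin
        return lo, hi

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "wall_contour": self.wall_contour.tolist(),
            "wall_labels": self.wall_labels,
            "wall_zeta": self.wall_zeta.tolist(),
            "outlet_segment": self.outlet_segment.tolist(),
            "leaflet_centerlines": [c.tolist() for c in self.leaflet_centerlines],
            "leaflet_materials": [
                {"c": m.material.c, "A": list(m.material.A),
                 "thickness": m.material.thickness, "rho_s": m.material.rho_s,
                 "q_variant": m.material.q_variant}
                for m in self.leaflets
            ],
            "static_obstacles": [o.tolist() for o in self.static_obstacles],
            "valve_y": self.valve_y,
            "leaflet_rise": self.leaflet_rise,
            "units": "cm",
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryBundle":
        params = AnatomyParams(**d["params"])
        leaflets, centerlines = [], []
        for cl, mspec in zip(d["leaflet_centerlines"], d["leaflet_materials"]):
            cl = np.asarray(cl)
            mat = FungMaterial(c=mspec["c"], A=tuple(mspec["A"]),
                               thickness=mspec["thickness"],
                               rho_s=mspec["rho_s"],
                               q_variant=mspec["q_variant"])
            leaflets.append(_mesh_leaflet(cl, mat, params))
            centerlines.append(cl)
        return cls(
            params=params,
            wall_contour=np.asarray(d["wall_contour"]),
            wall_labels=list(d["wall_labels"]),
            wall_zeta=np.asarray(d["wall_zeta"]),
            outlet_segment=np.asarray(d["outlet_segment"]),
            leaflets=leaflets,
            leaflet_centerlines=centerlines,
            static_obstacles=[np.asarray(o) for o in d["static_obstacles"]],
            valve_y=d["valve_y"],
            leaflet_rise=d["leaflet_rise"],
        )

    @classmethod
    def load_json(cls, path) -> "GeometryBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _resample(points: np.ndarray, ds: float) -> np.ndarray:
    """Resample an open polyline to roughly uniform spacing ds."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(s[-1] / ds)) + 1)
    si = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(si, s, points[:, 0]), np.interp(si, s, points[:, 1])]
    )


def _arc(a: np.ndarray, b: np.ndarray, arc_len: float, bulge_dir: np.ndarray,
         n: int) -> np.ndarray:
    """Circular arc from a to b with given arc length, bulging toward
    bulge_dir; n+1 sample points."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = float(np.linalg.norm(b - a))
    if c >= arc_len:
        raise ValueError("arc chord exceeds requested arc length")
    # solve sin(theta)/theta = c/arc_len for half-angle theta
    lo, hi = 1e-9, np.pi - 1e-9
    ratio = c / arc_len
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.sin(mid) / mid > ratio:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    R = c / (2.0 * np.sin(theta))
    mid_pt = 0.5 * (a + b)
    perp = np.array([-(b - a)[1], (b - a)[0]]) / c
    if np.dot(perp, bulge_dir) > 0:
        perp = -perp  # centre sits opposite the bulge
    centre = mid_pt + perp * R * np.cos(theta)
    ang_a = np.arctan2(a[1] - centre[1], a[0] - centre[0])
    ang_b = np.arctan2(b[1] - centre[1], b[0] - centre[0])
    dang = (ang_b - ang_a + np.pi) % (2 * np.pi) - np.pi
    angs = ang_a + np.linspace(0.0, dang, n + 1)
    return centre + R * np.column_stack([np.cos(angs), np.sin(angs)])


def _mesh_leaflet(centerline: np.ndarray, material: FungMaterial,
                  params: AnatomyParams) -> LeafletMesh:
    mesh = strip_mesh(
        _resample(centerline, np.linalg.norm(centerline[-1] - centerline[0])
                  / params.leaflet_elements),
        material.thickness,
        params.leaflet_thickness_elements,
        material,
    )
    # clamp the attachment (root) cross-section
    nt = params.leaflet_thickness_elements + 1
    mesh.fixed[:nt, :] = True
    return mesh


def _leaflet_pair(params: AnatomyParams, x_attach: float, y_attach: float,
                  length: float, material: FungMaterial,
                  chord_frac: float = 0.92):
    gap = params.initial_gap_frac * params.aorta_diameter
    dx = x_attach - gap / 2.0
    chord = chord_frac * length
    if chord <= dx:
        raise ValueError("leaflet too short to span the root")
    rise = float(np.sqrt(chord**2 - dx**2))
    meshes, centerlines = [], []
    for s in (-1.0, 1.0):
        a = np.array([s * x_attach, y_attach])
        b = np.array([s * gap / 2.0, y_attach + rise])
        cl = _arc(a, b, length, bulge_dir=np.array([s, 0.0]),
                  n=params.leaflet_elements)
        mat = FungMaterial(material.c, material.A, material.thickness,
                           material.rho_s, material.q_variant)
        m = _mesh_leaflet(cl, mat, params)
        m.label = f"leaflet-{1 if s < 0 else 2}"
        meshes.append(m)
        centerlines.append(cl)
    return meshes, centerlines, rise


def make_anatomy(params: AnatomyParams | None = None,
                 native_material: FungMaterial = NATIVE_MATERIAL,
                 tavr_material: FungMaterial = TAVR_MATERIAL) -> GeometryBundle:
    """Build the synthetic anatomy for one valve configuration.

    Deterministic: identical params (including seed) give byte-identical
    geometry.  The wall contour is identical across the three configs built
    from the same parameters; only leaflets and static obstacles differ.
    """
    p = params or AnatomyParams()
    D2 = p.aorta_diameter / 2.0
    wl = p.lvot_width / 2.0
    Ls = p.sinus_length_frac * p.aorta_diameter
    ytop = Ls + p.aorta_length
    ybase = -p.lvot_length
    yapex = ybase - p.lv_long_axis
    a_s = p.lv_short_axis / 2.0
    ds = p.ds

    # half-width of the sinus region vs height (0 at annulus, 1 at STJ)
    def sinus_w(tau):
        s = 3 * tau**2 - 2 * tau**3
        return wl + (D2 - wl) * s + p.sinus_bulge_depth * np.sin(np.pi * tau)

    # LV half-width profile vs longitudinal fraction t (0 base, 1 apex)
    hw = PchipInterpolator(
        [0.0, 0.35, 0.7, 0.92, 1.0],
        [wl, a_s, 0.8 * a_s, 0.42 * a_s, 0.0],
    )

    def chain(xsign):
        """Build one side top->apex (xsign=-1 left/septal)."""
        pts, labs, zet = [], [], []
        # aorta
        ys = np.arange(ytop, Ls, -ds)
        for y in ys:
            pts.append((xsign * D2, y))
            labs.append("fixed")
            zet.append(0.0)
        # sinus
        taus = np.arange(1.0, 0.0, -ds / max(Ls, ds))
        for tau in taus:
            pts.append((xsign * sinus_w(tau), tau * Ls))
            labs.append("fixed")
            zet.append(0.0)
        # LVOT (annulus corner exactly at (xsign*wl, 0))
        ys = np.arange(0.0, ybase, -ds)
        for y in ys:
            pts.append((xsign * wl, y))
            labs.append("fixed")
            zet.append(0.0)
        # LV
        ts = np.arange(0.0, 1.0, ds / p.lv_long_axis)
        lab = "septal" if xsign < 0 else "lateral"
        for t in ts:
            pts.append((xsign * float(hw(t)), ybase - p.lv_long_axis * t))
            labs.append(lab)
            zet.append(float(t))
        return pts, labs, zet

    lpts, llabs, lzet = chain(-1.0)
    rpts, rlabs, rzet = chain(+1.0)
    apex = [(0.0, yapex)]
    # outlet edge (right-to-left across the top, completing CCW)
    n_out = max(2, int(np.ceil(p.aorta_diameter / ds)))
    xs = np.linspace(D2, -D2, n_out + 1)[:-1]
    out_pts = [(x, ytop) for x in xs[1:]]  # skip corner duplicate

    contour = np.array(
        lpts + apex + rpts[::-1] + [(D2, ytop)] * 0 + out_pts
    )
    labels = (
        llabs + ["lateral"] + rlabs[::-1] + ["outlet"] * len(out_pts)
    )
    zeta = np.array(lzet + [1.0] + rzet[::-1] + [0.0] * len(out_pts))

    if p.contour_noise > 0:
        rng = np.random.default_rng(p.seed)
        bump = rng.normal(0.0, p.contour_noise, len(contour))
        k = np.ones(7) / 7.0
        bump = np.convolve(np.r_[bump[-3:], bump, bump[:3]], k, "same")[3:-3]
        nrm = _poly_normals(contour)
        keep = np.array([lab != "outlet" for lab in labels])
        contour[keep] += (bump[:, None] * nrm)[keep]

    ring = shapely.LinearRing(contour)
    if not ring.is_simple:
        raise ValueError("wall contour self-intersects for these parameters")
    if shapely.Polygon(contour).area < 0:
        contour = contour[::-1]

    outlet = np.array([[-D2, ytop], [D2, ytop]])

    static_obstacles: list[np.ndarray] = []
    if p.config == "TAVR":
        rr = p.tavr_ring_diameter / 2.0
        yr = p.tavr_ring_height
        Lt = p.tavr_leaflet_length or 0.85 * p.leaflet_length
        # nearly straight prosthetic leaflets (stent-mounted pericardium),
        # keeping clearance from the pushed-aside native material
        leaflets, cls_, rise = _leaflet_pair(p, rr, yr, Lt, tavr_material,
                                             chord_frac=0.985)
        # pushed-aside native leaflets: wedges sealing ring to sinus wall.
        # The prosthetic leaflet roots are embedded inside the wedge solid
        # (the same attachment pattern as native roots in the wall), and
        # the wedge slopes away above the anchor so the moving leaflets
        # have flow clearance.
        for s in (-1.0, 1.0):
            static_obstacles.append(np.array([
                [s * (wl + 0.3), -0.4],
                [s * (rr + 0.08), yr + 0.1],
                [s * (D2 + p.sinus_bulge_depth), 0.62 * Ls],
                [s * (D2 + p.sinus_bulge_depth), -0.4],
            ]))
    else:
        native = FungMaterial(native_material.c, native_material.A,
                              p.leaflet_thickness, native_material.rho_s,
                              native_material.q_variant)
        leaflets, cls_, rise = _leaflet_pair(
            p, wl, 0.0, p.leaflet_length, native
        )
        if p.config == "SAV":
            leaflets = apply_config_stiffening(leaflets, "SAV")

    return GeometryBundle(
        params=p,
        wall_contour=contour,
        wall_labels=labels,
        wall_zeta=zeta,
        outlet_segment=outlet,
        leaflets=leaflets,
        leaflet_centerlines=cls_,
        static_obstacles=static_obstacles,
        valve_y=0.0,
        leaflet_rise=rise,
    )


def _poly_normals(contour: np.ndarray) -> np.ndarray:
    nxt = np.roll(contour, -1, axis=0)
    prv = np.roll(contour, 1, axis=0)
    tang = nxt - prv
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-30)
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def apply_config_stiffening(leaflets: list[LeafletMesh], config: str):
    """Calcific stiffening: SAV multiplies the Fung scale c by exactly 10 on
    every element (uniform distribution); NAV and TAVR are identities.
    Re-applying SAV stiffening raises (idempotence guard)."""
    if config not in CONFIGS:
        raise ValueError(f"unknown config {config!r}")
    if config in ("NAV", "TAVR"):
        return leaflets
    out = []
    for m in leaflets:
        if getattr(m, "_stiffened", False):
            raise ValueError("leaflet already stiffened: refusing to apply "
                             "the 10-fold calcification factor twice")
        mm = m.copy()
        mm.material = m.material.scaled(10.0)
        mm._stiffened = True
        out.append(mm)
    return out


def leaflet_interface_polygon(
    mesh: LeafletMesh, min_half_thickness: float = 0.0, cap_points: int = 8
) -> np.ndarray:
    """Closed outline of the deformed leaflet for the fluid side (cm).

    An offset curve of the deformed centerline at half the leaflet
    thickness (floored at ``min_half_thickness``: the coupled solver keeps
    the hydrodynamic thickness resolvable even for sub-grid leaflets), with
    semicircular end caps.  Built with a fixed vertex count and smooth
    dependence on the nodal positions — the sub-iterated interface update
    needs the outline to move continuously with the structure.
    """
    cl = leaflet_centerline(mesh)
    half = max(mesh.material.thickness / 2.0, min_half_thickness)
    tang = np.gradient(cl, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-30)
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    up = cl + half * nrm
    dn = cl - half * nrm

    def cap(centre, n_from, k):
        # half-turn clockwise from +n through the outward tangent to -n
        # (n is the tangent rotated +90 deg, so -pi sweeps past the end)
        a0 = np.arctan2(n_from[1], n_from[0])
        angs = a0 + np.linspace(0.0, -np.pi, k + 2)[1:-1]
        return centre + half * np.column_stack([np.cos(angs), np.sin(angs)])

    tip = cap(cl[-1], nrm[-1], cap_points)
    root = cap(cl[0], -nrm[0], cap_points)
    return np.vstack([up, tip, dn[::-1], root])


def leaflet_centerline(mesh: LeafletMesh) -> np.ndarray:
    """Deformed centerline nodes (mean across the thickness)."""
    cur = mesh.current_nodes()
    nt = mesh.elements[:, 0].searchsorted  # unused; layout is structured
    n_thk = int(np.max(mesh.elements) + 1)
    # strip meshes are structured: (n_len+1) rows of (n_thk+1) nodes
    n_cols = _strip_cols(mesh)
    return cur.reshape(-1, n_cols, 2).mean(axis=1)


def leaflet_centerline_velocity(mesh: LeafletMesh) -> np.ndarray:
    n_cols = _strip_cols(mesh)
    return mesh.vel.reshape(-1, n_cols, 2).mean(axis=1)


def _strip_cols(mesh: LeafletMesh) -> int:
    # number of nodes across the thickness of a strip mesh
    ne = len(mesh.elements)
    nn = len(mesh.nodes)
    for nt in range(1, 5):
        if nn % (nt + 1) == 0 and ne == (nn // (nt + 1) - 1) * nt:
            return nt + 1
    raise ValueError("mesh is not a structured strip")
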