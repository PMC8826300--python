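"""Finite-element dynamics of hyperelastic valve leaflets.

The leaflet tissue follows the exponential (Fung-type) strain energy

.. math::

    W = \\tfrac{c}{2}\\,(e^Q - 1), \\qquad
    Q = A_1 E_{11}^2 + A_2 E_{22}^2 + A_3 E_{11}E_{22} + A_4 E_{12}^2
        + 2 A_5 E_{11}E_{22} + 2 A_6 E_{22}E_{12},

with :math:`E_{ij}` the in-plane Green--Lagrange strain components and the
second Piola--Kirchhoff stress :math:`S = \\partial W / \\partial E`.

Shear convention: ``W`` is treated as a function of the three independent
variables ``(E11, E22, E12)`` exactly as the energy is written, so
``S12 = dW/dE12`` with no tensor factor-of-two bookkeeping, and the element
kinematics use the matching convention (virtual work
``S11 dE11 + S22 dE22 + S12 dE12``).  The convention is internally consistent
and is what the coupled solver relies on.

Elements are 4-node plane quadrilaterals in a total-Lagrangian setting with
an enhanced-assumed-strain (EAS) field (four incompatible modes, condensed at
element level) to remove the parasitic shear stiffness that locks plain
bilinear elements in thin-leaflet bending.  Time integration is the implicit
Newmark scheme (beta=1/4, gamma=1/2) with a full Newton loop.

Units at the API surface follow the rest of the package: coordinates and
displacements in cm, material scale ``c`` in kPa, tractions in Pa, densities
in kg/m^3.  Assembly internally converts to SI; nodal forces are N per metre
of out-of-plane depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CM = 1e-2  # cm -> m
KPA = 1e3  # kPa -> Pa

_Q_OVERFLOW = 50.0

# 2x2 Gauss quadrature
_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS = np.array([(x, y) for x in _GP for y in _GP])
_WEIGHTS = np.ones(4)


@dataclass
class FungMaterial:
    """Exponential soft-tissue material.

    Parameters
    ----------
    c : stress scale in kPa (the constant multiplied 10-fold to model
        leaflet calcification).
    A : six dimensionless exponent constants A1..A6.
    thickness : leaflet physical thickness in cm (used by the mesher).
    rho_s : tissue density in kg/m^3.
    q_variant : ``"as_printed"`` keeps both the ``A3 E11 E22`` and
        ``2 A5 E11 E22`` pairings of the energy exactly as written;
        ``"a5_e11e12"`` replaces the second pairing by ``2 A5 E11 E12``.
    """

    c: float
    A: tuple[float, float, float, float, float, float]
    thickness: float = 0.05
    rho_s: float = 1100.0
    q_variant: str = "as_printed"

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("Fung scale constant c must be positive")
        if len(self.A) != 6:
            raise ValueError("need exactly six exponent constants A1..A6")
        if self.q_variant not in ("as_printed", "a5_e11e12"):
            raise ValueError(f"unknown q_variant {self.q_variant!r}")

    def scaled(self, factor: float) -> "FungMaterial":
        return FungMaterial(self.c * factor, self.A, self.thickness,
                            self.rho_s, self.q_variant)


def isotropic_fung_constants(
    e_modulus_kpa: float, nu: float, **kw
) -> FungMaterial:
    """Fung constants whose small-strain tangent is isotropic plane stress.

    In the package's engineering-shear convention (third strain slot is
    ``gamma = 2 E12``, with ``S12 = G gamma`` at small strain) the choice
    ``c = E/(1-nu^2)``, ``A1 = A2 = 1``, ``A3 = 2 nu``, ``A4 = (1-nu)/2``
    makes the exponent Q a true isotropic invariant
    (``nu (tr E)^2 + (1-nu) tr(E^2)``), so the material is frame
    indifferent exactly.  Useful for benchmarking against linear-elastic
    closed forms.
    """
    c = e_modulus_kpa / (1.0 - nu**2)
    return FungMaterial(c=c, A=(1.0, 1.0, 2.0 * nu, (1.0 - nu) / 2.0,
                                0.0, 0.0), **kw)


def _q_coeffs(mat: FungMaterial):
    """Quadratic-form matrix H with Q = e^T H e, e=(E11,E22,E12)."""
    A1, A2, A3, A4, A5, A6 = mat.A
    if mat.q_variant == "as_printed":
        h12 = (A3 + 2.0 * A5) / 2.0
        h13 = 0.0
    else:
        h12 = A3 / 2.0
        h13 = A5
    H = np.array(
        [[A1, h12, h13],
         [h12, A2, A6],
         [h13, A6, A4]]
    )
    return H


def fung_stress(E: np.ndarray, mat: FungMaterial, *, with_tangent: bool = True):
    """Second Piola--Kirchhoff stress (and consistent tangent) in kPa.

    ``E`` has shape (..., 3) holding (E11, E22, E12) per evaluation point.
    Returns ``S`` (..., 3) and, if requested, ``dS/dE`` (..., 3, 3).
    Raises if the exponent Q reaches the overflow guard.
    """
    E = np.asarray(E, dtype=float)
    if E.shape[-1] != 3:
        raise ValueError("strain state must have 3 components (E11, E22, E12)")
    H = _q_coeffs(mat)
    Q = np.einsum("...i,ij,...j->...", E, H, E)
    if np.any(Q >= _Q_OVERFLOW):
        raise FloatingPointError(
            "material overflow - check strain magnitude/units "
            f"(max Q = {np.max(Q):.3g} >= {_Q_OVERFLOW})"
        )
    dQ = 2.0 * np.einsum("ij,...j->...i", H, E)
    expQ = np.exp(Q)
    S = 0.5 * mat.c * expQ[..., None] * dQ
    if not with_tangent:
        return S
    tang = 0.5 * mat.c * expQ[..., None, None] * (
        np.einsum("...i,...j->...ij", dQ, dQ) + 2.0 * H
    )
    return S, tang


def strain_energy_density(E: np.ndarray, mat: FungMaterial) -> np.ndarray:
    """W = (c/2)(e^Q - 1) in kPa (= kJ/m^3)."""
    E = np.asarray(E, dtype=float)
    H = _q_coeffs(mat)
    Q = np.einsum("...i,ij,...j->...", E, H, E)
    return 0.5 * mat.c * (np.exp(Q) - 1.0)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------


@dataclass
class LeafletMesh:
    """Quadrilateral leaflet mesh with dynamic state.

    ``nodes`` are reference coordinates (cm); ``disp``/``vel``/``acc`` hold
    the nodal displacement (cm), velocity (cm/s) and acceleration (cm/s^2);
    ``fixed`` is a boolean (n_nodes, 2) mask of constrained dofs (leaflet
    attachment).  ``element_type`` selects the EAS element (default) or plain
    bilinear quads (kept for locking comparisons).
    """

    nodes: np.ndarray
    elements: np.ndarray
    material: FungMaterial
    fixed: np.ndarray | None = None
    disp: np.ndarray = None  # type: ignore[assignment]
    vel: np.ndarray = None  # type: ignore[assignment]
    acc: np.ndarray = None  # type: ignore[assignment]
    element_type: str = "eas"
    label: str = "leaflet"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        n = len(self.nodes)
        if self.fixed is None:
            self.fixed = np.zeros((n, 2), dtype=bool)
        for name in ("disp", "vel", "acc"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((n, 2)))
        if self.element_type not in ("eas", "q4"):
            raise ValueError(f"unknown element_type {self.element_type!r}")
        detj = _ref_jacobians(self.nodes[self.elements] * CM)[1]
        if np.any(detj <= 0):
            bad = int(np.argmax(np.any(detj <= 0, axis=1)))
            raise ValueError(f"inverted element {bad} in reference state")

    @property
    def n_dof(self) -> int:
        return 2 * len(self.nodes)

    def current_nodes(self) -> np.ndarray:
        return self.nodes + self.disp

    def copy(self) -> "LeafletMesh":
        return LeafletMesh(
            self.nodes.copy(), self.elements.copy(), self.material,
            self.fixed.copy(), self.disp.copy(), self.vel.copy(),
            self.acc.copy(), self.element_type, self.label,
        )

    def validate_attached(self) -> None:
        if not np.any(self.fixed):
            raise ValueError("leaflet mesh has no attachment constraints")


def rectangular_mesh(
    lx: float, ly: float, nx: int, ny: int, material: FungMaterial, **kw
) -> LeafletMesh:
    """Structured nx-by-ny quad mesh of an lx-by-ly rectangle (cm)."""
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    elems = [
        [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
        for i in range(nx)
        for j in range(ny)
    ]
    return LeafletMesh(nodes, np.array(elems), material, **kw)


def strip_mesh(
    centerline: np.ndarray, thickness: float, n_thk: int, material: FungMaterial,
    **kw,
) -> LeafletMesh:
    """Mesh a curved strip of given thickness around a centerline polyline.

    Nodes are laid out on offsets of the centerline along its normals; the
    element grid is len(centerline)-1 by n_thk.  Used to build leaflets whose
    reference shape is a circular arc.
    """
    cl = np.asarray(centerline, dtype=float)
    n_len = len(cl) - 1
    tang = np.gradient(cl, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    offs = np.linspace(-thickness / 2.0, thickness / 2.0, n_thk + 1)
    nodes = (cl[:, None, :] + offs[None, :, None] * nrm[:, None, :]).reshape(-1, 2)

    def nid(i, j):
        return i * (n_thk + 1) + j

    elems = [
        [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
        for i in range(n_len)
        for j in range(n_thk)
    ]
    return LeafletMesh(nodes, np.array(elems), material, **kw)


# ---------------------------------------------------------------------------
# batched element machinery (all arrays leading dim = n_elements, then 4 gp)
# ---------------------------------------------------------------------------


def _shape_derivs():
    """dN/dxi at the 4 Gauss points, shape (4gp, 4node, 2)."""
    out = np.empty((4, 4, 2))
    for g, (xi, eta) in enumerate(_GAUSS):
        out[g] = 0.25 * np.array(
            [
                [-(1 - eta), -(1 - xi)],
                [(1 - eta), -(1 + xi)],
                [(1 + eta), (1 + xi)],
                [-(1 + eta), (1 - xi)],
            ]
        )
    return out


_DNDXI = _shape_derivs()
_DNDXI0 = 0.25 * np.array(
    [[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]]
)
_N_GP = np.array(
    [
        [0.25 * (1 - x) * (1 - y), 0.25 * (1 + x) * (1 - y),
         0.25 * (1 + x) * (1 + y), 0.25 * (1 - x) * (1 + y)]
        for x, y in _GAUSS
    ]
)  # (4gp, 4node)


def _ref_jacobians(Xe: np.ndarray):
    """Reference Jacobians at gauss points. Xe: (ne, 4, 2) in metres.

    Returns dNdX (ne,4gp,4node,2), detJ (ne,4gp), J0inv (ne,2,2), detJ0 (ne,).
    """
    J = np.einsum("gai,naj->ngji", _DNDXI, Xe)  # (ne,4gp,2,2), J_ji = dX_j/dxi_i
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    Jinv = np.empty_like(J)
    Jinv[..., 0, 0] = J[..., 1, 1]
    Jinv[..., 1, 1] = J[..., 0, 0]
    Jinv[..., 0, 1] = -J[..., 0, 1]
    Jinv[..., 1, 0] = -J[..., 1, 0]
    Jinv = Jinv / np.where(detJ == 0, 1.0, detJ)[..., None, None]
    dNdX = np.einsum("gai,ngij->ngaj", _DNDXI, Jinv)
    J0 = np.einsum("ai,naj->nji", _DNDXI0, Xe)
    detJ0 = J0[:, 0, 0] * J0[:, 1, 1] - J0[:, 0, 1] * J0[:, 1, 0]
    J0inv = np.empty_like(J0)
    J0inv[:, 0, 0] = J0[:, 1, 1]
    J0inv[:, 1, 1] = J0[:, 0, 0]
    J0inv[:, 0, 1] = -J0[:, 0, 1]
    J0inv[:, 1, 0] = -J0[:, 1, 0]
    J0inv = J0inv / detJ0[:, None, None]
    return dNdX, detJ, J0inv, detJ0


def _eas_modes(J0inv: np.ndarray, detJ0: np.ndarray, detJ: np.ndarray):
    """EAS interpolation M: alpha (4,) -> enhanced strain (3,) per gp.

    Four incompatible modes in the parametric frame, mapped through the
    centre Jacobian and scaled by detJ0/detJ so the modes integrate to zero
    over the element (constant-stress patch test passes exactly).
    Returns M with shape (ne, 4gp, 3, 4).
    """
    ne = len(detJ0)
    T = J0inv  # (ne,2,2); rows of T enter as T_ik factors
    r0 = T[:, 0, :]  # (ne,2)
    r1 = T[:, 1, :]
    o00 = np.einsum("nk,nl->nkl", r0, r0)
    o11 = np.einsum("nk,nl->nkl", r1, r1)
    o01 = 0.5 * (np.einsum("nk,nl->nkl", r0, r1) + np.einsum("nk,nl->nkl", r1, r0))
    M = np.zeros((ne, 4, 3, 4))
    for g, (xi, eta) in enumerate(_GAUSS):
        # tensors for each alpha-mode, then take (11, 22, 12) components
        tens = [xi * o00, eta * o11, xi * o01, eta * o01]
        for m, Tm in enumerate(tens):
            M[:, g, 0, m] = Tm[:, 0, 0]
            M[:, g, 1, m] = Tm[:, 1, 1]
            M[:, g, 2, m] = Tm[:, 0, 1] + Tm[:, 1, 0]  # engineering shear
    scale = (detJ0[:, None] / detJ)[:, :, None, None]
    return M * scale


class _Assembler:
    """Cached reference-geometry data for batched assembly of one mesh."""

    def __init__(self, mesh: LeafletMesh):
        self.mesh = mesh
        self.conn = mesh.elements
        Xe = mesh.nodes[self.conn] * CM
        self.dNdX, self.detJ, J0inv, detJ0 = _ref_jacobians(Xe)
        self.use_eas = mesh.element_type == "eas"
        self.M = _eas_modes(J0inv, detJ0, self.detJ) if self.use_eas else None
        self.wdet = _WEIGHTS[None, :] * self.detJ  # (ne, 4gp)
        self.c_pa = mesh.material.c * KPA
        ne = len(self.conn)
        self.alpha = np.zeros((ne, 4))
        self._mass: np.ndarray | None = None

    # -- kinematics ---------------------------------------------------------
    def _strain_B(self, d_si: np.ndarray):
        """Compatible strain e (ne,4gp,3) and B matrix (ne,4gp,3,4node,2)."""
        de = d_si[self.conn]  # (ne,4,2)
        H = np.einsum("nai,ngaj->ngij", de, self.dNdX)  # grad u
        F = H.copy()
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        C = np.einsum("ngki,ngkj->ngij", F, F)
        # strain vector (E11, E22, gamma) with gamma = 2 E12 (engineering
        # shear), conjugate to (S11, S22, S12) with S12 = dW/d(slot 3)
        e = np.stack(
            [
                0.5 * (C[..., 0, 0] - 1.0),
                0.5 * (C[..., 1, 1] - 1.0),
                C[..., 0, 1],
            ],
            axis=-1,
        )
        B = np.empty(F.shape[:2] + (3, 4, 2))
        NaX = self.dNdX[..., 0]  # (ne,4gp,4node)
        NaY = self.dNdX[..., 1]
        for i in range(2):
            B[..., 0, :, i] = F[..., i, 0, None] * NaX
            B[..., 1, :, i] = F[..., i, 1, None] * NaY
            B[..., 2, :, i] = (
                F[..., i, 0, None] * NaY + F[..., i, 1, None] * NaX
            )
        return e, B, F

    def _stress(self, e_tot: np.ndarray):
        S_kpa, C_kpa = fung_stress(e_tot, self.mesh.material)
        return S_kpa * KPA, C_kpa * KPA

    def _solve_alpha(self, e_comp: np.ndarray, tol: float = 1e-10):
        """Condense the enhanced modes: find alpha with f_alpha = 0."""
        for _ in range(12):
            e_tot = e_comp + np.einsum("ngim,nm->ngi", self.M, self.alpha)
            S, Ct = self._stress(e_tot)
            f_a = np.einsum("ng,ngim,ngi->nm", self.wdet, self.M, S)
            K_aa = np.einsum("ng,ngim,ngij,ngjl->nml", self.wdet, self.M, Ct, self.M)
            # converge relative to the element force scale (round-off floor
            # sits a couple of decades below this)
            ref = tol * float(np.abs(S).max()) * float(self.wdet.max()) + 1e-30
            if np.abs(f_a).max() < ref:
                break
            K_aa = _regularize_batch(K_aa)
            self.alpha -= np.linalg.solve(K_aa, f_a[..., None])[..., 0]
        return S, Ct, _regularize_batch(K_aa)

    def internal_forces(self, d_cm: np.ndarray, *, with_tangent: bool = False):
        """Nodal internal force (N/m, shape (n,2)); optionally condensed K."""
        d_si = np.asarray(d_cm, float) * CM
        e_comp, B, F = self._strain_B(d_si)
        if self.use_eas:
            S, Ct, K_aa = self._solve_alpha(e_comp)
        else:
            e_tot = e_comp
            S, Ct = self._stress(e_tot)
            K_aa = None
        fe = np.einsum("ng,ngiak,ngi->nak", self.wdet, B, S)  # (ne,4,2)
        n = len(self.mesh.nodes)
        f = np.zeros((n, 2))
        np.add.at(f, self.conn, fe)
        if not with_tangent:
            return f
        # material + geometric stiffness, element blocks (ne, 8, 8)
        ne = len(self.conn)
        Bf = B.reshape(B.shape[:3] + (8,))
        Ke = np.einsum("ng,ngip,ngij,ngjq->npq", self.wdet, Bf, Ct, Bf)
        NaX = self.dNdX[..., 0]
        NaY = self.dNdX[..., 1]
        g_ab = np.einsum(
            "ng,ngab->nab",
            self.wdet,
            S[..., 0, None, None] * np.einsum("nga,ngb->ngab", NaX, NaX)
            + S[..., 1, None, None] * np.einsum("nga,ngb->ngab", NaY, NaY)
            + S[..., 2, None, None]
            * (
                np.einsum("nga,ngb->ngab", NaX, NaY)
                + np.einsum("nga,ngb->ngab", NaY, NaX)
            ),
        )
        Kg = np.zeros((ne, 8, 8))
        Kg[:, 0::2, 0::2] = g_ab
        Kg[:, 1::2, 1::2] = g_ab
        Ke = Ke + Kg
        if self.use_eas:
            K_ua = np.einsum("ng,ngip,ngij,ngjm->npm", self.wdet, Bf, Ct, self.M)
            Ke = Ke - np.einsum("npm,nml,nql->npq", K_ua, np.linalg.inv(K_aa), K_ua)
        # scatter to global dense matrix (leaflet meshes are small)
        K = np.zeros((2 * n, 2 * n))
        dofs = (2 * self.conn[:, :, None] + np.array([0, 1])[None, None]).reshape(ne, 8)
        for e in range(ne):
            ix = np.ix_(dofs[e], dofs[e])
            K[ix] += Ke[e]
        return f, K

    def mass_matrix(self) -> np.ndarray:
        """Consistent mass (kg/m per dof pair), dense (2n, 2n); cached."""
        if self._mass is not None:
            return self._mass
        rho = self.mesh.material.rho_s
        me = rho * np.einsum("ng,ga,gb->nab", self.wdet, _N_GP, _N_GP)
        n = len(self.mesh.nodes)
        M = np.zeros((2 * n, 2 * n))
        for e, conn in enumerate(self.conn):
            for a in range(4):
                for b in range(4):
                    for k in range(2):
                        M[2 * conn[a] + k, 2 * conn[b] + k] += me[e, a, b]
        self._mass = M
        return M

    def strain_energy(self, d_cm: np.ndarray) -> float:
        """Total strain energy in J per metre of depth."""
        d_si = np.asarray(d_cm, float) * CM
        e_comp, _, _ = self._strain_B(d_si)
        if self.use_eas:
            self._solve_alpha(e_comp)
            e_tot = e_comp + np.einsum("ngim,nm->ngi", self.M, self.alpha)
        else:
            e_tot = e_comp
        W = strain_energy_density(e_tot, self.mesh.material) * KPA
        return float(np.sum(self.wdet * W))


def _regularize_batch(K: np.ndarray) -> np.ndarray:
    """Tikhonov-protect a batch of small matrices against singularity
    (degenerate elements at extreme transient deformation)."""
    det = np.abs(np.linalg.det(K))
    tr = np.einsum("nii->n", np.abs(K)) + 1e-30
    bad = det < 1e-12 * tr**K.shape[-1]
    if bad.any():
        K = K.copy()
        K[bad] += (1e-8 * tr[bad, None, None] / K.shape[-1]) * np.eye(K.shape[-1])
    return K


_ASSEMBLER_CACHE: dict[tuple, _Assembler] = {}


def _assembler(mesh: LeafletMesh) -> _Assembler:
    # keyed by reference geometry + material so the per-step mesh copies of
    # the coupled solver reuse one assembler (the reference data never moves)
    m = mesh.material
    key = (
        hash(mesh.nodes.tobytes()),
        hash(mesh.elements.tobytes()),
        mesh.element_type,
        m.c, m.A, m.rho_s, m.q_variant,
    )
    asm = _ASSEMBLER_CACHE.get(key)
    if asm is None:
        asm = _Assembler(mesh)
        if len(_ASSEMBLER_CACHE) > 64:
            _ASSEMBLER_CACHE.clear()
        _ASSEMBLER_CACHE[key] = asm
    else:
        asm.mesh = mesh
    return asm


def assemble_internal_forces(mesh: LeafletMesh, disp: np.ndarray | None = None):
    """Nodal internal forces (N per unit depth, shape (n_nodes, 2)).

    A pure function of the displacement field: for EAS elements the enhanced
    modes are condensed out by an inner element-level Newton solve so the
    returned forces depend on ``disp`` alone.
    """
    asm = _assembler(mesh)
    d = mesh.disp if disp is None else disp
    return asm.internal_forces(d)


def mass_matrix(mesh: LeafletMesh) -> np.ndarray:
    return _assembler(mesh).mass_matrix()


def strain_energy(mesh: LeafletMesh) -> float:
    return _assembler(mesh).strain_energy(mesh.disp)


def kinetic_energy(mesh: LeafletMesh) -> float:
    """J per metre of depth."""
    M = _assembler(mesh).mass_matrix()
    v = (mesh.vel * CM).reshape(-1)
    return float(0.5 * v @ M @ v)


def consistent_line_forces(
    points: np.ndarray, tractions: np.ndarray
) -> np.ndarray:
    """Nodal forces (N/m) from tractions (Pa) along a polyline of points (cm).

    Trapezoidal lumping over the current (deformed) polyline, so pressure
    loads follow the surface.
    """
    p = np.asarray(points, float) * CM
    t = np.asarray(tractions, float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    f = np.zeros_like(t)
    f[:-1] += 0.5 * seg[:, None] * 0.5 * (t[:-1] + t[1:])
    f[1:] += 0.5 * seg[:, None] * 0.5 * (t[:-1] + t[1:])
    return f


def initialize_acceleration(mesh: LeafletMesh, f_ext: np.ndarray) -> LeafletMesh:
    """Set the initial acceleration consistently: ``M a0 = f_ext - f_int``.

    Newmark is second order (and exact for constant acceleration) only when
    started from an acceleration consistent with the initial loads.
    """
    asm = _assembler(mesh)
    M = asm.mass_matrix()
    fi = asm.internal_forces(mesh.disp)
    free = ~mesh.fixed.reshape(-1)
    rhs = (np.asarray(f_ext, float) - fi).reshape(-1)
    a = np.zeros(mesh.n_dof)
    if free.any():
        a[free] = np.linalg.solve(M[np.ix_(free, free)], rhs[free])
    out = mesh.copy()
    out.acc = (a / CM).reshape(-1, 2)
    return out


def newmark_step(
    mesh: LeafletMesh,
    f_ext: np.ndarray,
    dt: float,
    *,
    beta: float = 0.25,
    gamma: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 80,
    extra_mass: np.ndarray | None = None,
    acc_ref: np.ndarray | None = None,
    _load_stages: int = 1,
) -> LeafletMesh:
    """Advance the leaflet one implicit Newmark step under nodal loads.

    ``f_ext`` is the external nodal force vector in N per unit depth, shape
    (n_nodes, 2) — build it from surface tractions with
    :func:`consistent_line_forces`.  Newton iterates on the dynamic residual
    ``M a + f_int(d) - f_ext`` until its norm falls below ``tol`` times the
    force scale.  Returns a new mesh; the input is not mutated.

    ``extra_mass`` (per-dof, kg/m) with ``acc_ref`` (m/s^2, flat) adds the
    artificial-added-mass relaxation term ``m_a (a - a_ref)`` used by the
    partitioned coupling: it vanishes identically once the sub-iterations
    converge (``a == a_ref``), so the converged step is unchanged, but it
    scales down the interface added-mass gain seen by each sub-iterate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    asm = _assembler(mesh)
    M = asm.mass_matrix()
    n = len(mesh.nodes)
    free = ~mesh.fixed.reshape(-1)

    d0 = (mesh.disp * CM).reshape(-1)
    v0 = (mesh.vel * CM).reshape(-1)
    a0 = (mesh.acc * CM).reshape(-1)
    fe = np.asarray(f_ext, float).reshape(-1)

    c_a = 1.0 / (beta * dt**2)
    if extra_mass is not None:
        ma = np.asarray(extra_mass, float).reshape(-1)
        aref = np.zeros_like(d0) if acc_ref is None \
            else np.asarray(acc_ref, float).reshape(-1)
    else:
        ma = None

    def residual(dv, fet, tang=True):
        a = c_a * (dv - d0 - dt * v0) - (0.5 / beta - 1.0) * a0
        if tang:
            fi, K = asm.internal_forces((dv / CM).reshape(-1, 2),
                                        with_tangent=True)
        else:
            fi = asm.internal_forces((dv / CM).reshape(-1, 2))
            K = None
        R = M @ a + fi.reshape(-1) - fet
        if ma is not None:
            R = R + ma * (a - aref)
        return R, K, fi

    def newton(d_init, fet):
        d = d_init.copy()
        scale = 1e-12
        hist = []
        dd = np.zeros_like(d)
        d_best, res_best = d.copy(), np.inf
        for it in range(max_iter):
            try:
                R, K, fi = residual(d, fet)
            except FloatingPointError:
                if it == 0:
                    raise
                d = d - 0.5 * dd  # fall back half of the previous update
                continue
            scale = max(scale, np.abs(fet).max(), np.abs(fi).max(), 1e-12)
            res = np.abs(R[free]).max() if free.any() else np.abs(R).max()
            hist.append(res)
            if res < res_best:
                d_best, res_best = d.copy(), res
            if res <= tol * scale:
                return d
            J = c_a * M + K
            if ma is not None:
                J = J + np.diag(c_a * ma)
            dd = np.zeros_like(d)
            Jff = J[np.ix_(free, free)]
            try:
                dd[free] = np.linalg.solve(Jff, -R[free])
            except np.linalg.LinAlgError:
                # singular tangent at a buckling/limit point: damped solve
                lam = 1e-6 * np.abs(np.diag(Jff)).max() + 1e-30
                for _ in range(10):
                    try:
                        dd[free] = np.linalg.solve(
                            Jff + lam * np.eye(Jff.shape[0]), -R[free])
                        break
                    except np.linalg.LinAlgError:
                        lam *= 100.0
            # backtracking keeps the exponential material law inside its
            # admissible strain range under large transient loads
            step = 1.0
            for _ in range(12):
                try:
                    R2, _, _ = residual(d + step * dd, fet, tang=False)
                except FloatingPointError:
                    step *= 0.5
                    continue
                if np.abs(R2[free]).max() <= max(res * 1.2, tol * scale):
                    break
                step *= 0.5
            dd = step * dd
            d = d + dd
        if res_best <= 5e-3 * scale:
            # line-search plateau deep below the load scale: good enough
            # for a sub-iterate that the coupling loop will relax anyway
            return d_best
        raise RuntimeError(
            f"Newmark Newton failed to converge in {max_iter} iterations; "
            f"residual history: {['%.3e' % r for r in hist]}"
        )

    # constant-acceleration predictor, damped toward d0 if the extrapolated
    # configuration already leaves the material's admissible strain range
    for damp in (1.0, 0.5, 0.25, 0.0):
        d_pred = d0 + damp * (dt * v0 + 0.5 * dt**2 * a0)
        d_pred[~free] = d0[~free]
        try:
            residual(d_pred, fe, tang=False)
            break
        except FloatingPointError:
            continue
    if _load_stages == 1:
        try:
            d = newton(d_pred, fe)
        except (RuntimeError, FloatingPointError):
            # strongly nonlinear excursion: retry with load continuation
            return newmark_step(mesh, f_ext, dt, beta=beta, gamma=gamma,
                                tol=tol, max_iter=max_iter,
                                extra_mass=extra_mass, acc_ref=acc_ref,
                                _load_stages=8)
    else:
        d = d_pred
        for frac in np.linspace(1.0 / _load_stages, 1.0, _load_stages):
            d = newton(d, frac * fe)
    a = c_a * (d - d0 - dt * v0) - (0.5 / beta - 1.0) * a0
    a[~free] = 0.0
    v = v0 + dt * ((1 - gamma) * a0 + gamma * a)
    v[~free] = 0.0

    out = mesh.copy()
    out.disp = (d / CM).reshape(n, 2)
    out.vel = (v / CM).reshape(n, 2)
    out.acc = (a / CM).reshape(n, 2)
    return out
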