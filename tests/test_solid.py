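"""Fung material law, EAS elements, Newmark dynamics."""

import numpy as np
import pytest

from avfsi import solid
from avfsi.solid import CM, _assembler


def static_solve(mesh, f_ext, tol=1e-12, max_iter=40):
    """Small Newton driver for quasi-static checks."""
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


class TestFungStress:
    def test_zero_strain_zero_stress(self):
        mat = solid.FungMaterial(c=2.0, A=(1, 2, 0.5, 1, 0.2, 0.1))
        S = solid.fung_stress(np.zeros(3), mat, with_tangent=False)
        assert np.all(S == 0.0)

    def test_uniaxial_closed_form(self):
        # c=2 kPa, only A1 active: S11 = c A1 E11 exp(A1 E11^2)
        mat = solid.FungMaterial(c=2.0, A=(1.0, 0, 0, 0, 0, 0))
        E = np.array([0.1, 0.0, 0.0])
        S = solid.fung_stress(E, mat, with_tangent=False)
        assert S[0] == pytest.approx(2.0 * 0.1 * np.exp(0.01), rel=1e-14)
        assert S[1] == S[2] == 0.0

    @pytest.mark.parametrize("variant", ["as_printed", "a5_e11e12"])
    def test_matches_finite_differences_of_energy(self, rng, variant):
        # 1000 random admissible states: stress and tangent vs central FD
        worst_s, worst_c = 0.0, 0.0
        eps = 1e-6
        for _ in range(1000):
            mat = solid.FungMaterial(
                c=float(rng.uniform(0.5, 5)),
                A=tuple(rng.uniform(0.1, 3.0, 6)),
                q_variant=variant,
            )
            E = rng.uniform(-0.3, 0.3, 3)
            S, C = solid.fung_stress(E, mat)
            ref = max(np.abs(S).max(), 1e-12)
            for k in range(3):
                Ep, Em = E.copy(), E.copy()
                Ep[k] += eps
                Em[k] -= eps
                fd = (solid.strain_energy_density(Ep, mat)
                      - solid.strain_energy_density(Em, mat)) / (2 * eps)
                worst_s = max(worst_s, abs(fd - S[k]) / ref)
                Sp = solid.fung_stress(Ep, mat, with_tangent=False)
                Sm = solid.fung_stress(Em, mat, with_tangent=False)
                worst_c = max(
                    worst_c,
                    np.abs((Sp - Sm) / (2 * eps) - C[:, k]).max()
                    / max(np.abs(C).max(), 1e-12),
                )
        assert worst_s < 1e-6
        assert worst_c < 1e-6

    def test_overflow_guard(self):
        mat = solid.FungMaterial(c=1.0, A=(100.0, 0, 0, 0, 0, 0))
        with pytest.raises(FloatingPointError, match="material overflow"):
            solid.fung_stress(np.array([1.0, 0, 0]), mat)

    def test_tenfold_c_scales_stress_exactly(self, rng):
        # the calcific-stiffening mechanism: S is linear in c at fixed E
        mat = solid.FungMaterial(c=1.7, A=(2, 1, 0.5, 1.2, 0.3, 0.4))
        E = rng.uniform(-0.2, 0.2, (50, 3))
        S1 = solid.fung_stress(E, mat, with_tangent=False)
        S10 = solid.fung_stress(E, mat.scaled(10.0), with_tangent=False)
        assert np.allclose(S10, 10.0 * S1, rtol=0, atol=1e-14 * np.abs(S1).max())


class TestElements:
    def test_rigid_translation_zero_force(self):
        mat = solid.isotropic_fung_constants(100.0, 0.3)
        m = solid.rectangular_mesh(2.0, 0.5, 4, 2, mat)
        m.disp = np.tile([0.3, -0.7], (len(m.nodes), 1))
        f = solid.assemble_internal_forces(m)
        assert np.abs(f).max() < 1e-10

    @pytest.mark.parametrize("etype", ["eas", "q4"])
    def test_constant_strain_patch(self, etype):
        # 5-element irregular patch under uniform-strain boundary motion:
        # interior residuals vanish identically
        mat = solid.isotropic_fung_constants(100.0, 0.3)
        nodes = np.array([[0, 0], [2, 0], [2, 1], [0, 1], [0.6, 0.4],
                          [1.5, 0.3], [1.4, 0.7], [0.5, 0.65]], float)
        elems = np.array([[0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6],
                          [3, 0, 4, 7], [4, 5, 6, 7]])
        mesh = solid.LeafletMesh(nodes, elems, mat, element_type=etype)
        exx, eyy, gxy = 1e-3, -5e-4, 8e-4
        mesh.disp = np.column_stack([
            exx * nodes[:, 0] + 0.5 * gxy * nodes[:, 1],
            eyy * nodes[:, 1] + 0.5 * gxy * nodes[:, 0],
        ])
        f = solid.assemble_internal_forces(mesh)
        assert np.abs(f[4:]).max() < 1e-10 * np.abs(f).max()

    def test_slender_cantilever_eas_vs_locking_q4(self):
        # length/thickness = 100, 20x1 elements, small tip load: EAS within
        # 5% of Euler-Bernoulli PL^3/3EI while plain bilinear quads lock
        L, t = 10.0, 0.1
        mat = solid.isotropic_fung_constants(100.0, 0.0)
        E_pa = 100.0e3
        I = (t * CM) ** 3 / 12.0
        P = 1e-7 * 3 * E_pa * I / (L * CM) ** 3
        exact = P * (L * CM) ** 3 / (3 * E_pa * I)
        ratios = {}
        for etype in ("eas", "q4"):
            m = solid.rectangular_mesh(L, t, 20, 1, mat, element_type=etype)
            m.fixed[np.isclose(m.nodes[:, 0], 0.0)] = True
            fext = np.zeros_like(m.nodes)
            tip = np.isclose(m.nodes[:, 0], L)
            fext[tip, 1] = P / tip.sum()
            d = static_solve(m, fext)  # metres
            ratios[etype] = d[tip, 1].mean() / exact
        assert abs(ratios["eas"] - 1.0) < 0.05
        assert ratios["q4"] < 0.7  # >30% underprediction: shear locking

    def test_objectivity_material_frame(self, rng):
        # rotating reference and deformed configurations together leaves the
        # internal forces rotated but the strain state unchanged (isotropic
        # constants: the exponent's axes rotate with the reference frame)
        mat = solid.isotropic_fung_constants(80.0, 0.3)
        m = solid.rectangular_mesh(1.0, 0.4, 3, 2, mat)
        m.disp = 0.05 * rng.standard_normal(m.nodes.shape)
        f0 = solid.assemble_internal_forces(m)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m2 = solid.LeafletMesh(m.nodes @ R.T, m.elements, mat)
        cur = (m.nodes + m.disp) @ R.T
        m2.disp = cur - m2.nodes
        f2 = solid.assemble_internal_forces(m2)
        assert np.abs(f2 - f0 @ R.T).max() < 1e-10 * max(np.abs(f0).max(), 1e-30)

    def test_inverted_reference_element_rejected(self):
        mat = solid.isotropic_fung_constants(100.0, 0.3)
        nodes = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        elems = np.array([[0, 3, 2, 1]])  # clockwise: negative Jacobian
        with pytest.raises(ValueError, match="inverted element"):
            solid.LeafletMesh(nodes, elems, mat)


class TestNewmark:
    def test_stationary_without_load(self):
        mat = solid.FungMaterial(c=1.0, A=(1, 1, 0.3, 0.7, 0, 0))
        m = solid.rectangular_mesh(1.0, 0.2, 4, 1, mat)
        m.fixed[np.isclose(m.nodes[:, 0], 0.0)] = True
        out = solid.newmark_step(m, np.zeros_like(m.nodes), 1e-3)
        assert np.abs(out.disp).max() == 0.0
        assert np.abs(out.vel).max() == 0.0

    def test_constant_force_free_mass_exact(self):
        # uniform acceleration: Newmark (1/4, 1/2) reproduces d = a t^2 / 2
        # exactly at step points when started from a consistent acceleration
        mat = solid.FungMaterial(c=1.0, A=(1, 1, 0.3, 0.7, 0, 0),
                                 rho_s=1000.0)
        m = solid.rectangular_mesh(1.0, 1.0, 1, 1, mat)
        M = solid.mass_matrix(m)
        acc = 2.0  # m/s^2
        fext = (M @ np.tile([0.0, acc], 4)).reshape(-1, 2)
        m = solid.initialize_acceleration(m, fext)
        dt = 0.01
        for _ in range(10):
            m = solid.newmark_step(m, fext, dt)
        expected_cm = 0.5 * acc * (10 * dt) ** 2 / CM
        assert m.disp[:, 1].mean() == pytest.approx(expected_cm, rel=1e-12)

    def test_free_vibration_energy_drift(self):
        # beta=1/4, gamma=1/2 is non-dissipative: total mechanical energy
        # drifts < 1% over 1000 steps of small-amplitude free vibration
        mat = solid.isotropic_fung_constants(50.0, 0.0, rho_s=1100.0)
        m = solid.rectangular_mesh(2.0, 0.2, 8, 1, mat)
        m.fixed[np.isclose(m.nodes[:, 0], 0.0)] = True
        m.disp[:, 1] = 1e-3 * (m.nodes[:, 0] / 2.0) ** 2
        m = solid.initialize_acceleration(m, np.zeros_like(m.nodes))
        e0 = solid.strain_energy(m) + solid.kinetic_energy(m)
        zero = np.zeros_like(m.nodes)
        for _ in range(1000):
            m = solid.newmark_step(m, zero, 2.5e-4)
        e1 = solid.strain_energy(m) + solid.kinetic_energy(m)
        assert abs(e1 - e0) / e0 < 0.01
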