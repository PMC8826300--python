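"""Haemodynamic metrics against closed forms."""

import numpy as np
import pytest

from avfsi import fluid as fl
from avfsi import levelset as lv
from avfsi import metrics as me
from avfsi.grid import UniformGrid


def poiseuille_state(n=64, vbar=0.01, H=0.01, mu=1.0, nx=6):
    """Analytic parabolic channel profile loaded into a FluidState."""
    g = UniformGrid(nx, n, 100 * H / n)
    props = fl.FluidProperties(rho=1000.0, mu=mu)
    st = fl.FluidState(g, props)
    y = g.yc * fl.CM
    st.u[:, :] = 6.0 * vbar * y * (H - y) / H**2
    return st, g


class TestReynolds:
    def test_printed_stenotic_value(self):
        # mean AAo velocity 1.04 m/s, diameter 3.3 cm, blood properties
        re = me.reynolds(1.04, 0.033, fl.FluidProperties())
        assert re == pytest.approx(10350.0, rel=0.01)

    def test_all_three_valve_regimes(self):
        # 0.55 and 0.40 m/s give the transitional-regime values ~5600 and
        # ~4070 (the formula fixes which velocity goes with which number)
        props = fl.FluidProperties()
        assert me.reynolds(0.55, 0.033, props) == pytest.approx(5600, rel=0.02)
        assert me.reynolds(0.40, 0.033, props) == pytest.approx(4070, rel=0.02)

    def test_zero_velocity(self):
        assert me.reynolds(0.0, 0.033, fl.FluidProperties()) == 0.0

    def test_linear_in_velocity(self):
        props = fl.FluidProperties()
        assert me.reynolds(2.08, 0.033, props) == pytest.approx(
            2.0 * me.reynolds(1.04, 0.033, props), rel=1e-14)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            me.reynolds(1.0, -0.01, fl.FluidProperties())


class TestOrificeArea:
    def _leaflet_fields(self, gap):
        g = UniformGrid(128, 64, 4.0 / 128, -2.0, 0.0)
        X, Y = np.meshgrid(g.xc, g.yc, indexing="ij")
        # two half-plane "leaflets" leaving a central slot of width gap:
        # leaflet-1 fills X <= -gap/2 (fluid to its right), leaflet-2 fills
        # X >= gap/2 (fluid to its left)
        phi1 = X + gap / 2
        phi2 = (gap / 2) - X
        f1 = lv.LevelSetField(phi1, g, "leaflet-1")
        f2 = lv.LevelSetField(phi2, g, "leaflet-2")
        return g, [f1, f2]

    def test_slot_gap_measured(self):
        g, fields = self._leaflet_fields(0.8)
        gap, pseudo = me.orifice_area(fields, 1.0)
        assert gap == pytest.approx(0.8, abs=2 * 4.0 / 2000)
        assert pseudo == pytest.approx(np.pi * 0.4**2, rel=0.02)

    def test_no_leaflets_full_root(self):
        g = UniformGrid(64, 64, 4.0 / 64, -2.0, 0.0)
        open_ls = lv.LevelSetField(np.ones((64, 64)), g, "none")
        gap, _ = me.orifice_area([open_ls], 1.0, x_limits=(-1.65, 1.65))
        assert gap == pytest.approx(3.3, rel=0.01)

    def test_pseudo_area_is_circle_of_gap(self):
        g, fields = self._leaflet_fields(1.2)
        gap, pseudo = me.orifice_area(fields, 1.4)
        assert pseudo == pytest.approx(np.pi * (gap / 2) ** 2, rel=1e-12)

    def test_gap_matches_mask_scan_oracle(self):
        g, fields = self._leaflet_fields(0.9)
        gap, _ = me.orifice_area(fields, 1.5)
        mask = lv.combined_fluid_mask(fields)
        j = int((1.5 - g.y0) / g.h)
        ref = mask[:, j].sum() * g.h
        assert abs(gap - ref) <= g.h

    def test_plane_outside_domain_rejected(self):
        g, fields = self._leaflet_fields(0.5)
        with pytest.raises(ValueError, match="misses"):
            me.orifice_area(fields, 99.0)


class TestTransvalvularGradient:
    def test_uniform_pressure_zero(self):
        st, g = poiseuille_state()
        st.p[:] = 1234.5
        dp = me.transvalvular_gradient(st, (0.0, 0.5, 0.1, 0.3),
                                       (0.0, 0.5, 0.7, 0.9))
        assert dp == 0.0

    def test_poiseuille_closed_form(self):
        # dp = 12 mu vbar L / H^2 between probes L apart (2D channel),
        # converted to mmHg.  Build the linear pressure field directly.
        st, g = poiseuille_state()
        vbar, H, mu = 0.01, 0.01, 1.0
        # channel along y: pressure falls along x... here along the y axis
        Y = np.meshgrid(g.xc, g.yc, indexing="ij")[1] * fl.CM
        dpdx = 12 * mu * vbar / H**2
        st.p = -dpdx * Y
        box_up = (0.0, 0.6, 0.1, 0.2)
        box_dn = (0.0, 0.6, 0.7, 0.8)
        L = 0.6 * fl.CM  # probe-centre separation
        dp = me.transvalvular_gradient(st, box_up, box_dn)
        assert dp == pytest.approx(dpdx * L / me.MMHG, rel=0.02)

    def test_swapping_probes_negates(self):
        st, g = poiseuille_state()
        st.p = np.random.default_rng(0).normal(0, 50, st.p.shape)
        a = (0.0, 0.5, 0.1, 0.3)
        b = (0.0, 0.5, 0.6, 0.8)
        assert me.transvalvular_gradient(st, a, b) == pytest.approx(
            -me.transvalvular_gradient(st, b, a), rel=1e-14)

    def test_empty_probe_rejected(self):
        st, g = poiseuille_state()
        st.mask[:] = False
        with pytest.raises(ValueError, match="no fluid"):
            me.transvalvular_gradient(st, (0, 0.5, 0.1, 0.3), (0, 0.5, 0.6, 0.8))


class TestWallShearStress:
    def test_poiseuille_wall_wss(self):
        st, g = poiseuille_state()
        vbar, H, mu = 0.01, 0.01, 1.0
        phi = np.tile(np.minimum(g.yc, 1.0 - g.yc)[None, :], (g.nx, 1))
        wall = lv.LevelSetField(phi, g, "walls")
        xs = np.linspace(0.05, 0.25, 5)
        markers = np.column_stack([xs, np.zeros_like(xs)])
        wss = me.wall_shear_stress(st, wall, markers)
        assert np.abs(np.abs(wss) - 6 * mu * vbar / H).max() < 0.03 * 6 * mu * vbar / H

    def test_quiescent_zero(self):
        st, g = poiseuille_state()
        st.u[:] = 0.0
        phi = np.tile(np.minimum(g.yc, 1.0 - g.yc)[None, :], (g.nx, 1))
        wall = lv.LevelSetField(phi, g, "walls")
        wss = me.wall_shear_stress(st, wall, np.array([[0.1, 0.0]]))
        assert np.all(wss == 0.0)

    def test_symmetric_channel_equal_magnitudes(self):
        st, g = poiseuille_state()
        phi = np.tile(np.minimum(g.yc, 1.0 - g.yc)[None, :], (g.nx, 1))
        wall = lv.LevelSetField(phi, g, "walls")
        lo = me.wall_shear_stress(st, wall, np.array([[0.15, 0.0]]))
        hi = me.wall_shear_stress(st, wall, np.array([[0.15, 1.0]]))
        assert abs(abs(lo[0]) - abs(hi[0])) < 0.01 * abs(lo[0])


class TestQCriterion:
    def _state(self, ufun, vfun, n=48):
        g = UniformGrid(n, n, 2.0 / n, -1.0, -1.0)
        st = fl.FluidState(g, fl.FluidProperties(rho=1000.0, mu=1e-3))
        xf, yc = np.meshgrid(g.xf * fl.CM, g.yc * fl.CM, indexing="ij")
        st.u = ufun(xf, yc)
        xc, yf = np.meshgrid(g.xc * fl.CM, g.yf * fl.CM, indexing="ij")
        st.v = vfun(xc, yf)
        return st

    def test_pure_shear_zero(self):
        st = self._state(lambda x, y: 3.0 * y, lambda x, y: 0.0 * x)
        q = me.q_criterion(st)
        assert np.abs(q[2:-2, 2:-2]).max() < 1e-10

    def test_solid_rotation_omega_squared(self):
        om = 2.5
        st = self._state(lambda x, y: -om * y, lambda x, y: om * x)
        q = me.q_criterion(st)
        assert np.abs(q[2:-2, 2:-2] - om**2).max() < 1e-9

    def test_uniform_flow_zero(self):
        st = self._state(lambda x, y: 1.0 + 0 * x, lambda x, y: -2.0 + 0 * x)
        q = me.q_criterion(st)
        assert np.abs(q).max() < 1e-12

    def test_agrees_with_assembled_gradient(self):
        st = self._state(lambda x, y: np.sin(3 * x) * y,
                         lambda x, y: np.cos(2 * y) * x)
        q1 = me.q_criterion(st)
        dudx, dudy, dvdx, dvdy = me._gradients(st)
        s12 = 0.5 * (dudy + dvdx)
        w12 = 0.5 * (dudy - dvdx)
        q2 = 0.5 * (2 * w12**2 - (dudx**2 + dvdy**2 + 2 * s12**2))
        assert np.abs(q1 - q2).max() < 1e-12


class TestDissipation:
    def test_poiseuille_total_matches_pressure_work(self):
        st, g = poiseuille_state()
        vbar, H, mu = 0.01, 0.01, 1.0
        _, total = me.viscous_dissipation(st)
        length = g.nx * g.h * fl.CM
        per_len = total / length
        assert per_len == pytest.approx(12 * mu * vbar**2 / H, rel=0.02)
        # energy balance: dissipation = dp * Q (pressure work)
        dpdx = 12 * mu * vbar / H**2
        assert per_len == pytest.approx(dpdx * vbar * H, rel=0.02)

    def test_uniform_flow_zero(self):
        st, g = poiseuille_state()
        st.u[:] = 0.5
        _, total = me.viscous_dissipation(st)
        assert total < 1e-15

    def test_pointwise_nonnegative_random_fields(self, rng):
        g = UniformGrid(24, 24, 0.1)
        st = fl.FluidState(g, fl.FluidProperties())
        st.u = rng.standard_normal(st.u.shape)
        st.v = rng.standard_normal(st.v.shape)
        phi, _ = me.viscous_dissipation(st)
        assert phi.min() >= 0.0


class TestComparativeReport:
    def _report(self, gap, vel, dp, diss, wss):
        r = me.MetricsReport(config="x")
        r.time = [0.0, 0.1]
        r.gap = [gap, gap]
        r.pseudo_ava = [np.pi * (gap / 2) ** 2] * 2
        r.delta_p = [dp, dp]
        r.peak_velocity = [vel, vel]
        r.wss_max = [wss, wss]
        r.q_max = [0.0, 0.0]
        r.dissipation_total = [diss, diss]
        return r

    def test_identical_runs_tie(self):
        r = self._report(1.0, 1.0, 10.0, 1.0, 0.5)
        out = me.comparative_report({"SAV": r, "NAV": r, "TAVR": r})
        assert all(v == "tie" for v in out["flags"].values())

    def test_directional_flags(self):
        sav = self._report(0.4, 3.0, 35.0, 5.0, 0.9)
        nav = self._report(1.8, 1.1, 5.0, 1.0, 0.3)
        tavr = self._report(1.2, 1.6, 12.0, 1.5, 0.35)
        out = me.comparative_report({"SAV": sav, "NAV": nav, "TAVR": tavr})
        assert set(out["flags"].values()) == {"yes"}

    def test_missing_run_rejected(self):
        r = self._report(1, 1, 1, 1, 1)
        with pytest.raises(ValueError, match="TAVR"):
            me.comparative_report({"SAV": r, "NAV": r})
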