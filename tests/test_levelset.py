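"""Signed-distance construction, transport, reinitialization, extension."""

import numpy as np
import pytest
import shapely

from avfsi.grid import UniformGrid, interp_cc
from avfsi import levelset as lv


def brute_force_distance(pts, polyline, closed=True):
    """Exhaustive min distance over all segments — the reference oracle."""
    a = polyline
    b = np.roll(polyline, -1, axis=0) if closed else polyline[1:]
    if not closed:
        a = polyline[:-1]
    out = np.full(len(pts), np.inf)
    for k in range(len(a)):
        ab = b[k] - a[k]
        t = np.clip((pts - a[k]) @ ab / (ab @ ab), 0, 1)
        d = pts - a[k] - t[:, None] * ab
        out = np.minimum(out, np.hypot(d[:, 0], d[:, 1]))
    return out


class TestBuildSdf:
    def test_circle_centre_value(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        # cell centres nearest the origin sit half a cell away from it
        val = interp_cc(unit_grid, ls.phi, [[0.0, 0.0]])[0]
        assert val == pytest.approx(-0.5, abs=2.5 * unit_grid.h)

    def test_zero_on_contour(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        val = interp_cc(unit_grid, ls.phi, [[0.5, 0.0]])[0]
        assert abs(val) < unit_grid.h**2 + 1e-3

    def test_matches_brute_force(self, unit_grid, circle, rng):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        pts = unit_grid.cell_centres()
        ref = brute_force_distance(pts, circle)
        assert np.abs(np.abs(ls.phi.ravel()) - ref).max() < 1e-12

    def test_sign_convention_fluid_positive(self, unit_grid, circle):
        solid = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        assert solid.phi[32, 32] < 0  # inside the immersed body
        chamber = lv.build_sdf(circle, unit_grid, fluid_side="inside")
        assert chamber.phi[32, 32] > 0  # chamber interior is fluid

    def test_open_polyline_rejected(self, unit_grid):
        seg = np.array([[0.0, 0.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="open polyline"):
            lv.build_sdf(seg, unit_grid, closed=False)

    def test_self_intersection_rejected(self, unit_grid):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1.0]]) - 0.5
        with pytest.raises(ValueError, match="self-intersecting"):
            lv.build_sdf(bow, unit_grid)


class TestAdvect:
    def test_uniform_translation(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        V = lv.PropagationField(np.ones_like(ls.phi), np.zeros_like(ls.phi),
                                unit_grid)
        dt = 0.4 * unit_grid.h
        cur, moved = ls, 0.0
        while moved < 0.1 - 1e-12:
            step = min(dt, 0.1 - moved)
            cur = lv.advect(cur, V, step)
            moved += step
        val = interp_cc(unit_grid, cur.phi, [[0.6, 0.0]])[0]
        assert abs(val) < 0.1 * unit_grid.h + 1e-3

    def test_zero_velocity_identity(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        V = lv.PropagationField(np.zeros_like(ls.phi), np.zeros_like(ls.phi),
                                unit_grid)
        out = lv.advect(ls, V, 0.05)
        assert np.array_equal(out.phi, ls.phi)

    def test_cfl_violation_names_cell(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        vx = np.zeros_like(ls.phi)
        vx[10, 20] = 100.0
        V = lv.PropagationField(vx, np.zeros_like(ls.phi), unit_grid)
        with pytest.raises(ValueError, match=r"\(10, 20\)"):
            lv.advect(ls, V, 0.1)

    def test_rigid_rotation_preserves_area(self):
        # full revolution of an off-centre circle on a 256^2 grid
        g = UniformGrid(256, 256, 2.0 / 256, -1.0, -1.0)
        th = np.linspace(0, 2 * np.pi, 401)[:-1]
        circ = np.column_stack([0.4 + 0.25 * np.cos(th), 0.25 * np.sin(th)])
        ls = lv.build_sdf(circ, g, fluid_side="outside")
        X, Y = np.meshgrid(g.xc, g.yc, indexing="ij")
        omega = 1.0
        V = lv.PropagationField(-omega * Y, omega * X, g)
        area0 = np.count_nonzero(ls.phi < 0) * g.h**2
        dt = 0.4 * g.h / (np.hypot(X, Y).max() * omega)
        n = int(np.ceil(2 * np.pi / omega / dt))
        dt = 2 * np.pi / omega / n
        # rigid rotation preserves the signed-distance property, so no
        # reinitialization is needed within the revolution
        cur = ls
        for k in range(n):
            cur = lv.advect(cur, V, dt)
        area1 = np.count_nonzero(cur.phi < 0) * g.h**2
        assert abs(area1 - area0) / area0 < 0.01

    def test_rigid_translation_preserves_contour_distances(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        V = lv.PropagationField(np.full_like(ls.phi, 0.7),
                                np.full_like(ls.phi, 0.4), unit_grid)
        out = lv.advect(ls, V, 0.3 * unit_grid.h)

        def width(f):
            c = f.zero_contours()[0]
            return c[:, 0].max() - c[:, 0].min()

        assert width(out) == pytest.approx(width(ls), abs=3 * unit_grid.h**2 / 0.5)


class TestReinitialize:
    def test_planar_sdf_is_fixed_point(self, unit_grid):
        X, _ = np.meshgrid(unit_grid.xc, unit_grid.yc, indexing="ij")
        ls = lv.LevelSetField(X - 0.2, unit_grid, "plane")
        out = lv.reinitialize(ls, iterations=20)
        assert np.abs(out.phi - ls.phi).max() < 1e-10

    def test_scaled_field_restored(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        scaled = lv.LevelSetField(3.0 * ls.phi, unit_grid, "scaled")
        out = lv.reinitialize(scaled, iterations=60)
        gm = lv.gradient_magnitude(out)
        band = np.abs(ls.phi) < 5 * unit_grid.h
        assert gm[band].min() > 0.9
        assert gm[band].max() < 1.1

    def test_contour_stays_put(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        out = lv.reinitialize(ls, iterations=30)
        c = out.zero_contours()[0]
        r = np.hypot(c[:, 0], c[:, 1])
        assert np.abs(r - 0.5).max() < 0.1 * unit_grid.h + 2e-3

    def test_ellipse_matches_brute_force_in_band(self):
        g = UniformGrid(96, 96, 2.0 / 96, -1.0, -1.0)
        th = np.linspace(0, 2 * np.pi, 501)[:-1]
        ell = np.column_stack([0.6 * np.cos(th), 0.35 * np.sin(th)])
        ls = lv.build_sdf(ell, g, fluid_side="outside")
        distorted = lv.LevelSetField(ls.phi * (1.5 + 0.3 * np.tanh(ls.phi)),
                                     g, "ell")
        out = lv.reinitialize(distorted, iterations=80)
        band = np.abs(ls.phi) < 3 * g.h
        ref = brute_force_distance(g.cell_centres(), ell).reshape(96, 96)
        err = np.abs(np.abs(out.phi) - ref)[band]
        assert err.max() < g.h


class TestExtendVelocity:
    def test_uniform_velocity_everywhere(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        vel = np.tile([1.5, -0.5], (len(circle), 1))
        V = lv.extend_velocity(ls, circle, vel)
        assert np.allclose(V.vx, 1.5)
        assert np.allclose(V.vy, -0.5)

    def test_empty_samples_rejected(self, unit_grid, circle):
        ls = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        with pytest.raises(ValueError, match="empty"):
            lv.extend_velocity(ls, np.zeros((0, 2)), np.zeros((0, 2)))

    def test_flat_interface_constant_along_normals(self, unit_grid):
        # linear tangential profile on the line y=0: the extension must equal
        # the analytic normal projection v(x, y) = v(x, 0)
        X, _ = np.meshgrid(unit_grid.xc, unit_grid.yc, indexing="ij")
        ls = lv.LevelSetField(-np.meshgrid(unit_grid.xc, unit_grid.yc,
                                           indexing="ij")[1], unit_grid, "w")
        xs = np.linspace(-1, 1, 400)
        samples = np.column_stack([xs, np.zeros_like(xs)])
        vel = np.column_stack([2.0 * xs, np.zeros_like(xs)])
        V = lv.extend_velocity(ls, samples, vel)
        assert np.abs(V.vx - 2.0 * X).max() < 2.0 * (xs[1] - xs[0]) + 1e-9

    def test_per_label_extension_is_local(self, unit_grid, circle):
        # each field is extended from its own samples only
        ls1 = lv.build_sdf(circle, unit_grid, fluid_side="outside")
        vel1 = np.tile([1.0, 0.0], (len(circle), 1))
        V1 = lv.extend_velocity(ls1, circle, vel1)
        far = circle + [[0.9, 0.9]]
        ls2 = lv.build_sdf(far, unit_grid, fluid_side="outside", label="b")
        vel2 = np.tile([0.0, -2.0], (len(far), 1))
        V2 = lv.extend_velocity(ls2, far, vel2)
        assert np.allclose(V1.vx, 1.0) and np.allclose(V2.vy, -2.0)


def test_union_mask_matches_polygon_clipping(unit_grid, circle):
    square = np.array([[-0.9, -0.9], [0.9, -0.9], [0.9, 0.9], [-0.9, 0.9]])
    chamber = lv.build_sdf(square, unit_grid, fluid_side="inside")
    body = lv.build_sdf(circle, unit_grid, fluid_side="outside")
    mask = lv.combined_fluid_mask([chamber, body])
    region = shapely.Polygon(square).difference(shapely.Polygon(circle))
    pts = unit_grid.cell_centres()
    ref = shapely.contains_xy(region, pts[:, 0], pts[:, 1]).reshape(64, 64)
    # agreement away from the contours (cells cut by an interface may land
    # on either side at the grid level)
    near = (np.abs(chamber.phi) < unit_grid.h) | (np.abs(body.phi) < unit_grid.h)
    assert np.array_equal(mask[~near], ref[~near])
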