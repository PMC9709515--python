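"""Differential-geometry core: closed forms, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfscape import (Domain, LandscapeGrid, QuadraticSurface, RegionClass,
                       SurfacePatch, classify_point, curvature_field,
                       cylinder_patch, flat_surface, fundamental_forms,
                       gauss_curvature, gradient, mean_curvature,
                       principal_curvatures, saddle_surface, sphere_patch,
                       unit_normal)
from conftest import finite_difference_patch

SQ2 = np.sqrt(2.0)


class TestGradient:
    @pytest.mark.parametrize("point,expected", [
        ((0.0, 0.0), (0.0, 0.0)),
        ((2.0, 3.0), (3.0, 2.0)),   # f = xy, so (f_x, f_y) = (y, x)
    ])
    def test_saddle_closed_form(self, saddle, point, expected):
        assert gradient(saddle, point) == pytest.approx(expected)

    def test_general_quadratic_matches_symbolic_oracle(self):
        # d/dx (x²+2y²+3x+4y+5xy) = 2x+3+5y -> 10 at (1,1); d/dy -> 13
        s = QuadraticSurface(1, 2, 3, 4, 5)
        assert gradient(s, (1.0, 1.0)) == pytest.approx((10.0, 13.0))

    def test_rejects_nonfinite_point(self, saddle):
        with pytest.raises(ValueError):
            gradient(saddle, (np.nan, 0.0))


class TestUnitNormal:
    def test_flat_everywhere_and_saddle_origin_point_up(self, flat, saddle):
        for surf, pt in [(flat, (0.3, 0.7)), (saddle, (0.0, 0.0))]:
            np.testing.assert_allclose(unit_normal(surf, pt), [0, 0, 1], atol=1e-15)

    def test_saddle_off_origin_matches_cross_product_oracle(self, saddle):
        # (1,0,0) x (0,1,1) = (0,-1,1), normalized
        np.testing.assert_allclose(unit_normal(saddle, (1.0, 0.0)),
                                   np.array([0, -1, 1]) / SQ2, atol=1e-15)

    def test_unit_length_on_random_quadratics(self, random_quadratic):
        rng = np.random.default_rng(7)
        for seed in range(5):
            s = random_quadratic(seed)
            pts = rng.uniform(-2, 2, (20, 2))
            n = unit_normal(s, (pts[:, 0], pts[:, 1]))
            np.testing.assert_allclose(np.linalg.norm(n, axis=-1), 1.0, atol=1e-12)


class TestFundamentalForms:
    def test_flat(self, flat):
        f = fundamental_forms(flat, (0.4, 0.9))
        assert (f.E, f.F, f.G) == (1.0, 0.0, 1.0)
        assert (f.L, f.M, f.N) == (0.0, 0.0, 0.0)

    def test_saddle_origin(self, saddle):
        f = fundamental_forms(saddle, (0.0, 0.0))
        assert (f.E, f.F, f.G, f.L, f.N) == (1.0, 0.0, 1.0, 0.0, 0.0)
        assert f.M == pytest.approx(1.0)

    def test_saddle_at_one_one(self, saddle):
        # fx = fy = 1, W = sqrt(3)
        f = fundamental_forms(saddle, (1.0, 1.0))
        assert (f.E, f.F, f.G) == (2.0, 1.0, 2.0)
        assert f.L == f.N == 0.0
        assert f.M == pytest.approx(1 / np.sqrt(3))

    def test_discriminant_never_degenerate(self, random_quadratic):
        rng = np.random.default_rng(11)
        s = random_quadratic(3)
        pts = rng.uniform(-3, 3, (50, 2))
        f = fundamental_forms(s, (pts[:, 0], pts[:, 1]))
        assert np.all(f.discriminant >= 1.0)
        assert np.all(f.E >= 1.0) and np.all(f.G >= 1.0)


class TestCurvatures:
    def test_flat_plane_zero_everywhere(self, flat):
        f = fundamental_forms(flat, (0.2, 0.8))
        assert gauss_curvature(f) == 0.0
        assert mean_curvature(f) == 0.0

    def test_saddle_origin_textbook_values(self, saddle):
        f = fundamental_forms(saddle, (0.0, 0.0))
        assert gauss_curvature(f) == pytest.approx(-1.0)
        assert mean_curvature(f) == pytest.approx(0.0)
        k1, k2 = principal_curvatures(f)
        assert (k1, k2) == pytest.approx((1.0, -1.0))

    def test_sphere_patch_has_K_equal_inverse_radius_squared(self):
        for r in (0.5, 1.0, 2.0):
            sp = sphere_patch(r)
            for pt in [(0.0, 0.0), (0.1 * r, 0.2 * r), (-0.3 * r, 0.1 * r)]:
                f = fundamental_forms(sp, pt)
                assert gauss_curvature(f) == pytest.approx(1 / r**2, rel=1e-12)

    def test_cylinder_theorema_egregium(self):
        # isometric to the plane: K = 0; but extrinsically bent: H != 0
        cy = cylinder_patch(2.0)
        for pt in [(0.0, 0.3), (0.5, -1.0), (-1.2, 7.0)]:
            f = fundamental_forms(cy, pt)
            assert gauss_curvature(f) == pytest.approx(0.0, abs=1e-12)
            assert abs(mean_curvature(f)) > 0.01
        f0 = fundamental_forms(cy, (0.0, 0.0))
        assert mean_curvature(f0) == pytest.approx(-1 / (2 * 2.0))

    def test_eigenvalue_route_matches_closed_form(self, random_quadratic):
        """K and H from Eqs vs the shape operator I^-1 II eigenvalues."""
        rng = np.random.default_rng(123)
        n_checked = 0
        for seed in range(10):
            s = random_quadratic(seed)
            pts = rng.uniform(-2, 2, (100, 2))
            for x, y in pts:
                f = fundamental_forms(s, (x, y))
                I = np.array([[f.E, f.F], [f.F, f.G]])
                II = np.array([[f.L, f.M], [f.M, f.N]])
                eig = np.linalg.eigvals(np.linalg.solve(I, II))
                assert np.prod(eig.real) == pytest.approx(gauss_curvature(f), abs=1e-9)
                assert eig.real.sum() / 2 == pytest.approx(mean_curvature(f), abs=1e-9)
                n_checked += 1
        assert n_checked == 1000

    def test_closed_form_agrees_with_finite_difference_oracle(self, random_quadratic):
        for maker, pts in [
            (lambda: random_quadratic(5), [(0.3, 0.4), (-1.0, 0.8)]),
            (lambda: sphere_patch(2.0), [(0.2, 0.3)]),
            (lambda: cylinder_patch(3.0), [(0.5, 1.0)]),
        ]:
            surf = maker()
            dx, dy, dxx, dyy, dxy = finite_difference_patch(surf.height)
            numeric = SurfacePatch(surf.height, dx, dy, dxx, dyy, dxy)
            for pt in pts:
                fa = fundamental_forms(surf, pt)
                fn = fundamental_forms(numeric, pt)
                assert gauss_curvature(fn) == pytest.approx(gauss_curvature(fa), rel=1e-4, abs=1e-4)
                assert mean_curvature(fn) == pytest.approx(mean_curvature(fa), rel=1e-4, abs=1e-4)

    def test_intercept_does_not_change_curvature(self, random_quadratic):
        s = random_quadratic(9)
        shifted = s.with_intercept(s.intercept + 17.3)
        pt = (0.6, -0.2)
        fa, fb = fundamental_forms(s, pt), fundamental_forms(shifted, pt)
        assert gauss_curvature(fa) == gauss_curvature(fb)
        assert mean_curvature(fa) == mean_curvature(fb)
        assert principal_curvatures(fa) == principal_curvatures(fb)

    def test_domain_translation_shifts_curvature_fields_exactly(self, random_quadratic):
        s = random_quadratic(2)
        u, v = 0.7, -1.3
        g = s.translated(u, v)
        for x, y in [(0.0, 0.0), (1.1, 0.4), (-0.5, 2.0)]:
            fs = fundamental_forms(s, (x, y))
            fg = fundamental_forms(g, (x + u, y + v))
            assert gauss_curvature(fg) == pytest.approx(gauss_curvature(fs), rel=1e-12)
            assert mean_curvature(fg) == pytest.approx(mean_curvature(fs), rel=1e-12)


class TestClassify:
    @pytest.mark.parametrize("K,expected", [
        (0.0, RegionClass.FLAT),
        (0.5, RegionClass.CONVEX),
        (-1.0, RegionClass.HYPERBOLIC),
        (5e-9, RegionClass.FLAT),
    ])
    def test_sign_classification(self, K, expected):
        assert classify_point(K, tol=1e-8) is expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_point(np.nan)
        with pytest.raises(ValueError):
            classify_point(1.0, tol=0.0)

    @given(K=st.floats(-10, 10), tol=st.floats(1e-12, 1e-2))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_classification_is_exhaustive_and_consistent(self, K, tol):
        cls = classify_point(K, tol=tol)
        if abs(K) <= tol:
            assert cls is RegionClass.FLAT
        elif K > 0:
            assert cls is RegionClass.CONVEX
        else:
            assert cls is RegionClass.HYPERBOLIC


class TestCurvatureField:
    def test_flat_grid_all_zero_and_flat_class(self, flat):
        grid = LandscapeGrid.from_function(flat.height, Domain.unit(), 11, trait="flat")
        field = curvature_field(flat, grid)
        assert field.K.shape == (11, 11)
        np.testing.assert_array_equal(field.K, 0.0)
        np.testing.assert_array_equal(field.H, 0.0)
        assert all(rc is RegionClass.FLAT for rc in field.region_class.ravel())

    def test_saddle_grid_origin_node_and_H_sign_pattern(self, saddle):
        dom = Domain(1.0, 1.0)
        grid = LandscapeGrid.from_function(saddle.height, dom, 11, trait="saddle")
        field = curvature_field(saddle, grid)
        origin = (grid.x == 0) & (grid.y == 0)
        assert field.K[origin] == pytest.approx(-1.0)
        # closed form H = -xy / (1 + x² + y²)^{3/2}
        expect = -grid.x * grid.y / (1 + grid.x**2 + grid.y**2) ** 1.5
        np.testing.assert_allclose(field.H, expect, atol=1e-12)
        interior = (grid.x * grid.y) > 0
        assert np.all(field.H[interior] < 0)

    def test_saddle_H_antisymmetric_across_quadrants(self, saddle):
        xs = np.array([[0.5, -0.5], [0.5, -0.5]])
        ys = np.array([[0.5, 0.5], [-0.5, -0.5]])
        f = fundamental_forms(saddle, (xs, ys))
        H = mean_curvature(f)
        assert H[0, 0] < 0 and H[1, 1] < 0     # x*y > 0: bending upwards
        assert H[0, 1] > 0 and H[1, 0] > 0     # x*y < 0: bending downwards
        assert H[0, 0] == pytest.approx(-H[0, 1])

    def test_field_export_schema(self, saddle):
        grid = LandscapeGrid.from_function(saddle.height, Domain.unit(), 5, trait="saddle")
        frame = curvature_field(saddle, grid).to_frame()
        assert list(frame.columns) == ["x", "y", "z", "K", "H", "region_class"]
        assert len(frame) == 25
        assert set(frame["region_class"]) <= {"flat", "convex", "hyperbolic"}
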