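"""Signed-distance field machinery: mollifiers, band, curvature, regulariser."""

import numpy as np
import pytest

from alrls.level_set import (
    contour_points,
    curvature,
    dirac,
    distance_regularize,
    gradient_magnitude,
    heaviside,
    init_phi_circle,
    narrow_band,
)

EPS = 1.5


class TestInitPhiCircle:
    def test_signed_distance_values(self):
        phi = init_phi_circle((64, 64), (32, 32), 10)
        assert phi[32, 32] == pytest.approx(-10.0)
        assert abs(phi[32, 42]) < 1e-9  # on the circle
        err = np.abs(gradient_magnitude(phi) - 1.0)
        # away from the cone singularity at the centre and the image border
        # (replicate padding halves one-sided differences there)
        excluded = np.zeros((64, 64), dtype=bool)
        excluded[29:36, 29:36] = True
        excluded[0, :] = excluded[-1, :] = excluded[:, 0] = excluded[:, -1] = True
        assert err[~excluded].max() < 0.01

    def test_foreground_area_close_to_disk_area(self):
        phi = init_phi_circle((64, 64), (32, 32), 3)
        area = int((phi <= 0).sum())
        assert abs(area - np.pi * 9) <= 0.1 * np.pi * 9 + 3

    def test_border_touching_rejected(self):
        with pytest.raises(ValueError):
            init_phi_circle((32, 32), (5, 5), 6)
        with pytest.raises(ValueError):
            init_phi_circle((32, 32), (16, 16), 1)


class TestMollifiers:
    def test_heaviside_orientation(self):
        assert heaviside(0.0, EPS) == pytest.approx(0.5)
        assert heaviside(-10 * EPS, EPS) > 0.99
        assert heaviside(10 * EPS, EPS) < 0.01

    def test_heaviside_odd_symmetry(self, rng):
        x = rng.normal(0, 3, 100)
        np.testing.assert_allclose(
            np.asarray(heaviside(x, EPS)) + np.asarray(heaviside(-x, EPS)), 1.0, atol=1e-12
        )

    def test_dirac_peak_value(self):
        # compact cosine pair: peak (1 + cos 0) / (2 eps) = 1/eps
        assert dirac(0.0, EPS) == pytest.approx(1.0 / EPS)

    def test_dirac_compact_support(self):
        assert dirac(5 * EPS, EPS) == 0.0
        assert dirac(-1.01 * EPS, EPS) == 0.0

    def test_dirac_is_derivative_of_heaviside(self):
        x = np.linspace(-2 * EPS, 2 * EPS, 2001)
        h = np.asarray(heaviside(x, EPS))
        numeric = -np.gradient(h, x)
        np.testing.assert_allclose(numeric[5:-5], np.asarray(dirac(x, EPS))[5:-5], atol=2e-5)

    def test_dirac_unit_mass(self):
        x = np.linspace(-50 * EPS, 50 * EPS, 20001)
        mass = np.trapezoid(np.asarray(dirac(x, EPS)), x)
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_invalid_eps(self):
        with pytest.raises(ValueError):
            heaviside(0.0, 0.0)
        with pytest.raises(ValueError):
            dirac(0.0, -1.0)


class TestNarrowBand:
    def test_band_is_annulus_with_bounded_phi(self):
        phi = init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(phi, 2)
        assert np.all(np.abs(phi[band]) <= 2)
        assert not band[32, 32]

    def test_band_matches_exhaustive_scan(self):
        phi = init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(phi, 2)
        brute = np.zeros_like(band)
        for r in range(64):
            for c in range(64):
                brute[r, c] = abs(phi[r, c]) <= 2
        np.testing.assert_array_equal(band, brute)

    def test_saturating_width_covers_grid(self):
        phi = init_phi_circle((32, 32), (16, 16), 5)
        assert narrow_band(phi, float(np.abs(phi).max())).all()

    def test_width_validation(self):
        with pytest.raises(ValueError):
            narrow_band(np.zeros((4, 4)), 0.5)


class TestCurvature:
    def test_circle_curvature_one_over_r(self):
        for radius in (5, 8, 12):
            phi = init_phi_circle((64, 64), (32, 32), radius)
            pts = contour_points(phi)
            k = curvature(phi)[pts[:, 0], pts[:, 1]]
            assert np.median(k) == pytest.approx(1.0 / radius, rel=0.15)

    def test_plane_has_zero_curvature(self):
        rr = np.arange(32, dtype=float)[:, None] + np.zeros((1, 32))
        k = curvature(rr - 16.0)
        assert np.abs(k[2:-2, 2:-2]).max() < 1e-9

    def test_convex_foreground_sign_positive(self):
        phi = init_phi_circle((64, 64), (32, 32), 8)
        pts = contour_points(phi)
        assert np.median(curvature(phi)[pts[:, 0], pts[:, 1]]) > 0


class TestDistanceRegularize:
    @staticmethod
    def _band_err(phi, band):
        return np.abs(gradient_magnitude(phi) - 1.0)[band].mean()

    @pytest.mark.parametrize("well", ["single", "double"])
    def test_exact_sdf_is_near_fixed_point(self, well):
        phi = init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(phi, 6)
        before = self._band_err(phi, band)
        after = self._band_err(distance_regularize(phi, 0.2, 1.0, well=well), band)
        # near-fixed point: only discretisation-level drift allowed
        assert after <= before + 1e-4

    @pytest.mark.parametrize("well", ["single", "double"])
    def test_steep_sdf_error_decreases(self, well):
        phi = 2.0 * init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(init_phi_circle((64, 64), (32, 32), 10), 6)
        before = self._band_err(phi, band)
        out = phi
        for _ in range(5):
            out = distance_regularize(out, 0.2, 1.0, well=well)
        assert self._band_err(out, band) < before

    def test_shallow_sdf_single_well_recovers(self):
        # |grad phi| = 0.3: the single well drives the slope back toward 1;
        # the double well would drive it toward its flat (0) minimum instead
        phi = 0.3 * init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(init_phi_circle((64, 64), (32, 32), 10), 6)
        before = self._band_err(phi, band)
        out = phi
        for _ in range(5):
            out = distance_regularize(out, 0.2, 1.0, well="single")
        assert self._band_err(out, band) < before

    def test_shallow_sdf_double_well_stays_bounded(self):
        phi = 0.3 * init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(init_phi_circle((64, 64), (32, 32), 10), 6)
        before = self._band_err(phi, band)
        out = distance_regularize(phi, 0.2, 1.0, well="double")
        assert self._band_err(out, band) <= before + 0.01

    def test_stability_guard(self):
        with pytest.raises(ValueError):
            distance_regularize(np.zeros((8, 8)), weight=0.3, dt=1.0)

    def test_band_locality(self):
        phi = 2.0 * init_phi_circle((64, 64), (32, 32), 10)
        band = narrow_band(phi, 4)
        out = distance_regularize(phi, 0.2, 1.0, band=band)
        np.testing.assert_array_equal(out[~band], phi[~band])


class TestContourPoints:
    def test_count_scales_with_circumference(self):
        phi = init_phi_circle((64, 64), (32, 32), 10)
        n = len(contour_points(phi))
        assert 0.8 * 2 * np.pi * 10 <= n <= 1.3 * 2 * np.pi * 10

    def test_all_negative_gives_empty(self):
        assert len(contour_points(-np.ones((16, 16)))) == 0

    def test_single_pixel_foreground(self):
        phi = np.ones((16, 16))
        phi[8, 8] = -0.5
        pts = contour_points(phi)
        assert pts.tolist() == [[8, 8]]

    def test_points_lie_on_interior_side(self):
        phi = init_phi_circle((64, 64), (32, 32), 10)
        pts = contour_points(phi)
        assert np.all(phi[pts[:, 0], pts[:, 1]] <= 0)
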