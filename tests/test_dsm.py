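import numpy as np
import pytest

from sctdose.core_io import Contour, ImageGrid
from sctdose.dsm import (DoseSurfaceMap, binarize_dsm, dsm_to_eqd2,
                         interpolate_dsm, largest_cluster_ellipse,
                         unwrap_surface)


def circle_contour(slice_index, center=(25.0, 25.0), radius=10.0, n=48,
                   start=0):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(theta),
                           center[1] + radius * np.sin(theta)])
    return Contour("RECTUM", slice_index, np.roll(pts, start, axis=0))


def uniform_dose(value, shape=(6, 50, 50)):
    return ImageGrid(np.full(shape, float(value)), spacing=(2.5, 1, 1),
                     modality="DOSE", units="Gy")


class TestUnwrap:
    def test_uniform_field_gives_uniform_map(self):
        dose = uniform_dose(50.0)
        contours = [circle_contour(i) for i in range(6)]
        dsm = unwrap_surface(dose, contours, n_samples=60)
        assert dsm.raw.shape == (6, 60)
        assert np.allclose(dsm.raw, 50.0)

    def test_anterior_ramp_minimum_at_posterior_anchor(self):
        # dose grows in the anterior (row) direction: the posterior-most
        # sample (column 0) is the row minimum
        shape = (4, 50, 50)
        ramp = np.tile(np.arange(50, dtype=float)[None, :, None], (4, 1, 50))
        dose = ImageGrid(ramp, spacing=(2.5, 1, 1), modality="DOSE", units="Gy")
        dsm = unwrap_surface(dose, [circle_contour(i) for i in range(4)],
                             n_samples=80)
        assert np.all(np.argmin(dsm.raw, axis=1) == 0)
        # oracle: the ramp value at the posterior-most point (row 15)
        assert np.allclose(dsm.raw[:, 0], 15.0, atol=1e-6)

    def test_vertex_roll_invariance(self):
        dose = ImageGrid(np.random.default_rng(0).uniform(0, 60, (3, 50, 50)),
                         spacing=(2.5, 1, 1), modality="DOSE", units="Gy")
        a = unwrap_surface(dose, [circle_contour(1, start=0)], n_samples=50)
        b = unwrap_surface(dose, [circle_contour(1, start=17)], n_samples=50)
        assert np.allclose(a.raw, b.raw, atol=1e-9)

    def test_degenerate_contour_rejected(self):
        dose = uniform_dose(10.0)
        bad = Contour("RECTUM", 0, np.array([[0, 0], [1, 0], [0, 1]]))
        bad.points = bad.points[:2]  # bypass constructor check
        with pytest.raises(ValueError):
            unwrap_surface(dose, [bad])


class TestInterpolate:
    def test_constant_map_stays_constant(self):
        out = interpolate_dsm(np.full((9, 30), 7.0))
        assert out.interpolated.shape == (42, 42)
        assert np.allclose(out.interpolated, 7.0)

    def test_already_42x42_unchanged(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 70, (42, 42))
        out = interpolate_dsm(raw)
        assert np.allclose(out.interpolated, raw, atol=1e-12)

    def test_matches_brute_force_bilinear_oracle(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(0, 70, (21, 21))
        out = interpolate_dsm(raw).interpolated
        # oracle: direct bilinear with periodic columns
        rows = np.linspace(0, 20, 42)
        cols = np.linspace(0, 21, 42, endpoint=False)
        expect = np.empty((42, 42))
        for i, rp in enumerate(rows):
            r0 = min(int(np.floor(rp)), 19)
            tr = rp - r0
            for j, cp in enumerate(cols):
                c0 = int(np.floor(cp))
                tc = cp - c0
                c1 = (c0 + 1) % 21
                v00, v01 = raw[r0, c0], raw[r0, c1]
                v10, v11 = raw[r0 + 1, c0], raw[r0 + 1, c1]
                expect[i, j] = ((1 - tr) * ((1 - tc) * v00 + tc * v01)
                                + tr * ((1 - tc) * v10 + tc * v11))
        assert np.abs(out - expect).max() <= 1e-9

    def test_scaling_commutes_through_unwrap_and_interpolation(self):
        rng = np.random.default_rng(3)
        vox = rng.uniform(0, 60, (4, 50, 50))
        dose = ImageGrid(vox, spacing=(2.5, 1, 1), modality="DOSE", units="Gy")
        contours = [circle_contour(i) for i in range(4)]
        one = interpolate_dsm(unwrap_surface(dose, contours)).interpolated
        two = interpolate_dsm(unwrap_surface(dose.copy(voxels=2 * vox),
                                             contours)).interpolated
        assert np.allclose(two, 2 * one, atol=1e-9)


class TestBinaryMaps:
    def _eqd2_map(self, values):
        dsm = DoseSurfaceMap(raw=values, interpolated=values, is_eqd2=True)
        return dsm

    def test_full_map_area_one(self):
        binary, area = binarize_dsm(self._eqd2_map(np.full((42, 42), 70.0)), 51.0)
        assert area == 1.0

    def test_half_area(self):
        vals = np.zeros((42, 42))
        vals[:21] = 60.0
        _, area = binarize_dsm(self._eqd2_map(vals), 51.0)
        assert area == pytest.approx(0.5, abs=1e-12)

    def test_requires_eqd2(self):
        dsm = DoseSurfaceMap(raw=np.ones((42, 42)),
                             interpolated=np.ones((42, 42)), is_eqd2=False)
        with pytest.raises(ValueError):
            binarize_dsm(dsm, 51.0)

    def test_area_monotone_in_dose(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(30, 70, (42, 42))
        _, a = binarize_dsm(self._eqd2_map(vals), 51.0)
        _, b = binarize_dsm(self._eqd2_map(vals + 3.0), 51.0)
        assert b >= a

    def test_cranio_caudal_band_area_equals_row_fraction(self):
        # straight cylinder with dose varying only cranio-caudally:
        # every DSM row is constant, area = fraction of rows above threshold
        n_rows = 12
        raw = np.tile(np.linspace(30, 70, n_rows)[:, None], (1, 30))
        dsm = interpolate_dsm(raw)
        dsm = DoseSurfaceMap(raw=dsm.raw, interpolated=dsm.interpolated,
                             is_eqd2=True)
        _, area = binarize_dsm(dsm, 51.0)
        row_fraction = np.mean(np.linspace(30, 70, 42) >= 51.0)
        assert area == pytest.approx(row_fraction, abs=1 / 42)


class TestEllipse:
    def test_empty_map_degenerate_fit(self):
        fit = largest_cluster_ellipse(np.zeros((42, 42), dtype=bool))
        assert fit.relative_lateral_extent == 0.0
        assert fit.n_cells == 0

    def test_solid_band_closed_form_extent(self):
        # 42-row x 21-column solid band: moment ellipse of a uniform
        # rectangle has lateral extent w * 2/sqrt(3)
        binary = np.zeros((42, 42), dtype=bool)
        binary[:, 10:31] = True
        fit = largest_cluster_ellipse(binary)
        assert fit.relative_lateral_extent == pytest.approx(
            21 * (2 / np.sqrt(3)) / 42, abs=1e-9)

    def test_largest_cluster_wins(self):
        binary = np.zeros((42, 42), dtype=bool)
        binary[2:5, 2:5] = True          # 9 cells
        binary[20:30, 10:30] = True      # 200 cells
        fit = largest_cluster_ellipse(binary)
        assert fit.n_cells == 200
        assert 20 < fit.center[0] < 30

    def test_wraparound_cluster_is_single_component(self):
        binary = np.zeros((42, 42), dtype=bool)
        binary[10:20, :5] = True
        binary[10:20, -5:] = True
        fit = largest_cluster_ellipse(binary)
        assert fit.n_cells == 100
        # contiguous width 10 across the seam, not 42
        assert fit.lateral_extent < 15

    def test_eqd2_conversion_feeds_binarize(self):
        raw = np.full((10, 30), 60.0)
        dsm = dsm_to_eqd2(interpolate_dsm(raw), fractions=20, alpha_beta=3.0)
        assert np.allclose(dsm.interpolated, 72.0)
        _, area = binarize_dsm(dsm, 61.0)
        assert area == 1.0
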