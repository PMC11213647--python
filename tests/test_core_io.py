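import numpy as np
import pytest

from sctdose.core_io import (Contour, FormatError, GeometryError, ImageGrid,
                             rasterize, read_contours, read_volume, resample,
                             write_contours, write_volume)


def square(side_mm, center=(5.0, 5.0), name="SQ", slice_index=0):
    r0, c0 = center
    h = side_mm / 2
    pts = [(r0 - h, c0 - h), (r0 - h, c0 + h), (r0 + h, c0 + h), (r0 + h, c0 - h)]
    return Contour(name, slice_index, np.array(pts))


def grid(shape=(3, 12, 12), spacing=(2.5, 1.0, 1.0), fill=0.0, dtype=float):
    return ImageGrid(np.full(shape, fill, dtype=dtype), spacing=spacing)


class TestImageGrid:
    def test_rejects_nonpositive_spacing_and_nonfinite_voxels(self):
        with pytest.raises(GeometryError):
            ImageGrid(np.zeros((2, 2, 2)), spacing=(0.0, 1, 1))
        with pytest.raises(GeometryError):
            ImageGrid(np.full((2, 2, 2), np.nan))

    def test_default_spacing_matches_planning_ct_protocol(self):
        g = ImageGrid(np.zeros((2, 4, 4)))
        assert g.spacing == (2.5, 0.98, 0.98)


class TestVolumeRoundTrip:
    @pytest.mark.parametrize("dialect", ["nifti", "dicom_series"])
    def test_integer_ct_round_trip_is_exact(self, tmp_path, dialect):
        rng = np.random.default_rng(0)
        ct = ImageGrid(rng.integers(-1000, 1500, size=(3, 8, 8)).astype(np.int16),
                       spacing=(2.5, 0.98, 0.98), origin=(1.0, -2.0, 3.0))
        target = tmp_path / ("vol.nii.gz" if dialect == "nifti" else "series")
        write_volume(ct, target, dialect)
        back = read_volume(target, dialect, modality="CT")
        assert np.array_equal(back.voxels, ct.voxels)
        assert np.allclose(back.spacing, ct.spacing)
        assert np.allclose(back.origin, ct.origin)

    @pytest.mark.parametrize("dialect", ["nifti", "dicom_series"])
    def test_float_dose_round_trip_within_1e6(self, tmp_path, dialect):
        rng = np.random.default_rng(1)
        dose = ImageGrid(rng.uniform(0, 72, size=(3, 8, 8)),
                         modality="DOSE", units="Gy")
        target = tmp_path / ("dose.nii.gz" if dialect == "nifti" else "series")
        write_volume(dose, target, dialect)
        back = read_volume(target, dialect, modality="DOSE")
        assert np.abs(back.voxels - dose.voxels).max() <= 1e-6

    def test_dialect_file_layout(self, tmp_path):
        ct = grid(dtype=np.int16)
        write_volume(ct, tmp_path / "v.nii.gz", "nifti")
        write_volume(ct, tmp_path / "series", "dicom_series")
        assert (tmp_path / "v.nii.gz").is_file()
        assert len(list((tmp_path / "series").glob("*.dcm"))) == ct.shape[0]

    def test_dicom_rescale_applied(self, tmp_path):
        import pydicom

        ct = grid(shape=(2, 4, 4), fill=0.0, dtype=np.int16)
        write_volume(ct, tmp_path / "s", "dicom_series")
        f = sorted((tmp_path / "s").glob("*.dcm"))[0]
        ds = pydicom.dcmread(str(f))
        ds.RescaleIntercept = -1024
        ds.PixelData = (ds.pixel_array + 1024).astype(np.int16).tobytes()
        ds.save_as(str(f), enforce_file_format=True)
        back = read_volume(tmp_path / "s", "dicom_series")
        assert back.voxels[0].max() == 0  # 1024 stored, intercept -1024

    def test_mixed_orientation_series_rejected(self, tmp_path):
        import pydicom

        write_volume(grid(dtype=np.int16), tmp_path / "s", "dicom_series")
        f = sorted((tmp_path / "s").glob("*.dcm"))[1]
        ds = pydicom.dcmread(str(f))
        ds.ImageOrientationPatient = [0, 1, 0, 1, 0, 0]
        ds.save_as(str(f), enforce_file_format=True)
        with pytest.raises(FormatError):
            read_volume(tmp_path / "s", "dicom_series")

    def test_missing_file_raises_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_volume(tmp_path / "nope.nii.gz", "nifti")


class TestContoursIO:
    def test_json_round_trip(self, tmp_path):
        cs = [square(10), square(6, center=(3, 3), name="B", slice_index=2)]
        write_contours(cs, tmp_path / "c.json")
        back = read_contours(tmp_path / "c.json")
        assert [c.structure_name for c in back] == ["SQ", "B"]
        assert np.allclose(back[0].points, cs[0].points)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(Exception):
            Contour("X", 0, np.array([[0, 0], [1, 1]]))


class TestRasterize:
    def test_square_area_count(self):
        # 10 mm x 10 mm square, 1 mm pixels, centered off lattice points
        ref = grid()
        mask = rasterize([square(10.0, center=(5.5, 5.5))], ref)
        assert mask.voxels[0].sum() == 100
        assert mask.voxels[1:].sum() == 0

    def test_circle_area_matches_brute_force_point_in_polygon(self):
        r = 20.0
        ref = grid(shape=(1, 50, 50))
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        pts = np.column_stack([24.5 + r * np.cos(theta), 24.5 + r * np.sin(theta)])
        mask = rasterize([Contour("C", 0, pts)], ref)
        count = mask.voxels.sum()
        assert abs(count - np.pi * r ** 2) / (np.pi * r ** 2) < 0.05
        # oracle: winding test at every voxel center via crossing number
        inside = 0
        for rr in range(50):
            for cc in range(50):
                x, y = float(rr), float(cc)
                crossings = 0
                for i in range(len(pts)):
                    (r1, c1), (r2, c2) = pts[i], pts[(i + 1) % len(pts)]
                    if (c1 > y) != (c2 > y):
                        xr = r1 + (y - c1) / (c2 - c1) * (r2 - r1)
                        if x < xr:
                            crossings += 1
                inside += crossings % 2
        assert count == inside

    def test_empty_contour_list_gives_empty_mask(self):
        assert not rasterize([], grid()).voxels.any()

    def test_nested_polygon_is_monotone_and_even_odd(self):
        ref = grid()
        outer = rasterize([square(10, center=(5.5, 5.5))], ref)
        inner = rasterize([square(4, center=(5.5, 5.5))], ref)
        both = rasterize([square(10, center=(5.5, 5.5)),
                          square(4, center=(5.5, 5.5))], ref)
        assert (outer.voxels & inner.voxels).sum() == inner.voxels.sum()
        # even-odd: the nested square punches a hole
        assert both.voxels.sum() == outer.voxels.sum() - inner.voxels.sum()

    def test_contour_outside_grid_raises(self):
        with pytest.raises(IndexError):
            rasterize([square(4, slice_index=9)], grid())


class TestResample:
    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(2)
        g = ImageGrid(rng.normal(size=(4, 10, 10)), spacing=(2.5, 1, 1))
        out = resample(g, g, "trilinear")
        assert np.allclose(out.voxels, g.voxels)

    def test_constant_preserved_on_finer_grid(self):
        g = grid(fill=50.0)
        fine = ImageGrid(np.zeros((3, 23, 23)), spacing=(2.5, 0.5, 0.5))
        out = resample(g, fine, "trilinear")
        interior = out.voxels[:, 2:-2, 2:-2]
        assert np.allclose(interior, 50.0)

    def test_linear_ramp_exact_at_half_spacing(self):
        ramp = np.tile(np.arange(12, dtype=float)[None, :, None], (3, 1, 12))
        g = ImageGrid(ramp, spacing=(2.5, 2.0, 2.0))
        fine = ImageGrid(np.zeros((3, 21, 12)), spacing=(2.5, 1.0, 2.0))
        out = resample(g, fine, "trilinear")
        expected = np.arange(21) / 2.0  # analytic ramp in target coordinates
        assert np.allclose(out.voxels[1, :, 5], expected)

    def test_nearest_preserves_value_set(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.0, 7.0, 11.0], size=(4, 9, 9))
        g = ImageGrid(vals, spacing=(2.5, 1, 1))
        fine = ImageGrid(np.zeros((4, 17, 17)), spacing=(2.5, 0.5, 0.5))
        out = resample(g, fine, "nearest")
        assert set(np.unique(out.voxels)) <= {0.0, 7.0, 11.0, -1000.0}

    def test_disjoint_extents_rejected(self):
        g = grid()
        far = ImageGrid(np.zeros((3, 4, 4)), spacing=(2.5, 1, 1),
                        origin=(500.0, 0, 0))
        with pytest.raises(GeometryError):
            resample(g, far)
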