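"""I/O layer: rescale contract, series assembly, format round-trips."""

import numpy as np
import pydicom
import pytest

import bonemap as bm


class TestRescale:
    @pytest.mark.parametrize(
        "stored, m, b, hu",
        [
            (1024, 1.0, -1024.0, 0.0),  # water reference
            (24, 1.0, -1024.0, -1000.0),  # air reference
            (500, 2.0, -1000.0, 0.0),  # non-unit slope
        ],
    )
    def test_stored_to_hu(self, stored, m, b, hu):
        v = bm.CTVolume(voxels=np.full((2, 2, 2), stored, dtype=np.int16),
                        spacing=np.ones(3), rescale_slope=m, rescale_intercept=b)
        out = bm.stored_to_hu(v)
        assert out.units == "HU"
        assert np.all(out.values == hu)

    def test_hu_to_stored_inverse(self):
        hu = bm.ScalarVolume(values=np.full((2, 2, 2), 0.0), units="HU",
                             spacing=np.ones(3))
        ct = bm.hu_to_stored(hu, m=1.0, b=-1024.0)
        assert np.all(ct.voxels == 1024)
        hu2 = bm.ScalarVolume(values=np.full((2, 2, 2), -1000.0), units="HU",
                              spacing=np.ones(3))
        assert np.all(bm.hu_to_stored(hu2, m=1.0, b=-1024.0).voxels == 24)

    def test_round_trip_identity_on_integers(self, rng):
        stored = rng.integers(-2000, 3000, size=(4, 8, 8)).astype(np.int16)
        v = bm.CTVolume(voxels=stored, spacing=np.ones(3),
                        rescale_slope=1.0, rescale_intercept=-1024.0)
        back = bm.hu_to_stored(bm.stored_to_hu(v), m=1.0, b=-1024.0)
        assert np.array_equal(back.voxels, stored)

    def test_round_trip_within_half_slope(self, rng):
        vals = rng.uniform(-1000, 2000, size=(3, 4, 4))
        hu = bm.ScalarVolume(values=vals, units="HU", spacing=np.ones(3))
        m, b = 2.0, -1000.0
        rebuilt = bm.stored_to_hu(bm.hu_to_stored(hu, m=m, b=b))
        assert np.max(np.abs(rebuilt.values - vals)) <= abs(m) / 2

    def test_out_of_range_rejected(self):
        hu = bm.ScalarVolume(values=np.full((1, 1, 2), 1e7), units="HU",
                             spacing=np.ones(3))
        with pytest.raises(bm.DataError, match="representable range"):
            bm.hu_to_stored(hu, m=1.0, b=0.0)

    def test_zero_slope_rejected(self):
        hu = bm.ScalarVolume(values=np.zeros((1, 1, 1)), units="HU", spacing=np.ones(3))
        with pytest.raises(bm.DataError):
            bm.hu_to_stored(hu, m=0.0)


class TestDicomSeries:
    def test_writer_reader_round_trip(self, tmp_path, make_random_ct):
        v = make_random_ct(shape=(4, 8, 8))
        bm.write_dicom_series(v, tmp_path / "series")
        back = bm.read_dicom_series(tmp_path / "series")
        assert np.array_equal(back.voxels, v.voxels)
        assert back.rescale_slope == v.rescale_slope
        assert back.rescale_intercept == v.rescale_intercept
        assert np.allclose(back.spacing, v.spacing)
        assert np.allclose(back.origin, v.origin)
        assert np.allclose(back.orientation, v.orientation)

    def test_shuffled_filenames_sorted_by_position(self, tmp_path, make_random_ct):
        """Slice order must come from spatial position, never from filenames."""
        v = make_random_ct(shape=(5, 6, 6))
        paths = bm.write_dicom_series(v, tmp_path / "series")
        # rename so lexical order reverses spatial order
        for i, p in enumerate(paths):
            p.rename(p.parent / f"z_{len(paths) - i:02d}.dcm")
        back = bm.read_dicom_series(tmp_path / "series")
        assert np.array_equal(back.voxels, v.voxels)

    def test_missing_rescale_tags_default_with_warning(self, tmp_path, make_random_ct):
        v = make_random_ct(shape=(2, 4, 4))
        paths = bm.write_dicom_series(v, tmp_path / "series")
        for p in paths:
            ds = pydicom.dcmread(p)
            del ds.RescaleSlope
            del ds.RescaleIntercept
            ds.save_as(p, enforce_file_format=True)
        with pytest.warns(UserWarning, match="rescale tags"):
            back = bm.read_dicom_series(tmp_path / "series")
        assert back.rescale_slope == 1.0
        assert back.rescale_intercept == 0.0

    def test_mixed_series_rejected(self, tmp_path, make_random_ct):
        v = make_random_ct(shape=(2, 4, 4))
        bm.write_dicom_series(v, tmp_path / "series")
        # second series into the same directory -> mixed UIDs
        v2 = make_random_ct(shape=(2, 4, 4))
        paths = bm.write_dicom_series(v2, tmp_path / "other")
        for p in paths:
            p.rename(tmp_path / "series" / ("b_" + p.name))
        with pytest.raises(bm.DataError, match="series UIDs"):
            bm.read_dicom_series(tmp_path / "series")

    def test_empty_directory_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(bm.DataError):
            bm.read_dicom_series(tmp_path / "empty")


class TestScalarFormats:
    @pytest.mark.parametrize("suffix", [".nii", ".mha", ".mhd"])
    def test_float_round_trip_lossless(self, tmp_path, suffix, bone_volume):
        _, truth = bone_volume
        path = tmp_path / f"modulus{suffix}"
        bm.write_volume(truth.modulus, path)
        back = bm.read_volume(path, units="MPa")
        assert np.array_equal(back.values, truth.modulus.values)
        assert np.allclose(back.spacing, truth.modulus.spacing)
        assert np.allclose(back.origin, truth.modulus.origin)
        assert np.allclose(back.orientation, truth.modulus.orientation)

    def test_metaimage_units_survive(self, tmp_path, bone_volume):
        _, truth = bone_volume
        bm.write_volume(truth.modulus, tmp_path / "e.mha")
        assert bm.read_volume(tmp_path / "e.mha").units == "MPa"

    def test_dicom_encoding_within_one_step(self, tmp_path, bone_volume):
        """A 17 GPa-range float map survives 16-bit DICOM within one slope step."""
        _, truth = bone_volume
        bm.write_volume(truth.modulus, tmp_path / "edicom", format="dicom")
        back = bm.read_dicom_series(tmp_path / "edicom")
        slope = back.rescale_slope
        decoded = slope * back.voxels.astype(float) + back.rescale_intercept
        assert np.max(np.abs(decoded - truth.modulus.values)) <= slope
        assert slope == pytest.approx(truth.modulus.values.max() / 65535.0)

    def test_negative_values_rejected_for_dicom(self, tmp_path):
        v = bm.ScalarVolume(values=np.full((1, 2, 2), -5.0), units="HU",
                            spacing=np.ones(3))
        with pytest.raises(bm.DataError, match="negative"):
            bm.write_volume(v, tmp_path / "neg", format="dicom")

    def test_empty_path_rejected(self, bone_volume):
        _, truth = bone_volume
        with pytest.raises(bm.DataError):
            bm.write_volume(truth.modulus, "")

    def test_unknown_format_rejected(self, tmp_path, bone_volume):
        _, truth = bone_volume
        with pytest.raises(bm.DataError):
            bm.write_volume(truth.modulus, tmp_path / "x.nii", format="analyze")
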