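import numpy as np
import pydicom
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from noduletex import (
    CTVolume, load_archive, quantize_12bit, read_dicom_series, save_archive,
    validate_protocol, write_dicom_series,
)
from noduletex.volume_io import HU_MAX, HU_MIN

from conftest import make_volume


class TestDicomRoundTrip:
    def test_distinct_voxels_roundtrip_exactly(self, tmp_path, rng):
        voxels = rng.integers(-1024, 3071, size=(2, 2, 2))
        vol = make_volume(voxels, spacing=(0.7, 0.7, 1.1), thickness=1.1)
        write_dicom_series(vol, tmp_path)
        back = read_dicom_series(tmp_path)
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.spacing == pytest.approx(vol.spacing)

    def test_constant_volume_decodes_to_constant(self, tmp_path):
        vol = make_volume(np.full((3, 4, 4), -800))
        write_dicom_series(vol, tmp_path)
        assert np.all(read_dicom_series(tmp_path).voxels == -800)

    def test_slice_thickness_read_back(self, tmp_path):
        vol = make_volume(np.zeros((3, 4, 4)), spacing=(1, 1, 1.0),
                          thickness=1.0)
        write_dicom_series(vol, tmp_path)
        assert read_dicom_series(tmp_path).slice_thickness == 1.0

    def test_rescale_applied(self, tmp_path):
        """Stored value 100 with slope 1, intercept -1024 decodes to -924."""
        vol = make_volume(np.full((1, 2, 2), -924))
        write_dicom_series(vol, tmp_path)
        ds = pydicom.dcmread(next(tmp_path.glob("*.dcm")))
        assert float(ds.RescaleIntercept) == -1024
        assert ds.pixel_array[0, 0] == 100
        assert read_dicom_series(tmp_path).voxels[0, 0, 0] == -924

    def test_slices_sorted_by_position_not_name(self, tmp_path):
        vol = make_volume(np.arange(3 * 4 * 4).reshape(3, 4, 4) % 100)
        write_dicom_series(vol, tmp_path)
        # scramble file names; position metadata must still order the slices
        files = sorted(tmp_path.glob("*.dcm"))
        files[0].rename(tmp_path / "zzz.dcm")
        np.testing.assert_array_equal(read_dicom_series(tmp_path).voxels,
                                      vol.voxels)

    def test_invalid_volume_rejected(self, tmp_path):
        vol = make_volume(np.zeros((2, 2, 2)), spacing=(1, -1, 1))
        with pytest.raises(ValueError, match="positive"):
            write_dicom_series(vol, tmp_path)

    def test_mixed_series_rejected(self, tmp_path):
        write_dicom_series(make_volume(np.zeros((2, 2, 2))), tmp_path / "a")
        write_dicom_series(make_volume(np.ones((2, 2, 2))), tmp_path / "b")
        for f in (tmp_path / "b").glob("*.dcm"):
            ds = pydicom.dcmread(f)
            ds.SeriesInstanceUID = pydicom.uid.generate_uid()
            ds.save_as(tmp_path / "a" / ("x" + f.name))
        with pytest.raises(ValueError, match="mixed series"):
            read_dicom_series(tmp_path / "a")

    def test_missing_rescale_metadata_named(self, tmp_path):
        write_dicom_series(make_volume(np.zeros((2, 2, 2))), tmp_path)
        for f in tmp_path.glob("*.dcm"):
            ds = pydicom.dcmread(f)
            del ds.RescaleIntercept
            ds.save_as(f)
        with pytest.raises(ValueError, match="RescaleIntercept"):
            read_dicom_series(tmp_path)

    def test_nonuniform_slice_spacing_rejected(self, tmp_path):
        write_dicom_series(make_volume(np.zeros((3, 2, 2))), tmp_path)
        f = sorted(tmp_path.glob("*.dcm"))[2]
        ds = pydicom.dcmread(f)
        ds.ImagePositionPatient = [0.0, 0.0, 2.5]
        ds.save_as(f)
        with pytest.raises(ValueError, match="non-uniform"):
            read_dicom_series(tmp_path)


class TestQuantize12Bit:
    @pytest.mark.parametrize("hu,expected", [(5000, 3071), (-2000, -1024),
                                             (0, 0), (3071, 3071)])
    def test_clamping(self, hu, expected):
        vol = CTVolume(np.full((1, 1, 1), float(hu)), (1, 1, 1), 1.0)
        assert quantize_12bit(vol).voxels[0, 0, 0] == expected

    @settings(max_examples=50, deadline=None)
    @given(arrays(float, (3, 3, 3),
                  elements=st.floats(-3000, 6000, allow_nan=False)))
    def test_idempotent_and_order_preserving(self, values):
        vol = CTVolume(values, (1, 1, 1), 1.0)
        once = quantize_12bit(vol)
        twice = quantize_12bit(once)
        np.testing.assert_array_equal(once.voxels, twice.voxels)
        order = np.argsort(values.ravel(), kind="stable")
        q = once.voxels.ravel()[order]
        assert np.all(np.diff(q.astype(int)) >= 0)

    def test_range_invariant(self, rng):
        vol = CTVolume(rng.normal(0, 2000, (4, 4, 4)), (1, 1, 1), 1.0)
        q = quantize_12bit(vol).voxels
        assert q.min() >= HU_MIN and q.max() <= HU_MAX


class TestProtocolValidation:
    def test_conformant_protocol(self):
        vol = make_volume(np.zeros((1, 512, 512)), thickness=1.0)
        report = validate_protocol(vol)
        assert report.conformant and report.violations == []

    @pytest.mark.parametrize("thickness", [2.5, 0.89, 1.26])
    def test_thickness_violation(self, thickness):
        vol = make_volume(np.zeros((1, 512, 512)), thickness=thickness)
        report = validate_protocol(vol)
        assert not report.conformant
        assert report.violations == [
            ("slice_thickness", thickness, (0.90, 1.25))]

    def test_all_violations_listed(self):
        vol = make_volume(np.zeros((1, 256, 256)), thickness=0.89)
        report = validate_protocol(vol)
        assert len(report.violations) == 2
        assert {v[0] for v in report.violations} == {"slice_thickness",
                                                     "matrix_size"}

    @pytest.mark.parametrize("thickness", [0.90, 1.25])
    def test_boundaries_inclusive(self, thickness):
        vol = make_volume(np.zeros((1, 512, 512)), thickness=thickness)
        assert validate_protocol(vol).conformant


class TestArchive:
    def test_roundtrip(self, tmp_path, rng):
        vol = make_volume(rng.integers(-1024, 3071, (4, 5, 6)),
                          spacing=(0.6, 0.7, 1.2), thickness=1.2)
        vol.series_metadata["KVP"] = 120
        path = save_archive(vol, tmp_path / "vol")
        back = load_archive(path)
        np.testing.assert_array_equal(back.voxels, vol.voxels)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.slice_thickness == 1.2
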