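"""CT volume model, coordinate maps, trilinear interpolation, and readers."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bonemap as bm
from bonemap.errors import OutOfBoundsError, VolumeReadError
from bonemap.imaging import interpolate_hu, voxel_to_world, world_to_voxel

from conftest import affine_hu


def _rotation(angle, axis=2):
    c, s = np.cos(angle), np.sin(angle)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


class TestCTVolumeInvariants:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            bm.CTVolume(hu=np.zeros((3, 3, 3)), spacing=(1, 0, 1), origin=(0, 0, 0))

    def test_rejects_tiny_dims(self):
        with pytest.raises(ValueError, match="dimension"):
            bm.CTVolume(hu=np.zeros((1, 3, 3)), spacing=(1, 1, 1), origin=(0, 0, 0))

    def test_rejects_nonorthonormal_orientation(self):
        bad = np.eye(3)
        bad[0, 1] = 1e-3
        with pytest.raises(ValueError, match="orthonormal"):
            bm.CTVolume(hu=np.zeros((3, 3, 3)), spacing=(1, 1, 1), origin=(0, 0, 0),
                        orientation=bad)

    def test_rejects_nonfinite_hu(self):
        hu = np.zeros((3, 3, 3))
        hu[1, 1, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            bm.CTVolume(hu=hu, spacing=(1, 1, 1), origin=(0, 0, 0))

    def test_rigid_transform_rejects_reflection(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="determinant"):
            bm.RigidTransform(rotation=R)


class TestCoordinateMaps:
    def test_origin_maps_to_zero_index(self):
        vol = bm.CTVolume(hu=np.zeros((4, 4, 4)), spacing=(2, 3, 4), origin=(5, -1, 2),
                          orientation=_rotation(0.3))
        assert np.allclose(world_to_voxel(vol, vol.origin), (0, 0, 0), atol=1e-12)

    def test_one_step_along_each_axis(self):
        vol = bm.CTVolume(hu=np.zeros((4, 4, 4)), spacing=(2, 3, 4), origin=(5, -1, 2),
                          orientation=_rotation(0.3))
        p = vol.origin + vol.orientation @ vol.spacing
        assert np.allclose(world_to_voxel(vol, p), (1, 1, 1), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=3, max_size=3))
    def test_maps_are_mutual_inverses(self, p):
        vol = bm.CTVolume(hu=np.zeros((5, 5, 5)), spacing=(0.7, 1.3, 2.1),
                          origin=(3, -4, 1), orientation=_rotation(-0.7, axis=1))
        p = np.array(p)
        assert np.allclose(voxel_to_world(vol, world_to_voxel(vol, p)), p, atol=1e-10)
        ijk = world_to_voxel(vol, p)
        assert np.allclose(world_to_voxel(vol, voxel_to_world(vol, ijk)), ijk, atol=1e-10)


class TestInterpolation:
    def test_constant_field_everywhere(self, constant_volume):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0.5, 6.5, size=(50, 3))
        vals, clamped = interpolate_hu(constant_volume, pts)
        assert np.allclose(vals, 250.0)
        assert not clamped.any()

    def test_midpoint_of_linear_ramp(self):
        hu = np.broadcast_to(np.arange(8, dtype=float)[:, None, None], (8, 8, 8)).copy()
        vol = bm.CTVolume(hu=hu, spacing=(1, 1, 1), origin=(0, 0, 0))
        assert bm.hu_at(vol, (2.5, 3.0, 3.0)) == pytest.approx(2.5, abs=1e-12)

    def test_affine_field_reproduced_exactly(self, affine_volume):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0.0, 13.0, size=(200, 3))
        vals, _ = interpolate_hu(affine_volume, pts)
        exact = affine_hu(pts)
        assert np.allclose(vals, exact, rtol=1e-9, atol=1e-9 * np.abs(exact).max())

    def test_no_overshoot_beyond_stencil(self):
        rng = np.random.default_rng(3)
        hu = rng.uniform(-1000, 2000, size=(6, 6, 6))
        vol = bm.CTVolume(hu=hu, spacing=(1, 1, 1), origin=(0, 0, 0))
        pts = rng.uniform(0, 5, size=(300, 3))
        vals, _ = interpolate_hu(vol, pts)
        assert vals.min() >= hu.min() - 1e-12
        assert vals.max() <= hu.max() + 1e-12

    def test_clamp_mode_counts_and_uses_boundary(self, constant_volume):
        before = constant_volume.n_clamped
        v = bm.hu_at(constant_volume, (-5.0, 3.0, 3.0), oob="clamp")
        assert v == 250.0
        assert constant_volume.n_clamped == before + 1

    def test_error_mode_reports_world_coordinate(self, constant_volume):
        with pytest.raises(OutOfBoundsError, match=r"-5"):
            bm.hu_at(constant_volume, (-5.0, 3.0, 3.0), oob="error")


class TestRawRoundTrip:
    def test_constant_round_trip(self, tmp_path):
        vol = bm.CTVolume(hu=np.full((2, 2, 2), 100.0), spacing=(1, 1, 1), origin=(0, 0, 0))
        header = bm.write_volume(vol, tmp_path / "c.json", "raw")
        back = bm.read_volume(header, "raw")
        assert back.dims == (2, 2, 2)
        assert np.array_equal(back.hu, vol.hu)
        assert np.array_equal(back.spacing, vol.spacing)

    def test_missing_header_field_is_named(self, tmp_path):
        (tmp_path / "bad.json").write_text(json.dumps({"dims": [2, 2, 2]}))
        with pytest.raises(VolumeReadError, match="spacing"):
            bm.read_volume(tmp_path / "bad.json", "raw")

    def test_rescale_applied(self, tmp_path):
        vol = bm.CTVolume(hu=np.full((2, 2, 2), 10.0), spacing=(1, 1, 1), origin=(0, 0, 0))
        header = bm.write_volume(vol, tmp_path / "r.json", "raw")
        meta = json.loads(header.read_text())
        meta.update(rescale_slope=2.0, rescale_intercept=-5.0)
        header.write_text(json.dumps(meta))
        back = bm.read_volume(header, "raw")
        assert np.allclose(back.hu, 15.0)


class TestNiftiRoundTrip:
    def test_affine_ramp_bitwise(self, tmp_path, affine_volume):
        path = bm.write_volume(affine_volume, tmp_path / "a.nii", "nifti")
        back = bm.read_volume(path, "nifti")
        assert np.array_equal(back.hu, affine_volume.hu)
        assert np.allclose(back.spacing, affine_volume.spacing, atol=1e-6)
        assert np.allclose(back.origin, affine_volume.origin, atol=1e-6)


def _write_dicom_slice(path, k, rows=8, cols=8, value=100, slice_z=None, drop=()):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = rows, cols
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 1
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
    ds.PixelSpacing = [0.5, 0.5]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [0.0, 0.0, slice_z if slice_z is not None else 2.0 * k]
    arr = np.full((rows, cols), value + k, dtype=np.int16)
    ds.PixelData = arr.tobytes()
    for name in drop:
        delattr(ds, name)
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomSeries:
    def test_series_values_and_geometry(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        for k in range(4):
            _write_dicom_slice(d / f"s{k:02d}.dcm", k)
        vol = bm.read_volume(d, "dicom_dir")
        assert vol.dims == (8, 8, 4)
        # HU = stored + intercept, slice k holds 100 + k
        assert np.allclose(vol.hu[:, :, 0], 100 - 1024)
        assert np.allclose(vol.hu[:, :, 3], 103 - 1024)
        assert np.allclose(vol.spacing, (0.5, 0.5, 2.0))

    def test_missing_slice_triggers_spacing_error(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        for k in (0, 1, 3, 4):  # slice 2 deleted
            _write_dicom_slice(d / f"s{k:02d}.dcm", k)
        with pytest.raises(VolumeReadError, match="non-uniform slice spacing"):
            bm.read_volume(d, "dicom_dir")

    def test_missing_rescale_is_named(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        for k in range(3):
            _write_dicom_slice(d / f"s{k}.dcm", k, drop=("RescaleSlope",))
        with pytest.raises(VolumeReadError, match="RescaleSlope"):
            bm.read_volume(d, "dicom_dir")
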