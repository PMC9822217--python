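"""CT volume data model and continuous Hounsfield-field evaluation.

A CT scan is modelled as a regular voxel grid of Hounsfield units (HU)
together with a voxel-to-world affine map

    world = origin + orientation @ (spacing * index)

with 0-based indices and the voxel value located at the voxel center.
All geometry is in millimetres.  The HU field is evaluated at arbitrary
world points by trilinear interpolation among the eight surrounding voxel
centers, which is exact for fields that are affine in world coordinates.

Readers are provided for DICOM series directories (rescale slope and
intercept honoured), NIfTI-1 (the sform/qform affine is converted to the
internal origin/orientation/spacing form), and raw binary arrays with a
JSON sidecar header.  Voxel data is stored as float64 after any rescale,
regardless of the on-disk integer type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import OutOfBoundsError, VolumeReadError

__all__ = [
    "CTVolume",
    "RigidTransform",
    "read_volume",
    "write_volume",
    "world_to_voxel",
    "voxel_to_world",
    "hu_at",
    "interpolate_hu",
]

_ORTHO_TOL = 1e-8


def _check_orthonormal(mat: np.ndarray, name: str) -> None:
    if mat.shape != (3, 3):
        raise ValueError(f"{name} must be 3x3, got {mat.shape}")
    err = np.abs(mat.T @ mat - np.eye(3)).max()
    if err > _ORTHO_TOL:
        raise ValueError(f"{name} not orthonormal (max deviation {err:.2e})")


@dataclass
class CTVolume:
    """Regular voxel grid of Hounsfield units with a voxel->world map.

    Parameters
    ----------
    hu
        Voxel values in HU, shape ``dims``, any float dtype (stored as is).
    spacing
        Voxel pitch along each grid axis, mm, all > 0.
    origin
        World position of voxel (0, 0, 0)'s center, mm.
    orientation
        3x3 direction-cosine matrix; column ``k`` is the world direction of
        grid axis ``k``.  Must be orthonormal within 1e-8.
    """

    hu: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    #: number of interpolation queries clamped to the hull so far
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=np.float64)
        if self.hu.ndim != 3:
            raise ValueError("hu array must be 3-D")
        if any(d < 2 for d in self.hu.shape):
            raise ValueError(f"each dimension must be >= 2, got {self.hu.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        _check_orthonormal(self.orientation, "orientation")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.hu.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world homogeneous affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def hu_range(self) -> tuple[float, float]:
        return float(self.hu.min()), float(self.hu.max())


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map taking mesh coordinates into CT world coordinates (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64).reshape(3)
        )
        _check_orthonormal(self.rotation, "rotation")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (determinant +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return bool(
            np.array_equal(self.rotation, np.eye(3))
            and np.array_equal(self.translation, np.zeros(3))
        )


# ---------------------------------------------------------------------------
# coordinate maps
# ---------------------------------------------------------------------------

def voxel_to_world(vol: CTVolume, ijk: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices (..., 3) to world mm coordinates."""
    ijk = np.asarray(ijk, dtype=np.float64)
    return (ijk * vol.spacing) @ vol.orientation.T + vol.origin


def world_to_voxel(vol: CTVolume, p: np.ndarray) -> np.ndarray:
    """Map world mm coordinates (..., 3) to continuous voxel indices.

    Exact inverse of :func:`voxel_to_world`; may return out-of-grid values.
    """
    p = np.asarray(p, dtype=np.float64)
    return ((p - vol.origin) @ vol.orientation) / vol.spacing


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def interpolate_hu(
    vol: CTVolume, points: np.ndarray, oob: str = "clamp"
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear HU evaluation at world points.

    Parameters
    ----------
    points
        (n, 3) world coordinates in mm.
    oob
        ``"clamp"``: coordinates outside the voxel-center hull are clamped
        onto the hull boundary (counted on ``vol.n_clamped``);
        ``"error"``: raise :class:`OutOfBoundsError` for the first outside
        point, reporting its world coordinate.

    Returns
    -------
    values, clamped
        ``values``: (n,) interpolated HU; ``clamped``: (n,) bool mask of
        queries that fell outside the hull.
    """
    if oob not in ("clamp", "error"):
        raise ValueError(f"oob must be 'clamp' or 'error', got {oob!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    c = world_to_voxel(vol, pts)
    upper = np.array(vol.dims, dtype=np.float64) - 1.0
    outside = np.any((c < 0.0) | (c > upper), axis=1)
    if oob == "error" and outside.any():
        bad = pts[np.argmax(outside)]
        raise OutOfBoundsError(
            f"point ({bad[0]:g}, {bad[1]:g}, {bad[2]:g}) mm is outside the "
            f"voxel-center hull"
        )
    if outside.any():
        c = np.clip(c, 0.0, upper)
        vol.n_clamped += int(outside.sum())

    # lower corner index, clipped so i0+1 is always valid
    i0 = np.minimum(np.floor(c), upper - 1.0).astype(np.intp)
    i0 = np.maximum(i0, 0)
    f = c - i0
    hu = vol.hu
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    c000 = hu[x0, y0, z0]
    c100 = hu[x0 + 1, y0, z0]
    c010 = hu[x0, y0 + 1, z0]
    c110 = hu[x0 + 1, y0 + 1, z0]
    c001 = hu[x0, y0, z0 + 1]
    c101 = hu[x0 + 1, y0, z0 + 1]
    c011 = hu[x0, y0 + 1, z0 + 1]
    c111 = hu[x0 + 1, y0 + 1, z0 + 1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz, outside


def hu_at(vol: CTVolume, p: np.ndarray, oob: str = "clamp") -> float:
    """Trilinear HU value at a single world point (mm)."""
    values, _ = interpolate_hu(vol, np.asarray(p, dtype=np.float64).reshape(1, 3), oob=oob)
    return float(values[0])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume as HU.

    ``format`` is one of ``dicom_dir``, ``nifti``, ``raw`` (raw binary plus
    JSON sidecar header); if omitted it is inferred from the path (directory
    -> DICOM series, ``.nii``/``.nii.gz`` -> NIfTI, ``.json`` -> raw).
    Any rescale declared by the format is applied, so voxel values are HU.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "dicom_dir"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif path.suffix == ".json":
            format = "raw"
        else:
            raise VolumeReadError(f"cannot infer volume format from {path}")
    if format == "dicom_dir":
        return _read_dicom_dir(path)
    if format == "nifti":
        return _read_nifti(path)
    if format in ("raw", "raw+header"):
        return _read_raw(path)
    raise VolumeReadError(f"unknown volume format {format!r}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise VolumeReadError(f"cannot read NIfTI {path}: {exc}") from exc
    aff = np.asarray(img.affine, dtype=np.float64)
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise VolumeReadError(f"NIfTI {path}: degenerate affine (zero column)")
    orientation = lin / spacing[np.newaxis, :]
    try:
        _check_orthonormal(orientation, "NIfTI affine directions")
    except ValueError as exc:
        raise VolumeReadError(f"NIfTI {path}: sheared affine unsupported: {exc}") from exc
    data = np.asarray(img.get_fdata(dtype=np.float64))  # scl_slope/inter applied
    if data.ndim != 3:
        raise VolumeReadError(f"NIfTI {path}: expected 3-D data, got {data.ndim}-D")
    return CTVolume(hu=data, spacing=spacing, origin=aff[:3, 3], orientation=orientation)


_RAW_FIELDS = ("dims", "spacing", "origin", "dtype")


def _read_raw(path: Path) -> CTVolume:
    try:
        header = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise VolumeReadError(f"cannot read raw header {path}: {exc}") from exc
    for key in _RAW_FIELDS:
        if key not in header:
            raise VolumeReadError(f"raw header {path} missing required field {key!r}")
    dims = tuple(int(d) for d in header["dims"])
    dtype = np.dtype(header["dtype"])
    if header.get("byte_order") == "big":
        dtype = dtype.newbyteorder(">")
    raw_name = header.get("data", path.stem + ".raw")
    raw_path = path.parent / raw_name
    try:
        flat = np.fromfile(raw_path, dtype=dtype)
    except OSError as exc:
        raise VolumeReadError(f"cannot read raw data {raw_path}: {exc}") from exc
    if flat.size != int(np.prod(dims)):
        raise VolumeReadError(
            f"raw data {raw_path}: {flat.size} values, header declares {np.prod(dims)}"
        )
    hu = flat.astype(np.float64).reshape(dims, order="C")
    slope = float(header.get("rescale_slope", 1.0))
    intercept = float(header.get("rescale_intercept", 0.0))
    hu = hu * slope + intercept
    return CTVolume(
        hu=hu,
        spacing=header["spacing"],
        origin=header["origin"],
        orientation=np.asarray(header.get("orientation", np.eye(3).tolist()), dtype=float),
    )


_SLICE_SPACING_TOL = 1e-3  # mm


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise VolumeReadError(f"no DICOM image slices found in {path}")
    ref = slices[0]
    for name in ("RescaleSlope", "RescaleIntercept", "ImageOrientationPatient",
                 "ImagePositionPatient", "PixelSpacing"):
        if not hasattr(ref, name):
            raise VolumeReadError(f"DICOM series {path}: missing required field {name}")
    iop = np.asarray([float(v) for v in ref.ImageOrientationPatient])
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    slices.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))
    positions = np.array(
        [np.dot(np.asarray(ds.ImagePositionPatient, float), normal) for ds in slices]
    )
    if len(slices) < 2:
        raise VolumeReadError(f"DICOM series {path}: need at least two slices")
    steps = np.diff(positions)
    if np.any(steps <= 0):
        raise VolumeReadError(f"DICOM series {path}: duplicate slice positions")
    if steps.max() - steps.min() > _SLICE_SPACING_TOL:
        raise VolumeReadError(
            f"DICOM series {path}: non-uniform slice spacing "
            f"(min {steps.min():.6g} mm, max {steps.max():.6g} mm, tol {_SLICE_SPACING_TOL} mm)"
        )
    slice_step = float(steps.mean())
    # PixelSpacing = (row pitch, column pitch) = (step along col_dir, step along row_dir)
    pix = [float(v) for v in ref.PixelSpacing]
    spacing = np.array([pix[1], pix[0], slice_step])
    orientation = np.column_stack([row_dir, col_dir, normal])
    nrow, ncol = int(ref.Rows), int(ref.Columns)
    hu = np.empty((ncol, nrow, len(slices)), dtype=np.float64)
    for k, ds in enumerate(slices):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(ds.RescaleSlope)
        intercept = float(ds.RescaleIntercept)
        # pixel_array is (rows, cols); grid axis 0 runs along the row direction
        hu[:, :, k] = (arr * slope + intercept).T
    origin = np.asarray(slices[0].ImagePositionPatient, dtype=np.float64)
    return CTVolume(hu=hu, spacing=spacing, origin=origin, orientation=orientation)


def write_volume(vol: CTVolume, path: str | Path, format: str | None = None) -> Path:
    """Write a volume to NIfTI (``.nii``/``.nii.gz``) or raw+JSON sidecar."""
    path = Path(path)
    if format is None:
        format = "nifti" if path.name.endswith((".nii", ".nii.gz")) else "raw"
    if format == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(vol.hu, vol.affine)
        img.set_data_dtype(np.float64)
        nib.save(img, str(path))
        return path
    if format in ("raw", "raw+header"):
        if path.suffix != ".json":
            path = path.with_suffix(".json")
        raw_path = path.with_suffix(".raw")
        vol.hu.astype(np.float64).tofile(raw_path)
        header = {
            "dims": list(vol.dims),
            "spacing": vol.spacing.tolist(),
            "origin": vol.origin.tolist(),
            "orientation": vol.orientation.tolist(),
            "dtype": "float64",
            "byte_order": "little",
            "data": raw_path.name,
        }
        path.write_text(json.dumps(header, indent=1))
        return path
    raise VolumeReadError(f"unknown volume format {format!r}")
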