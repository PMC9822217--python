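"""Deterministic synthetic CT volumes and structured tet meshes.

Every phantom kind has a closed-form HU field in world coordinates, so all
interpolation and element-averaging stages can be checked against exact
oracles without any patient data:

``constant``
    Uniform HU everywhere.
``affine``
    HU(x, y, z) = ax + by + cz + d — trilinear interpolation reproduces
    this field exactly, making it the canonical interpolation oracle.
``shell``
    A bone-like body: a thin high-HU spherical shell (cortical bone)
    around a low-HU interior (trabecular bone), in a soft background.
``two_phase``
    A voxel-parity checkerboard alternating between two HU values —
    a worst case for sub-voxel averaging.

Optional Gaussian noise is applied only when a seed is given, so
every volume is bitwise reproducible for a fixed spec.

Box meshes use the Kuhn 6-tet subdivision of each grid cube, so all
elements are congruent up to reflection and the mesh volume equals the box
volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .femesh import FEMesh
from .imaging import CTVolume, voxel_to_world

__all__ = ["PhantomSpec", "make_volume", "phantom_field", "make_box_mesh", "load_phantom_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic CT phantom description.

    Parameters
    ----------
    kind
        ``constant`` | ``affine`` | ``shell`` | ``two_phase``.
    params
        Kind-specific:

        * constant: ``{"hu": value}``
        * affine: ``{"coeffs": [a, b, c, d]}`` for HU = ax + by + cz + d
        * shell: ``{"center": [x,y,z], "r_inner": mm, "r_outer": mm,
          "hu_shell": HU, "hu_interior": HU, "hu_background": HU,
          "norm": "l2"|"linf"}`` — ``l2`` (default) is a spherical body;
          ``linf`` is a cubic body whose interfaces are axis-aligned
          planes, convenient when the shell must conform to a box mesh
        * two_phase: ``{"hu_low": HU, "hu_high": HU}`` (voxel-parity board)
    dims, spacing, origin
        Grid geometry (voxels, mm, mm).
    noise_sd
        Optional additive Gaussian noise in HU; requires ``seed``.
    """

    kind: str
    params: dict
    dims: tuple[int, int, int] = (16, 16, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "affine", "shell", "two_phase"):
            raise ConfigError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ConfigError("noise requires an explicit seed")
        if self.kind == "shell":
            ri, ro = self.params.get("r_inner", 0), self.params.get("r_outer", 0)
            if not 0 < ri < ro:
                raise ConfigError(f"shell radii must satisfy 0 < inner < outer, got {ri}, {ro}")


def phantom_field(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Noise-free analytic HU at world points (n, 3) — the exact oracle.

    The ``two_phase`` board is defined on voxel parity, so between voxel
    centers this returns the value of the *nearest* voxel, matching the
    sampled volume only at voxel centers.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    p = spec.params
    if spec.kind == "constant":
        return np.full(len(pts), float(p["hu"]))
    if spec.kind == "affine":
        a, b, c, d = (float(v) for v in p["coeffs"])
        return a * pts[:, 0] + b * pts[:, 1] + c * pts[:, 2] + d
    if spec.kind == "shell":
        d = pts - np.asarray(p["center"], dtype=np.float64)
        if p.get("norm", "l2") == "linf":
            r = np.abs(d).max(axis=1)
        else:
            r = np.linalg.norm(d, axis=1)
        hu = np.full(len(pts), float(p.get("hu_background", 0.0)))
        hu[r <= p["r_outer"]] = float(p["hu_shell"])
        hu[r <= p["r_inner"]] = float(p["hu_interior"])
        return hu
    # two_phase: parity of the nearest voxel index sum
    idx = np.rint((pts - np.asarray(spec.origin)) / np.asarray(spec.spacing)).astype(np.int64)
    low, high = float(p["hu_low"]), float(p["hu_high"])
    return np.where(idx.sum(axis=1) % 2 == 0, low, high)


def make_volume(spec: PhantomSpec) -> CTVolume:
    """Sample the analytic field at voxel centers; bitwise reproducible."""
    nx, ny, nz = spec.dims
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    vol_stub = CTVolume(
        hu=np.zeros(spec.dims),
        spacing=np.asarray(spec.spacing),
        origin=np.asarray(spec.origin),
    )
    pts = voxel_to_world(vol_stub, idx)
    hu = phantom_field(spec, pts).reshape(spec.dims)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
    return CTVolume(hu=hu, spacing=np.asarray(spec.spacing), origin=np.asarray(spec.origin))


# ---------------------------------------------------------------------------
# structured box mesh
# ---------------------------------------------------------------------------

# Kuhn subdivision: one tet per permutation pi of the axes; the tet walks
# from (0,0,0) to (1,1,1) adding one unit step per axis in pi's order.
_KUHN_TETS: list[np.ndarray] = []
for _pi in sorted(permutations(range(3))):
    _verts = [np.zeros(3)]
    for _ax in _pi:
        _step = np.zeros(3)
        _step[_ax] = 1.0
        _verts.append(_verts[-1] + _step)
    _KUHN_TETS.append(np.array(_verts))


def make_box_mesh(
    extent: tuple[float, float, float],
    divisions: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> FEMesh:
    """Structured tet mesh of an axis-aligned box (mm).

    Each of the ``nx*ny*nz`` grid cubes is split into the six Kuhn
    tetrahedra, so the element count is ``6*nx*ny*nz`` and the summed
    element volume equals the box volume exactly.  Node and element ids
    are 1-based.
    """
    extent = np.asarray(extent, dtype=np.float64)
    div = np.asarray(divisions, dtype=np.int64)
    if np.any(div < 1):
        raise ConfigError(f"divisions must be >= 1, got {divisions}")
    if np.any(extent <= 0):
        raise ConfigError(f"extent must be positive, got {extent}")
    h = extent / div
    nx, ny, nz = (int(d) + 1 for d in div)

    def node_index(i, j, k):
        return (i * ny + j) * nz + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    grid = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    coords = grid * h + np.asarray(origin, dtype=np.float64)

    conn = []
    for ci in range(int(div[0])):
        for cj in range(int(div[1])):
            for ck in range(int(div[2])):
                base = np.array([ci, cj, ck])
                for tet in _KUHN_TETS:
                    quad = [
                        node_index(*(base + v.astype(np.int64))) for v in tet
                    ]
                    conn.append(quad)
    conn = np.asarray(conn, dtype=np.int64)
    n_pts = nx * ny * nz
    return FEMesh(
        node_ids=np.arange(1, n_pts + 1),
        coords=coords,
        elem_ids=np.arange(1, len(conn) + 1),
        conn=conn,
    )


def load_phantom_spec(source: str | Path | dict) -> PhantomSpec:
    """Phantom spec from a YAML/JSON file or dict."""
    if not isinstance(source, dict):
        import yaml

        source = yaml.safe_load(Path(source).read_text())
    if not isinstance(source, dict):
        raise ConfigError("phantom spec must be a mapping")
    known = {"kind", "params", "dims", "spacing", "origin", "noise_sd", "seed"}
    unknown = set(source) - known
    if unknown:
        raise ConfigError(f"unknown phantom spec fields: {sorted(unknown)}")
    src = dict(source)
    for key in ("dims", "spacing", "origin"):
        if key in src:
            src[key] = tuple(src[key])
    return PhantomSpec(**src)
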