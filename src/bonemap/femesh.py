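"""Tetrahedral FE mesh container, geometry predicates, and Abaqus/VTK I/O.

Meshes are 4-node linear tetrahedra only (the constant-strain element);
quadratic tets and other cell types are rejected with an explicit error.
Node coordinates are in mm.  On construction every element is put into
positive orientation (signed volume > 0) by swapping its last two nodes
where needed, and elements below the degeneracy tolerance raise.

The Abaqus dialect is the comma-separated ``.inp`` subset: ``*NODE``,
``*ELEMENT, TYPE=C3D4``, ``*ELSET``, ``*NSET``, ``*MATERIAL``/``*ELASTIC``/
``*DENSITY``, ``*SOLID SECTION``.  Keyword lines are case-insensitive and
ids are 1-based as in the format.  Unrecognised keyword blocks are kept
verbatim and re-emitted on write so a mapped file remains usable downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .errors import DegenerateElementError, MeshError, UnsupportedElementError

if TYPE_CHECKING:  # pragma: no cover
    from .binning import MaterialBin
    from .hu_mapping import MaterialAssignment

__all__ = [
    "FEMesh",
    "MaterialCard",
    "read_abaqus_inp",
    "write_abaqus_inp",
    "write_vtk",
    "read_vtk",
    "tet_volume",
    "element_centroid",
    "point_in_tet",
]

#: elements with |volume| below this are degenerate (mm^3)
DEGENERATE_VOLUME = 1e-12

_TET4_ALIASES = {"C3D4", "C3D4H", "C3D4T", "DC3D4"}


@dataclass(frozen=True)
class MaterialCard:
    """Isotropic linear-elastic material constants for one element set."""

    name: str
    young_modulus: float  # MPa
    poisson_ratio: float
    density: float | None = None  # g/cm^3

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}")


@dataclass
class FEMesh:
    """Tet4 mesh: node table, connectivity, and named node/element sets.

    ``conn`` holds 0-based row indices into ``coords``; the public id
    spaces (``node_ids``, ``elem_ids``) are arbitrary unique integers as
    read from file (1-based for Abaqus sources).
    """

    node_ids: np.ndarray  # (n,) int
    coords: np.ndarray  # (n, 3) float, mm
    elem_ids: np.ndarray  # (m,) int
    conn: np.ndarray  # (m, 4) int, rows into coords
    elsets: dict[str, np.ndarray] = dc_field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = dc_field(default_factory=dict)
    extra_blocks: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.elem_ids = np.asarray(self.elem_ids, dtype=np.int64)
        self.conn = np.asarray(self.conn, dtype=np.int64).reshape(-1, 4)
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise MeshError("duplicate node ids")
        if len(np.unique(self.elem_ids)) != len(self.elem_ids):
            raise MeshError("duplicate element ids")
        if self.conn.size and (self.conn.min() < 0 or self.conn.max() >= len(self.coords)):
            raise MeshError("element references a non-existent node")
        self._eid_to_row = {int(e): i for i, e in enumerate(self.elem_ids)}
        self._nid_to_row = {int(n): i for i, n in enumerate(self.node_ids)}
        self._fix_orientation()

    def _fix_orientation(self) -> None:
        vols = self.signed_volumes()
        flip = vols < 0
        if flip.any():
            self.conn[flip] = self.conn[flip][:, [0, 1, 3, 2]]
            vols = np.abs(vols)
        bad = np.flatnonzero(vols < DEGENERATE_VOLUME)
        if bad.size:
            ids = self.elem_ids[bad[:10]].tolist()
            raise DegenerateElementError(
                f"{bad.size} degenerate element(s) (volume < {DEGENERATE_VOLUME} mm^3), "
                f"e.g. ids {ids}"
            )

    # -- geometry ----------------------------------------------------------

    def vertex_tensor(self) -> np.ndarray:
        """(m, 4, 3) vertex coordinates per element."""
        return self.coords[self.conn]

    def signed_volumes(self) -> np.ndarray:
        v = self.vertex_tensor()
        e = v[:, 1:, :] - v[:, :1, :]
        return np.linalg.det(e) / 6.0

    def volumes(self) -> np.ndarray:
        """(m,) element volumes in mm^3 (positive after orientation fix-up)."""
        return np.abs(self.signed_volumes())

    def centroids(self) -> np.ndarray:
        """(m, 3) element centroids (vertex means), mm."""
        return self.vertex_tensor().mean(axis=1)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_elements(self) -> int:
        return len(self.elem_ids)

    def elem_row(self, eid: int) -> int:
        try:
            return self._eid_to_row[int(eid)]
        except KeyError:
            raise MeshError(f"no element with id {eid}") from None

    def node_row(self, nid: int) -> int:
        try:
            return self._nid_to_row[int(nid)]
        except KeyError:
            raise MeshError(f"no node with id {nid}") from None

    def element_vertices(self, eid: int) -> np.ndarray:
        return self.coords[self.conn[self.elem_row(eid)]]

    def total_volume(self) -> float:
        return float(self.volumes().sum())


def tet_volume(mesh: FEMesh, eid: int) -> float:
    """Element volume |det(edge matrix)|/6 in mm^3."""
    v = mesh.element_vertices(eid)
    vol = abs(float(np.linalg.det(v[1:] - v[0]))) / 6.0
    if vol < DEGENERATE_VOLUME:
        raise DegenerateElementError(f"element {eid} is degenerate (volume {vol:g} mm^3)")
    return vol


def element_centroid(mesh: FEMesh, eid: int) -> np.ndarray:
    """Vertex-mean centroid of an element, mm."""
    return mesh.element_vertices(eid).mean(axis=0)


def barycentric_coordinates(vertices: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of ``p`` w.r.t. a tet's (4, 3) vertices."""
    T = (vertices[1:] - vertices[0]).T
    det = np.linalg.det(T)
    if abs(det) / 6.0 < DEGENERATE_VOLUME:
        raise DegenerateElementError("degenerate tetrahedron in barycentric test")
    lam = np.linalg.solve(T, np.asarray(p, dtype=np.float64) - vertices[0])
    return np.concatenate([[1.0 - lam.sum()], lam])


def point_in_tet(mesh: FEMesh, eid: int, p: np.ndarray, tol: float = 1e-9) -> bool:
    """True iff all barycentric coordinates of ``p`` are >= -tol."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    lam = barycentric_coordinates(mesh.element_vertices(eid), p)
    return bool(np.all(lam >= -tol))


def points_in_tet(vertices: np.ndarray, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Vectorised membership mask of (n, 3) points in one tet."""
    T = (vertices[1:] - vertices[0]).T
    if abs(np.linalg.det(T)) / 6.0 < DEGENERATE_VOLUME:
        raise DegenerateElementError("degenerate tetrahedron in membership test")
    lam = np.linalg.solve(T, (np.atleast_2d(pts) - vertices[0]).T).T
    lam0 = 1.0 - lam.sum(axis=1)
    return (lam0 >= -tol) & np.all(lam >= -tol, axis=1)


# ---------------------------------------------------------------------------
# Abaqus .inp subset
# ---------------------------------------------------------------------------

def _parse_keyword_line(line: str) -> tuple[str, dict[str, str]]:
    parts = [p.strip() for p in line.lstrip("*").split(",")]
    keyword = parts[0].upper()
    params: dict[str, str] = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            params[k.strip().upper()] = v.strip()
        elif p:
            params[p.upper()] = ""
    return keyword, params


def read_abaqus_inp(path: str | Path) -> FEMesh:
    """Read the supported Abaqus ``.inp`` subset into an :class:`FEMesh`.

    Raises :class:`UnsupportedElementError` for any element type outside the
    C3D4 family, naming the offending type.  Unknown keyword blocks are
    preserved verbatim on ``extra_blocks``.
    """
    lines = Path(path).read_text().splitlines()
    node_ids: list[int] = []
    coords: list[list[float]] = []
    elem_ids: list[int] = []
    elem_nodes: list[list[int]] = []
    elsets: dict[str, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    extra: list[str] = []

    i = 0
    n = len(lines)

    def block_end(j: int) -> int:
        while j < n and not lines[j].lstrip().startswith("*"):
            j += 1
        return j

    while i < n:
        stripped = lines[i].strip()
        if not stripped or stripped.startswith("**"):
            i += 1
            continue
        if not stripped.startswith("*"):
            raise MeshError(f"{path}: stray data line outside any keyword block: {stripped!r}")
        keyword, params = _parse_keyword_line(stripped)
        j = block_end(i + 1)
        data = [ln for ln in lines[i + 1 : j] if ln.strip() and not ln.strip().startswith("**")]
        if keyword == "NODE":
            for ln in data:
                fields = [f for f in ln.split(",") if f.strip()]
                node_ids.append(int(fields[0]))
                coords.append([float(f) for f in fields[1:4]])
        elif keyword == "ELEMENT":
            etype = params.get("TYPE", "").upper()
            if etype not in _TET4_ALIASES:
                raise UnsupportedElementError(
                    f"{path}: element type {etype or '<missing>'} is not a supported "
                    f"4-node tetrahedron ({sorted(_TET4_ALIASES)})"
                )
            first_new = len(elem_ids)
            pending: list[str] = []
            for ln in data:
                pending.extend(f for f in ln.split(",") if f.strip())
                # a C3D4 record is id + 4 nodes; records may wrap lines
                while len(pending) >= 5:
                    rec, pending = pending[:5], pending[5:]
                    elem_ids.append(int(rec[0]))
                    elem_nodes.append([int(v) for v in rec[1:5]])
            if pending:
                raise MeshError(f"{path}: incomplete element record {pending}")
            target = params.get("ELSET")
            if target:
                elsets.setdefault(target, []).extend(elem_ids[first_new:])
        elif keyword in ("ELSET", "NSET"):
            name = params.get("ELSET" if keyword == "ELSET" else "NSET", "")
            ids: list[int] = []
            if "GENERATE" in params:
                for ln in data:
                    lo, hi, *step = [int(f) for f in ln.split(",") if f.strip()]
                    ids.extend(range(lo, hi + 1, step[0] if step else 1))
            else:
                for ln in data:
                    ids.extend(int(f) for f in ln.split(",") if f.strip())
            (elsets if keyword == "ELSET" else nsets).setdefault(name, []).extend(ids)
        else:
            extra.append("\n".join(lines[i:j]))
        i = j

    if not node_ids or not elem_ids:
        raise MeshError(f"{path}: no *NODE or *ELEMENT block found")
    if len(set(node_ids)) != len(node_ids):
        raise MeshError(f"{path}: duplicate node ids")
    if len(set(elem_ids)) != len(elem_ids):
        raise MeshError(f"{path}: duplicate element ids")
    nid_to_row = {nid: k for k, nid in enumerate(node_ids)}
    try:
        conn = np.array([[nid_to_row[v] for v in quad] for quad in elem_nodes], dtype=np.int64)
    except KeyError as exc:
        raise MeshError(f"{path}: element references undefined node {exc}") from None
    return FEMesh(
        node_ids=np.array(node_ids),
        coords=np.array(coords),
        elem_ids=np.array(elem_ids),
        conn=conn,
        elsets={k: np.array(sorted(set(v)), dtype=np.int64) for k, v in elsets.items()},
        node_sets={k: np.array(sorted(set(v)), dtype=np.int64) for k, v in nsets.items()},
        extra_blocks=extra,
    )


def _chunk(values: Iterable[int], per_line: int = 16) -> Iterable[str]:
    buf: list[str] = []
    for v in values:
        buf.append(str(v))
        if len(buf) == per_line:
            yield ", ".join(buf)
            buf = []
    if buf:
        yield ", ".join(buf)


def write_abaqus_inp(
    mesh: FEMesh,
    path: str | Path,
    assignment: "MaterialAssignment | None" = None,
    bins: "list[MaterialBin] | None" = None,
    poisson_ratio: float = 0.3,
) -> Path:
    """Write the mesh, and optionally one material per bin, as Abaqus ``.inp``.

    With ``bins`` given, every element must belong to exactly one bin; each
    bin is emitted as an ``*ELSET`` plus a ``*MATERIAL``/``*ELASTIC`` card
    (E in MPa, the bin's representative modulus) and a ``*SOLID SECTION``
    tying the two together.
    """
    path = Path(path)
    out: list[str] = ["*NODE"]
    for nid, (x, y, z) in zip(mesh.node_ids, mesh.coords):
        out.append(f"{nid}, {x:.10g}, {y:.10g}, {z:.10g}")
    out.append("*ELEMENT, TYPE=C3D4")
    for eid, quad in zip(mesh.elem_ids, mesh.conn):
        nids = mesh.node_ids[quad]
        out.append(f"{eid}, {nids[0]}, {nids[1]}, {nids[2]}, {nids[3]}")
    for name, ids in mesh.node_sets.items():
        out.append(f"*NSET, NSET={name}")
        out.extend(_chunk(ids))

    if bins is not None:
        covered = np.concatenate([b.element_ids for b in bins]) if bins else np.array([], int)
        if len(covered) != len(np.unique(covered)):
            raise MeshError("material bins overlap: an element appears in two bins")
        missing = np.setdiff1d(mesh.elem_ids, covered)
        if missing.size:
            raise MeshError(
                f"{missing.size} element(s) not assigned to any material bin, "
                f"e.g. ids {missing[:10].tolist()}"
            )
        rho_by_eid = None
        if assignment is not None:
            rho_by_eid = dict(zip(assignment.elem_ids.tolist(), assignment.rho.tolist()))
        for b in bins:
            set_name = f"MAT_BIN_{b.index}"
            out.append(f"*ELSET, ELSET={set_name}")
            out.extend(_chunk(sorted(int(e) for e in b.element_ids)))
            out.append(f"*MATERIAL, NAME={set_name}")
            out.append("*ELASTIC")
            out.append(f"{b.representative_modulus:.10g}, {poisson_ratio:.10g}")
            if rho_by_eid is not None:
                mean_rho = float(np.mean([rho_by_eid[int(e)] for e in b.element_ids]))
                out.append("*DENSITY")
                out.append(f"{mean_rho:.10g}")
            out.append(f"*SOLID SECTION, ELSET={set_name}, MATERIAL={set_name}")
    else:
        for name, ids in mesh.elsets.items():
            out.append(f"*ELSET, ELSET={name}")
            out.extend(_chunk(ids))

    out.extend(mesh.extra_blocks)
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# legacy VTK unstructured grid
# ---------------------------------------------------------------------------

def write_vtk(
    mesh: FEMesh,
    path: str | Path,
    assignment: "MaterialAssignment | None" = None,
    bin_ids: np.ndarray | None = None,
    extra_cell_data: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write an ASCII legacy-VTK unstructured grid (cell type 10 = tetra).

    With an assignment, per-cell scalar fields ``HU``, ``rho``, ``E`` (MPa)
    and, if provided, ``bin_id`` are attached as CELL_DATA.
    """
    path = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        "bonemap tet4 mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y, z in mesh.coords:
        out.append(f"{x:.10g} {y:.10g} {z:.10g}")
    m = mesh.n_elements
    out.append(f"CELLS {m} {5 * m}")
    for quad in mesh.conn:
        out.append("4 " + " ".join(str(int(v)) for v in quad))
    out.append(f"CELL_TYPES {m}")
    out.extend(["10"] * m)

    fields: dict[str, np.ndarray] = {}
    if assignment is not None:
        order = np.array([assignment.row_of(int(e)) for e in mesh.elem_ids])
        fields["HU"] = assignment.hu_mean[order]
        fields["rho"] = assignment.rho[order]
        fields["E"] = assignment.young_modulus[order]
    if bin_ids is not None:
        fields["bin_id"] = np.asarray(bin_ids)
    if extra_cell_data:
        fields.update(extra_cell_data)
    if fields:
        out.append(f"CELL_DATA {m}")
        for name, values in fields.items():
            dtype = "int" if np.issubdtype(np.asarray(values).dtype, np.integer) else "double"
            out.append(f"SCALARS {name} {dtype} 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{v:.10g}" if dtype == "double" else str(int(v)) for v in values)
    path.write_text("\n".join(out) + "\n")
    return path


def read_vtk(path: str | Path) -> tuple[FEMesh, dict[str, np.ndarray]]:
    """Read back a legacy-VTK tet grid written by :func:`write_vtk`.

    Returns the mesh (ids renumbered 1-based in file order) and the
    CELL_DATA scalar fields.
    """
    tokens = Path(path).read_text().split("\n")
    idx = 0

    def next_line() -> str:
        nonlocal idx
        while idx < len(tokens):
            line = tokens[idx].strip()
            idx += 1
            if line:
                return line
        raise MeshError(f"{path}: truncated VTK file")

    header = [next_line() for _ in range(3)]
    if header[2].upper() != "ASCII":
        raise MeshError(f"{path}: only ASCII VTK supported")
    if "UNSTRUCTURED_GRID" not in next_line().upper():
        raise MeshError(f"{path}: not an unstructured grid")
    m = re.match(r"POINTS\s+(\d+)", next_line(), re.I)
    if not m:
        raise MeshError(f"{path}: missing POINTS")
    n_pts = int(m.group(1))
    coords = np.array([[float(v) for v in next_line().split()] for _ in range(n_pts)])
    m = re.match(r"CELLS\s+(\d+)\s+(\d+)", next_line(), re.I)
    if not m:
        raise MeshError(f"{path}: missing CELLS")
    n_cells = int(m.group(1))
    conn = []
    for _ in range(n_cells):
        rec = [int(v) for v in next_line().split()]
        if rec[0] != 4:
            raise UnsupportedElementError(f"{path}: cell with {rec[0]} points is not tet4")
        conn.append(rec[1:5])
    if not re.match(r"CELL_TYPES", next_line(), re.I):
        raise MeshError(f"{path}: missing CELL_TYPES")
    for _ in range(n_cells):
        if next_line() != "10":
            raise UnsupportedElementError(f"{path}: non-tetra cell type")
    fields: dict[str, np.ndarray] = {}
    try:
        line = next_line()
    except MeshError:
        line = ""
    if line.upper().startswith("CELL_DATA"):
        while True:
            try:
                line = next_line()
            except MeshError:
                break
            sm = re.match(r"SCALARS\s+(\S+)\s+(\S+)", line, re.I)
            if not sm:
                break
            name, dtype = sm.group(1), sm.group(2)
            next_line()  # LOOKUP_TABLE
            vals = [next_line() for _ in range(n_cells)]
            fields[name] = (
                np.array(vals, dtype=np.int64) if dtype == "int" else np.array(vals, dtype=float)
            )
    mesh = FEMesh(
        node_ids=np.arange(1, n_pts + 1),
        coords=coords,
        elem_ids=np.arange(1, n_cells + 1),
        conn=np.array(conn, dtype=np.int64),
    )
    return mesh, fields
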