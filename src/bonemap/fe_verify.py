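"""Minimal linear-elastic tet4 solver for verifying mapped material fields.

This is a verification tool, not a production solver: small-strain
isotropic elasticity with constant-strain tetrahedra, a direct sparse
solve, and just enough boundary-condition machinery for patch tests,
laminate (series-spring) bounds, and qualitative load-path checks on
phantom geometries.  Production analyses of full patient models belong in
a general-purpose FE package.

Boundary conditions
-------------------
Dirichlet constraints address named node sets; the prescribed value is a
single (3,) displacement applied to every node of the set, an (n, 3)
array aligned with the set's (sorted) node ids, or a callable
``f(coords) -> (n, 3)``.  NaN components are left free, so "fix x only"
is ``(0, nan, nan)``.  Neumann loads are uniform tractions (MPa) on
triangular faces given by node-id triples; the consistent load for a
constant traction on a linear triangle is area/3 per node.

Stress is reported per element in Voigt order (xx, yy, zz, xy, yz, zx)
together with the von Mises equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError
from .femesh import FEMesh
from .hu_mapping import MaterialAssignment

__all__ = ["VerifyConfig", "SolutionField", "solve_static", "von_mises", "isotropic_D"]

DirichletValue = Sequence[float] | np.ndarray | Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class VerifyConfig:
    """Boundary conditions and the global Poisson ratio.

    The Poisson ratio defaults to 0.3, the conventional value for bone in
    the FE literature; it is a modelling choice of this package, applied
    globally, and is reported with every solution.
    """

    poisson_ratio: float = 0.3
    dirichlet: Mapping[str, DirichletValue] = field(default_factory=dict)
    neumann: Sequence[tuple[Sequence[int], Sequence[float]]] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.poisson_ratio < 0.5:
            raise SolverError(f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}")


@dataclass
class SolutionField:
    """Static solution: nodal displacements and element stresses."""

    node_ids: np.ndarray
    displacement: np.ndarray  # (n, 3) mm
    stress_voigt: np.ndarray  # (m, 6) MPa: xx, yy, zz, xy, yz, zx
    von_mises: np.ndarray  # (m,) MPa
    poisson_ratio: float

    def stress_tensor(self, row: int) -> np.ndarray:
        s = self.stress_voigt[row]
        return np.array(
            [[s[0], s[3], s[5]], [s[3], s[1], s[4]], [s[5], s[4], s[2]]]
        )


def isotropic_D(E: float | np.ndarray, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix (6x6, Voigt, engineering shear strains).

    Vectorised: with an (m,) modulus array the result is (m, 6, 6).
    """
    E = np.asarray(E, dtype=np.float64)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] = lam + 2 * mu
    for i in range(3, 6):
        D[..., i, i] = mu
    return D


def von_mises(stress) -> float | np.ndarray:
    """Von Mises equivalent stress from Voigt (..., 6) or a 3x3 tensor."""
    s = np.asarray(stress, dtype=np.float64)
    if s.shape[-2:] == (3, 3):
        s = np.stack(
            [s[..., 0, 0], s[..., 1, 1], s[..., 2, 2], s[..., 0, 1], s[..., 1, 2], s[..., 0, 2]],
            axis=-1,
        )
    sx, sy, sz, sxy, syz, szx = (s[..., k] for k in range(6))
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + szx**2)
    )
    return float(vm) if vm.ndim == 0 else vm


def _element_B_and_volume(verts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices (m, 6, 12) and volumes (m,) for tet4."""
    e = verts[:, 1:, :] - verts[:, :1, :]  # (m, 3, 3)
    det = np.linalg.det(e)
    vol = np.abs(det) / 6.0
    inv = np.linalg.inv(e)  # rows: d(local)/d(x)
    # gradients of the 4 shape functions: N0 = 1 - sum(local), Ni = local_i
    grad = np.empty((len(verts), 4, 3))
    grad[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grad[:, 0, :] = -grad[:, 1:, :].sum(axis=1)
    B = np.zeros((len(verts), 6, 12))
    for a in range(4):
        gx, gy, gz = grad[:, a, 0], grad[:, a, 1], grad[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def _resolve_dirichlet(
    mesh: FEMesh, cfg: VerifyConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained DOF indices and their prescribed values."""
    fixed: dict[int, float] = {}
    for set_name, value in cfg.dirichlet.items():
        if set_name not in mesh.node_sets:
            raise SolverError(f"unknown node set {set_name!r}")
        nids = np.sort(np.asarray(mesh.node_sets[set_name]))
        rows = np.array([mesh.node_row(n) for n in nids])
        if callable(value):
            vals = np.asarray(value(mesh.coords[rows]), dtype=np.float64)
        else:
            vals = np.asarray(value, dtype=np.float64)
            if vals.shape == (3,):
                vals = np.broadcast_to(vals, (len(rows), 3))
        if vals.shape != (len(rows), 3):
            raise SolverError(
                f"dirichlet value for {set_name!r} must be (3,) or ({len(rows)}, 3)"
            )
        for r, v in zip(rows, vals):
            for k in range(3):
                if np.isfinite(v[k]):
                    fixed[3 * r + k] = float(v[k])
    if not fixed:
        raise SolverError(
            "no Dirichlet constraints: the stiffness matrix has 6 free rigid-body modes"
        )
    dofs = np.array(sorted(fixed), dtype=np.int64)
    return dofs, np.array([fixed[d] for d in dofs])


def _neumann_forces(mesh: FEMesh, cfg: VerifyConfig, n_dof: int) -> np.ndarray:
    f = np.zeros(n_dof)
    for face_nodes, traction in cfg.neumann:
        rows = np.array([mesh.node_row(n) for n in face_nodes])
        if len(rows) != 3:
            raise SolverError("Neumann faces must be triangles (3 node ids)")
        p = mesh.coords[rows]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        load = np.asarray(traction, dtype=np.float64) * area / 3.0
        for r in rows:
            f[3 * r : 3 * r + 3] += load
    return f


def solve_static(
    mesh: FEMesh, assignment: MaterialAssignment, cfg: VerifyConfig
) -> SolutionField:
    """Solve the static small-strain problem and report element stresses.

    Every element takes its Young's modulus from the assignment; the
    Poisson ratio is the global ``cfg.poisson_ratio``.  Raises
    :class:`SolverError` when the constrained system is singular, naming
    the number of free (near-null) modes.
    """
    m = mesh.n_elements
    order = np.array([assignment.row_of(int(e)) for e in mesh.elem_ids])
    E = np.asarray(assignment.young_modulus, dtype=np.float64)[order]
    if np.any(E <= 0):
        raise SolverError("all element moduli must be positive")

    verts = mesh.vertex_tensor()
    B, vol = _element_B_and_volume(verts)
    D = isotropic_D(E, cfg.poisson_ratio)
    ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol)  # (m, 12, 12)

    dof_map = (3 * mesh.conn[:, :, np.newaxis] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dof_map, 12, axis=1).ravel()
    cols = np.tile(dof_map, (1, 12)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()

    f = _neumann_forces(mesh, cfg, n_dof)
    fixed_dofs, fixed_vals = _resolve_dirichlet(mesh, cfg)
    free = np.setdiff1d(np.arange(n_dof), fixed_dofs)

    u = np.zeros(n_dof)
    u[fixed_dofs] = fixed_vals
    rhs = f[free] - K[free][:, fixed_dofs] @ fixed_vals
    Kff = K[free][:, free]
    if len(free):
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", spla.MatrixRankWarning)
            u_free = spla.spsolve(Kff.tocsc(), rhs)
        resid = np.linalg.norm(Kff @ u_free - rhs)
        scale = np.linalg.norm(rhs) + np.linalg.norm(Kff.diagonal()) * (
            np.linalg.norm(u_free) + 1.0
        )
        if not np.all(np.isfinite(u_free)) or resid > 1e-6 * max(scale, 1.0):
            n_modes = _count_null_modes(Kff)
            raise SolverError(
                f"singular stiffness system: ~{n_modes} unconstrained mode(s); "
                f"add Dirichlet constraints"
            )
        u[free] = u_free

    ue = u[dof_map]  # (m, 12)
    strain = np.einsum("mij,mj->mi", B, ue)
    stress = np.einsum("mij,mj->mi", D, strain)
    return SolutionField(
        node_ids=mesh.node_ids.copy(),
        displacement=u.reshape(-1, 3),
        stress_voigt=stress,
        von_mises=von_mises(stress),
        poisson_ratio=cfg.poisson_ratio,
    )


def _count_null_modes(Kff: sp.spmatrix) -> int:
    n = Kff.shape[0]
    if n == 0:
        return 0
    if n <= 200:
        w = np.linalg.eigvalsh(Kff.toarray())
    else:  # pragma: no cover - large singular systems are rare in verification
        try:
            w = spla.eigsh(Kff.tocsc(), k=min(12, n - 1), sigma=0, return_eigenvectors=False)
        except Exception:
            return -1
    tol = 1e-10 * max(abs(w).max(), 1.0)
    return int(np.sum(np.abs(w) < tol))
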