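"""Linear static finite-element kernel.

Element formulations, constraint elimination, and the sparse solve.
Elements are the minimal set the carpal model needs:

* constant-strain tetrahedra for cancellous bone volume;
* constant-strain plane-stress membranes (triangles in 3D) for the thin
  cortical and cartilage layers, sharing nodes with the solid surface so
  the two discretisations are fully displacement-coupled;
* two-node axial springs (ligaments) and grounded directional springs
  (elastic foundation restraints).

Non-separation contact ties — (u_A - u_B) . n = 0 per coincident node
pair, tangential sliding free — are applied by master-slave elimination,
which keeps the reduced operator symmetric positive definite.  Units:
mm, N, MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "SolverError",
    "LinearSystem",
    "ReducedSystem",
    "DisplacementField",
    "elastic_C",
    "plane_stress_C",
    "tet_stiffness",
    "membrane_stiffness",
    "tet_B_matrices",
    "membrane_B_matrices",
    "apply_constraints",
    "solve_linear",
]


class SolverError(RuntimeError):
    """Raised for degenerate elements, singular or inconsistent systems."""


# ---------------------------------------------------------------------
# constitutive matrices (Voigt order: xx, yy, zz, xy, yz, zx;
# engineering shear strains)
# ---------------------------------------------------------------------


def elastic_C(E: float, nu: float) -> np.ndarray:
    """Isotropic 3-D elasticity matrix (6x6, MPa)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


def plane_stress_C(E: float, nu: float) -> np.ndarray:
    """Isotropic plane-stress elasticity matrix (3x3, MPa)."""
    c = E / (1 - nu**2)
    return c * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])


# ---------------------------------------------------------------------
# element stiffness
# ---------------------------------------------------------------------


def tet_B_matrices(nodes: np.ndarray, tets: np.ndarray):
    """Strain-displacement matrices and volumes for all tets, vectorised.

    Returns ``(B, V)`` with ``B`` of shape (M, 6, 12) mapping the 12
    nodal displacements (x0,y0,z0,...,z3) to Voigt strain, and ``V`` the
    signed volumes.
    """
    p = nodes[tets]  # (M, 4, 3)
    e = p[:, 1:] - p[:, :1]  # (M, 3, 3) edge vectors
    detJ = np.linalg.det(e)
    V = detJ / 6.0
    # gradients of the 4 linear shape functions: rows of inv(e) give
    # grad N1..N3; grad N0 = -(sum)
    invJ = np.linalg.inv(e)  # (M, 3, 3)
    grads = np.empty((len(tets), 4, 3))
    grads[:, 1:, :] = np.transpose(invJ, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    B = np.zeros((len(tets), 6, 12))
    gx, gy, gz = grads[..., 0], grads[..., 1], grads[..., 2]
    for a in range(4):
        c = 3 * a
        B[:, 0, c + 0] = gx[:, a]
        B[:, 1, c + 1] = gy[:, a]
        B[:, 2, c + 2] = gz[:, a]
        B[:, 3, c + 0] = gy[:, a]
        B[:, 3, c + 1] = gx[:, a]
        B[:, 4, c + 1] = gz[:, a]
        B[:, 4, c + 2] = gy[:, a]
        B[:, 5, c + 0] = gz[:, a]
        B[:, 5, c + 2] = gx[:, a]
    return B, V


def tet_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of one constant-strain tetrahedron (N/mm)."""
    coords = np.asarray(coords, dtype=float)
    vol = np.linalg.det(coords[1:] - coords[0]) / 6.0
    if vol <= 0:
        raise SolverError("degenerate or inverted tetrahedron")
    B, V = tet_B_matrices(coords, np.arange(4)[None, :])
    C = elastic_C(E, nu)
    return V[0] * B[0].T @ C @ B[0]


def membrane_B_matrices(nodes: np.ndarray, tris: np.ndarray):
    """Local strain-displacement data for all membrane triangles.

    Returns ``(B2, T, A, basis)``: ``B2`` (T, 3, 6) maps in-plane nodal
    displacements to in-plane Voigt strain, ``T`` (T, 6, 9) projects the
    9 global nodal displacements onto the 6 in-plane ones, ``A`` the
    areas and ``basis`` the (e1, e2, n) triads.
    """
    p = nodes[tris]
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    n = np.cross(v1, v2)
    A2 = np.linalg.norm(n, axis=1)  # = 2 * area
    if np.any(A2 <= 0):
        raise SolverError("zero-area membrane triangle")
    nhat = n / A2[:, None]
    e1 = v1 / np.linalg.norm(v1, axis=1, keepdims=True)
    e2 = np.cross(nhat, e1)
    # local 2-D coordinates of the 3 vertices
    x = np.stack([np.einsum("ij,ij->i", p[:, a] - p[:, 0], e1) for a in range(3)], axis=1)
    y = np.stack([np.einsum("ij,ij->i", p[:, a] - p[:, 0], e2) for a in range(3)], axis=1)
    area = 0.5 * A2
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    B2 = np.zeros((len(tris), 3, 6))
    for a in range(3):
        B2[:, 0, 2 * a + 0] = b[:, a]
        B2[:, 1, 2 * a + 1] = c[:, a]
        B2[:, 2, 2 * a + 0] = c[:, a]
        B2[:, 2, 2 * a + 1] = b[:, a]
    B2 /= (2 * area)[:, None, None]
    T = np.zeros((len(tris), 6, 9))
    for a in range(3):
        T[:, 2 * a + 0, 3 * a : 3 * a + 3] = e1
        T[:, 2 * a + 1, 3 * a : 3 * a + 3] = e2
    basis = np.stack([e1, e2, nhat], axis=1)
    return B2, T, area, basis


def membrane_stiffness(
    coords: np.ndarray, E: float, nu: float, thickness: float
) -> np.ndarray:
    """9x9 stiffness of one plane-stress membrane triangle in 3-D (N/mm)."""
    coords = np.asarray(coords, dtype=float)
    B2, T, area, _ = membrane_B_matrices(coords, np.arange(3)[None, :])
    C = plane_stress_C(E, nu)
    K6 = area[0] * thickness * B2[0].T @ C @ B2[0]
    return T[0].T @ K6 @ T[0]


# ---------------------------------------------------------------------
# system containers
# ---------------------------------------------------------------------


@dataclass
class LinearSystem:
    """Assembled symmetric stiffness, loads and constraint set.

    DOF convention: node i, axis a -> index 3*i + a.
    """

    K: sp.csr_matrix  # (3N, 3N), N/mm
    f: np.ndarray  # (3N,), N
    fixed_dofs: np.ndarray  # sorted unique DOF indices, zero displacement
    ties: List[Tuple[int, int, np.ndarray]]  # (node A, node B, unit normal)
    grounded_springs: List[Tuple[int, np.ndarray, float]]  # (node, direction, N/mm)
    n_nodes: int
    meta: Dict = field(default_factory=dict)

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes


@dataclass
class ReducedSystem:
    """Constraint-eliminated system: u_full = T @ u_red."""

    K: sp.csc_matrix
    f: np.ndarray
    T: sp.csr_matrix  # (3N, n_red)
    full: LinearSystem


@dataclass
class DisplacementField:
    """Solution of a linear static solve."""

    u: np.ndarray  # (N, 3), mm
    reactions: np.ndarray  # (n_fixed,), N — at fixed DOFs, full-system rows
    fixed_dofs: np.ndarray
    ground_forces: np.ndarray  # (n_springs, 3), N — foundation reactions
    residual: float  # relative residual of the reduced solve

    def reaction_total(self) -> np.ndarray:
        """Resultant of fixed-support plus foundation reactions (N)."""
        r = np.zeros(3)
        for dof, val in zip(self.fixed_dofs, self.reactions):
            r[dof % 3] += val
        return r + self.ground_forces.sum(axis=0)


# ---------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------


def apply_constraints(system: LinearSystem) -> ReducedSystem:
    """Eliminate fixed DOFs and contact ties from the system.

    Each tie enforces ``(u_A - u_B) . n = 0`` exactly by expressing the
    dominant normal component of node A in terms of the remaining DOFs
    (master-slave elimination); tangential relative motion stays free.
    """
    nd = system.n_dofs
    fixed = set(int(d) for d in system.fixed_dofs)

    # Each tie contributes one homogeneous row  (u_A - u_B) . n = 0 over
    # up to six DOFs.  Nodes lying on two contact patches couple their
    # rows, so a plain master-slave substitution can cycle; instead run
    # exact Gaussian elimination over the constraint rows: choose one
    # pivot (slave) DOF per row, forward-substitute earlier pivots, then
    # back-substitute in reverse order.
    raw_rows: List[Dict[int, float]] = []
    pref_pivot: List[int] = []
    for a, b, n in system.ties:
        n = np.asarray(n, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise SolverError("tie constraint with zero normal")
        n = n / nn
        row = {}
        for k in range(3):
            if n[k] != 0.0:
                row[3 * int(a) + k] = float(n[k])
                row[3 * int(b) + k] = float(-n[k])
        raw_rows.append(row)
        pref_pivot.append(3 * int(a) + int(np.argmax(np.abs(n))))

    pivots: Dict[int, Dict[int, float]] = {}  # pivot DOF -> row of masters
    order: List[int] = []
    for row, pref in zip(raw_rows, pref_pivot):
        # drop fixed DOFs (zero) and substitute earlier pivots
        cur = {d: c for d, c in row.items() if d not in fixed}
        changed = True
        while changed:
            changed = False
            for d in list(cur):
                if d in pivots:
                    c = cur.pop(d)
                    for d2, c2 in pivots[d].items():
                        cur[d2] = cur.get(d2, 0.0) + c * c2
                    changed = True
        cur = {d: c for d, c in cur.items() if abs(c) > 1e-12}
        if not cur:
            continue  # redundant tie (e.g. both nodes fixed)
        piv = pref if pref in cur else max(cur, key=lambda d: abs(cur[d]))
        cp = cur.pop(piv)
        pivots[piv] = {d: -c / cp for d, c in cur.items()}
        order.append(piv)

    # back-substitution: later pivots may appear in earlier rows
    for piv in reversed(order):
        row = pivots[piv]
        changed = True
        while changed:
            changed = False
            for d in list(row):
                if d in pivots and d != piv:
                    c = row.pop(d)
                    for d2, c2 in pivots[d].items():
                        row[d2] = row.get(d2, 0.0) + c * c2
                    changed = True
        pivots[piv] = {d: c for d, c in row.items() if abs(c) > 1e-14}

    resolved = pivots

    keep = np.array(
        [d for d in range(nd) if d not in fixed and d not in resolved],
        dtype=np.int64,
    )
    red_index = {int(d): i for i, d in enumerate(keep)}
    n_red = len(keep)

    ti, tj, tv = list(keep), list(range(n_red)), [1.0] * n_red
    for s, row in resolved.items():
        for d, c in row.items():
            ti.append(s)
            tj.append(red_index[int(d)])
            tv.append(c)
    T = sp.csr_matrix((tv, (ti, tj)), shape=(nd, n_red))
    K_red = (T.T @ system.K @ T).tocsc()
    f_red = T.T @ system.f
    return ReducedSystem(K=K_red, f=f_red, T=T, full=system)


# ---------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------


def solve_linear(reduced: ReducedSystem, tol: float = 1e-8) -> DisplacementField:
    """Direct sparse solve of the reduced SPD system.

    Raises :class:`SolverError` when the reduced operator is singular
    (an unsupported rigid-body mode survived the constraints).
    """
    K, f = reduced.K, reduced.f
    if K.shape[0] == 0:
        u_red = np.zeros(0)
    else:
        try:
            lu = spla.splu(K.tocsc())
            u_red = lu.solve(f)
        except RuntimeError as exc:
            raise SolverError(f"singular reduced system: {exc}") from exc
        if not np.all(np.isfinite(u_red)):
            raise SolverError(
                "singular reduced system: factorization produced non-finite "
                "displacements (unconstrained rigid-body mode)"
            )
    fn = np.linalg.norm(f)
    residual = float(np.linalg.norm(K @ u_red - f) / fn) if fn > 0 else 0.0
    if fn > 0 and residual > tol:
        raise SolverError(f"solver residual {residual:.3e} exceeds {tol:.1e}")

    full = reduced.full
    u_full = reduced.T @ u_red
    r = full.K @ u_full - full.f
    reactions = r[full.fixed_dofs]
    gf = np.zeros((len(full.grounded_springs), 3))
    for i, (node, direction, k) in enumerate(full.grounded_springs):
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        gf[i] = -k * float(d @ u_full[3 * node : 3 * node + 3]) * d
    return DisplacementField(
        u=u_full.reshape(-1, 3),
        reactions=reactions,
        fixed_dofs=full.fixed_dofs,
        ground_forces=gf,
        residual=residual,
    )


def equilibrium_gap(system: LinearSystem, sol: DisplacementField) -> float:
    """Relative imbalance between applied loads and all reactions."""
    applied = system.f.reshape(-1, 3).sum(axis=0)
    total = applied + sol.reaction_total()
    scale = max(np.linalg.norm(applied), 1e-30)
    return float(np.linalg.norm(total) / scale)
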