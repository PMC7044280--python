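"""FE kernel: elements, constraints, solves against closed forms."""

import numpy as np
import pytest
import scipy.sparse as sp

from carpofem import solver
from carpofem.geometry import all_contact_interfaces
from carpofem.solver import (
    SolverError,
    apply_constraints,
    equilibrium_gap,
    membrane_stiffness,
    solve_linear,
    tet_stiffness,
)
from carpofem.verification import (
    assemble_tet_box,
    bar_elongation,
    box_tet_mesh,
    cantilever_tip_deflection,
    grounded_spring_displacement,
    patch_test_error,
)

TET = np.array([[0.0, 0, 0], [1.3, 0, 0], [0.2, 1.1, 0], [0.1, 0.3, 0.9]])
TRI = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.3, 1.5, 0.4]])


class TestTetStiffness:
    def test_symmetric(self):
        K = tet_stiffness(TET, 500.0, 0.3)
        assert np.max(np.abs(K - K.T)) <= 1e-12 * np.max(np.abs(K))

    def test_six_rigid_modes(self):
        K = tet_stiffness(TET, 500.0, 0.3)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-9 * w.max()) == 6
        assert np.all(w > -1e-9 * w.max())  # positive semidefinite

    def test_rigid_rotation_gives_zero_force(self):
        K = tet_stiffness(TET, 500.0, 0.3)
        # infinitesimal rotation about an arbitrary axis
        omega = np.array([0.3, -0.2, 0.5])
        u = np.cross(omega, TET).ravel()
        assert np.allclose(K @ u, 0.0, atol=1e-10)

    def test_degenerate_rejected(self):
        flat = TET.copy()
        flat[3, 2] = 0.0
        with pytest.raises(SolverError):
            tet_stiffness(flat, 500.0, 0.3)


class TestMembraneStiffness:
    def test_thickness_scaling(self):
        K1 = membrane_stiffness(TRI, 7.0, 0.3, 0.55)
        K2 = membrane_stiffness(TRI, 7.0, 0.3, 1.10)
        assert np.allclose(K2, 2.0 * K1, rtol=1e-12)

    def test_rigid_translation_zero_force(self):
        K = membrane_stiffness(TRI, 7.0, 0.3, 0.55)
        for direction in np.eye(3):
            u = np.tile(direction, 3)
            assert np.allclose(K @ u, 0.0, atol=1e-12)

    def test_uniaxial_closed_form(self):
        """Unit right triangle, nu = 0: stretching edge x by du gives the
        plane-stress force E*t*du/2 per loaded corner pair."""
        E, t = 100.0, 0.5
        tri = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0]])
        K = membrane_stiffness(tri, E, 0.0, t)
        u = np.zeros(9)
        u[3] = 1e-3  # stretch node 1 along x
        f = K @ u
        # closed form: sigma = E*eps_xx, force on node 1 = E*t*eps/2 * width
        assert f[3] == pytest.approx(E * t * 1e-3 / 2, rel=1e-12)

    def test_zero_area_rejected(self):
        degenerate = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(SolverError):
            membrane_stiffness(degenerate, 7.0, 0.3, 0.5)


class TestConstraints:
    def test_tie_normal_fixed_tangential_free(self):
        """Tie with n = (0,0,1): relative z pinned, relative x,y free."""
        k = 10.0
        K = sp.csr_matrix((6, 6))
        system = solver.LinearSystem(
            K=K + sp.eye(6) * 0.0,
            f=np.zeros(6),
            fixed_dofs=np.array([], dtype=int),
            ties=[(0, 1, np.array([0.0, 0.0, 1.0]))],
            grounded_springs=[],
            n_nodes=2,
        )
        red = apply_constraints(system)
        # 5 remaining DOFs; the z DOF of node 0 follows node 1's z
        assert red.K.shape[0] == 5
        u_red = np.arange(5, dtype=float)
        u_full = red.T @ u_red
        u = u_full.reshape(2, 3)
        assert u[0, 2] == pytest.approx(u[1, 2], abs=1e-14)
        assert u[0, 0] != u[1, 0] and u[0, 1] != u[1, 1]

    def test_fully_fixed_tet_reduces_to_empty(self):
        nodes, tets = box_tet_mesh((1, 1, 1), (1.0, 1.0, 1.0))
        system = assemble_tet_box(
            nodes, tets, 500.0, 0.3,
            range(3 * len(nodes)), np.zeros(3 * len(nodes)),
        )
        red = apply_constraints(system)
        assert red.K.shape == (0, 0)
        sol = solve_linear(red)
        assert np.allclose(sol.u, 0.0)

    def test_reduced_system_positive_definite(self, solved_unfused):
        system, _ = solved_unfused
        red = apply_constraints(system)
        # smallest eigenvalue of the reduced operator is positive
        from scipy.sparse.linalg import eigsh

        w = eigsh(red.K, k=1, which="SA", return_eigenvectors=False)
        assert w[0] > 0

    def test_contradictory_slave_rejected(self):
        system = solver.LinearSystem(
            K=sp.eye(6).tocsr(),
            f=np.zeros(6),
            fixed_dofs=np.array([], dtype=int),
            ties=[
                (0, 1, np.array([0.0, 0.0, 1.0])),
                (0, 1, np.array([0.0, 0.0, 1.0])),
            ],
            grounded_springs=[],
            n_nodes=2,
        )
        # a duplicated tie is redundant, not contradictory: it must not
        # produce a second constraint row
        red = apply_constraints(system)
        assert red.K.shape[0] == 5


class TestSolve:
    def test_single_spring(self):
        assert grounded_spring_displacement(40.0, 20.0) == pytest.approx(0.5)

    def test_patch_test_exact(self):
        assert patch_test_error() < 1e-10

    def test_bar_elongation(self):
        assert bar_elongation() == pytest.approx(0.02, rel=1e-8)

    def test_cantilever_monotone_convergence(self):
        """Displacement-based elements approach the Euler-Bernoulli tip
        deflection from below, monotonically under refinement."""
        d = [cantilever_tip_deflection(r) for r in (1, 2, 3)]
        assert d[0] < d[1] < d[2] < 0.2012  # bound: closed form + shear term

    def test_zero_load_zero_displacement(self, unfused_mesh):
        from tests_helpers import zero_load_system

        system = zero_load_system(unfused_mesh)
        sol = solve_linear(apply_constraints(system))
        assert np.allclose(sol.u, 0.0)
        assert sol.residual == 0.0

    def test_singular_system_raises(self):
        nodes, tets = box_tet_mesh((1, 1, 1), (1.0, 1.0, 1.0))
        f = np.zeros(3 * len(nodes))
        f[2] = 1.0
        system = assemble_tet_box(nodes, tets, 500.0, 0.3, [], f)
        with pytest.raises(SolverError):
            solve_linear(apply_constraints(system))

    def test_sparse_matches_dense_oracle(self):
        """On a small supported model the sparse solve equals a dense solve."""
        nodes, tets = box_tet_mesh((2, 2, 2), (2.0, 2.0, 2.0))  # 81 DOFs
        base = np.flatnonzero(np.abs(nodes[:, 2]) < 1e-12)
        fixed = (3 * base[:, None] + np.arange(3)).ravel()
        rng = np.random.default_rng(0)
        f = rng.normal(size=3 * len(nodes))
        system = assemble_tet_box(nodes, tets, 500.0, 0.3, fixed, f)
        red = apply_constraints(system)
        sol = solve_linear(red, tol=1e-6)
        dense = np.linalg.solve(red.K.toarray(), red.f)
        u_red_sparse = np.linalg.lstsq(
            red.T.toarray(), sol.u.ravel(), rcond=None
        )[0]
        assert np.allclose(u_red_sparse, dense, rtol=1e-10, atol=1e-14)


class TestCarpalSolves:
    def test_equilibrium(self, solved_unfused, solved_fused):
        for system, sol in (solved_unfused, solved_fused):
            assert equilibrium_gap(system, sol) < 1e-8

    def test_residual_tolerance(self, solved_unfused):
        _, sol = solved_unfused
        assert sol.residual <= 1e-8

    def test_tie_gap_closed_and_sliding_free(self, unfused_mesh, solved_unfused):
        _, sol = solved_unfused
        max_slip = 0.0
        for ci in all_contact_interfaces(unfused_mesh):
            du = sol.u[ci.pairs[:, 0]] - sol.u[ci.pairs[:, 1]]
            gap = np.einsum("ij,ij->i", du, ci.normals)
            assert np.max(np.abs(gap)) <= 1e-10
            slip = du - gap[:, None] * ci.normals
            max_slip = max(max_slip, float(np.linalg.norm(slip, axis=1).max()))
        assert max_slip > 1e-6  # sliding is genuinely unconstrained
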