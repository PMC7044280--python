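"""Stress recovery, von Mises, and mesh-weighted statistics."""

import numpy as np
import pytest

from carpofem.model import MaterialSet
from carpofem.stress import (
    StressError,
    mwam,
    mwm,
    recover_stress,
    stress_summary,
    von_mises,
    weighted_quantile,
)
from tests_helpers import brute_force_weighted_quantile


class TestVonMises:
    @pytest.mark.parametrize(
        "tensor,expected",
        [
            ((100, 0, 0, 0, 0, 0), 100.0),  # uniaxial
            ((50, 50, 50, 0, 0, 0), 0.0),  # hydrostatic
            ((0, 0, 0, 10, 0, 0), 10 * np.sqrt(3)),  # pure shear
        ],
    )
    def test_fixtures(self, tensor, expected):
        assert von_mises(np.array(tensor, dtype=float)) == pytest.approx(
            expected, abs=1e-10
        )

    def test_rotation_invariance(self):
        """Equivalent stress is frame-independent."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(42)
        for _ in range(50):
            S = rng.normal(size=(3, 3)) * 10
            S = 0.5 * (S + S.T)
            R = Rotation.random(random_state=rng).as_matrix()
            Sr = R @ S @ R.T

            def voigt(M):
                return np.array(
                    [M[0, 0], M[1, 1], M[2, 2], M[0, 1], M[1, 2], M[0, 2]]
                )

            assert von_mises(voigt(S)) == pytest.approx(
                von_mises(voigt(Sr)), abs=1e-10
            )

    def test_nonfinite_rejected(self):
        with pytest.raises(StressError):
            von_mises(np.array([np.nan, 0, 0, 0, 0, 0]))


class TestWeightedStats:
    def test_mwam_fixtures(self):
        assert mwam([1, 2, 3], [1, 1, 1]) == pytest.approx(2.0)
        assert mwam([2, 4], [1, 3]) == pytest.approx(3.5)
        assert mwam([5], [2.0]) == pytest.approx(5.0)

    def test_mwm_fixtures(self):
        assert mwm([1, 2, 3], [1, 1, 1]) == 2.0
        assert mwm([1, 10], [3, 1]) == 1.0  # cum weight 3/4 >= 1/2 at v=1
        assert mwm([7], [1]) == 7.0

    def test_empty_rejected(self):
        with pytest.raises(StressError):
            mwam([], [])
        with pytest.raises(StressError):
            mwm([], [])

    def test_subdivision_invariance(self):
        """Splitting any element into equal-stress parts with the same
        total weight leaves MWAM and MWM unchanged."""
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 10, size=40)
        w = rng.uniform(0.1, 3, size=40)
        # split each element into 3 parts with random weight fractions
        fracs = rng.dirichlet([1, 1, 1], size=40)
        v_split = np.repeat(v, 3)
        w_split = (w[:, None] * fracs).ravel()
        assert mwam(v_split, w_split) == pytest.approx(mwam(v, w), abs=1e-12)
        assert mwm(v_split, w_split) == pytest.approx(mwm(v, w), abs=1e-12)
        for q in (0.25, 0.75):
            assert weighted_quantile(v_split, w_split, q) == pytest.approx(
                weighted_quantile(v, w, q), abs=1e-12
            )

    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(2)
        for n in (5, 6, 51):
            v = rng.normal(size=n)
            w = np.full(n, 0.7)
            assert mwam(v, w) == pytest.approx(np.mean(v), abs=1e-12)
            # cumulative-weight median picks an order statistic; for odd n
            # it is the classical median
            if n % 2 == 1:
                assert mwm(v, w) == np.median(v)

    def test_quantile_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(1, 20))
            v = rng.uniform(-5, 5, size=n).round(2)
            w = rng.uniform(0.1, 2, size=n)
            for q in (0.25, 0.5, 0.75):
                assert weighted_quantile(v, w, q) == brute_force_weighted_quantile(
                    v.tolist(), w.tolist(), q
                )

    def test_bounds(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=30)
        w = rng.uniform(0.1, 1, size=30)
        assert v.min() <= mwm(v, w) <= v.max()
        assert v.min() <= mwam(v, w) <= v.max()


class TestRecovery:
    def test_rigid_translation_zero_stress(self, unfused_mesh):
        u = np.tile([0.1, -0.2, 0.3], (len(unfused_mesh.nodes), 1))
        field = recover_stress(unfused_mesh, MaterialSet(), u)
        assert np.allclose(field.tensors, 0.0, atol=1e-10)

    def test_single_tet_hookes_law(self):
        """Uniform axial strain 0.01 with E = 1000, nu = 0 -> sigma = 10."""
        from carpofem import solver

        coords = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]]
        )
        B, V = solver.tet_B_matrices(coords, np.arange(4)[None, :])
        C = solver.elastic_C(1000.0, 0.0)
        u = np.zeros((4, 3))
        u[:, 2] = 0.01 * coords[:, 2]
        sigma = C @ (B[0] @ u.ravel())
        assert sigma[2] == pytest.approx(10.0, rel=1e-12)
        assert np.allclose(np.delete(sigma, 2), 0.0, atol=1e-12)

    def test_hydrostatic_field_has_zero_shear(self, unfused_mesh):
        u = 0.001 * unfused_mesh.nodes  # uniform volumetric expansion
        field = recover_stress(unfused_mesh, MaterialSet(), u)
        ntet = len(unfused_mesh.tets)
        assert np.allclose(field.tensors[:ntet, 3:], 0.0, atol=1e-9)

    def test_shape_mismatch_rejected(self, unfused_mesh):
        with pytest.raises(StressError):
            recover_stress(
                unfused_mesh, MaterialSet(), np.zeros((10, 3))
            )


class TestSummary:
    def test_uniform_field_constant_summary(self, unfused_mesh):
        """A homogeneous axial compression of the whole assembly yields
        identical (constant) statistics in every summary slot."""
        from carpofem.stress import StressField, TISSUES

        field = recover_stress(
            unfused_mesh, MaterialSet(), np.zeros((len(unfused_mesh.nodes), 3))
        )
        field.tensors[:] = 0.0
        field.tensors[:, 0] = 3.0  # constant uniaxial stress everywhere
        summ = stress_summary(field)
        for s in summ.values():
            for stat in ("mwam", "mwm", "median", "q25", "q75", "min", "max"):
                assert getattr(s, stat) == pytest.approx(3.0, abs=1e-12)

    def test_body_counts(self, unfused_mesh, fused_mesh, solved_unfused, solved_fused):
        for mesh, (_, sol), n in (
            (unfused_mesh, solved_unfused, 3),
            (fused_mesh, solved_fused, 2),
        ):
            field = recover_stress(mesh, MaterialSet(), sol.u)
            assert len(stress_summary(field)) == n

    def test_summary_excludes_cartilage(self, unfused_mesh, solved_unfused):
        from carpofem.stress import TISSUES

        _, sol = solved_unfused
        field = recover_stress(unfused_mesh, MaterialSet(), sol.u)
        s = stress_summary(field)["capitate"]
        bone = (field.tissue != TISSUES.index("cartilage")) & (
            field.body == unfused_mesh.body_id("capitate")
        )
        assert s.n_elements == int(bone.sum())

    def test_unknown_body_rejected(self, unfused_mesh, solved_unfused):
        _, sol = solved_unfused
        field = recover_stress(unfused_mesh, MaterialSet(), sol.u)
        with pytest.raises(StressError):
            stress_summary(field, scope=["hamate"])

    def test_ordering_invariants(self, unfused_mesh, solved_unfused):
        _, sol = solved_unfused
        field = recover_stress(unfused_mesh, MaterialSet(), sol.u)
        for s in stress_summary(field).values():
            assert s.min <= s.q25 <= s.median <= s.q75 <= s.max
            assert s.min <= s.mwam <= s.max
            assert s.min <= s.mwm <= s.max
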