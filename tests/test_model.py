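"""Model setup: loads, load cases, springs, assembly contracts."""

import numpy as np
import pytest

from carpofem.geometry import GeometryParams, generate_carpal_set
from carpofem.model import (
    LigamentSpec,
    MaterialSet,
    ModelError,
    STANDARD_GRAVITY,
    assemble_model,
    build_foundation_springs,
    compute_total_load,
    default_boundary,
    distribute_ligament_springs,
    make_load_case,
)


# The five study individuals: printed body masses and applied loads (N).
TABLE1 = [
    ("H. sapiens", 72.1, 141.41),
    ("G. gorilla", 170.4, 334.21),
    ("P. troglodytes", 59.7, 117.09),
    ("P. abelii", 77.9, 152.79),
    ("H. lar", 9.5, 18.63),
]


@pytest.mark.parametrize("species,mass,expected", TABLE1)
def test_total_load_reproduces_printed_values(species, mass, expected):
    assert round(compute_total_load(mass), 2) == pytest.approx(expected, abs=1e-9)


def test_total_load_edge_cases():
    assert compute_total_load(0.0) == 0.0
    with pytest.raises(ModelError):
        compute_total_load(-1.0)
    with pytest.raises(ModelError):
        compute_total_load(10.0, fraction=1.5)


def test_standard_gravity_not_rounded():
    # the printed loads only round-trip with the standard constant
    assert round(0.2 * 170.4 * STANDARD_GRAVITY, 2) == 334.21
    assert round(0.2 * 170.4 * 9.81, 2) != 334.21


def test_load_case_direction():
    lc0 = make_load_case(72.1, tilt_deg=0.0)
    assert np.allclose(lc0.direction, [0, 0, -1])
    lc5 = make_load_case(72.1, tilt_deg=5.0)
    assert np.linalg.norm(lc5.direction) == pytest.approx(1.0, abs=1e-12)
    assert float(lc5.direction @ lc0.direction) == pytest.approx(
        0.996195, abs=5e-7  # cos 5 deg
    )
    with pytest.raises(ModelError):
        make_load_case(72.1, tilt_deg=95.0)
    with pytest.raises(ModelError):
        make_load_case(72.1, partition_rule="equal-ish")


def test_explicit_partition_splits_force(unfused_mesh):
    lc = make_load_case(72.1, partition_rule={"radial": 0.6, "lunate": 0.4})
    system = assemble_model(
        unfused_mesh, MaterialSet(), LigamentSpec(topology="serial"),
        default_boundary(unfused_mesh), lc,
    )
    # per-facet shares recorded by the assembly
    assert system.meta["facet_share"]["radial_facet"] == pytest.approx(0.6)
    assert system.meta["facet_share"]["lunate_facet"] == pytest.approx(0.4)
    resultant = system.f.reshape(-1, 3).sum(axis=0)
    assert np.allclose(resultant, lc.force * lc.direction, rtol=1e-12)


class TestLigamentSprings:
    def test_serial_composition(self, unfused_mesh):
        spec = LigamentSpec(total_rigidity=40.0, strand_count=1, topology="serial")
        springs = distribute_ligament_springs(unfused_mesh, spec)
        ks = [k for _, _, k in springs.springs]
        assert ks == [80.0, 80.0]  # series of two 80s = 40

    def test_direct_equal_split(self, fused_mesh):
        spec = LigamentSpec(total_rigidity=40.0, strand_count=8, topology="direct")
        springs = distribute_ligament_springs(fused_mesh, spec)
        ks = [k for _, _, k in springs.springs]
        assert ks == [5.0] * 8

    @pytest.mark.parametrize("n", [1, 2, 4, 8])
    @pytest.mark.parametrize("topology", ["serial", "direct"])
    def test_reduction_reproduces_total(self, unfused_mesh, fused_mesh, n, topology):
        """Series/parallel algebra on the spring set returns the spec total."""
        mesh = fused_mesh if topology == "direct" else unfused_mesh
        spec = LigamentSpec(total_rigidity=40.0, strand_count=n, topology=topology)
        springs = distribute_ligament_springs(mesh, spec)
        if topology == "direct":
            total = sum(k for _, _, k in springs.springs)
        else:
            pairs = springs.springs
            assert len(pairs) == 2 * n
            total = 0.0
            for i in range(n):
                k1, k2 = pairs[2 * i][2], pairs[2 * i + 1][2]
                total += 1.0 / (1.0 / k1 + 1.0 / k2)
        assert total == pytest.approx(40.0, rel=1e-9)

    def test_topology_variant_mismatch(self, unfused_mesh, fused_mesh):
        with pytest.raises(ModelError):
            distribute_ligament_springs(
                unfused_mesh, LigamentSpec(topology="direct")
            )
        with pytest.raises(ModelError):
            distribute_ligament_springs(
                fused_mesh, LigamentSpec(topology="serial")
            )


class TestFoundationSprings:
    @pytest.mark.parametrize("patch", ["lunate", "hamate", "trapezoid"])
    def test_total_stiffness_partition(self, unfused_mesh, patch):
        springs = build_foundation_springs(unfused_mesh, patch, 20.5)
        assert springs.total_grounded_stiffness() == pytest.approx(20.5, rel=1e-9)
        for _, d, k in springs.grounded:
            assert k > 0
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)

    def test_missing_patch(self, unfused_mesh):
        with pytest.raises(ModelError):
            build_foundation_springs(unfused_mesh, "pisiform", 20.5)


class TestAssembly:
    def test_stiffness_symmetric(self, solved_unfused):
        system, _ = solved_unfused
        scale = abs(system.K).max()
        assert abs(system.K - system.K.T).max() <= 1e-10 * scale

    def test_load_resultant(self, solved_unfused):
        system, _ = solved_unfused
        resultant = system.f.reshape(-1, 3).sum(axis=0)
        expected = system.meta["force_N"] * system.meta["direction"]
        assert np.allclose(resultant, expected, rtol=1e-12)

    def test_load_conserved_across_partition_and_mesh(self):
        """Total applied force is independent of split rule and resolution."""
        totals = []
        for h in (2.0, 2.5):
            for rule in ("area", {"radial": 1.0, "lunate": 1.0}):
                mesh = generate_carpal_set(
                    GeometryParams(seed=2, edge_length=h), "unfused"
                )
                lc = make_load_case(59.7, partition_rule=rule)
                system = assemble_model(
                    mesh, MaterialSet(),
                    LigamentSpec(topology="serial", strand_count=2),
                    default_boundary(mesh), lc,
                )
                totals.append(system.f.reshape(-1, 3).sum(axis=0))
        assert np.allclose(totals, totals[0], rtol=1e-12)

    def test_fixed_dofs_on_correct_bodies(self, solved_unfused, solved_fused):
        for (system, _), bodies in (
            (solved_unfused, {"capitate", "centrale"}),
            (solved_fused, {"capitate", "scaphoid"}),
        ):
            mesh_bodies = system.meta["fixed_bodies"]
            assert mesh_bodies == bodies

    def test_unconstrained_body_has_six_rigid_modes(self):
        """A single free elastic body's stiffness has exactly 6 zero modes."""
        from carpofem.verification import box_tet_mesh, assemble_tet_box

        nodes, tets = box_tet_mesh((2, 2, 2), (2.0, 2.0, 2.0))
        system = assemble_tet_box(
            nodes, tets, 500.0, 0.3, [], np.zeros(3 * len(nodes))
        )
        w = np.linalg.eigvalsh(system.K.toarray())
        assert np.sum(np.abs(w) < 1e-8 * w.max()) == 6


def test_materials_validation():
    with pytest.raises(ModelError):
        MaterialSet(cortical_E=-1).validate()
    with pytest.raises(ModelError):
        MaterialSet(cancellous_nu=0.5).validate()
    with pytest.raises(ModelError):
        MaterialSet(cartilage_thickness=0.0).validate()
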