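import numpy as np
import pytest

from carpofem import (
    GeometryParams,
    LigamentSpec,
    MaterialSet,
    apply_constraints,
    assemble_model,
    default_boundary,
    generate_carpal_set,
    make_load_case,
    solve_linear,
)

# Coarse (2 mm lattice) meshes keep the unit-test solves fast; the
# acceptance tests run the default 1 mm resolution.


@pytest.fixture(scope="session")
def coarse_params():
    return GeometryParams(seed=5, edge_length=2.0)


@pytest.fixture(scope="session")
def unfused_mesh(coarse_params):
    return generate_carpal_set(coarse_params, "unfused")


@pytest.fixture(scope="session")
def fused_mesh(coarse_params):
    return generate_carpal_set(coarse_params, "fused")


def solve_model(mesh, mass=72.1, tilt_deg=0.0, materials=None):
    """Assemble and solve one carpal model; returns (system, solution)."""
    materials = materials or MaterialSet()
    topo = "direct" if mesh.variant == "fused" else "serial"
    system = assemble_model(
        mesh,
        materials,
        LigamentSpec(topology=topo),
        default_boundary(mesh),
        make_load_case(mass, tilt_deg=tilt_deg),
    )
    return system, solve_linear(apply_constraints(system))


@pytest.fixture(scope="session")
def solved_unfused(unfused_mesh):
    return solve_model(unfused_mesh)


@pytest.fixture(scope="session")
def solved_fused(fused_mesh):
    return solve_model(fused_mesh)
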