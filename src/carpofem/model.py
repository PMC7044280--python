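"""Model parameterisation and assembly.

Turns a labelled carpal mesh into a fully specified linear static model:
isotropic materials for cancellous bone (solid tetrahedra) and for the
thin cortical and cartilage layers (membranes on every surface triangle,
sharing nodes with the solid so their DOFs are fully coupled), ligament
spring strands, lateral elastic-foundation restraints, distal fixation,
non-separation contact ties, and the knuckle-walking load case.

Defaults follow the standard human-derived parameterisation used in
carpal FE work: cortical bone E = 10 GPa / nu = 0.22, cancellous bone
0.5 GPa / 0.3, cartilage 7 MPa / 0.3 with a 0.55 mm layer; ligament
rigidity 40 N/mm; lateral restraint stiffness 20.5 N/mm per neighbouring
bone; load = 20% of body mass times standard gravity (forelimbs carry
about 40% of body weight in quadrupedal stance, split over two limbs).
Units: mm, N, MPa; masses kg, g in m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .geometry import (
    ContactInterface,
    GeometryError,
    LabeledMesh,
    LATERAL_PATCHES,
    REGION_ID,
    all_contact_interfaces,
)
from . import solver
from .solver import LinearSystem, SolverError

__all__ = [
    "ModelError",
    "MaterialSet",
    "LigamentSpec",
    "BoundarySpec",
    "LoadCase",
    "SpringSet",
    "STANDARD_GRAVITY",
    "compute_total_load",
    "make_load_case",
    "distribute_ligament_springs",
    "build_foundation_springs",
    "assemble_model",
    "default_boundary",
]

#: Standard gravity (m/s^2).  The tabulated species loads round-trip to
#: 0.01 N only with the standard constant, not the rounded 9.81.
STANDARD_GRAVITY = 9.80665


class ModelError(RuntimeError):
    """Raised for invalid model parameterisations."""


@dataclass(frozen=True)
class MaterialSet:
    """Elastic constants and layer thicknesses of the three tissues."""

    cortical_E: float = 10000.0  # MPa
    cortical_nu: float = 0.22
    cancellous_E: float = 500.0  # MPa
    cancellous_nu: float = 0.3
    cartilage_E: float = 7.0  # MPa
    cartilage_nu: float = 0.3
    cortical_thickness: Dict[str, float] = field(
        default_factory=lambda: {"capitate": 1.0, "scaphoid": 1.0, "centrale": 1.0}
    )
    cartilage_thickness: float = 0.55  # mm

    def validate(self) -> None:
        for E in (self.cortical_E, self.cancellous_E, self.cartilage_E):
            if E <= 0:
                raise ModelError("Young moduli must be > 0")
        for nu in (self.cortical_nu, self.cancellous_nu, self.cartilage_nu):
            if not (0 <= nu < 0.5):
                raise ModelError("Poisson ratios must satisfy 0 <= nu < 0.5")
        if self.cartilage_thickness <= 0 or any(
            t <= 0 for t in self.cortical_thickness.values()
        ):
            raise ModelError("layer thicknesses must be > 0")


@dataclass(frozen=True)
class LigamentSpec:
    """One inter-bone ligament modelled as parallel spring strands.

    ``serial`` topology routes every strand scaphoid -> centrale ->
    capitate (the scaphocentralecapitate ligament of the unfused wrist);
    ``direct`` connects scaphoid to capitate (the scaphocapitate ligament
    of the fused wrist).
    """

    total_rigidity: float = 40.0  # N/mm
    strand_count: int = 8
    topology: str = "serial"  # "serial" | "direct"

    def validate(self) -> None:
        if self.total_rigidity <= 0:
            raise ModelError("ligament rigidity must be > 0")
        if self.strand_count < 1:
            raise ModelError("strand count must be >= 1")
        if self.topology not in ("serial", "direct"):
            raise ModelError(f"unknown ligament topology {self.topology!r}")


@dataclass
class BoundarySpec:
    """Supports of the model: fixation, elastic foundation, contact."""

    fixed_regions: Tuple[str, ...] = ("distal_fixed",)
    foundation_stiffness: Dict[str, float] = field(
        default_factory=lambda: {p: 20.5 for p in LATERAL_PATCHES}
    )  # N/mm per lateral restraint patch
    contacts: List[ContactInterface] = field(default_factory=list)

    def validate(self) -> None:
        if not self.fixed_regions:
            raise ModelError("at least one fixed region is required")
        if any(k <= 0 for k in self.foundation_stiffness.values()):
            raise ModelError("foundation stiffnesses must be > 0")


@dataclass(frozen=True)
class LoadCase:
    """Total knuckle-walking load and its direction.

    ``partition_rule`` splits the total force between the radial facet
    (scaphoid) and the lunate facet (capitate): ``"area"`` divides it in
    proportion to facet area; a mapping ``{"radial": w1, "lunate": w2}``
    prescribes the split explicitly.
    """

    mass: float  # kg
    fraction: float = 0.2
    g: float = STANDARD_GRAVITY
    tilt_deg: float = 0.0
    tilt_axis: str = "y"
    partition_rule: object = "area"

    @property
    def force(self) -> float:
        """Total applied force (N)."""
        return compute_total_load(self.mass, self.fraction, self.g)

    @property
    def direction(self) -> np.ndarray:
        """Unit load direction: proximodistal compression, tilted."""
        t = np.radians(self.tilt_deg)
        base = np.array([0.0, 0.0, -1.0])
        axes = {"x": 0, "y": 1}
        if self.tilt_axis not in axes:
            raise ModelError(f"tilt axis must be 'x' or 'y', got {self.tilt_axis!r}")
        c, s = np.cos(t), np.sin(t)
        if self.tilt_axis == "y":  # rotate about +y
            R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
        else:  # rotate about +x
            R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        return R @ base


@dataclass
class SpringSet:
    """Collection of two-node axial springs and grounded springs."""

    springs: List[Tuple[int, int, float]] = field(default_factory=list)
    grounded: List[Tuple[int, np.ndarray, float]] = field(default_factory=list)

    def extend(self, other: "SpringSet") -> None:
        self.springs.extend(other.springs)
        self.grounded.extend(other.grounded)

    def total_grounded_stiffness(self) -> float:
        return float(sum(k for _, _, k in self.grounded))


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------


def compute_total_load(
    mass: float, fraction: float = 0.2, g: float = STANDARD_GRAVITY
) -> float:
    """Total applied force in N: ``fraction * mass * g``."""
    if mass < 0:
        raise ModelError("body mass must be >= 0")
    if not (0 < fraction < 1):
        raise ModelError("load fraction must be in (0, 1)")
    if g <= 0:
        raise ModelError("g must be > 0")
    return fraction * mass * g


def make_load_case(
    mass: float,
    fraction: float = 0.2,
    g: float = STANDARD_GRAVITY,
    tilt_deg: float = 0.0,
    partition_rule: object = "area",
    tilt_axis: str = "y",
) -> LoadCase:
    """Build a load case; validates the tilt and partition rule."""
    if not (0 <= tilt_deg < 90):
        raise ModelError("tilt angle must be in [0, 90) degrees")
    if not (partition_rule == "area" or isinstance(partition_rule, dict)):
        raise ModelError(f"unknown partition rule {partition_rule!r}")
    if isinstance(partition_rule, dict):
        if set(partition_rule) != {"radial", "lunate"} or any(
            w < 0 for w in partition_rule.values()
        ) or sum(partition_rule.values()) <= 0:
            raise ModelError(f"invalid partition weights {partition_rule!r}")
    compute_total_load(mass, fraction, g)  # validates the load inputs
    return LoadCase(
        mass=mass,
        fraction=fraction,
        g=g,
        tilt_deg=tilt_deg,
        tilt_axis=tilt_axis,
        partition_rule=partition_rule,
    )


def _pick_strand_nodes(
    mesh: LabeledMesh, patch: str, n: int
) -> np.ndarray:
    """Deterministically pick n attachment nodes spread over a patch."""
    tri_idx = mesh.patch_tris("ligament_attach", patch)
    if len(tri_idx) == 0:
        raise ModelError(f"ligament attachment patch {patch!r} missing from mesh")
    nodes = mesh.patch_nodes(tri_idx)
    if len(nodes) < n:
        raise ModelError(
            f"ligament patch {patch!r} has {len(nodes)} nodes, "
            f"fewer than {n} strands"
        )
    order = np.lexsort(mesh.nodes[nodes].T)  # sort by (z, y, x)
    sel = np.linspace(0, len(nodes) - 1, n).round().astype(int)
    return nodes[order][sel]


def distribute_ligament_springs(mesh: LabeledMesh, spec: LigamentSpec) -> SpringSet:
    """Realise a ligament as n parallel strands of springs.

    Direct topology: n springs scaphoid->capitate of stiffness total/n.
    Serial topology: each strand is two segments (scaphoid->centrale,
    centrale->capitate) of stiffness ``2 * total / n`` so that the series
    combination of one strand is ``total / n`` and the n parallel strands
    reproduce the specified total rigidity.
    """
    spec.validate()
    if mesh.variant == "fused" and spec.topology == "serial":
        raise ModelError("serial ligament topology requires an unfused mesh")
    if mesh.variant == "unfused" and spec.topology == "direct":
        raise ModelError("direct ligament topology requires a fused mesh")
    n = spec.strand_count
    k_strand = spec.total_rigidity / n
    out = SpringSet()
    if spec.topology == "direct":
        a = _pick_strand_nodes(mesh, "scaphoid", n)
        b = _pick_strand_nodes(mesh, "capitate", n)
        out.springs = [(int(ai), int(bi), k_strand) for ai, bi in zip(a, b)]
    else:
        a = _pick_strand_nodes(mesh, "scaphoid", n)
        m = _pick_strand_nodes(mesh, "centrale", n)
        b = _pick_strand_nodes(mesh, "capitate", n)
        k_seg = 2 * k_strand  # 1/k = 1/(2k') + 1/(2k')  ->  series = k'
        for ai, mi, bi in zip(a, m, b):
            out.springs.append((int(ai), int(mi), k_seg))
            out.springs.append((int(mi), int(bi), k_seg))
    return out


def build_foundation_springs(
    mesh: LabeledMesh, patch: str, total_stiffness: float = 20.5
) -> SpringSet:
    """Grounded springs along the patch normal, split by tributary area."""
    if total_stiffness <= 0:
        raise ModelError("foundation stiffness must be > 0")
    if patch not in LATERAL_PATCHES:
        raise ModelError(
            f"unknown lateral restraint patch {patch!r}; have {LATERAL_PATCHES}"
        )
    tri_idx = mesh.patch_tris("lateral_restraint", patch)
    if len(tri_idx) == 0:
        raise ModelError(f"lateral restraint patch {patch!r} missing from mesh")
    areas = mesh.tri_areas(tri_idx)
    total_area = areas.sum()
    if total_area <= 0:
        raise ModelError(f"lateral restraint patch {patch!r} has zero area")
    # tributary area and area-weighted normal per node
    trib = np.zeros(len(mesh.nodes))
    nsum = np.zeros((len(mesh.nodes), 3))
    tn = mesh.tri_normals(tri_idx) * areas[:, None]
    for k in range(3):
        np.add.at(trib, mesh.tris[tri_idx, k], areas / 3.0)
        np.add.at(nsum, mesh.tris[tri_idx, k], tn / 3.0)
    nodes = mesh.patch_nodes(tri_idx)
    out = SpringSet()
    for node in nodes:
        d = nsum[node]
        d = d / np.linalg.norm(d)
        out.grounded.append((int(node), d, total_stiffness * trib[node] / total_area))
    return out


def default_boundary(mesh: LabeledMesh) -> BoundarySpec:
    """Boundary specification with all contacts and default restraints."""
    return BoundarySpec(contacts=all_contact_interfaces(mesh))


# ---------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------


def _scatter(ii, jj, vv, dofs, Ke):
    """Append element stiffness blocks to triplet lists (vectorised)."""
    n = dofs.shape[1]
    ii.append(np.repeat(dofs, n, axis=1).ravel())
    jj.append(np.tile(dofs, (1, n)).ravel())
    vv.append(Ke.reshape(len(dofs), -1).ravel())


def assemble_model(
    mesh: LabeledMesh,
    materials: MaterialSet,
    ligaments: LigamentSpec,
    boundary: BoundarySpec,
    load_case: LoadCase,
) -> LinearSystem:
    """Assemble the full linear system for one carpal model.

    The stiffness comprises cancellous tetrahedra, a cortical membrane
    layer and a cartilage membrane layer on every surface triangle
    (node-shared with the solid, i.e. fully displacement-coupled),
    ligament strands and foundation springs.  The load vector lumps the
    facet tractions area-consistently; its resultant equals
    ``F * direction`` by construction.
    """
    materials.validate()
    boundary.validate()
    nd = 3 * len(mesh.nodes)
    ii: List[np.ndarray] = []
    jj: List[np.ndarray] = []
    vv: List[np.ndarray] = []

    # ---- cancellous tetrahedra --------------------------------------
    B, V = solver.tet_B_matrices(mesh.nodes, mesh.tets)
    if np.any(V <= 0):
        raise ModelError("mesh contains non-positive-volume tetrahedra")
    C = solver.elastic_C(materials.cancellous_E, materials.cancellous_nu)
    Ke = np.einsum("eki,kl,elj->eij", B, C, B) * V[:, None, None]
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    _scatter(ii, jj, vv, dofs, Ke)

    # ---- membrane layers (cortical + cartilage) ---------------------
    B2, T, A, _ = solver.membrane_B_matrices(mesh.nodes, mesh.tris)
    tdofs = (3 * mesh.tris[:, :, None] + np.arange(3)).reshape(-1, 9)
    t_cort = np.array(
        [materials.cortical_thickness[mesh.body_names[b]] for b in mesh.tri_body]
    )
    for E, nu, thick in (
        (materials.cortical_E, materials.cortical_nu, t_cort),
        (materials.cartilage_E, materials.cartilage_nu,
         np.full(len(mesh.tris), materials.cartilage_thickness)),
    ):
        Cm = solver.plane_stress_C(E, nu)
        K6 = np.einsum("eki,kl,elj->eij", B2, Cm, B2) * (A * thick)[:, None, None]
        K9 = np.einsum("eki,ekl,elj->eij", T, K6, T)
        _scatter(ii, jj, vv, tdofs, K9)

    # ---- springs -----------------------------------------------------
    springs = distribute_ligament_springs(mesh, ligaments)
    for patch, k_total in boundary.foundation_stiffness.items():
        springs.extend(build_foundation_springs(mesh, patch, k_total))
    for a, b, k in springs.springs:
        d = mesh.nodes[b] - mesh.nodes[a]
        ln = np.linalg.norm(d)
        if ln == 0:
            raise ModelError("zero-length ligament spring")
        d = d / ln
        kb = k * np.outer(d, d)
        block = np.block([[kb, -kb], [-kb, kb]])
        e = np.array([3 * a, 3 * a + 1, 3 * a + 2, 3 * b, 3 * b + 1, 3 * b + 2])
        _scatter(ii, jj, vv, e[None, :], block[None, :, :])
    for node, d, k in springs.grounded:
        kb = k * np.outer(d, d)
        e = np.array([3 * node, 3 * node + 1, 3 * node + 2])
        _scatter(ii, jj, vv, e[None, :], kb[None, :, :])

    K = sp.csr_matrix(
        (np.concatenate(vv), (np.concatenate(ii), np.concatenate(jj))),
        shape=(nd, nd),
    )
    K = 0.5 * (K + K.T)  # symmetrise accumulation round-off

    # ---- load vector -------------------------------------------------
    f = np.zeros(nd)
    facets = {
        "radial_facet": mesh.region_tris("radial_facet"),
        "lunate_facet": mesh.region_tris("lunate_facet"),
    }
    areas = {k: mesh.tri_areas(v).sum() for k, v in facets.items()}
    if load_case.partition_rule == "area":
        tot = areas["radial_facet"] + areas["lunate_facet"]
        share = {k: a / tot for k, a in areas.items()}
    elif isinstance(load_case.partition_rule, dict):
        w = load_case.partition_rule
        tot = w["radial"] + w["lunate"]
        share = {"radial_facet": w["radial"] / tot, "lunate_facet": w["lunate"] / tot}
    else:
        raise ModelError(f"unknown partition rule {load_case.partition_rule!r}")
    Fvec = load_case.force * load_case.direction
    for facet, tri_idx in facets.items():
        if len(tri_idx) == 0:
            raise ModelError(f"loaded facet {facet!r} missing from mesh")
        a = mesh.tri_areas(tri_idx)
        node_share = np.zeros(len(mesh.nodes))
        for k in range(3):
            np.add.at(node_share, mesh.tris[tri_idx, k], a / 3.0)
        node_share *= share[facet] / a.sum()
        f += (node_share[:, None] * Fvec[None, :]).ravel()

    # ---- constraints -------------------------------------------------
    fixed_nodes: List[np.ndarray] = []
    for region in boundary.fixed_regions:
        tri_idx = mesh.region_tris(region)
        if len(tri_idx) == 0:
            raise ModelError(f"fixed region {region!r} missing from mesh")
        fixed_nodes.append(mesh.patch_nodes(tri_idx))
    fixed_nodes_arr = np.unique(np.concatenate(fixed_nodes))
    fixed_dofs = (3 * fixed_nodes_arr[:, None] + np.arange(3)).ravel()

    # ties: slave side is body A; pairs with a fixed A node are swapped
    # (or dropped when both sides are fixed and the tie is vacuous)
    fixed_set = set(int(x) for x in fixed_nodes_arr)
    ties: List[Tuple[int, int, np.ndarray]] = []
    for ci in boundary.contacts:
        for (a, b), n in zip(ci.pairs, ci.normals):
            a, b = int(a), int(b)
            if a in fixed_set and b in fixed_set:
                continue
            if a in fixed_set:
                a, b, n = b, a, -n
            ties.append((a, b, n))

    return LinearSystem(
        K=K,
        f=f,
        fixed_dofs=fixed_dofs,
        ties=ties,
        grounded_springs=springs.grounded,
        n_nodes=len(mesh.nodes),
        meta={
            "variant": mesh.variant,
            "force_N": load_case.force,
            "direction": load_case.direction,
            "facet_share": share,
            "n_ligament_springs": len(springs.springs),
            "n_foundation_springs": len(springs.grounded),
            "fixed_bodies": {
                mesh.body_names[b]
                for b in np.unique(mesh.node_body[fixed_nodes_arr])
            },
        },
    )
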