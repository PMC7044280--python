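"""Synthetic carpal geometry generation.

Builds simplified, parametric stand-ins for the scaphoid / centrale /
capitate complex: convex bone bodies carved from a shared cubic lattice,
tetrahedralised, and labelled with the articular / fixation / restraint /
ligament / contact regions a wrist load-transfer model needs.  Because all
bodies are carved from the same lattice, opposing contact patches are
mirror-conforming (node-coincident pairs), which lets non-separation
contact be expressed as exact linear node-pair constraints downstream.

The fused variant merges scaphoid and centrale into a single continuous
body (the scaphoid-centrale interface disappears); the unfused variant
keeps three separate bodies whose interfaces carry contact constraints.

Units are mm throughout.  A single integer seed fully determines the
output: the only randomness is a smooth low-frequency perturbation field
applied to the whole assembly, which deforms every body identically and
therefore cannot break contact conformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GeometryError",
    "GeometryParams",
    "LabeledMesh",
    "ContactInterface",
    "QualityReport",
    "REGION_NAMES",
    "CONTACT_LABELS",
    "generate_carpal_set",
    "build_contact_interface",
    "mesh_quality",
    "tet_volumes",
]


class GeometryError(RuntimeError):
    """Raised when geometry generation or validation fails."""


# Region labels carried by every surface triangle (exactly one each).
REGION_NAMES: Tuple[str, ...] = (
    "free",
    "radial_facet",
    "lunate_facet",
    "distal_fixed",
    "lateral_restraint",
    "ligament_attach",
    "contact_scaphoid_capitate",
    "contact_scaphoid_centrale",
    "contact_centrale_capitate",
)
REGION_ID: Dict[str, int] = {n: i for i, n in enumerate(REGION_NAMES)}

CONTACT_LABELS: Tuple[str, ...] = (
    "contact_scaphoid_capitate",
    "contact_scaphoid_centrale",
    "contact_centrale_capitate",
)

# body-name pair (A, B) per contact label; A is the side whose surface
# normals are reported and whose nodes become constraint slaves.
_CONTACT_BODIES: Dict[str, Tuple[str, str]] = {
    "contact_scaphoid_capitate": ("scaphoid", "capitate"),
    "contact_scaphoid_centrale": ("scaphoid", "centrale"),
    "contact_centrale_capitate": ("centrale", "capitate"),
}

# named sub-patches within the shared labels
LATERAL_PATCHES: Tuple[str, ...] = ("lunate", "hamate", "trapezoid")
LIGAMENT_PATCHES: Tuple[str, ...] = ("scaphoid", "centrale", "capitate")


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the synthetic carpal assembly.

    Semi-axes follow rough hominoid carpal proportions: the capitate is
    the largest bone of the distal row, the os centrale by far the
    smallest element, the scaphoid intermediate.  ``edge_length`` is the
    lattice pitch and hence the target tetrahedron edge length.
    ``perturb_amplitude`` scales a smooth seeded displacement field that
    roughens the assembly away from a perfect block stack.
    """

    capitate_semi_axes: Tuple[float, float, float] = (7.0, 6.0, 10.0)
    scaphoid_semi_axes: Tuple[float, float, float] = (5.0, 4.0, 6.0)
    centrale_semi_axes: Tuple[float, float, float] = (3.5, 3.5, 3.0)
    cartilage_gap: float = 0.0  # nominal joint-space offset (mm)
    edge_length: float = 1.0  # lattice pitch / target tet edge (mm)
    perturb_amplitude: float = 0.25  # surface roughening (mm)
    scale: float = 1.0  # isometric size factor (per-species)
    facet_fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "radial": 1.0,  # share of the scaphoid proximal face loaded
            "lunate": 0.6,  # share of the capitate proximal face loaded
            "lateral": 0.5,  # share of each lateral face restrained
            "ligament": 0.25,  # ligament attachment patch size
        }
    )
    seed: int = 0

    def validate(self) -> None:
        axes = np.array(
            self.capitate_semi_axes
            + self.scaphoid_semi_axes
            + self.centrale_semi_axes
        )
        if not np.all(axes > 0):
            raise GeometryError("all semi-axes must be > 0")
        if self.edge_length <= 0 or self.scale <= 0:
            raise GeometryError("edge_length and scale must be > 0")
        if self.cartilage_gap < 0:
            raise GeometryError("cartilage_gap must be >= 0")
        if self.perturb_amplitude < 0:
            raise GeometryError("perturb_amplitude must be >= 0")
        if self.perturb_amplitude >= 0.1 * axes.min():
            raise GeometryError(
                "perturb_amplitude must stay below 10% of the smallest "
                "semi-axis to keep bodies convex-like and elements valid"
            )
        for key in ("radial", "lunate", "lateral", "ligament"):
            f = self.facet_fractions.get(key)
            if f is None or not (0 < f <= 1):
                raise GeometryError(f"facet fraction {key!r} must be in (0, 1]")
        if not isinstance(self.seed, (int, np.integer)):
            raise GeometryError("seed must be an integer")


@dataclass
class LabeledMesh:
    """Multi-body tetrahedral mesh with labelled surface triangles."""

    nodes: np.ndarray  # (N, 3) float, mm
    node_body: np.ndarray  # (N,) int
    tets: np.ndarray  # (M, 4) int, positive orientation
    tet_body: np.ndarray  # (M,) int
    tris: np.ndarray  # (T, 3) int, outward oriented
    tri_body: np.ndarray  # (T,) int
    tri_region: np.ndarray  # (T,) int, REGION_NAMES codes
    tri_subpatch: np.ndarray  # (T,) int, index into LATERAL/LIGAMENT patches, -1 else
    variant: str  # "fused" | "unfused"
    body_names: Tuple[str, ...]
    params: GeometryParams

    # -- convenience ---------------------------------------------------
    @property
    def n_bodies(self) -> int:
        return len(self.body_names)

    def body_id(self, name: str) -> int:
        try:
            return self.body_names.index(name)
        except ValueError:
            raise GeometryError(
                f"unknown body {name!r}; present: {self.body_names}"
            ) from None

    def region_tris(self, region: str, body: str | None = None) -> np.ndarray:
        """Indices of surface triangles with a region label (optionally one body)."""
        mask = self.tri_region == REGION_ID[region]
        if body is not None:
            mask &= self.tri_body == self.body_id(body)
        return np.flatnonzero(mask)

    def patch_tris(self, region: str, patch: str) -> np.ndarray:
        """Triangles of a named lateral-restraint or ligament sub-patch."""
        names = LATERAL_PATCHES if region == "lateral_restraint" else LIGAMENT_PATCHES
        if patch not in names:
            raise GeometryError(f"unknown patch {patch!r} for region {region!r}")
        mask = (self.tri_region == REGION_ID[region]) & (
            self.tri_subpatch == names.index(patch)
        )
        return np.flatnonzero(mask)

    def patch_nodes(self, tri_idx: np.ndarray) -> np.ndarray:
        """Sorted unique node indices of a set of surface triangles."""
        return np.unique(self.tris[tri_idx])

    def tri_areas(self, tri_idx: np.ndarray | None = None) -> np.ndarray:
        t = self.tris if tri_idx is None else self.tris[tri_idx]
        p = self.nodes[t]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def tri_normals(self, tri_idx: np.ndarray | None = None) -> np.ndarray:
        t = self.tris if tri_idx is None else self.tris[tri_idx]
        p = self.nodes[t]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def body_volume(self, name: str) -> float:
        vols = tet_volumes(self.nodes, self.tets)
        return float(vols[self.tet_body == self.body_id(name)].sum())

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        vols = tet_volumes(self.nodes, self.tets)
        if vols.size == 0:
            raise GeometryError("mesh has no tetrahedra")
        if np.any(vols <= 0):
            raise GeometryError(
                f"{int(np.sum(vols <= 0))} non-positive-volume tetrahedra"
            )
        expected = 2 if self.variant == "fused" else 3
        if self.n_bodies != expected:
            raise GeometryError(
                f"{self.variant} mesh must have {expected} bodies, "
                f"found {self.n_bodies}"
            )
        for b in range(self.n_bodies):
            self._check_closed(b)

    def _check_closed(self, body: int) -> None:
        """Each body surface must be closed: every edge shared by 2 triangles."""
        tris = self.tris[self.tri_body == body]
        edges = np.sort(
            np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]),
            axis=1,
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise GeometryError(
                f"surface of body {self.body_names[body]!r} is not watertight"
            )


@dataclass
class ContactInterface:
    """Node-pair description of one conforming contact patch."""

    pairs: np.ndarray  # (P, 2) int: (body A node, body B node)
    normals: np.ndarray  # (P, 3) unit outward normals of body A
    label: str
    body_a: str
    body_b: str

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class QualityReport:
    n_elements: int
    volume_cv: float
    min_dihedral_deg: float
    max_dihedral_deg: float
    quasi_ideal: bool
    cv_threshold: float


# ---------------------------------------------------------------------
# lattice helpers
# ---------------------------------------------------------------------

# Kuhn triangulation: 6 tets per cube, consistent across the lattice.
# Corner index = ix + 2*iy + 4*iz.
_KUHN_TETS = np.array(
    [
        [0, 1, 3, 7],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 6, 7],
        [0, 4, 5, 7],
        [0, 4, 6, 7],
    ]
)
_CORNER_OFFSETS = np.array(
    [[i, j, k] for k in (0, 1) for j in (0, 1) for i in (0, 1)]
)


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return (
        np.linalg.det(np.stack(
            [p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=1
        ))
        / 6.0
    )


def _box_points(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """All integer lattice points of [lo, hi] (inclusive), lexicographic."""
    ax = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    g = np.meshgrid(*ax, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def _box_tets(lo: np.ndarray, hi: np.ndarray, index_of) -> np.ndarray:
    """Tetrahedra of the Kuhn-split box, node ids via ``index_of`` lookup."""
    nc = hi - lo  # cells per axis
    cells = _box_points(lo, hi - 1)
    corners = cells[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (C, 8, 3)
    ids = index_of(corners.reshape(-1, 3)).reshape(-1, 8)
    tets = ids[:, _KUHN_TETS].reshape(-1, 4)
    return tets


def _lattice_index_factory(points: np.ndarray):
    """Map integer lattice coordinates -> row index in ``points``."""
    key = {tuple(p): i for i, p in enumerate(points)}

    def index_of(q: np.ndarray) -> np.ndarray:
        return np.array([key[tuple(row)] for row in q], dtype=np.int64)

    return index_of


def _boundary_tris(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles of a tet mesh (positive tets)."""
    # faces opposite each vertex, ordered outward for positively oriented tets
    faces = np.concatenate(
        [
            tets[:, [1, 2, 3]],
            tets[:, [0, 3, 2]],
            tets[:, [0, 1, 3]],
            tets[:, [0, 2, 1]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    return faces[first[counts == 1]]


# ---------------------------------------------------------------------
# assembly layout
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class _Layout:
    """Integer-lattice bounding boxes and interface planes of the assembly."""

    cap_lo: np.ndarray
    cap_hi: np.ndarray
    sca_lo: np.ndarray
    sca_hi: np.ndarray
    cen_lo: np.ndarray
    cen_hi: np.ndarray
    x_if: int  # capitate | scaphoid-column interface plane
    z_if: int  # centrale | scaphoid interface plane


def _layout(params: GeometryParams) -> _Layout:
    h = params.edge_length

    def ncells(semi_axes):
        n = np.maximum(1, np.rint(2 * np.asarray(semi_axes) / h).astype(int))
        return n

    nc = ncells(params.capitate_semi_axes)
    ns = ncells(params.scaphoid_semi_axes)
    nce = ncells(params.centrale_semi_axes)
    if nce[1] > nc[1] or ns[1] > nc[1]:
        raise GeometryError("capitate must be at least as deep (y) as the others")
    if nce[0] > ns[0]:
        raise GeometryError("centrale must not be wider (x) than the scaphoid")
    if nce[2] >= nc[2]:
        raise GeometryError("centrale must be shorter (z) than the capitate")
    x_if = nc[0]
    z_if = nce[2]
    cap_lo = np.array([0, 0, 0])
    cap_hi = nc.copy()
    cen_lo = np.array([x_if, (nc[1] - nce[1]) // 2, 0])
    cen_hi = cen_lo + nce
    sca_lo = np.array([x_if, (nc[1] - ns[1]) // 2, z_if])
    sca_hi = sca_lo + ns
    # the scaphoid must actually touch the capitate above the centrale
    if min(sca_hi[2], nc[2]) <= z_if:
        raise GeometryError("no scaphoid-capitate contact overlap")
    return _Layout(cap_lo, cap_hi, sca_lo, sca_hi, cen_lo, cen_hi, x_if, z_if)


def _build_body(boxes: List[Tuple[np.ndarray, np.ndarray]]):
    """Mesh one body made of one or more lattice-aligned boxes (merged nodes)."""
    pts = np.unique(np.concatenate([_box_points(lo, hi) for lo, hi in boxes]), axis=0)
    index_of = _lattice_index_factory(pts)
    tets = np.concatenate([_box_tets(lo, hi, index_of) for lo, hi in boxes])
    # merged multi-box bodies can duplicate cells only if boxes overlap —
    # the fused pair shares a face, not a volume, so tets are unique
    return pts, tets


# ---------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------


def _rect_mask(c, axis_val, axis, lo0, hi0, ax0, lo1, hi1, ax1, tol=0.25):
    """Centroids on plane ``axis == axis_val`` within a lattice rectangle."""
    on_plane = np.abs(c[:, axis] - axis_val) < tol
    in0 = (c[:, ax0] > lo0 - tol) & (c[:, ax0] < hi0 + tol)
    in1 = (c[:, ax1] > lo1 - tol) & (c[:, ax1] < hi1 + tol)
    return on_plane & in0 & in1


def _label_body(
    name: str,
    lat_cent: np.ndarray,  # triangle centroids in lattice coordinates
    L: _Layout,
    params: GeometryParams,
    variant: str,
):
    """Assign one region label (and sub-patch id) per surface triangle."""
    n = len(lat_cent)
    region = np.full(n, REGION_ID["free"], dtype=np.int64)
    subpatch = np.full(n, -1, dtype=np.int64)
    fr = params.facet_fractions
    c = lat_cent

    def put(mask, reg, sub=-1):
        free = region == REGION_ID["free"]
        sel = mask & free
        region[sel] = REGION_ID[reg]
        subpatch[sel] = sub

    sca_lo, sca_hi = L.sca_lo, L.sca_hi
    cen_lo, cen_hi = L.cen_lo, L.cen_hi
    cap_lo, cap_hi = L.cap_lo, L.cap_hi

    # ---- contact patches (highest priority) --------------------------
    y0_sc = max(sca_lo[1], cap_lo[1])
    y1_sc = min(sca_hi[1], cap_hi[1])
    z0_sc, z1_sc = L.z_if, min(sca_hi[2], cap_hi[2])
    y0_cc = max(cen_lo[1], cap_lo[1])
    y1_cc = min(cen_hi[1], cap_hi[1])
    x0_scc = max(cen_lo[0], sca_lo[0])
    x1_scc = min(cen_hi[0], sca_hi[0])
    y0_scc = max(cen_lo[1], sca_lo[1])
    y1_scc = min(cen_hi[1], sca_hi[1])

    if name in ("scaphoid", "capitate"):
        put(
            _rect_mask(c, L.x_if, 0, y0_sc, y1_sc, 1, z0_sc, z1_sc, 2),
            "contact_scaphoid_capitate",
        )
    if name in ("centrale", "capitate") or (variant == "fused" and name == "scaphoid"):
        put(
            _rect_mask(c, L.x_if, 0, y0_cc, y1_cc, 1, 0, L.z_if, 2),
            "contact_centrale_capitate",
        )
    if variant == "unfused" and name in ("scaphoid", "centrale"):
        put(
            _rect_mask(c, L.z_if, 2, x0_scc, x1_scc, 0, y0_scc, y1_scc, 1),
            "contact_scaphoid_centrale",
        )

    # ---- distal fixation (z = 0 faces) -------------------------------
    if name == "capitate" or name == "centrale" or (
        variant == "fused" and name == "scaphoid"
    ):
        put(np.abs(c[:, 2] - 0.0) < 0.25, "distal_fixed")

    # ---- loaded articular facets -------------------------------------
    if name == "scaphoid":
        x1 = sca_lo[0] + fr["radial"] * (sca_hi[0] - sca_lo[0])
        put(
            _rect_mask(c, sca_hi[2], 2, sca_lo[0], x1, 0, sca_lo[1], sca_hi[1], 1),
            "radial_facet",
        )
    if name == "capitate":
        x1 = cap_lo[0] + fr["lunate"] * (cap_hi[0] - cap_lo[0])
        put(
            _rect_mask(c, cap_hi[2], 2, cap_lo[0], x1, 0, cap_lo[1], cap_hi[1], 1),
            "lunate_facet",
        )

    # ---- ligament attachment patches (on the y-max faces) ------------
    s_l = max(2, int(round(fr["ligament"] * 8)))
    if name == "scaphoid":
        put(
            _rect_mask(
                c, sca_hi[1], 1,
                L.x_if + 1, L.x_if + 1 + s_l, 0,
                L.z_if + 1, L.z_if + 1 + s_l, 2,
            ),
            "ligament_attach",
            LIGAMENT_PATCHES.index("scaphoid"),
        )
    if name == "centrale" and variant == "unfused":
        put(
            _rect_mask(
                c, cen_hi[1], 1,
                L.x_if + 1, L.x_if + 1 + s_l, 0,
                max(cen_lo[2], L.z_if - 1 - s_l), L.z_if - 1, 2,
            ),
            "ligament_attach",
            LIGAMENT_PATCHES.index("centrale"),
        )
    if name == "capitate":
        put(
            _rect_mask(
                c, cap_hi[1], 1,
                L.x_if - 1 - s_l, L.x_if - 1, 0,
                L.z_if + 1, L.z_if + 1 + s_l, 2,
            ),
            "ligament_attach",
            LIGAMENT_PATCHES.index("capitate"),
        )

    # ---- lateral elastic restraints ----------------------------------
    def centered(lo, hi, frac):
        mid = 0.5 * (lo + hi)
        half = 0.5 * frac * (hi - lo)
        return mid - half, mid + half

    lat = fr["lateral"]
    if name == "scaphoid":  # lunate side of the scaphoid column
        x0, x1 = centered(sca_lo[0], sca_hi[0], lat)
        z0, z1 = centered(sca_lo[2], sca_hi[2], lat)
        put(
            _rect_mask(c, sca_hi[1], 1, x0, x1, 0, z0, z1, 2),
            "lateral_restraint",
            LATERAL_PATCHES.index("lunate"),
        )
    if name == "capitate":
        x0, x1 = centered(cap_lo[0], cap_hi[0], lat)
        z0, z1 = centered(cap_lo[2], cap_hi[2], lat)
        put(  # hamate side
            _rect_mask(c, cap_hi[1], 1, x0, x1, 0, z0, z1, 2),
            "lateral_restraint",
            LATERAL_PATCHES.index("hamate"),
        )
        y0, y1 = centered(cap_lo[1], cap_hi[1], lat)
        put(  # trapezoid side
            _rect_mask(c, cap_lo[0], 0, y0, y1, 1, z0, z1, 2),
            "lateral_restraint",
            LATERAL_PATCHES.index("trapezoid"),
        )

    return region, subpatch


# ---------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------


#: Obliquity of the articular planes to the load axis (radians).  Carpal
#: articulations are not perpendicular to the proximodistal load path —
#: the scaphoid famously lies oblique to the wrist axis — so the whole
#: assembly is sheared by this angle, tilting every interface plane
#: uniformly while keeping contact pairs coincident and sliding smooth.
ARTICULAR_OBLIQUITY = np.radians(30.0)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3 - 2 * t)


def _deform(
    lat_pts: np.ndarray, params: GeometryParams, extent: np.ndarray, L: "_Layout"
) -> np.ndarray:
    """Map lattice coordinates to physical mm with smooth global shaping.

    One smooth map is applied to the entire assembly, so node-coincident
    contact pairs stay coincident and the displacement gradient is kept
    small enough that no lattice tetrahedron inverts.  The seeded
    roughening is tapered to zero near the articular interface planes:
    articular surfaces are smooth (cartilage-covered) even where the
    rest of the bone is irregular, and roughening a contact plane would
    spuriously interlock a joint that should slide freely.
    """
    h = params.edge_length
    X = lat_pts * h
    span = extent * h
    mid = 0.5 * span

    # gentle barrel profile: the assembly narrows toward its proximal and
    # distal ends, roughly like a stack of convex bones
    out = X.copy()
    out[:, 1] = mid[1] + (X[:, 1] - mid[1]) * (
        0.92 + 0.08 * np.cos(np.pi * (X[:, 2] - mid[2]) / span[2])
    )

    amp = params.perturb_amplitude
    if amp > 0:
        # fade the roughening within 3 cells of the two interface planes
        d_if = np.minimum(
            np.abs(lat_pts[:, 0] - L.x_if), np.abs(lat_pts[:, 2] - L.z_if)
        )
        taper = _smoothstep(d_if / 3.0)
        rng = np.random.default_rng(params.seed)
        n_modes = 4
        # wavelengths >= 12 lattice cells keep |grad d| << 1
        kvec = rng.uniform(-1.0, 1.0, size=(3, n_modes, 3))
        kvec *= 2 * np.pi / (12.0 * h) / np.maximum(
            1.0, np.linalg.norm(kvec, axis=2, keepdims=True)
        )
        phase = rng.uniform(0, 2 * np.pi, size=(3, n_modes))
        w = rng.uniform(0.5, 1.0, size=(3, n_modes))
        for c in range(3):
            s = np.zeros(len(X))
            for m in range(n_modes):
                s += w[c, m] * np.sin(X @ kvec[c, m] + phase[c, m])
            out[:, c] += amp * taper * s / np.sum(w[c])

    # uniform articular obliquity: shear the stack so interface planes sit
    # at an angle to the (proximodistal) load axis
    out[:, 2] += np.tan(ARTICULAR_OBLIQUITY) * (out[:, 0] - mid[0])
    return out * params.scale


# ---------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------


def generate_carpal_set(params: GeometryParams, variant: str) -> LabeledMesh:
    """Generate the fused or unfused carpal assembly as a labelled tet mesh.

    The unfused assembly holds three bodies (capitate, scaphoid,
    centrale); the fused assembly merges scaphoid and centrale into one
    continuous body and the scaphoid-centrale interface vanishes.
    """
    params.validate()
    if variant not in ("fused", "unfused"):
        raise GeometryError(f"variant must be 'fused' or 'unfused', got {variant!r}")
    L = _layout(params)

    bodies: List[Tuple[str, List[Tuple[np.ndarray, np.ndarray]]]] = [
        ("capitate", [(L.cap_lo, L.cap_hi)]),
    ]
    if variant == "fused":
        bodies.append(
            ("scaphoid", [(L.sca_lo, L.sca_hi), (L.cen_lo, L.cen_hi)])
        )
    else:
        bodies.append(("scaphoid", [(L.sca_lo, L.sca_hi)]))
        bodies.append(("centrale", [(L.cen_lo, L.cen_hi)]))

    all_pts, all_tets, all_tris = [], [], []
    node_body, tet_body, tri_body = [], [], []
    tri_region, tri_subpatch = [], []
    offset = 0
    names: List[str] = []
    for body_id, (name, boxes) in enumerate(bodies):
        pts, tets = _build_body(boxes)
        vols = tet_volumes(pts.astype(float), tets)
        neg = vols < 0  # fix orientation cell-by-cell
        tets[neg] = tets[neg][:, [0, 1, 3, 2]]
        if np.any(tet_volumes(pts.astype(float), tets) <= 0):
            raise GeometryError(f"degenerate lattice tetrahedra in body {name!r}")
        tris = _boundary_tris(tets)
        cent = pts[tris].mean(axis=1)
        region, subpatch = _label_body(name, cent, L, params, variant)
        all_pts.append(pts)
        all_tets.append(tets + offset)
        all_tris.append(tris + offset)
        node_body.append(np.full(len(pts), body_id))
        tet_body.append(np.full(len(tets), body_id))
        tri_body.append(np.full(len(tris), body_id))
        tri_region.append(region)
        tri_subpatch.append(subpatch)
        names.append(name)
        offset += len(pts)

    lat_pts = np.concatenate(all_pts).astype(float)
    nb = np.concatenate(node_body)
    # nominal joint-space offsets (default 0: contacts are node-coincident)
    if params.cartilage_gap > 0:
        g = params.cartilage_gap / params.edge_length
        col = nb != names.index("capitate")  # scaphoid column moves radially
        lat_pts[col, 0] += g
        if "centrale" in names:
            lat_pts[nb == names.index("scaphoid"), 2] += g

    extent = np.array([L.sca_hi[0], L.cap_hi[1], max(L.cap_hi[2], L.sca_hi[2])])
    nodes = _deform(lat_pts, params, extent, L)

    mesh = LabeledMesh(
        nodes=nodes,
        node_body=nb,
        tets=np.concatenate(all_tets),
        tet_body=np.concatenate(tet_body),
        tris=np.concatenate(all_tris),
        tri_body=np.concatenate(tri_body),
        tri_region=np.concatenate(tri_region),
        tri_subpatch=np.concatenate(tri_subpatch),
        variant=variant,
        body_names=tuple(names),
        params=params,
    )
    mesh.validate()
    _check_labels(mesh)
    return mesh


def _check_labels(mesh: LabeledMesh) -> None:
    present = {REGION_NAMES[r] for r in np.unique(mesh.tri_region)}
    if mesh.variant == "unfused":
        missing = set(REGION_NAMES) - present
        if missing:
            raise GeometryError(f"unfused mesh missing regions: {sorted(missing)}")
    else:
        if "contact_scaphoid_centrale" in present:
            raise GeometryError(
                "fused mesh must not carry a scaphoid-centrale contact patch"
            )


def build_contact_interface(mesh: LabeledMesh, patch_label: str) -> ContactInterface:
    """Pair the coincident nodes of one contact patch across its two bodies.

    Every patch node on body A is paired with exactly one coincident node
    on body B; the per-pair normal is the area-weighted outward normal of
    body A's patch surface at that node.
    """
    if patch_label not in CONTACT_LABELS:
        raise GeometryError(f"{patch_label!r} is not a contact patch label")
    name_a, name_b = _CONTACT_BODIES[patch_label]
    if mesh.variant == "fused":
        if patch_label == "contact_scaphoid_centrale":
            raise GeometryError(
                "patch 'contact_scaphoid_centrale' absent: fused variant"
            )
        if name_a == "centrale":  # centrale is part of the fused scaphoid
            name_a = "scaphoid"
    code = REGION_ID[patch_label]
    mask = mesh.tri_region == code
    tris_a = np.flatnonzero(mask & (mesh.tri_body == mesh.body_id(name_a)))
    tris_b = np.flatnonzero(mask & (mesh.tri_body == mesh.body_id(name_b)))
    if len(tris_a) == 0 or len(tris_b) == 0:
        raise GeometryError(f"contact patch {patch_label!r} absent from mesh")
    nodes_a = mesh.patch_nodes(tris_a)
    nodes_b = mesh.patch_nodes(tris_b)
    if len(nodes_a) != len(nodes_b):
        raise GeometryError(
            f"contact patch {patch_label!r} is non-conforming: "
            f"{len(nodes_a)} vs {len(nodes_b)} nodes"
        )
    gap = mesh.params.cartilage_gap * mesh.params.scale
    tol = 1e-6 + 1.5 * gap
    tree = cKDTree(mesh.nodes[nodes_b])
    dist, j = tree.query(mesh.nodes[nodes_a])
    if np.any(dist > tol) or len(np.unique(j)) != len(j):
        raise GeometryError(
            f"contact patch {patch_label!r} is non-conforming: "
            "opposing nodes do not pair one-to-one"
        )
    pairs = np.stack([nodes_a, nodes_b[j]], axis=1)

    # area-weighted outward normals of body A at each paired node
    pn = np.zeros((len(mesh.nodes), 3))
    tri_n = mesh.tri_normals(tris_a) * mesh.tri_areas(tris_a)[:, None]
    for k in range(3):
        np.add.at(pn, mesh.tris[tris_a, k], tri_n)
    normals = pn[nodes_a]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return ContactInterface(
        pairs=pairs,
        normals=normals,
        label=patch_label,
        body_a=name_a,
        body_b=name_b,
    )


def mesh_quality(mesh: LabeledMesh, cv_threshold: float = 0.5) -> QualityReport:
    """Element-size statistics over the tetrahedra.

    A quasi-ideal mesh has nearly (not exactly) uniform element sizes;
    the flag is set when the element-volume coefficient of variation
    stays below ``cv_threshold``.
    """
    vols = tet_volumes(mesh.nodes, mesh.tets)
    if vols.size == 0:
        raise GeometryError("empty mesh")
    if np.any(vols <= 0):
        raise GeometryError("mesh contains non-positive-volume tetrahedra")
    cv = float(np.std(vols) / np.mean(vols))
    dmin, dmax = _dihedral_range(mesh.nodes, mesh.tets)
    return QualityReport(
        n_elements=int(vols.size),
        volume_cv=cv,
        min_dihedral_deg=dmin,
        max_dihedral_deg=dmax,
        quasi_ideal=cv < cv_threshold,
        cv_threshold=cv_threshold,
    )


def _dihedral_range(nodes: np.ndarray, tets: np.ndarray) -> Tuple[float, float]:
    p = nodes[tets]
    # inward face normals; face f is opposite vertex f
    faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    n = []
    for (a, b, c) in faces:
        v = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
        n.append(v / np.linalg.norm(v, axis=1, keepdims=True))
    n = np.stack(n, axis=1)  # (M, 4, 3) outward
    angles = []
    for i in range(4):
        for j in range(i + 1, 4):
            cosang = np.clip(-(n[:, i] * n[:, j]).sum(axis=1), -1.0, 1.0)
            angles.append(np.degrees(np.arccos(cosang)))
    angles = np.concatenate(angles)
    return float(angles.min()), float(angles.max())


def all_contact_interfaces(mesh: LabeledMesh) -> List[ContactInterface]:
    """Every contact interface present in the mesh."""
    present = {REGION_NAMES[r] for r in np.unique(mesh.tri_region)}
    return [
        build_contact_interface(mesh, lab)
        for lab in CONTACT_LABELS
        if lab in present
    ]
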