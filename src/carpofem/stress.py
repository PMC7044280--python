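"""Stress recovery and mesh-weighted statistics.

Recovers per-element constitutive stresses from a displacement solution,
evaluates the von Mises equivalent stress, and summarises it per bone
with statistics that weight each element by its size: the mesh-weighted
arithmetic mean (MWAM) and mesh-weighted median (MWM).  Size weighting
corrects for the non-uniform element sizes of a quasi-ideal mesh, where
an unweighted mean would over-count regions meshed more finely.

Per-bone summaries pool cortical and cancellous elements and exclude
cartilage, since the comparison of interest is stress in the bone
tissue.  Element weights are volume (mm^3) for tetrahedra and
area x thickness for membranes.  Stress unit: MPa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np

from . import solver
from .geometry import LabeledMesh
from .model import MaterialSet

__all__ = [
    "StressError",
    "StressField",
    "StressSummary",
    "TISSUES",
    "recover_stress",
    "von_mises",
    "mwam",
    "mwm",
    "weighted_quantile",
    "stress_summary",
    "export_fields",
]

TISSUES = ("cancellous", "cortical", "cartilage")


class StressError(RuntimeError):
    pass


@dataclass
class StressField:
    """Per-element stress tensors with element weights and provenance.

    ``tensors`` holds Voigt components (xx, yy, zz, xy, yz, zx) in MPa;
    ``weight`` is the element size measure used by the mesh-weighted
    statistics; ``body`` and ``tissue`` are integer codes (tissue indexes
    :data:`TISSUES`).
    """

    tensors: np.ndarray  # (n, 6)
    weight: np.ndarray  # (n,)
    body: np.ndarray  # (n,)
    tissue: np.ndarray  # (n,)
    body_names: tuple

    def von_mises(self) -> np.ndarray:
        return von_mises(self.tensors)


@dataclass(frozen=True)
class StressSummary:
    """Weighted summary of one bone's von Mises stress distribution (MPa)."""

    body: str
    mwam: float
    mwm: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    n_elements: int
    total_weight: float


def von_mises(tensor: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of Voigt tensors (xx,yy,zz,xy,yz,zx)."""
    t = np.atleast_2d(np.asarray(tensor, dtype=float))
    if not np.all(np.isfinite(t)):
        raise StressError("non-finite stress components")
    s11, s22, s33, s12, s23, s13 = t.T
    vm = np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s13**2)
    )
    return vm if np.ndim(tensor) > 1 else float(vm[0])


def recover_stress(
    mesh: LabeledMesh, materials: MaterialSet, u: np.ndarray
) -> StressField:
    """Constitutive stress per element from a nodal displacement field.

    Constant-strain recovery: cancellous tets via the 3-D elasticity
    matrix, cortical and cartilage membranes via plane stress in the
    triangle plane, embedded back into the global tensor frame.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (len(mesh.nodes), 3):
        raise StressError(
            f"displacement shape {u.shape} does not match mesh "
            f"({len(mesh.nodes)} nodes)"
        )
    uflat = u.ravel()
    tensors, weights, bodies, tissues = [], [], [], []

    # cancellous tetrahedra
    B, V = solver.tet_B_matrices(mesh.nodes, mesh.tets)
    C = solver.elastic_C(materials.cancellous_E, materials.cancellous_nu)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    eps = np.einsum("eij,ej->ei", B, uflat[dofs])
    tensors.append(eps @ C.T)
    weights.append(V)
    bodies.append(mesh.tet_body)
    tissues.append(np.full(len(mesh.tets), TISSUES.index("cancellous")))

    # membrane layers
    B2, T, A, basis = solver.membrane_B_matrices(mesh.nodes, mesh.tris)
    tdofs = (3 * mesh.tris[:, :, None] + np.arange(3)).reshape(-1, 9)
    ue = uflat[tdofs]
    eps2 = np.einsum("eij,ejk,ek->ei", B2, T, ue)
    e1, e2 = basis[:, 0], basis[:, 1]
    # outer-product frames for embedding the in-plane tensor in 3-D
    def embed(sig_local):
        s11, s22, s12 = sig_local.T
        M = (
            s11[:, None, None] * np.einsum("ei,ej->eij", e1, e1)
            + s22[:, None, None] * np.einsum("ei,ej->eij", e2, e2)
            + s12[:, None, None]
            * (np.einsum("ei,ej->eij", e1, e2) + np.einsum("ei,ej->eij", e2, e1))
        )
        return np.stack(
            [M[:, 0, 0], M[:, 1, 1], M[:, 2, 2], M[:, 0, 1], M[:, 1, 2], M[:, 0, 2]],
            axis=1,
        )

    t_cort = np.array(
        [materials.cortical_thickness[mesh.body_names[b]] for b in mesh.tri_body]
    )
    for tissue, E, nu, thick in (
        ("cortical", materials.cortical_E, materials.cortical_nu, t_cort),
        ("cartilage", materials.cartilage_E, materials.cartilage_nu,
         np.full(len(mesh.tris), materials.cartilage_thickness)),
    ):
        Cm = solver.plane_stress_C(E, nu)
        tensors.append(embed(eps2 @ Cm.T))
        weights.append(A * thick)
        bodies.append(mesh.tri_body)
        tissues.append(np.full(len(mesh.tris), TISSUES.index(tissue)))

    return StressField(
        tensors=np.concatenate(tensors),
        weight=np.concatenate(weights),
        body=np.concatenate(bodies),
        tissue=np.concatenate(tissues),
        body_names=mesh.body_names,
    )


# ---------------------------------------------------------------------
# mesh-weighted statistics
# ---------------------------------------------------------------------


def _check_wv(values, weights):
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise StressError("empty sample")
    if v.shape != w.shape:
        raise StressError("values and weights must have equal length")
    if np.any(w <= 0):
        raise StressError("weights must be > 0")
    return v, w


def mwam(values: Sequence[float], weights: Sequence[float]) -> float:
    """Mesh-weighted arithmetic mean: sum(v*w) / sum(w)."""
    v, w = _check_wv(values, weights)
    return float(np.dot(v, w) / w.sum())


def weighted_quantile(
    values: Sequence[float], weights: Sequence[float], q: float
) -> float:
    """Smallest value whose cumulative weight reaches ``q`` of the total."""
    v, w = _check_wv(values, weights)
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, q * cum[-1] - 1e-12 * cum[-1]))
    return float(v[min(idx, len(v) - 1)])


def mwm(values: Sequence[float], weights: Sequence[float]) -> float:
    """Mesh-weighted median: weighted quantile at 1/2."""
    return weighted_quantile(values, weights, 0.5)


def stress_summary(
    field: StressField, scope: Iterable[str] | None = None
) -> Dict[str, StressSummary]:
    """Per-bone weighted summaries of the von Mises field.

    Statistics pool cancellous and cortical elements (cartilage layers
    are excluded) and weight each element by its size.
    """
    vm = field.von_mises()
    bone = field.tissue != TISSUES.index("cartilage")
    names = list(scope) if scope is not None else list(field.body_names)
    out: Dict[str, StressSummary] = {}
    for name in names:
        if name not in field.body_names:
            raise StressError(
                f"unknown body {name!r}; present: {field.body_names}"
            )
        b = field.body_names.index(name)
        sel = bone & (field.body == b)
        if not np.any(sel):
            raise StressError(f"no bone elements for body {name!r}")
        v, w = vm[sel], field.weight[sel]
        out[name] = StressSummary(
            body=name,
            mwam=mwam(v, w),
            mwm=mwm(v, w),
            median=weighted_quantile(v, w, 0.5),
            q25=weighted_quantile(v, w, 0.25),
            q75=weighted_quantile(v, w, 0.75),
            min=float(v.min()),
            max=float(v.max()),
            n_elements=int(sel.sum()),
            total_weight=float(w.sum()),
        )
    return out


def export_fields(
    mesh: LabeledMesh,
    field: StressField,
    summaries: Dict[str, StressSummary],
    vtu_path,
    csv_path=None,
    csv_keys: Dict[str, object] | None = None,
):
    """Write the stress field as VTU cell data and the summaries as CSV."""
    from . import vtkio
    import pandas as pd

    vm = field.von_mises()
    n_tet = len(mesh.tets)
    n_tri = len(mesh.tris)
    # cell order in the file: tets, then cortical tris, then cartilage tris
    cell_data = {
        "von_mises": vm,
        "body_id": field.body,
        "tissue": field.tissue,
        "region_label": np.concatenate(
            [np.full(n_tet, -1), mesh.tri_region, mesh.tri_region]
        ),
    }
    vtkio.write_vtu(
        vtu_path,
        mesh.nodes,
        [("tetra", mesh.tets), ("triangle", mesh.tris), ("triangle", mesh.tris)],
        cell_data,
    )
    if csv_path is not None:
        rows = []
        for name, s in summaries.items():
            row = dict(csv_keys or {})
            row.update(
                body=name, mwam=s.mwam, mwm=s.mwm, median=s.median,
                q25=s.q25, q75=s.q75, min=s.min, max=s.max,
                n_elements=s.n_elements, total_weight=s.total_weight,
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(csv_path, index=False)
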