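"""Config-driven orchestration of the fused-vs-unfused carpal study.

Runs the full experiment — five hominoid species configurations, fused
and unfused variants, one or two load angles — from seeded geometry
generation through solved models to per-bone stress summaries and the
Welch comparisons, with everything reproducible from (config, seed).

Species enter the models through the applied load (20% of body mass
times standard gravity) and, by default, an isometric size factor
``(mass / reference_mass)^(1/3)`` on all semi-axes: a gibbon's carpus is
not gorilla-sized, and isometry is the standard null for size scaling in
comparative biomechanics.  Per-species shapes additionally differ by the
seeded surface perturbation (one sub-seed per species).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryParams, generate_carpal_set, mesh_quality
from .model import (
    BoundarySpec,
    LigamentSpec,
    LoadCase,
    MaterialSet,
    assemble_model,
    default_boundary,
    make_load_case,
)
from . import solver
from .stats import ComparisonReport, compare_fused_unfused, welch_t
from .stress import recover_stress, stress_summary, export_fields

__all__ = [
    "StudyError",
    "StudyConfig",
    "StudyReport",
    "TABLE1_MASSES",
    "run_study",
    "sensitivity_compare",
    "load_config",
    "subseed",
]

log = logging.getLogger("carpofem")

#: Body masses (kg) of the five study individuals.
TABLE1_MASSES: Dict[str, float] = {
    "H. sapiens": 72.1,
    "G. gorilla": 170.4,
    "P. troglodytes": 59.7,
    "P. abelii": 77.9,
    "H. lar": 9.5,
}

SUMMARY_COLUMNS = [
    "species", "variant", "angle_deg", "body",
    "mwam", "mwm", "median", "q25", "q75", "min", "max",
    "n_elements", "total_weight", "mass_kg", "force_N",
]


class StudyError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    """Everything needed to reproduce the experiment bit-identically."""

    species: Dict[str, float] = field(default_factory=lambda: dict(TABLE1_MASSES))
    variants: Tuple[str, ...] = ("fused", "unfused")
    angles: Tuple[float, ...] = (0.0,)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: MaterialSet = field(default_factory=MaterialSet)
    ligament_rigidity: float = 40.0
    strand_count: int = 8
    foundation_stiffness: float = 20.5
    load_fraction: float = 0.2
    partition_rule: object = "area"
    tilt_axis: str = "y"
    isometric_scaling: bool = True
    reference_mass: float = 72.1  # default anatomy is human-sized
    seed: int = 0
    output_dir: Path | None = None
    write_fields: bool = False

    def validate(self) -> None:
        if any(m <= 0 for m in self.species.values()):
            raise StudyError("species masses must be > 0")
        bad = set(self.variants) - {"fused", "unfused"}
        if bad:
            raise StudyError(f"unknown variants: {sorted(bad)}")
        if not isinstance(self.seed, (int, np.integer)):
            raise StudyError("a master seed is mandatory")

    def resolved_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        d["materials"] = asdict(self.materials)
        d["output_dir"] = str(self.output_dir) if self.output_dir else None
        return d

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.resolved_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Results of one full study run."""

    results: pd.DataFrame  # one row per (species, variant, angle, body)
    comparisons: List[ComparisonReport]
    config: StudyConfig
    config_hash: str
    diagnostics: List[dict]

    def samples(self) -> pd.DataFrame:
        """Tidy MWAM table for the statistics stage."""
        return self.results.rename(columns={"body": "bone"})[
            ["species", "bone", "variant", "angle_deg", "mwam"]
        ]

    def comparison_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                bone=c.bone, angle_deg=c.angle_deg, n1=c.n_fused, n2=c.n_unfused,
                mean_fused=c.mean_fused, mean_unfused=c.mean_unfused,
                W=c.shapiro_W, p_W=c.shapiro_p, t=c.t, df=c.df, p_t=c.p,
            )
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)


def subseed(master_seed: int, species_index: int) -> int:
    """Per-species sub-seed: ``(master * 1000003 + index) mod 2^31``."""
    return int((int(master_seed) * 1000003 + species_index) % 2**31)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full species x variant x angle experiment.

    For each combination: generate the seeded geometry, assemble the
    model with the species load, solve, and summarise per-bone von Mises
    stress; afterwards run the fused-vs-unfused Welch comparison per
    bone and angle.  Any stage failure aborts with the failing
    combination named.
    """
    config.validate()
    outdir = Path(config.output_dir) if config.output_dir else None
    fh = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "study.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(fh)
        log.setLevel(logging.INFO)

    rows: List[dict] = []
    diagnostics: List[dict] = []
    try:
        for i, (species, mass) in enumerate(config.species.items()):
            scale = (
                (mass / config.reference_mass) ** (1.0 / 3.0)
                if config.isometric_scaling
                else 1.0
            )
            geo = replace(
                config.geometry, seed=subseed(config.seed, i), scale=scale
            )
            for variant in config.variants:
                combo = f"{species}/{variant}"
                try:
                    mesh = generate_carpal_set(geo, variant)
                except Exception as exc:
                    raise StudyError(f"geometry failed for {combo}: {exc}") from exc
                quality = mesh_quality(mesh)
                ligament = LigamentSpec(
                    total_rigidity=config.ligament_rigidity,
                    strand_count=config.strand_count,
                    topology="direct" if variant == "fused" else "serial",
                )
                boundary = default_boundary(mesh)
                boundary.foundation_stiffness = {
                    k: config.foundation_stiffness
                    for k in boundary.foundation_stiffness
                }
                for angle in config.angles:
                    combo = f"{species}/{variant}/{angle:g}deg"
                    t0 = time.perf_counter()
                    try:
                        lc = make_load_case(
                            mass,
                            fraction=config.load_fraction,
                            tilt_deg=angle,
                            partition_rule=config.partition_rule,
                            tilt_axis=config.tilt_axis,
                        )
                        system = assemble_model(
                            mesh, config.materials, ligament, boundary, lc
                        )
                        reduced = solver.apply_constraints(system)
                        sol = solver.solve_linear(reduced)
                        fld = recover_stress(mesh, config.materials, sol.u)
                        summ = stress_summary(fld)
                    except Exception as exc:
                        raise StudyError(f"solve failed for {combo}: {exc}") from exc
                    equil = solver.equilibrium_gap(system, sol)
                    diagnostics.append(
                        dict(
                            combo=combo, n_dofs=system.n_dofs,
                            n_reduced=reduced.K.shape[0],
                            n_ties=len(system.ties),
                            residual=sol.residual, equilibrium_gap=equil,
                            volume_cv=quality.volume_cv,
                            quasi_ideal=quality.quasi_ideal,
                            seconds=time.perf_counter() - t0,
                        )
                    )
                    log.info(
                        "%s: %d DOFs, residual %.2e, equilibrium %.2e, %.1fs",
                        combo, system.n_dofs, sol.residual, equil,
                        time.perf_counter() - t0,
                    )
                    for body, s in summ.items():
                        rows.append(
                            dict(
                                species=species, variant=variant,
                                angle_deg=angle, body=body,
                                mwam=s.mwam, mwm=s.mwm, median=s.median,
                                q25=s.q25, q75=s.q75, min=s.min, max=s.max,
                                n_elements=s.n_elements,
                                total_weight=s.total_weight,
                                mass_kg=mass, force_N=lc.force,
                            )
                        )
                    if outdir and config.write_fields:
                        name = (
                            f"{species.replace(' ', '_').replace('.', '')}"
                            f"_{variant}_{angle:g}deg.vtu"
                        )
                        export_fields(mesh, fld, summ, outdir / name)
    except StudyError:
        if outdir:
            (outdir / "STALE").write_text(
                "run aborted; partial outputs are stale\n"
            )
        raise
    finally:
        if fh is not None:
            log.removeHandler(fh)
            fh.close()

    results = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    samples = results.rename(columns={"body": "bone"})[
        ["species", "bone", "variant", "angle_deg", "mwam"]
    ]
    comparisons = []
    # the Welch test needs >= 2 species per group and the pooled
    # normality check >= 3 values; single-species runs skip inference
    if {"fused", "unfused"} <= set(config.variants) and len(config.species) >= 2:
        for angle in config.angles:
            for bone in ("scaphoid", "capitate"):
                comparisons.append(
                    compare_fused_unfused(samples, bone, angle_deg=angle)
                )

    report = StudyReport(
        results=results,
        comparisons=comparisons,
        config=config,
        config_hash=config.config_hash(),
        diagnostics=diagnostics,
    )
    if outdir:
        results.to_csv(outdir / "summaries.csv", index=False)
        report.comparison_frame().to_csv(outdir / "comparisons.csv", index=False)
        (outdir / "config.resolved.yaml").write_text(
            yaml.safe_dump(config.resolved_dict(), sort_keys=True)
        )
        stale = outdir / "STALE"
        if stale.exists():
            stale.unlink()
    return report


def sensitivity_compare(
    report: StudyReport, angle_a: float, angle_b: float
) -> Dict[str, Tuple[float, float, float]]:
    """Welch test of pooled per-bone MWAM samples between two load angles.

    Pools both variants at each angle (n = species x variants per group)
    and returns ``{bone: (t, df, p)}`` for the bones present in both
    variants.
    """
    res = report.results
    present = set(np.round(res["angle_deg"].unique(), 9))
    for angle in (angle_a, angle_b):
        if angle not in present:
            raise StudyError(f"angle {angle} missing from the report")
    out: Dict[str, Tuple[float, float, float]] = {}
    for bone in ("scaphoid", "capitate"):
        a = res[(res["body"] == bone) & (res["angle_deg"] == angle_a)]["mwam"]
        b = res[(res["body"] == bone) & (res["angle_deg"] == angle_b)]["mwam"]
        out[bone] = welch_t(a.to_numpy(), b.to_numpy())
    return out


# ---------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------


def load_config(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file; the seed is mandatory."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    geo_kwargs = raw.pop("geometry", {})
    if "seed" not in geo_kwargs and "seed" not in raw:
        raise StudyError("config must set a seed (top-level or geometry.seed)")
    mat_kwargs = raw.pop("materials", {})
    lig = raw.pop("ligaments", {})
    bnd = raw.pop("boundary", {})
    load = raw.pop("load", {})
    cfg_kwargs = dict(raw)
    seed = cfg_kwargs.pop("seed", geo_kwargs.get("seed", 0))
    geo_kwargs.setdefault("seed", seed)
    if "semi_axes" in geo_kwargs:  # nested form {bone: [a, b, c]}
        sa = geo_kwargs.pop("semi_axes")
        for bone in ("capitate", "scaphoid", "centrale"):
            if bone in sa:
                geo_kwargs[f"{bone}_semi_axes"] = tuple(sa[bone])
    cfg = StudyConfig(
        geometry=GeometryParams(**geo_kwargs),
        materials=MaterialSet(**mat_kwargs),
        ligament_rigidity=lig.get("total_rigidity", 40.0),
        strand_count=lig.get("strand_count", 8),
        foundation_stiffness=bnd.get("foundation_stiffness", 20.5),
        load_fraction=load.get("fraction", 0.2),
        partition_rule=load.get("partition_rule", "area"),
        tilt_axis=load.get("tilt_axis", "y"),
        seed=int(seed),
        **{
            k: v
            for k, v in cfg_kwargs.items()
            if k in (
                "species", "variants", "angles", "isometric_scaling",
                "reference_mass", "output_dir", "write_fields",
            )
        },
    )
    if isinstance(cfg.variants, list):
        cfg.variants = tuple(cfg.variants)
    if isinstance(cfg.angles, list):
        cfg.angles = tuple(float(a) for a in cfg.angles)
    cfg.validate()
    return cfg
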