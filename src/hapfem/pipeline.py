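"""Orchestration of the five-scenario, two-phase insert study.

``run_study`` executes, for each requested scenario, the loading protocol:
cavity scenarios get phase 1 (polymerization-shrinkage analog) followed by
phase 2 (shrinkage plus the 2 kN occlusal force in one linear solve);
the healthy tooth gets a mechanical-only solve.  Region statistics,
contraction rates and control-vs-insert percent-decrease pairs are
collected into a :class:`~hapfem.postprocess.StudyReport`.  Everything is
deterministic: identical configs yield byte-identical JSON reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import postprocess as post
from .elasticity import LoadSpec, Phase, run_phases
from .geometry import SCENARIO_IDS, ToothDims, build_scenario
from .materials import (
    DEFAULT_DELTA_T,
    DEFAULT_SHRINKAGE,
    MaterialRecord,
    MaterialTable,
    default_material_table,
)
from .geometry import RegionLabel
from .meshing import generate_mesh, jacobian_quality
from .postprocess import GROUPS, StudyReport
from .vtkio import write_vtk

__all__ = ["StudyConfig", "run_study", "load_config"]

log = logging.getLogger("hapfem")

#: (control, insert) scenario pairs sharing identical cavity dimensions.
PAIRS = (("small_c", "small_ic"), ("big_c", "big_ic"))


@dataclass
class StudyConfig:
    """All knobs of one study run; defaults reproduce the study conditions."""

    scenarios: Sequence[str] = SCENARIO_IDS
    h: float = 0.6                      # mm, uniform mesh size
    S_target: float = DEFAULT_SHRINKAGE  # composite volumetric shrinkage
    delta_T: float = DEFAULT_DELTA_T     # degC cooling of the analog
    F_total: float = 2000.0              # N occlusal force
    support_mode: str = "full"           # "full" (bone lateral) or "simple" (base)
    tissue_expansion: bool = False
    dims_overrides: Dict[str, object] = field(default_factory=dict)
    material_overrides: Dict[str, Dict[str, float]] = field(default_factory=dict)
    outdir: Optional[str] = None
    export_vtk: bool = False

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")
        unknown = [s for s in self.scenarios if s not in SCENARIO_IDS]
        if unknown:
            raise ValueError(f"unknown scenarios: {unknown}")
        if self.h <= 0:
            raise ValueError("mesh size h must be positive")
        if not 0.0 < self.S_target < 1.0:
            raise ValueError("S_target must lie in (0, 1)")
        if self.support_mode not in ("full", "simple"):
            raise ValueError("support_mode must be 'full' or 'simple'")

    def dims(self) -> ToothDims:
        overrides = dict(self.dims_overrides)
        for key in ("pulp_semi_axes", "pulp_z_range", "bone_block"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        return ToothDims(**overrides)

    def materials(self) -> MaterialTable:
        table = default_material_table(
            S_target=self.S_target,
            delta_T=self.delta_T,
            tissue_expansion=self.tissue_expansion,
        )
        for region_name, fields in self.material_overrides.items():
            table = table.with_override(RegionLabel[region_name.upper()], **fields)
        return table

    @property
    def support_set(self) -> str:
        return "fixed_support" if self.support_mode == "full" else "base"


def load_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML (or JSON) file."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return StudyConfig(**data)


def _scenario_phases(scenario_id: str) -> List[Phase]:
    if scenario_id == "healthy":
        return [Phase.MECHANICAL_ONLY]
    return [Phase.PHASE1_THERMAL, Phase.PHASE2_THERMAL_PLUS_OCCLUSAL]


def run_study(config: StudyConfig) -> StudyReport:
    """Run the configured scenarios and assemble the full study report.

    A failure in one scenario is recorded in ``report.failures`` and does
    not abort the others.
    """
    report = StudyReport(config=dataclasses.asdict(config))
    report.config["scenarios"] = list(config.scenarios)
    materials = config.materials()
    solutions: Dict[str, Dict[str, object]] = {}
    meshes = {}
    geoms = {}

    for sid in config.scenarios:
        try:
            geom = build_scenario(sid, config.dims())
            mesh = generate_mesh(geom, config.h)
            quality = jacobian_quality(mesh)
            log.info(
                "scenario %s: %d nodes, %d elements, %d with Q>0.7",
                sid, mesh.n_nodes, mesh.n_elements, quality.n_above_07,
            )
            report.mesh_info[sid] = {
                "n_nodes": mesh.n_nodes,
                "n_elements": mesh.n_elements,
                "n_quality_above_0.7": quality.n_above_07,
                "region_counts": {k.name: v for k, v in mesh.region_counts().items()},
                "total_volume_mm3": float(quality.volumes.sum()),
            }
            geoms[sid], meshes[sid] = geom, mesh
            solutions[sid] = {}
            report.stats[sid] = {}
            phases = _scenario_phases(sid)
            sols = run_phases(
                mesh,
                materials,
                [LoadSpec(phase=p, F_total=config.F_total) for p in phases],
                support=config.support_set,
            )
            for phase, sol in zip(phases, sols):
                solutions[sid][phase.value] = sol
                report.stats[sid][phase.value] = {}
                for group in GROUPS:
                    try:
                        st = post.region_stats(mesh, sol, group)
                        report.stats[sid][phase.value][group] = dataclasses.asdict(st)
                    except post.EmptyGroupError:
                        pass  # e.g. restoration group in the healthy tooth
                if phase is Phase.PHASE1_THERMAL:
                    cr = post.contraction_rate(mesh, sol.u)
                    report.contraction[sid] = dataclasses.asdict(cr)
                if config.export_vtk and config.outdir:
                    _export(config, sid, phase, mesh, sol)
        except Exception as exc:  # noqa: BLE001 - study-level fault barrier
            log.exception("scenario %s failed", sid)
            report.failures[sid] = f"{type(exc).__name__}: {exc}"
            solutions.pop(sid, None)

    _compare_pairs(report, config, geoms, meshes, solutions)
    if config.outdir:
        post.write_report(report, config.outdir)
    return report


def _compare_pairs(report, config, geoms, meshes, solutions) -> None:
    for control, insert in PAIRS:
        if control not in solutions or insert not in solutions:
            continue
        pair = f"{control}_vs_{insert}"
        for phase in (Phase.PHASE1_THERMAL, Phase.PHASE2_THERMAL_PLUS_OCCLUSAL):
            pv = phase.value
            for group in GROUPS:
                sc = report.stats[control].get(pv, {}).get(group)
                si = report.stats[insert].get(pv, {}).get(group)
                if not sc or not si:
                    continue
                for quantity, key in (("max_vm", "max"), ("max_displacement", "max_displacement")):
                    pd_ = post.percent_decrease(sc[key], si[key])
                    report.comparisons.append(
                        {
                            "pair": pair,
                            "phase": pv,
                            "group": group,
                            "quantity": quantity,
                            "control": sc[key],
                            "insert": si[key],
                            "percent_decrease": pd_,
                            "flagged_increase": bool(pd_ < 0),
                        }
                    )
        # near-floor dentin stress after phase 2 (cavity-bottom relocation)
        p2 = Phase.PHASE2_THERMAL_PLUS_OCCLUSAL.value
        if p2 in solutions.get(control, {}) and p2 in solutions.get(insert, {}):
            try:
                nf_c = post.near_floor_stress(meshes[control], solutions[control][p2], geoms[control])
                nf_i = post.near_floor_stress(meshes[insert], solutions[insert][p2], geoms[insert])
                report.comparisons.append(
                    {
                        "pair": pair,
                        "phase": p2,
                        "group": "dentin_near_cavity_floor",
                        "quantity": "mean_vm_within_0.5mm",
                        "control": nf_c,
                        "insert": nf_i,
                        "percent_decrease": post.percent_decrease(nf_c, nf_i),
                        "flagged_increase": bool(nf_i > nf_c),
                    }
                )
            except post.EmptyGroupError:
                log.warning("near-floor band empty for pair %s", pair)


def _export(config, sid, phase, mesh, sol) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    point_data = {"displacement": sol.u}
    if sol.temperature is not None:
        point_data["temperature"] = sol.temperature
    write_vtk(
        outdir / f"{sid}_{phase.value}.vtk",
        mesh,
        point_data=point_data,
        cell_data={"von_mises": sol.vm, "stress_voigt": sol.stress},
    )
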