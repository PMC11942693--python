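"""Reduction of solution fields to the study's reported quantities.

Outputs mirror the study's reporting: per-region-group maxima of von Mises
stress, descriptive statistics over all elements of a group, maximum
displacement magnitudes, the volumetric contraction rate of the restoration
after the shrinkage phase, and percent-decrease comparisons between
composite-only controls and insert scenarios.

Region groups: ``enamel``, ``dentin`` and ``restoration`` (the union of
composite, cement and insert, since the study reports a single restoration
row).  Maxima are taken over per-element constant stresses, never over
extrapolated nodal values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .geometry import GeometrySpec, RegionLabel, RESTORATION_LABELS
from .elasticity import SolutionFields
from .meshing import Mesh

__all__ = [
    "GROUPS",
    "RegionStats",
    "ContractionResult",
    "StudyReport",
    "EmptyGroupError",
    "region_stats",
    "contraction_rate",
    "percent_decrease",
    "near_floor_stress",
    "write_report",
]

GROUPS: Dict[str, tuple] = {
    "enamel": (RegionLabel.ENAMEL,),
    "dentin": (RegionLabel.DENTIN,),
    "restoration": RESTORATION_LABELS,
}


class EmptyGroupError(ValueError):
    pass


@dataclass
class RegionStats:
    group: str
    n_elements: int
    average: float
    stdev: float
    q1: float
    median: float
    q3: float
    max: float
    max_displacement: float  # mm, over nodes of the group's elements


@dataclass
class ContractionResult:
    V0: float                      # mm^3 undeformed
    V1: float                      # mm^3 deformed
    rate_percent: float            # 100 (V0 - V1)/V0
    rate_percent_cylinder_fit: Optional[float] = None


@dataclass
class StudyReport:
    """Full numeric payload of a multi-scenario, multi-phase run."""

    config: Dict = field(default_factory=dict)
    # scenario -> phase -> group -> RegionStats-as-dict
    stats: Dict[str, Dict[str, Dict[str, Dict]]] = field(default_factory=dict)
    contraction: Dict[str, Dict] = field(default_factory=dict)
    # comparisons: list of dicts with pair/phase/group/quantity/percent_decrease
    comparisons: List[Dict] = field(default_factory=list)
    mesh_info: Dict[str, Dict] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)


def region_stats(mesh: Mesh, fields: SolutionFields, group: str) -> RegionStats:
    """Descriptive statistics of element von Mises stress for one group.

    Unweighted over elements ("for all elements"); quartiles by linear
    interpolation between order statistics.  Displacement is the max
    Euclidean norm over the nodes touching the group's elements.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    els = mesh.elements_of(*GROUPS[group])
    if els.size == 0:
        raise EmptyGroupError(f"group {group!r} has no elements in this scenario")
    vm = fields.vm[els]
    nodes = np.unique(mesh.tets[els])
    disp = float(np.linalg.norm(fields.u[nodes], axis=1).max())
    q1, med, q3 = np.percentile(vm, [25, 50, 75])
    return RegionStats(
        group=group,
        n_elements=int(els.size),
        average=float(vm.mean()),
        stdev=float(vm.std(ddof=1)) if els.size > 1 else 0.0,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(vm.max()),
        max_displacement=disp,
    )


def _deformed_volume(nodes: np.ndarray, tets: np.ndarray, u: np.ndarray) -> float:
    p = (nodes + u)[tets]
    e = p[:, 1:, :] - p[:, :1, :]
    return float(
        np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])).sum() / 6.0
    )


def contraction_rate(
    mesh: Mesh,
    u: np.ndarray,
    labels=RESTORATION_LABELS,
    cylinder_fit: bool = True,
) -> ContractionResult:
    """Volumetric contraction of the restoration from the phase-1 solution.

    Default method: exact pre/post tetrahedron volumes of the restoration
    elements with deformed node positions x + u.  The optional
    ``cylinder_fit`` method mirrors the study's description — approximate
    the restoration as a cylinder, shift its mean radius by the mean radial
    displacement of its lateral-surface nodes and its height by the mean
    axial displacements of top and bottom nodes, and compare pi r^2 h
    before/after.
    """
    els = mesh.elements_of(*labels)
    if els.size == 0:
        raise EmptyGroupError("no restoration elements in this mesh")
    tets = mesh.tets[els]
    e = mesh.nodes[tets][:, 1:, :] - mesh.nodes[tets][:, :1, :]
    V0 = float(np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2])).sum() / 6.0)
    V1 = _deformed_volume(mesh.nodes, tets, u)
    rate = 100.0 * (V0 - V1) / V0
    result = ContractionResult(V0=V0, V1=V1, rate_percent=rate)
    if cylinder_fit:
        result.rate_percent_cylinder_fit = _cylinder_fit_rate(mesh, u, tets)
    return result


def _cylinder_fit_rate(mesh: Mesh, u: np.ndarray, tets: np.ndarray) -> float:
    nodes = np.unique(tets)
    x = mesh.nodes[nodes]
    ux = u[nodes]
    r = np.hypot(x[:, 0] - x[:, 0].mean(), x[:, 1] - x[:, 1].mean())
    z = x[:, 2]
    tol = 1e-9
    lateral = r >= r.max() - tol
    top = z >= z.max() - tol
    bottom = z <= z.min() + tol
    er = np.column_stack([x[:, 0] - x[:, 0].mean(), x[:, 1] - x[:, 1].mean()])
    er = er / np.maximum(np.linalg.norm(er, axis=1, keepdims=True), 1e-30)
    u_r = np.einsum("ij,ij->i", ux[:, :2], er)
    r0 = r[lateral].mean()
    r1 = r0 + u_r[lateral].mean()
    h0 = z[top].mean() - z[bottom].mean()
    h1 = h0 + ux[top, 2].mean() - ux[bottom, 2].mean()
    return 100.0 * (1.0 - (r1**2 * h1) / (r0**2 * h0))


def percent_decrease(control_value: float, insert_value: float) -> float:
    """Signed decrease 100 (control - insert)/control; negative = increase."""
    if control_value <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * (control_value - insert_value) / control_value


def near_floor_stress(
    mesh: Mesh,
    fields: SolutionFields,
    geom: GeometrySpec,
    distance: float = 0.5,
) -> float:
    """Mean dentin von Mises stress within ``distance`` mm below the cavity floor.

    Element membership is by centroid: dentin elements whose centroid lies
    under the cavity footprint (radius = cavity radius) within the band
    [floor - distance, floor].
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    floor_z = geom.cavity_floor_z  # raises for healthy
    cav_r = geom.dims.cavity_diameter / 2.0
    cen = mesh.element_centroids()
    r2 = cen[:, 0] ** 2 + cen[:, 1] ** 2
    sel = (
        (mesh.region == int(RegionLabel.DENTIN))
        & (cen[:, 2] >= floor_z - distance)
        & (cen[:, 2] <= floor_z)
        & (r2 <= cav_r**2)
    )
    if not np.any(sel):
        raise EmptyGroupError(
            f"no dentin elements within {distance} mm below the cavity floor"
        )
    return float(fields.vm[sel].mean())


# ---------------------------------------------------------------------------
# report serialization


def _stats_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for scen, phases in report.stats.items():
        for phase, groups in phases.items():
            for group, st in groups.items():
                rows.append({"scenario": scen, "phase": phase, **st})
    cols = [
        "scenario", "phase", "group", "n_elements", "average", "stdev",
        "q1", "median", "q3", "max", "max_displacement",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_report(report: StudyReport, outdir) -> List[Path]:
    """Write the JSON payload and the four CSV tables; returns paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(asdict(report), indent=2, sort_keys=True))
    written.append(jpath)

    df = _stats_frame(report)
    p = outdir / "descriptive_stats.csv"
    df.to_csv(p, index=False)
    written.append(p)

    maxima = df[["scenario", "phase", "group", "max"]].rename(columns={"max": "max_vm_mpa"}) if len(df) else pd.DataFrame(columns=["scenario", "phase", "group", "max_vm_mpa"])
    p = outdir / "stress_maxima.csv"
    maxima.to_csv(p, index=False)
    written.append(p)

    disp = df[["scenario", "phase", "group", "max_displacement"]].rename(columns={"max_displacement": "max_displacement_mm"}) if len(df) else pd.DataFrame(columns=["scenario", "phase", "group", "max_displacement_mm"])
    p = outdir / "displacement.csv"
    disp.to_csv(p, index=False)
    written.append(p)

    comp = pd.DataFrame(
        report.comparisons,
        columns=["pair", "phase", "group", "quantity", "control", "insert", "percent_decrease", "flagged_increase"],
    )
    p = outdir / "percent_decrease.csv"
    comp.to_csv(p, index=False)
    written.append(p)
    return written
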