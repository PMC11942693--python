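"""Parametric restored-tooth geometry as a point classifier.

The study geometry is an idealized lower first molar: an elliptic-cylinder
tooth (enamel cap over a dentin body with a pulp chamber), wrapped below the
crown by a thin periodontal-ligament (PDL) shell and embedded in a
rectangular alveolar-bone block.  A Class-I-like cavity is an axis-centered
vertical cylinder opened from the occlusal surface; it is filled either with
composite alone ("C" scenarios) or with a stack of hydroxyapatite insert,
luting cement and a composite cap ("I+C" scenarios).

Every dimension is an explicit parameter (mm), so each of the five study
scenarios — healthy, small_c, small_ic, big_c, big_ic — is fully
reproducible from numbers alone.  Coordinates: z vertical, origin on the
root-apex plane, occlusal plane at z = height; the tooth axis is the z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "RegionLabel",
    "ToothDims",
    "ScenarioSpec",
    "GeometrySpec",
    "InvalidGeometryError",
    "OutOfDomainError",
    "SCENARIO_IDS",
    "build_scenario",
    "classify_point",
    "classify_points",
    "expected_region_volumes",
    "monte_carlo_region_volumes",
]

SCENARIO_IDS = ("healthy", "small_c", "small_ic", "big_c", "big_ic")


class RegionLabel(IntEnum):
    """Material region of a point; every domain point has exactly one."""

    ENAMEL = 0
    DENTIN = 1
    PULP = 2
    PDL = 3
    BONE = 4
    COMPOSITE = 5
    CEMENT = 6
    INSERT = 7


#: Regions forming the restoration stack.
RESTORATION_LABELS = (RegionLabel.COMPOSITE, RegionLabel.CEMENT, RegionLabel.INSERT)


class InvalidGeometryError(ValueError):
    """Raised when tooth dimensions produce an impossible geometry."""


class OutOfDomainError(ValueError):
    """Raised when a query point lies outside the model bounding box."""


@dataclass(frozen=True)
class ToothDims:
    """All linear dimensions of the synthetic tooth model, in mm.

    Defaults follow the study model: 21 mm tooth height, 10 mm
    vestibulo-oral and 11 mm mesio-distal width, a 5.5 mm diameter
    cylindrical cavity, 4.7 mm diameter inserts of 1.7 mm (small) or
    4.7 mm (big) thickness, a 0.5 mm cement floor and a 2.0 mm composite
    cap.  The lateral cement thickness is the radial gap
    (5.5 - 4.7)/2 = 0.4 mm implied by the cavity and insert diameters.
    """

    height: float = 21.0
    vo_width: float = 10.0
    md_width: float = 11.0
    crown_height: float = 8.0
    enamel_occlusal_thickness: float = 2.5
    enamel_lateral_thickness: float = 1.5
    pulp_semi_axes: Tuple[float, float] = (1.5, 1.8)
    pulp_z_range: Tuple[float, float] = (2.0, 12.0)
    cavity_diameter: float = 5.5
    insert_diameter: float = 4.7
    insert_thickness: float = 1.7
    cement_floor_thickness: float = 0.5
    composite_cap_thickness: float = 2.0
    bone_block: Tuple[float, float, float] = (16.0, 17.0, 14.0)
    pdl_thickness: float = 0.25

    def __post_init__(self) -> None:
        scalars = (
            self.height,
            self.vo_width,
            self.md_width,
            self.crown_height,
            self.enamel_occlusal_thickness,
            self.enamel_lateral_thickness,
            self.cavity_diameter,
            self.insert_diameter,
            self.insert_thickness,
            self.cement_floor_thickness,
            self.pdl_thickness,
            *self.pulp_semi_axes,
            *self.bone_block,
        )
        if any(v <= 0 for v in scalars):
            raise InvalidGeometryError("all tooth dimensions must be strictly positive")
        if self.composite_cap_thickness < 0:
            raise InvalidGeometryError("composite cap thickness must be non-negative")
        if self.cavity_diameter >= min(self.vo_width, self.md_width):
            raise InvalidGeometryError("cavity diameter must be smaller than the tooth")
        if self.insert_diameter >= self.cavity_diameter:
            raise InvalidGeometryError("insert must fit inside the cavity")
        if not self.pulp_z_range[0] < self.pulp_z_range[1] < self.height:
            raise InvalidGeometryError("pulp chamber must lie inside the tooth")

    @property
    def cavity_depth(self) -> float:
        """Cavity depth from the occlusal surface (cap + cement floor + insert)."""
        return (
            self.composite_cap_thickness
            + self.cement_floor_thickness
            + self.insert_thickness
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the five study scenarios together with its dimensions."""

    scenario_id: str
    dims: ToothDims

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario {self.scenario_id!r}; expected one of {SCENARIO_IDS}"
            )

    @property
    def has_cavity(self) -> bool:
        return self.scenario_id != "healthy"

    @property
    def has_insert(self) -> bool:
        return self.scenario_id.endswith("_ic")

    @property
    def cavity_depth(self) -> float:
        return self.dims.cavity_depth if self.has_cavity else 0.0


@dataclass(frozen=True)
class GeometrySpec:
    """A scenario bound to a concrete bounding box and classification rules."""

    scenario: ScenarioSpec
    bbox_min: Tuple[float, float, float] = field(init=False)
    bbox_max: Tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        bx, by, bz = self.scenario.dims.bone_block
        object.__setattr__(self, "bbox_min", (-bx / 2.0, -by / 2.0, 0.0))
        object.__setattr__(
            self, "bbox_max", (bx / 2.0, by / 2.0, self.scenario.dims.height)
        )

    # -- convenience accessors -------------------------------------------------
    @property
    def dims(self) -> ToothDims:
        return self.scenario.dims

    @property
    def cavity_floor_z(self) -> float:
        """z of the cavity floor (occlusal surface minus cavity depth)."""
        d = self.dims
        if not self.scenario.has_cavity:
            raise InvalidGeometryError("healthy scenario has no cavity")
        return d.height - d.cavity_depth

    @property
    def bone_top_z(self) -> float:
        return self.scenario.dims.bone_block[2]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lo = np.asarray(self.bbox_min)
        hi = np.asarray(self.bbox_max)
        return np.all((pts >= lo - 1e-12) & (pts <= hi + 1e-12), axis=1)


def _validate_cavity(spec: ScenarioSpec) -> None:
    d = spec.dims
    if not spec.has_cavity:
        return
    if d.cavity_depth >= d.height - 1.0:
        raise InvalidGeometryError(
            f"cavity depth {d.cavity_depth} mm leaves less than 1 mm of tooth"
        )
    floor_z = d.height - d.cavity_depth
    pulp_top = d.pulp_z_range[1]
    # Cavity cylinder and pulp ellipse always overlap radially on the axis,
    # so non-intersection reduces to the floor staying above the pulp roof.
    if floor_z < pulp_top:
        raise InvalidGeometryError(
            f"cavity floor (z={floor_z} mm) penetrates the pulp chamber "
            f"(roof at z={pulp_top} mm)"
        )


def build_scenario(scenario_id: str, dims: Optional[ToothDims] = None) -> GeometrySpec:
    """Build the classifier for one scenario.

    For the "small" scenarios the default insert thickness (1.7 mm) applies;
    "big" scenarios use a 4.7 mm insert unless ``dims`` overrides it.  The
    insert thickness sets the cavity depth for the paired composite-only
    control, so ``small_c``/``small_ic`` and ``big_c``/``big_ic`` share
    identical cavities.
    """
    if dims is None:
        dims = ToothDims()
    if scenario_id.startswith("big") and dims.insert_thickness == 1.7:
        dims = replace(dims, insert_thickness=4.7)
    spec = ScenarioSpec(scenario_id=scenario_id, dims=dims)
    _validate_cavity(spec)
    return GeometrySpec(scenario=spec)


def classify_points(geom: GeometrySpec, pts: np.ndarray) -> np.ndarray:
    """Vectorized classification; returns int array, -1 for void points.

    Void means inside the bounding box but outside every material region
    (e.g. the air beside the crown, above the bone block).
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    d = geom.dims
    s = geom.scenario
    out = np.full(len(pts), -1, dtype=np.int64)

    a, b = d.vo_width / 2.0, d.md_width / 2.0
    in_tooth = ((x / a) ** 2 + (y / b) ** 2 <= 1.0) & (z >= 0.0) & (z <= d.height)

    r2 = x**2 + y**2
    cav_r = d.cavity_diameter / 2.0
    if s.has_cavity:
        floor_z = d.height - d.cavity_depth
        in_cavity = in_tooth & (r2 <= cav_r**2) & (z >= floor_z)
    else:
        in_cavity = np.zeros(len(pts), dtype=bool)

    # Priority 1-3: restoration stack inside the cavity cylinder.
    if s.has_cavity:
        if s.has_insert:
            ins_r = d.insert_diameter / 2.0
            ins_top = d.height - d.composite_cap_thickness
            ins_bot = ins_top - d.insert_thickness
            in_insert = in_cavity & (r2 <= ins_r**2) & (z >= ins_bot) & (z <= ins_top)
            # cement: lateral ring beside the insert plus the floor layer below
            in_cement = in_cavity & ~in_insert & (z <= ins_top)
            in_composite = in_cavity & ~in_insert & ~in_cement
            out[in_insert] = RegionLabel.INSERT
            out[in_cement] = RegionLabel.CEMENT
            out[in_composite] = RegionLabel.COMPOSITE
        else:
            out[in_cavity] = RegionLabel.COMPOSITE

    # Priority 4: pulp chamber (inner elliptic cylinder).
    pa, pb = d.pulp_semi_axes
    z0, z1 = d.pulp_z_range
    in_pulp = (
        in_tooth
        & ~in_cavity
        & ((x / pa) ** 2 + (y / pb) ** 2 <= 1.0)
        & (z >= z0)
        & (z <= z1)
    )
    out[in_pulp] = RegionLabel.PULP

    # Priority 5: enamel crown shell.
    crown = in_tooth & ~in_cavity & ~in_pulp & (z >= d.height - d.crown_height)
    t = d.enamel_lateral_thickness
    lateral_shell = (x / (a - t)) ** 2 + (y / (b - t)) ** 2 >= 1.0
    occlusal_cap = z >= d.height - d.enamel_occlusal_thickness
    in_enamel = crown & (lateral_shell | occlusal_cap)
    out[in_enamel] = RegionLabel.ENAMEL

    # Priority 6: dentin = rest of the tooth.
    in_dentin = in_tooth & ~in_cavity & ~in_pulp & ~in_enamel
    out[in_dentin] = RegionLabel.DENTIN

    # Priority 7: PDL shell around the root (below the crown).
    p = d.pdl_thickness
    below_crown = (z >= 0.0) & (z < d.height - d.crown_height)
    in_pdl = (
        ~in_tooth
        & below_crown
        & ((x / (a + p)) ** 2 + (y / (b + p)) ** 2 <= 1.0)
    )
    out[in_pdl] = RegionLabel.PDL

    # Priority 8: bone block remainder.
    bx, by, bz = d.bone_block
    in_bone = (
        (out == -1)
        & (np.abs(x) <= bx / 2.0)
        & (np.abs(y) <= by / 2.0)
        & (z >= 0.0)
        & (z <= bz)
        & ~in_tooth
        & ~in_pdl
    )
    out[in_bone] = RegionLabel.BONE
    return out


def classify_point(geom: GeometrySpec, point) -> Optional[RegionLabel]:
    """Classify a single point; ``None`` for void points inside the box."""
    pt = np.asarray(point, dtype=float).reshape(1, 3)
    if not geom.contains(pt)[0]:
        raise OutOfDomainError(f"point {point} outside bounding box")
    code = classify_points(geom, pt)[0]
    return None if code < 0 else RegionLabel(code)


def expected_region_volumes(geom: GeometrySpec) -> Dict[RegionLabel, float]:
    """Closed-form volumes (mm^3) of the cylindrical restoration components.

    Tissue-region volumes have no simple closed form once the cavity and
    shells intersect; use :func:`monte_carlo_region_volumes` for those.
    """
    d = geom.dims
    s = geom.scenario
    vols = {lab: 0.0 for lab in RESTORATION_LABELS}
    if not s.has_cavity:
        return vols
    cav_area = np.pi * (d.cavity_diameter / 2.0) ** 2
    if s.has_insert:
        ins_area = np.pi * (d.insert_diameter / 2.0) ** 2
        vols[RegionLabel.INSERT] = ins_area * d.insert_thickness
        vols[RegionLabel.CEMENT] = (
            (cav_area - ins_area) * d.insert_thickness
            + cav_area * d.cement_floor_thickness
        )
        vols[RegionLabel.COMPOSITE] = cav_area * d.composite_cap_thickness
    else:
        vols[RegionLabel.COMPOSITE] = cav_area * d.cavity_depth
    return vols


def monte_carlo_region_volumes(
    geom: GeometrySpec, n_samples: int = 200_000, seed: int = 0
) -> Dict[RegionLabel, Tuple[float, float]]:
    """Monte-Carlo region volumes with standard errors, as (volume, se) mm^3."""
    rng = np.random.default_rng(seed)
    lo = np.asarray(geom.bbox_min)
    hi = np.asarray(geom.bbox_max)
    box_vol = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    codes = classify_points(geom, pts)
    result: Dict[RegionLabel, Tuple[float, float]] = {}
    for lab in RegionLabel:
        p = float(np.mean(codes == int(lab)))
        se = box_vol * np.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
        result[lab] = (box_vol * p, se)
    return result
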