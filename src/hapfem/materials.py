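"""Per-region constitutive constants and the shrinkage-analog calibration.

Elastic constants follow the study's material table (MPa):

=========  ========  ====
Region     E (MPa)   nu
=========  ========  ====
PULP           6.8   0.45
DENTIN      18600    0.31
ENAMEL      84100    0.30
BONE         1370    0.30
CEMENT       4000    0.35
COMPOSITE   16600    0.24
INSERT     100000    0.28  (sintered hydroxyapatite, modeled solid)
PDL            50    0.45  (literature-typical soft record; no printed value)
=========  ========  ====

Polymerization contraction is emulated by cooling the polymerizing
materials (composite and cement) by ``delta_T`` with a linear expansion
coefficient ``alpha`` calibrated so free shrinkage reproduces a target
volumetric contraction S: ``(1 + alpha*dT)^3 = 1 - S``.  Tissues default to
``alpha = 0`` so only the analog produces strain; literature coefficients
(enamel 11.4e-6, dentin 8e-6, insert 13.3e-6 per degC) are available as an
opt-in mode.  Thermal conductivity only enters through ratios under the
all-Dirichlet boundary conditions used here, so it defaults to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict

import numpy as np

from .geometry import RegionLabel

__all__ = [
    "MaterialRecord",
    "MaterialTable",
    "SingularMaterialError",
    "default_material_table",
    "calibrate_alpha",
    "elasticity_tensor",
    "DEFAULT_SHRINKAGE",
    "DEFAULT_DELTA_T",
]

#: Default target volumetric shrinkage of the composite (fraction).
DEFAULT_SHRINKAGE = 0.037
#: Temperature drop of the analog: 36 degC body reference -> 10 degC cured.
DEFAULT_DELTA_T = 26.0


class SingularMaterialError(ValueError):
    pass


@dataclass(frozen=True)
class MaterialRecord:
    """Isotropic linear-elastic record: E (MPa), nu, alpha (1/degC), k."""

    E: float
    nu: float
    alpha: float = 0.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise SingularMaterialError(f"Poisson ratio {self.nu} outside [0, 0.5)")
        if self.alpha < 0:
            raise ValueError("expansion coefficient must be non-negative")
        if self.k <= 0:
            raise ValueError("conductivity must be positive")


@dataclass(frozen=True)
class MaterialTable:
    records: Dict[RegionLabel, MaterialRecord]
    T_ref: float = 36.0

    def __post_init__(self) -> None:
        missing = [lab.name for lab in RegionLabel if lab not in self.records]
        if missing:
            raise ValueError(f"material table missing regions: {missing}")

    def __getitem__(self, label: RegionLabel) -> MaterialRecord:
        return self.records[label]

    def with_override(self, label: RegionLabel, **fields) -> "MaterialTable":
        recs = dict(self.records)
        recs[label] = replace(recs[label], **fields)
        return MaterialTable(records=recs, T_ref=self.T_ref)


def calibrate_alpha(S_target: float = DEFAULT_SHRINKAGE, delta_T: float = DEFAULT_DELTA_T) -> float:
    """Expansion coefficient reproducing volumetric shrinkage S under cooling.

    Inverts the free-shrinkage relation (1 + alpha*dT)^3 = 1 - S for a
    uniform temperature drop of ``delta_T`` (> 0): cooling by delta_T then
    contracts each linear dimension by alpha*delta_T.
    """
    if not 0.0 < S_target < 1.0:
        raise ValueError("shrinkage target must lie in (0, 1)")
    if delta_T <= 0:
        raise ValueError("delta_T must be positive")
    return (1.0 - (1.0 - S_target) ** (1.0 / 3.0)) / delta_T


def default_material_table(
    S_target: float = DEFAULT_SHRINKAGE,
    delta_T: float = DEFAULT_DELTA_T,
    tissue_expansion: bool = False,
) -> MaterialTable:
    """Study material table with the shrinkage analog calibrated in.

    ``tissue_expansion`` switches on literature thermal-expansion
    coefficients for enamel, dentin and the insert; by default they are 0 so
    the only thermal strain is the polymerization analog in composite and
    cement.
    """
    a = calibrate_alpha(S_target, delta_T)
    recs = {
        RegionLabel.PULP: MaterialRecord(E=6.8, nu=0.45),
        RegionLabel.DENTIN: MaterialRecord(E=18_600.0, nu=0.31),
        RegionLabel.ENAMEL: MaterialRecord(E=84_100.0, nu=0.30),
        RegionLabel.BONE: MaterialRecord(E=1_370.0, nu=0.30),
        RegionLabel.CEMENT: MaterialRecord(E=4_000.0, nu=0.35, alpha=a),
        RegionLabel.COMPOSITE: MaterialRecord(E=16_600.0, nu=0.24, alpha=a),
        RegionLabel.INSERT: MaterialRecord(E=100_000.0, nu=0.28),
        RegionLabel.PDL: MaterialRecord(E=50.0, nu=0.45),
    }
    if tissue_expansion:
        recs[RegionLabel.ENAMEL] = replace(recs[RegionLabel.ENAMEL], alpha=11.4e-6)
        recs[RegionLabel.DENTIN] = replace(recs[RegionLabel.DENTIN], alpha=8.0e-6)
        recs[RegionLabel.INSERT] = replace(recs[RegionLabel.INSERT], alpha=13.3e-6)
    return MaterialTable(records=recs, T_ref=36.0)


def elasticity_tensor(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic stiffness, Voigt order (xx, yy, zz, yz, xz, xy).

    Engineering-shear convention: shear diagonal entries are mu.
    """
    if nu >= 0.5:
        raise SingularMaterialError("nu >= 0.5 gives a singular stiffness")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.diag_indices(3)] = lam + 2.0 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C
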