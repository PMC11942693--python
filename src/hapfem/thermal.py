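"""Steady-state heat conduction driving the shrinkage analog.

The polymerization-contraction analog prescribes 10 degC on every node of
the shrinking materials (composite and cement), 36 degC on the external
model surface and on the insert, and solves Laplace's equation
div(k grad T) = 0 in between with linear tetrahedral elements.  The
resulting nodal field is purely Dirichlet-driven, so it is bounded by
[10, 36] (discrete maximum principle) and independent of a uniform scaling
of all conductivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import RegionLabel
from .materials import MaterialTable
from .meshing import Mesh, element_volumes

__all__ = [
    "ThermalBCs",
    "TemperatureField",
    "SingularSystemError",
    "default_bcs",
    "shape_gradients",
    "solve_temperature",
    "element_delta_T",
]

T_CURED = 10.0
T_BODY = 36.0


class SingularSystemError(RuntimeError):
    pass


@dataclass
class ThermalBCs:
    """Dirichlet data: node index -> prescribed temperature (degC)."""

    prescribed: Dict[int, float] = field(default_factory=dict)

    @property
    def node_index(self) -> np.ndarray:
        return np.fromiter(self.prescribed.keys(), dtype=np.int64, count=len(self.prescribed))

    @property
    def values(self) -> np.ndarray:
        return np.fromiter(self.prescribed.values(), dtype=float, count=len(self.prescribed))


@dataclass
class TemperatureField:
    values: np.ndarray  # per-node degC


def default_bcs(mesh: Mesh, T_cold: float = T_CURED, T_warm: float = T_BODY) -> ThermalBCs:
    """Study boundary conditions for one mesh.

    External surface and insert nodes are pinned at body temperature, every
    composite/cement node at the cured temperature.  At cement-insert (or
    cavity-wall) interface nodes the shrinking-material set wins, mirroring
    the prescription that *all* nodes of the shrinking materials are cooled.
    """
    bc: Dict[int, float] = {}
    for n in mesh.node_sets.get("external_surface", ()):
        bc[int(n)] = T_warm
    for n in mesh.node_sets.get("insert_nodes", ()):
        bc[int(n)] = T_warm
    for n in mesh.node_sets.get("composite_cement_nodes", ()):
        bc[int(n)] = T_cold  # shrinking materials override shared nodes
    return ThermalBCs(prescribed=bc)


def shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Constant shape-function gradients per element: (m, 4, 3), volumes (m,)."""
    p = nodes[tets]
    e = p[:, 1:, :] - p[:, :1, :]              # (m, 3, 3) edge matrix rows
    vol6 = np.einsum("ij,ij->i", e[:, 0], np.cross(e[:, 1], e[:, 2]))
    inv = np.linalg.inv(e)                     # columns are grads of N1..N3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g, vol6 / 6.0


def _conductance_matrix(mesh: Mesh, materials: MaterialTable) -> sp.csr_matrix:
    g, vol = shape_gradients(mesh.nodes, mesh.tets)
    k = np.empty(mesh.n_elements)
    for lab in RegionLabel:
        sel = mesh.region == int(lab)
        if np.any(sel):
            k[sel] = materials[lab].k
    ke = np.einsum("e,eid,ejd->eij", k * vol, g, g)  # (m, 4, 4)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()
    return K


def solve_temperature(mesh: Mesh, materials: MaterialTable, bcs: ThermalBCs) -> TemperatureField:
    """Galerkin solve of div(k grad T) = 0 with the given Dirichlet sets."""
    if len(bcs.prescribed) == 0:
        raise SingularSystemError("no Dirichlet nodes; thermal system is singular")
    fixed = bcs.node_index
    tvals = bcs.values
    T = np.zeros(mesh.n_nodes)
    T[fixed] = tvals
    free = np.setdiff1d(np.arange(mesh.n_nodes), fixed, assume_unique=False)
    if free.size == 0:
        return TemperatureField(values=T)
    K = _conductance_matrix(mesh, materials)
    rhs = -K[free][:, fixed] @ tvals
    T[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return TemperatureField(values=T)


def element_delta_T(mesh: Mesh, fieldT: TemperatureField, T_ref: float) -> np.ndarray:
    """Per-element temperature change: centroid value of the linear field."""
    return fieldT.values[mesh.tets].mean(axis=1) - T_ref
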