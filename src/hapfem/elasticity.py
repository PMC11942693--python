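"""Linear elastic statics with thermal-strain loads on tetrahedral meshes.

Constant-strain tetrahedra (4-node, linear shape functions) with isotropic
materials.  Loads are (a) thermal strains eps_th = alpha*dT*(1,1,1,0,0,0)
emulating polymerization shrinkage and (b) a uniform occlusal pressure
resultant F applied along -z over the occlusal facet set.  The study
protocol is two phases: phase 1 applies the shrinkage analog alone,
phase 2 adds the occlusal force; by linearity phase 2 equals the
superposition of phase 1 and a mechanical-only solve, which is asserted as
a property test rather than assumed silently.

The constrained system is solved by row/column reduction and sparse LU
factorization; reactions are recovered as K u - f on the constrained dofs.
Fully unconstrained problems (free-shrinkage fixtures) are solved with
MINRES on the singular but consistent system, which converges to the
solution orthogonal to the rigid-body modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import RegionLabel
from .materials import MaterialTable, elasticity_tensor
from .meshing import Mesh, extract_facets
from .thermal import (
    TemperatureField,
    default_bcs,
    element_delta_T,
    shape_gradients,
    solve_temperature,
)

__all__ = [
    "Phase",
    "LoadSpec",
    "SolutionFields",
    "SolveError",
    "element_stiffness",
    "assemble",
    "thermal_load_vector",
    "occlusal_load_vector",
    "solve_static",
    "compute_stress",
    "von_mises",
    "run_phase",
]

VOIGT_ID = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


class Phase(str, Enum):
    PHASE1_THERMAL = "phase1_thermal"
    PHASE2_THERMAL_PLUS_OCCLUSAL = "phase2_thermal_plus_occlusal"
    MECHANICAL_ONLY = "mechanical_only"


@dataclass(frozen=True)
class LoadSpec:
    phase: Phase
    F_total: float = 2000.0  # N, along -z over the occlusal facets

    def __post_init__(self) -> None:
        if self.F_total < 0:
            raise ValueError("occlusal force must be non-negative")


@dataclass
class SolutionFields:
    """Bundle of one solve: nodal u/T, element stress, support reactions."""

    u: np.ndarray                      # (n, 3) mm
    temperature: Optional[np.ndarray]  # (n,) degC or None
    stress: np.ndarray                 # (m, 6) MPa, Voigt
    vm: np.ndarray                     # (m,) MPa
    reactions: np.ndarray              # (n_fixed, 3) N
    fixed_nodes: np.ndarray            # node indices of the supports
    phase: Phase

    @property
    def reaction_totals(self) -> np.ndarray:
        return self.reactions.sum(axis=0)


class SolveError(RuntimeError):
    pass


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 12) from shape gradients (m, 4, 3).

    Voigt order (xx, yy, zz, yz, xz, xy) with engineering shear strains.
    """
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 1] = gz
        B[:, 3, c + 2] = gy
        B[:, 4, c + 0] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 0] = gy
        B[:, 5, c + 1] = gx
    return B


def element_stiffness(tet_coords: np.ndarray, C: np.ndarray) -> np.ndarray:
    """12x12 stiffness K_e = V B^T C B of one constant-strain tetrahedron."""
    coords = np.asarray(tet_coords, dtype=float).reshape(4, 3)
    e = coords[1:] - coords[0]
    if np.linalg.det(e) <= 0:
        raise SolveError("degenerate element (non-positive volume)")
    grads, vol = shape_gradients(coords, np.arange(4).reshape(1, 4))
    B = _b_matrix(grads)[0]
    return vol[0] * B.T @ C @ B


def _element_data(mesh: Mesh, materials: MaterialTable):
    grads, vol = shape_gradients(mesh.nodes, mesh.tets)
    B = _b_matrix(grads)
    C = np.zeros((mesh.n_elements, 6, 6))
    alpha = np.zeros(mesh.n_elements)
    for lab in RegionLabel:
        sel = mesh.region == int(lab)
        if np.any(sel):
            rec = materials[lab]
            C[sel] = elasticity_tensor(rec.E, rec.nu)
            alpha[sel] = rec.alpha
    return B, C, vol, alpha


def assemble(mesh: Mesh, materials: MaterialTable) -> sp.csr_matrix:
    """Sparse global stiffness (3 n_nodes square), symmetric."""
    B, C, vol, _ = _element_data(mesh, materials)
    ke = np.einsum("e,eki,ekl,elj->eij", vol, B, C, B, optimize=True)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def thermal_load_vector(mesh: Mesh, materials: MaterialTable, delta_T: np.ndarray) -> np.ndarray:
    """Equivalent nodal forces of eps_th = alpha dT (1,1,1,0,0,0) per element."""
    B, C, vol, alpha = _element_data(mesh, materials)
    eps_th = (alpha * delta_T)[:, None] * VOIGT_ID  # (m, 6)
    fe = np.einsum("e,eki,ekl,el->ei", vol, B, C, eps_th, optimize=True)  # (m, 12)
    f = np.zeros(3 * mesh.n_nodes)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    np.add.at(f, dofs.ravel(), fe.ravel())
    return f


def occlusal_load_vector(mesh: Mesh, F_total: float, set_name: str = "occlusal") -> np.ndarray:
    """Uniform -z pressure with resultant F_total over a facet set.

    Each flat facet contributes p*A_f/3 to each of its 3 nodes; the nodal
    sum equals (0, 0, -F_total) by construction.
    """
    tris, areas, _ = extract_facets(mesh, set_name)
    if len(tris) == 0 or areas.sum() <= 0:
        raise SolveError(f"facet set {set_name!r} is empty; cannot apply load")
    p = F_total / areas.sum()
    f = np.zeros(3 * mesh.n_nodes)
    fz = -p * np.repeat(areas / 3.0, 3)
    np.add.at(f, 3 * tris.ravel() + 2, fz)
    return f


def _rigid_modes(nodes: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes, (3n, 6)."""
    x = nodes - nodes.mean(axis=0)
    n = len(nodes)
    R = np.zeros((3 * n, 6))
    for k in range(3):
        R[k::3, k] = 1.0
    R[1::3, 3], R[2::3, 3] = -x[:, 2], x[:, 1]   # rotation about x
    R[0::3, 4], R[2::3, 4] = x[:, 2], -x[:, 0]   # rotation about y
    R[0::3, 5], R[1::3, 5] = -x[:, 1], x[:, 0]   # rotation about z
    q, _ = np.linalg.qr(R)
    return q


class StaticSolver:
    """Factorized constrained stiffness, reusable across load cases.

    The fixed dofs are eliminated by reduction and the reduced matrix is
    LU-factorized once (sparse direct, symmetric-pattern ordering); each
    ``solve`` is then a cheap triangular backsubstitution.  With an empty
    fixed set the system is regularized by Lagrange multipliers on the 6
    rigid-body modes, so self-equilibrated loads (free-floating fixtures)
    solve exactly; reactions are then empty.
    """

    def __init__(self, K: sp.spmatrix, fixed_nodes: np.ndarray, nodes: Optional[np.ndarray] = None):
        self.K = K.tocsr()
        self.n = K.shape[0]
        self.fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
        if self.fixed_nodes.size == 0:
            if nodes is None:
                raise SolveError("free-floating solve requires node coordinates")
            R = sp.csc_matrix(_rigid_modes(nodes))
            A = sp.bmat([[self.K, R], [R.T, None]], format="csc")
            self._lu = spla.splu(A)
            self.fixed_dofs = np.empty(0, dtype=np.int64)
            self.free = np.arange(self.n)
            return
        self.fixed_dofs = (3 * self.fixed_nodes[:, None] + np.arange(3)).ravel()
        self.free = np.setdiff1d(np.arange(self.n), self.fixed_dofs)
        Kff = self.K[self.free][:, self.free].tocsc()
        try:
            self._lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
        except RuntimeError as exc:  # singular factorization
            raise SolveError(f"singular reduced system: {exc}") from exc

    def solve(self, f: np.ndarray):
        """Return (u flat, reactions (n_fixed, 3) as K u - f on fixed dofs)."""
        if self.fixed_dofs.size == 0:
            sol = self._lu.solve(np.concatenate([f, np.zeros(6)]))
            return sol[: self.n], np.zeros((0, 3))
        u = np.zeros(self.n)
        u[self.free] = self._lu.solve(f[self.free])
        if not np.all(np.isfinite(u)):
            raise SolveError("singular reduced system (non-finite solution)")
        r = (self.K @ u - f)[self.fixed_dofs].reshape(-1, 3)
        return u, r


def solve_static(
    K: sp.spmatrix,
    f: np.ndarray,
    fixed_nodes: np.ndarray,
    nodes: Optional[np.ndarray] = None,
):
    """One-shot constrained solve; see :class:`StaticSolver`."""
    return StaticSolver(K, fixed_nodes, nodes=nodes).solve(f)


def compute_stress(
    mesh: Mesh,
    materials: MaterialTable,
    u: np.ndarray,
    delta_T: Optional[np.ndarray] = None,
):
    """Per-element Voigt stress sigma = C (B u_e - eps_th) and von Mises."""
    B, C, vol, alpha = _element_data(mesh, materials)
    ue = u.reshape(-1, 3)[mesh.tets].reshape(-1, 12)
    eps = np.einsum("eij,ej->ei", B, ue)
    if delta_T is not None:
        eps = eps - (alpha * delta_T)[:, None] * VOIGT_ID
    sigma = np.einsum("eij,ej->ei", C, eps)
    return sigma, von_mises(sigma)


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Equivalent (von Mises) stress from Voigt components (xx,yy,zz,yz,xz,xy)."""
    s = np.atleast_2d(sigma)
    d = (
        (s[:, 0] - s[:, 1]) ** 2
        + (s[:, 1] - s[:, 2]) ** 2
        + (s[:, 2] - s[:, 0]) ** 2
        + 6.0 * (s[:, 3] ** 2 + s[:, 4] ** 2 + s[:, 5] ** 2)
    )
    return np.sqrt(d / 2.0)


def run_phases(
    mesh: Mesh,
    materials: MaterialTable,
    loads,
    support: str = "fixed_support",
):
    """Run several loading phases on one meshed scenario, factorizing once.

    ``support`` names the node set clamped to zero ("fixed_support" for the
    bone-block lateral faces, "base" for the simple z=0 mode, or "" for
    free-floating fixtures).  The stiffness, thermal field and load vectors
    are shared across phases; each phase is one backsubstitution.
    """
    loads = list(loads)
    K = assemble(mesh, materials)
    fixed = (
        mesh.node_sets.get(support, np.empty(0, dtype=np.int64))
        if support
        else np.empty(0, dtype=np.int64)
    )
    solver = StaticSolver(K, fixed, nodes=mesh.nodes)

    temperature = None
    dT = None
    f_th = None
    if any(l.phase is not Phase.MECHANICAL_ONLY for l in loads):
        field = solve_temperature(mesh, materials, default_bcs(mesh))
        temperature = field.values
        dT = element_delta_T(mesh, field, materials.T_ref)
        f_th = thermal_load_vector(mesh, materials, dT)

    results = []
    for load in loads:
        thermal_active = load.phase is not Phase.MECHANICAL_ONLY
        f = np.zeros(3 * mesh.n_nodes)
        if thermal_active:
            f += f_th
        if load.phase is not Phase.PHASE1_THERMAL and load.F_total > 0:
            f += occlusal_load_vector(mesh, load.F_total)
        u, reactions = solver.solve(f)
        sigma, vm = compute_stress(mesh, materials, u, dT if thermal_active else None)
        results.append(
            SolutionFields(
                u=u.reshape(-1, 3),
                temperature=temperature if thermal_active else None,
                stress=sigma,
                vm=vm,
                reactions=reactions,
                fixed_nodes=np.asarray(fixed, dtype=np.int64),
                phase=load.phase,
            )
        )
    return results


def run_phase(
    mesh: Mesh,
    materials: MaterialTable,
    load: LoadSpec,
    support: str = "fixed_support",
) -> SolutionFields:
    """Run one loading phase of the study protocol on a meshed scenario."""
    return run_phases(mesh, materials, [load], support=support)[0]
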