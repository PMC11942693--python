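"""Elastic solver verification against independent analytic/dense oracles."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from hapfem.fixtures import box_mesh, series_bar_mesh
from hapfem.geometry import RegionLabel, build_scenario
from hapfem.materials import default_material_table, elasticity_tensor
from hapfem.meshing import generate_mesh
from hapfem.elasticity import (
    LoadSpec,
    Phase,
    SolveError,
    assemble,
    compute_stress,
    element_stiffness,
    occlusal_load_vector,
    run_phase,
    run_phases,
    solve_static,
    thermal_load_vector,
    von_mises,
)


@pytest.fixture(scope="module")
def materials():
    return default_material_table()


# ---------------------------------------------------------------------------
# independent dense oracle: B from a Vandermonde fit of the linear shape
# functions, K_e = V B^T C B assembled with plain python loops


def oracle_b_matrix(coords):
    V = np.column_stack([np.ones(4), coords])
    coef = np.linalg.inv(V)  # row 1..3 of column a = grad N_a
    grads = coef[1:, :].T    # (4, 3)
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[a]
        B[0, 3 * a] = gx
        B[1, 3 * a + 1] = gy
        B[2, 3 * a + 2] = gz
        B[3, 3 * a + 1] = gz
        B[3, 3 * a + 2] = gy
        B[4, 3 * a] = gz
        B[4, 3 * a + 2] = gx
        B[5, 3 * a] = gy
        B[5, 3 * a + 1] = gx
    vol = abs(np.linalg.det(coords[1:] - coords[0])) / 6.0
    return B, vol


def oracle_dense_stiffness(mesh, materials):
    n = 3 * mesh.n_nodes
    K = np.zeros((n, n))
    for e in range(mesh.n_elements):
        coords = mesh.nodes[mesh.tets[e]]
        rec = materials[RegionLabel(mesh.region[e])]
        C = elasticity_tensor(rec.E, rec.nu)
        B, vol = oracle_b_matrix(coords)
        ke = vol * B.T @ C @ B
        dofs = np.concatenate([3 * i + np.arange(3) for i in mesh.tets[e]])
        for a, ga in enumerate(dofs):
            for b, gb in enumerate(dofs):
                K[ga, gb] += ke[a, b]
    return K


def test_element_stiffness_reference_tet_matches_oracle():
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    C = elasticity_tensor(1.0, 0.0)
    Ke = element_stiffness(coords, C)
    B, vol = oracle_b_matrix(coords)
    assert np.allclose(Ke, vol * B.T @ C @ B, rtol=1e-12, atol=1e-14)


def test_element_stiffness_symmetric_with_rigid_kernel():
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 1, size=(4, 3))
    if np.linalg.det(coords[1:] - coords[0]) < 0:
        coords = coords[[0, 2, 1, 3]]
    C = elasticity_tensor(18_600.0, 0.31)
    Ke = element_stiffness(coords, C)
    assert np.allclose(Ke, Ke.T, atol=1e-9 * np.abs(Ke).max())
    for t in np.eye(3):
        rigid = np.tile(t, 4)
        assert np.abs(Ke @ rigid).max() < 1e-9 * np.abs(Ke).max()
    eig = np.linalg.eigvalsh(Ke)
    assert np.sum(np.abs(eig) < 1e-8 * eig.max()) == 6  # 6 rigid-body modes


def test_degenerate_element_rejected():
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
    with pytest.raises(SolveError):
        element_stiffness(coords, elasticity_tensor(1.0, 0.0))


def test_sparse_assembly_equals_dense_oracle(materials):
    mesh = box_mesh((1, 1, 2), 1.0, region=int(RegionLabel.COMPOSITE))
    mesh.region[mesh.element_centroids()[:, 2] > 1.0] = int(RegionLabel.DENTIN)
    assert 3 * mesh.n_nodes <= 60
    K = assemble(mesh, materials).toarray()
    Kd = oracle_dense_stiffness(mesh, materials)
    assert np.allclose(K, Kd, rtol=1e-9, atol=1e-9 * np.abs(Kd).max())


def test_global_rigid_translation_in_kernel(materials):
    mesh = box_mesh((1, 1, 1), 0.5)
    K = assemble(mesh, materials)
    for t in np.eye(3):
        rigid = np.tile(t, mesh.n_nodes)
        assert np.abs(K @ rigid).max() < 1e-8 * np.abs(K.data).max()


def test_disconnected_meshes_give_block_diagonal_stiffness(materials):
    from hapfem.meshing import Mesh

    a = box_mesh((1, 1, 1), 1.0)
    b = box_mesh((1, 1, 1), 1.0, origin=(5.0, 0.0, 0.0))
    nodes = np.vstack([a.nodes, b.nodes])
    tets = np.vstack([a.tets, b.tets + a.n_nodes])
    merged = Mesh(nodes=nodes, tets=tets, region=np.concatenate([a.region, b.region]))
    K = assemble(merged, materials).toarray()
    off = K[: 3 * a.n_nodes, 3 * a.n_nodes :]
    assert np.abs(off).max() == 0.0


def test_thermal_load_zero_without_shrinkage(materials):
    mesh = box_mesh((1, 1, 1), 0.5, region=int(RegionLabel.DENTIN))  # alpha = 0
    f = thermal_load_vector(mesh, materials, np.full(mesh.n_elements, -26.0))
    assert np.abs(f).max() == 0.0
    mesh2 = box_mesh((1, 1, 1), 0.5)  # composite, alpha > 0, but dT = 0
    f2 = thermal_load_vector(mesh2, materials, np.zeros(mesh2.n_elements))
    assert np.abs(f2).max() == 0.0


def test_free_uniform_cooling_gives_stress_free_isotropic_contraction(materials):
    mesh = box_mesh((1, 1, 1), 0.5)  # composite
    rec = materials[RegionLabel.COMPOSITE]
    dT = np.full(mesh.n_elements, -26.0)
    K = assemble(mesh, materials)
    f = thermal_load_vector(mesh, materials, dT)
    u, _ = solve_static(K, f, np.empty(0, dtype=int), nodes=mesh.nodes)
    _, vm = compute_stress(mesh, materials, u, dT)
    assert vm.max() < 1e-6 * rec.E * rec.alpha * 26.0
    # relative displacement between node pairs matches u = alpha dT x
    u3 = u.reshape(-1, 3)
    d01 = mesh.nodes[1] - mesh.nodes[0]
    assert np.allclose(u3[1] - u3[0], rec.alpha * (-26.0) * d01, atol=1e-12)


def test_occlusal_load_resultant_and_zero_force(materials):
    mesh = generate_mesh(build_scenario("healthy"), 1.0)
    f = occlusal_load_vector(mesh, 2000.0)
    assert f[2::3].sum() == pytest.approx(-2000.0, abs=1e-9)
    assert np.abs(f[0::3]).max() == 0.0 and np.abs(f[1::3]).max() == 0.0
    assert np.abs(occlusal_load_vector(mesh, 0.0)).max() == 0.0
    # implied pressure matches F / (ellipse area) within the stair-step error
    from hapfem.meshing import extract_facets

    _, areas, _ = extract_facets(mesh, "occlusal")
    p = 2000.0 / areas.sum()
    assert p == pytest.approx(2000.0 / (np.pi * 5.0 * 5.5), rel=0.05)


def test_patch_test_constant_stress(materials):
    """Linear boundary displacement reproduces constant stress to 1e-8."""
    mesh = box_mesh((1, 1, 1), 1.0 / 3.0, region=int(RegionLabel.DENTIN))
    A = np.array([[1e-3, 2e-4, 0.0], [0.0, -3e-4, 1e-4], [2e-4, 0.0, 5e-4]])
    ub = mesh.nodes @ A.T
    bnodes = mesh.node_sets["external_surface"]
    fixed_dofs = (3 * bnodes[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed_dofs)
    K = assemble(mesh, materials)
    u = np.zeros(3 * mesh.n_nodes)
    u[fixed_dofs] = ub.ravel()[fixed_dofs]
    rhs = -K[free][:, fixed_dofs] @ u[fixed_dofs]
    u[free] = spla.splu(K[free][:, free].tocsc()).solve(rhs)
    sigma, _ = compute_stress(mesh, materials, u)
    spread = np.abs(sigma - sigma.mean(axis=0)).max()
    assert spread < 1e-8 * np.abs(sigma).max()


def test_series_bar_tip_displacement(materials):
    """Two-material column under end load matches (F/A)(L1/E1 + L2/E2)."""
    mesh = series_bar_mesh(cross=1.0, L1=2.0, L2=2.0, h=0.25)
    K = assemble(mesh, materials)
    F = 100.0
    f = occlusal_load_vector(mesh, F)
    nodes = mesh.nodes
    fixed = set(int(3 * n + 2) for n in mesh.node_sets["base"])
    i0 = int(np.flatnonzero(np.linalg.norm(nodes, axis=1) < 1e-9)[0])
    i1 = int(np.flatnonzero(
        (np.abs(nodes[:, 0] - 1) < 1e-9) & (np.abs(nodes[:, 1]) < 1e-9) & (np.abs(nodes[:, 2]) < 1e-9)
    )[0])
    fixed |= {3 * i0, 3 * i0 + 1, 3 * i1 + 1}
    fixed_dofs = np.array(sorted(fixed))
    free = np.setdiff1d(np.arange(3 * mesh.n_nodes), fixed_dofs)
    u = np.zeros(3 * mesh.n_nodes)
    u[free] = spla.splu(K[free][:, free].tocsc()).solve(f[free])
    tip = u.reshape(-1, 3)[np.abs(nodes[:, 2] - 4.0) < 1e-9, 2].mean()
    E1 = materials[RegionLabel.COMPOSITE].E
    E2 = materials[RegionLabel.DENTIN].E
    exact = -(F / 1.0) * (2.0 / E1 + 2.0 / E2)
    assert tip == pytest.approx(exact, rel=0.01)


def test_reactions_balance_applied_load(materials):
    mesh = generate_mesh(build_scenario("small_ic"), 1.2)
    sol = run_phase(mesh, materials, LoadSpec(phase=Phase.PHASE2_THERMAL_PLUS_OCCLUSAL))
    totals = sol.reaction_totals
    assert abs(totals[2] - 2000.0) < 1e-6
    assert abs(totals[0]) < 1e-6 and abs(totals[1]) < 1e-6


def test_superposition_phase2_equals_phase1_plus_mechanical(materials):
    mesh = generate_mesh(build_scenario("big_ic"), 1.2)
    loads = [
        LoadSpec(phase=Phase.PHASE1_THERMAL),
        LoadSpec(phase=Phase.PHASE2_THERMAL_PLUS_OCCLUSAL),
        LoadSpec(phase=Phase.MECHANICAL_ONLY),
    ]
    s1, s2, sm = run_phases(mesh, materials, loads)
    err = np.abs(s2.u - (s1.u + sm.u)).max()
    assert err < 1e-8 * np.abs(s2.u).max()


def test_healthy_mechanical_only_has_no_thermal_strain(materials):
    mesh = generate_mesh(build_scenario("healthy"), 1.5)
    sol = run_phase(mesh, materials, LoadSpec(phase=Phase.MECHANICAL_ONLY))
    assert sol.temperature is None
    assert np.linalg.norm(sol.u, axis=1).max() > 0.0


def test_mesh_refinement_stability_small_c(materials):
    """Max displacement of small_c changes < 10% between h=1.0 and h=0.5."""
    vals = {}
    for h in (1.0, 0.5):
        mesh = generate_mesh(build_scenario("small_c"), h)
        sol = run_phase(mesh, materials, LoadSpec(phase=Phase.MECHANICAL_ONLY))
        vals[h] = np.linalg.norm(sol.u, axis=1).max()
    assert abs(vals[0.5] - vals[1.0]) / vals[0.5] < 0.10


@pytest.mark.parametrize(
    "sigma, expected",
    [
        ((5.0, 5.0, 5.0, 0.0, 0.0, 0.0), 0.0),           # hydrostatic
        ((7.0, 0.0, 0.0, 0.0, 0.0, 0.0), 7.0),           # uniaxial
        ((0.0, 0.0, 0.0, 0.0, 0.0, 10.0), 10.0 * np.sqrt(3.0)),  # pure shear
    ],
)
def test_von_mises_reference_states(sigma, expected):
    assert von_mises(np.array([sigma]))[0] == pytest.approx(expected, abs=1e-12)
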