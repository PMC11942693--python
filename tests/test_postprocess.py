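"""Reduction operations: statistics, contraction, comparisons, reports."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hapfem.fixtures import box_mesh
from hapfem.geometry import RegionLabel, build_scenario
from hapfem.meshing import Mesh, generate_mesh
from hapfem.elasticity import SolutionFields, Phase
from hapfem.postprocess import (
    ContractionResult,
    EmptyGroupError,
    StudyReport,
    contraction_rate,
    near_floor_stress,
    percent_decrease,
    region_stats,
    write_report,
)


def _fields(mesh, vm, u=None):
    n = mesh.n_nodes
    return SolutionFields(
        u=np.zeros((n, 3)) if u is None else u,
        temperature=None,
        stress=np.zeros((mesh.n_elements, 6)),
        vm=np.asarray(vm, dtype=float),
        reactions=np.zeros((0, 3)),
        fixed_nodes=np.empty(0, dtype=int),
        phase=Phase.MECHANICAL_ONLY,
    )


def _single_region_mesh(values, region=RegionLabel.ENAMEL):
    mesh = box_mesh((1, 1, 1), 1.0, region=int(region))
    assert mesh.n_elements >= len(values)
    vm = np.zeros(mesh.n_elements)
    vm[: len(values)] = values
    return mesh, vm


def test_region_stats_single_value():
    mesh = box_mesh((1, 1, 1), 1.0, region=int(RegionLabel.DENTIN))
    mesh.region[:] = int(RegionLabel.PULP)
    mesh.region[0] = int(RegionLabel.DENTIN)
    st_ = region_stats(mesh, _fields(mesh, np.full(mesh.n_elements, 7.0)), "dentin")
    assert st_.average == st_.median == st_.max == 7.0
    assert st_.stdev == 0.0


def test_region_stats_quartiles_linear_interpolation():
    mesh = box_mesh((2, 2, 1), 1.0, region=int(RegionLabel.PULP))
    mesh.region[:4] = int(RegionLabel.ENAMEL)
    vm = np.zeros(mesh.n_elements)
    vm[:4] = [1.0, 2.0, 3.0, 4.0]
    st_ = region_stats(mesh, _fields(mesh, vm), "enamel")
    assert st_.q1 == pytest.approx(1.75)
    assert st_.median == pytest.approx(2.5)
    assert st_.q3 == pytest.approx(3.25)
    assert st_.q1 <= st_.median <= st_.q3 <= st_.max


def test_region_stats_invariant_under_element_reordering():
    mesh = generate_mesh(build_scenario("small_c"), 1.5)
    rng = np.random.default_rng(5)
    vm = rng.uniform(0, 100, mesh.n_elements)
    a = region_stats(mesh, _fields(mesh, vm), "dentin")
    perm = rng.permutation(mesh.n_elements)
    shuffled = Mesh(
        nodes=mesh.nodes, tets=mesh.tets[perm], region=mesh.region[perm],
        node_sets=mesh.node_sets, facet_sets=mesh.facet_sets,
    )
    b = region_stats(shuffled, _fields(shuffled, vm[perm]), "dentin")
    for k in ("average", "stdev", "q1", "median", "q3", "max"):
        assert getattr(a, k) == pytest.approx(getattr(b, k))


def test_restoration_group_absent_in_healthy():
    mesh = generate_mesh(build_scenario("healthy"), 1.5)
    with pytest.raises(EmptyGroupError):
        region_stats(mesh, _fields(mesh, np.zeros(mesh.n_elements)), "restoration")


def test_contraction_rate_uniform_strain_closed_form():
    mesh = box_mesh((2, 2, 2), 0.5)  # composite
    for eps in (-0.0125, 0.01):
        u = eps * mesh.nodes
        res = contraction_rate(mesh, u, cylinder_fit=False)
        assert res.rate_percent == pytest.approx(100.0 * (1.0 - (1.0 + eps) ** 3), rel=1e-10)
    res0 = contraction_rate(mesh, np.zeros_like(mesh.nodes))
    assert res0.rate_percent == 0.0
    assert res0.V0 == pytest.approx(8.0)


def test_contraction_rate_requires_restoration_elements():
    mesh = box_mesh((1, 1, 1), 0.5, region=int(RegionLabel.DENTIN))
    with pytest.raises(EmptyGroupError):
        contraction_rate(mesh, np.zeros_like(mesh.nodes))


def test_contraction_methods_agree_on_free_cylinder(free_cylinder_run):
    mesh, _, sol = free_cylinder_run
    res = contraction_rate(mesh, sol.u)
    assert res.rate_percent_cylinder_fit == pytest.approx(res.rate_percent, rel=0.10)


def test_percent_decrease_reference_pairs():
    assert percent_decrease(518.47, 322.63) == pytest.approx(37.77, abs=0.005)
    pd_ = percent_decrease(186.43, 192.59)
    assert pd_ == pytest.approx(-3.30, abs=0.005)
    assert pd_ < 0  # an increase, flagged by the caller
    assert percent_decrease(123.4, 123.4) == 0.0
    with pytest.raises(ValueError):
        percent_decrease(0.0, 1.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    c=st.floats(min_value=1e-3, max_value=1e6),
    e=st.floats(min_value=0.0, max_value=1e6),
)
def test_percent_decrease_inverts_exactly(c, e):
    pd_ = percent_decrease(c, e)
    assert e == pytest.approx(c * (1.0 - pd_ / 100.0), rel=1e-12, abs=1e-9)


def test_near_floor_stress_errors():
    geom = build_scenario("healthy")
    mesh = generate_mesh(geom, 1.5)
    f = _fields(mesh, np.zeros(mesh.n_elements))
    with pytest.raises(Exception):
        near_floor_stress(mesh, f, geom)  # healthy: no cavity floor
    geom2 = build_scenario("big_c")
    mesh2 = generate_mesh(geom2, 1.5)
    f2 = _fields(mesh2, np.zeros(mesh2.n_elements))
    with pytest.raises(ValueError):
        near_floor_stress(mesh2, f2, geom2, distance=0.0)


def test_near_floor_selects_dentin_band():
    geom = build_scenario("big_c")
    mesh = generate_mesh(geom, 0.8)
    vm = np.zeros(mesh.n_elements)
    cen = mesh.element_centroids()
    floor = geom.cavity_floor_z
    band = (
        (mesh.region == int(RegionLabel.DENTIN))
        & (cen[:, 2] >= floor - 0.5) & (cen[:, 2] <= floor)
        & (cen[:, 0] ** 2 + cen[:, 1] ** 2 <= 2.75**2)
    )
    vm[band] = 42.0
    assert near_floor_stress(mesh, _fields(mesh, vm), geom, 0.5) == pytest.approx(42.0)


def test_write_report_roundtrip_and_files(tmp_path):
    report = StudyReport(
        config={"h": 1.0},
        stats={"small_c": {"phase1_thermal": {"dentin": {
            "group": "dentin", "n_elements": 3, "average": 1.0, "stdev": 0.1,
            "q1": 0.9, "median": 1.0, "q3": 1.1, "max": 1.2, "max_displacement": 0.01,
        }}}},
        contraction={"small_c": {"V0": 10.0, "V1": 9.6, "rate_percent": 4.0,
                                 "rate_percent_cylinder_fit": None}},
        comparisons=[],
    )
    paths = write_report(report, tmp_path)
    assert all(p.exists() for p in paths)
    payload = json.loads((tmp_path / "report.json").read_text())
    assert StudyReport(**payload).stats == report.stats

    empty = write_report(StudyReport(), tmp_path / "empty")
    for p in empty:
        assert p.exists()
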