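"""Shared fixtures; the heavy study runs are session-scoped and reused."""

import numpy as np
import pytest

from hapfem.elasticity import LoadSpec, Phase, run_phase, run_phases
from hapfem.fixtures import make_fixture
from hapfem.geometry import build_scenario
from hapfem.materials import default_material_table
from hapfem.meshing import generate_mesh
from hapfem.pipeline import StudyConfig, run_study


@pytest.fixture(scope="session")
def materials_table():
    return default_material_table()


@pytest.fixture(scope="session")
def free_cylinder_run(materials_table):
    """Free composite cylinder cooled 36 -> 10 degC: phase-1 shrinkage solve."""
    mesh, info = make_fixture("free_cylinder")
    sol = run_phase(
        mesh, materials_table, LoadSpec(phase=Phase.PHASE1_THERMAL), support=""
    )
    return mesh, info, sol


@pytest.fixture(scope="session")
def small_c_default_run(materials_table):
    """small_c scenario at the default mesh size, all three load cases."""
    geom = build_scenario("small_c")
    mesh = generate_mesh(geom, StudyConfig().h)
    loads = [
        LoadSpec(phase=Phase.PHASE1_THERMAL),
        LoadSpec(phase=Phase.PHASE2_THERMAL_PLUS_OCCLUSAL),
        LoadSpec(phase=Phase.MECHANICAL_ONLY),
    ]
    sols = run_phases(mesh, materials_table, loads)
    return geom, mesh, dict(zip(("phase1", "phase2", "mech"), sols))


@pytest.fixture(scope="session")
def full_study_report():
    """The five-scenario, two-phase study at the default configuration."""
    return run_study(StudyConfig())
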