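"""Small deterministic meshes used by the analytic verification fixtures.

Four named fixtures back the solver verification suite:

- ``unit_cube``       — Kuhn-split unit cube (patch test, volume checks).
- ``series_bar``      — two-material column, composite stacked on dentin,
                        for the series-spring tip-displacement oracle.
- ``free_cylinder``   — homogeneous composite cylinder with no supports,
                        used for the free-shrinkage contraction rate.
- ``tiny_tooth``      — a shrunken full scenario mesh (coarse h) that runs
                        the whole pipeline end-to-end in seconds.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .geometry import RegionLabel, build_scenario
from .meshing import Mesh, _KUHN_TETS, element_volumes, boundary_facets

__all__ = ["make_fixture", "box_mesh", "cylinder_mesh", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("unit_cube", "series_bar", "free_cylinder", "tiny_tooth")


def box_mesh(
    size: Tuple[float, float, float],
    h: float,
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0),
    region: int = int(RegionLabel.COMPOSITE),
) -> Mesh:
    """Structured Kuhn-split box; single region tag unless retagged later."""
    size = np.asarray(size, dtype=float)
    origin = np.asarray(origin, dtype=float)
    ncell = np.maximum(1, np.round(size / h).astype(int))
    spacing = size / ncell
    nx, ny, nz = (int(v) for v in ncell)

    gi, gj, gk = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    nodes = np.column_stack(
        [
            origin[0] + gi.ravel() * spacing[0],
            origin[1] + gj.ravel() * spacing[1],
            origin[2] + gk.ravel() * spacing[2],
        ]
    )

    def gid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    corners = np.empty((ci.size, 8), dtype=np.int64)
    for v in range(8):
        corners[:, v] = gid(ci + (v & 1), cj + ((v >> 1) & 1), ck + ((v >> 2) & 1))
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)

    mesh = Mesh(
        nodes=nodes.astype(float),
        tets=tets,
        region=np.full(len(tets), region, dtype=np.int64),
    )
    _basic_sets(mesh)
    return mesh


def _basic_sets(mesh: Mesh) -> None:
    """Exterior/occlusal facets, base and external-surface sets for fixtures."""
    tol = 1e-9
    tris, _ = boundary_facets(mesh)
    mesh.facet_sets["exterior"] = tris
    mesh.node_sets["external_surface"] = np.unique(tris)
    z = mesh.nodes[:, 2]
    zc = mesh.nodes[tris][:, :, 2]
    top = np.all(np.abs(zc - z.max()) < tol, axis=1)
    mesh.facet_sets["occlusal"] = tris[top]
    mesh.node_sets["base"] = np.flatnonzero(np.abs(z - z.min()) < tol)
    mesh.node_sets["fixed_support"] = mesh.node_sets["base"]
    mesh.node_sets["composite_cement_nodes"] = mesh.nodes_of(
        RegionLabel.COMPOSITE, RegionLabel.CEMENT
    )
    mesh.node_sets["insert_nodes"] = mesh.nodes_of(RegionLabel.INSERT)


def cylinder_mesh(
    diameter: float, height: float, h: float, region: int = int(RegionLabel.COMPOSITE)
) -> Mesh:
    """Stair-step voxel cylinder, axis along z, base at z = 0."""
    r = diameter / 2.0
    full = box_mesh((diameter, diameter, height), h, origin=(-r, -r, 0.0), region=region)
    cen = full.element_centroids()
    keep = cen[:, 0] ** 2 + cen[:, 1] ** 2 <= r**2
    tets = full.tets[keep]
    used, renum = np.unique(tets, return_inverse=True)
    mesh = Mesh(
        nodes=full.nodes[used],
        tets=renum.reshape(-1, 4),
        region=full.region[keep],
    )
    _basic_sets(mesh)
    return mesh


def series_bar_mesh(
    cross: float = 1.0, L1: float = 2.0, L2: float = 2.0, h: float = 0.25
) -> Mesh:
    """Composite (top, length L1) stacked on dentin (bottom, length L2)."""
    mesh = box_mesh((cross, cross, L1 + L2), h)
    cen = mesh.element_centroids()
    mesh.region = np.where(
        cen[:, 2] >= L2, int(RegionLabel.COMPOSITE), int(RegionLabel.DENTIN)
    )
    _basic_sets(mesh)
    return mesh


def make_fixture(name: str, h: float | None = None):
    """Return (mesh, info dict) for a named verification fixture."""
    if name == "unit_cube":
        mesh = box_mesh((1.0, 1.0, 1.0), h or 0.5)
        info = {"volume": 1.0}
    elif name == "series_bar":
        mesh = series_bar_mesh(h=h or 0.25)
        info = {"cross_section": 1.0, "L1": 2.0, "L2": 2.0}
    elif name == "free_cylinder":
        mesh = cylinder_mesh(diameter=5.5, height=4.2, h=h or 0.35)
        info = {"diameter": 5.5, "height": 4.2}
    elif name == "tiny_tooth":
        from .meshing import generate_mesh

        geom = build_scenario("small_ic")
        mesh = generate_mesh(geom, h or 1.5)
        info = {"scenario": "small_ic", "h": h or 1.5}
    else:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    info["n_elements"] = mesh.n_elements
    info["n_nodes"] = mesh.n_nodes
    info["total_volume"] = float(element_volumes(mesh.nodes, mesh.tets).sum())
    return mesh, info
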