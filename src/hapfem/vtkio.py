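"""Legacy ASCII VTK unstructured-grid I/O for meshes and solution fields.

Writes the classic version-2.0 VTK format readable by ParaView and most
mesh tools: tetrahedral connectivity, region tags as cell data, node sets
as point-data masks, and optional solution fields (temperature,
displacement, Voigt stress, von Mises).  A matching reader recovers a
region-tagged mesh, which is how externally produced tetrahedral meshes can
enter the pipeline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .geometry import RegionLabel
from .meshing import Mesh

__all__ = ["write_vtk", "read_vtk"]

_VTK_TETRA = 10


def write_vtk(
    path,
    mesh: Mesh,
    point_data: Optional[dict] = None,
    cell_data: Optional[dict] = None,
) -> Path:
    """Write mesh (+ per-node / per-element arrays) as legacy ASCII VTK."""
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 2.0",
        "hapfem unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{v:.12g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in mesh.tets]
    lines.append(f"CELL_TYPES {m}")
    lines += [str(_VTK_TETRA)] * m

    cdata = {"region": mesh.region.astype(np.int64)}
    if cell_data:
        cdata.update(cell_data)
    lines.append(f"CELL_DATA {m}")
    for name, arr in cdata.items():
        lines += _data_array(name, np.asarray(arr), m)

    pdata = {}
    for sname, idx in mesh.node_sets.items():
        mask = np.zeros(n, dtype=np.int64)
        mask[idx] = 1
        pdata[f"set_{sname}"] = mask
    if point_data:
        pdata.update(point_data)
    if pdata:
        lines.append(f"POINT_DATA {n}")
        for name, arr in pdata.items():
            lines += _data_array(name, np.asarray(arr), n)

    path.write_text("\n".join(lines) + "\n")
    return path


def _data_array(name: str, arr: np.ndarray, expected: int):
    if len(arr) != expected:
        raise ValueError(f"array {name!r} has wrong length {len(arr)} != {expected}")
    out = []
    if arr.ndim == 1:
        dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        out.append(f"SCALARS {name} {dtype} 1")
        out.append("LOOKUP_TABLE default")
        fmt = (lambda v: str(int(v))) if dtype == "int" else (lambda v: f"{v:.12g}")
        out += [fmt(v) for v in arr]
    elif arr.shape[1] == 3:
        out.append(f"VECTORS {name} double")
        out += [" ".join(f"{v:.12g}" for v in row) for row in arr]
    else:
        out.append(f"FIELD {name}_field 1")
        out.append(f"{name} {arr.shape[1]} {len(arr)} double")
        out += [" ".join(f"{v:.12g}" for v in row) for row in arr]
    return out


def read_vtk(path) -> Mesh:
    """Read a legacy ASCII VTK tetrahedral grid back into a Mesh.

    Only tetrahedral cells are accepted; a ``region`` cell-data scalar is
    used for tags when present (otherwise all elements get DENTIN).  Node
    and facet sets are not reconstructed beyond the set_* masks present.
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nodes = tets = None
    region = None
    node_sets = {}
    n = m = 0
    section = "cell"
    for line in it:
        if line.startswith("CELL_DATA"):
            section = "cell"
            continue
        if line.startswith("POINT_DATA"):
            section = "point"
            continue
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            while len(vals) < 3 * n:
                vals += next(it).split()
            nodes = np.array(vals, dtype=float).reshape(n, 3)
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            rows = [next(it).split() for _ in range(m)]
            if any(r[0] != "4" for r in rows):
                raise ValueError("only tetrahedral cells are supported")
            tets = np.array([r[1:] for r in rows], dtype=np.int64)
        elif line.startswith("CELL_TYPES"):
            types = [int(next(it)) for _ in range(m)]
            if any(t != _VTK_TETRA for t in types):
                raise ValueError("only tetrahedral cells are supported")
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            next(it)  # LOOKUP_TABLE
            count = m if section == "cell" else n
            vals = [next(it) for _ in range(count)]
            if name == "region":
                region = np.array(vals, dtype=float).astype(np.int64)
            elif name.startswith("set_"):
                mask = np.array(vals, dtype=float).astype(np.int64)
                node_sets[name[4:]] = np.flatnonzero(mask)
    if nodes is None or tets is None:
        raise ValueError(f"{path} is not a legacy VTK unstructured grid")
    if region is None:
        region = np.full(len(tets), int(RegionLabel.DENTIN), dtype=np.int64)
    return Mesh(nodes=nodes, tets=tets, region=region, node_sets=node_sets)
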