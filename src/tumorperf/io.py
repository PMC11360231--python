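"""Plain-text input/output: legacy VTK, contour CSV, mesh CSV tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import Mesh

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_contours_csv",
    "read_contours_csv",
    "write_mesh_csv",
    "read_mesh_csv",
]

_VTK_QUAD, _VTK_TRI = 9, 5


def write_vtk(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None, title: str = "tumorperf") -> None:
    """Write a mesh with optional point/cell fields as legacy ASCII VTK.

    Scalar fields are (n,) arrays; vector fields (n, 2) arrays (padded
    with a zero z-component).  Cells are written quads-first, matching
    ``Mesh.element_nodes`` order.
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    n = mesh.n_nodes
    cells = list(mesh.element_nodes())
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        size = sum(len(c) + 1 for c in cells)
        f.write(f"CELLS {len(cells)} {size}\n")
        for c in cells:
            f.write(f"{len(c)} " + " ".join(str(int(i)) for i in c) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        for c in cells:
            f.write(f"{_VTK_QUAD if len(c) == 4 else _VTK_TRI}\n")

        def dump(fields, count):
            for name, arr in fields.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        f.write(f"{v:.10g}\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for v in arr:
                        z = v[2] if len(v) > 2 else 0.0
                        f.write(f"{v[0]:.10g} {v[1]:.10g} {z:.10g}\n")

        if point_data:
            f.write(f"POINT_DATA {n}\n")
            dump(point_data, n)
        if cell_data:
            f.write(f"CELL_DATA {len(cells)}\n")
            dump(cell_data, len(cells))


def read_vtk(path) -> Mesh:
    """Read the mesh (geometry only) back from a legacy ASCII VTK file."""
    with open(path) as f:
        tokens = f.read().split()
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3:i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = tokens.index("CELLS")
    n_cells = int(tokens[i + 1])
    pos = i + 3
    conns = []
    for _ in range(n_cells):
        m = int(tokens[pos])
        conns.append([int(t) for t in tokens[pos + 1:pos + 1 + m]])
        pos += m + 1
    quads = [c for c in conns if len(c) == 4]
    tris = [c for c in conns if len(c) == 3]
    nodes = coords[:, :2]
    # boundary nodes: edges used by exactly one element
    from collections import Counter
    edge_count = Counter()
    for c in conns:
        for a, b in zip(c, c[1:] + c[:1]):
            edge_count[frozenset((a, b))] += 1
    boundary = sorted({i for e, cnt in edge_count.items() if cnt == 1
                       for i in e})
    return Mesh(nodes=nodes,
                quads=np.array(quads) if quads else np.empty((0, 4), int),
                tris=np.array(tris) if tris else np.empty((0, 3), int),
                boundary_nodes=np.array(boundary))


def write_contours_csv(path, times, contours) -> None:
    """Contours as tidy CSV with columns x_um, y_um, time_day."""
    frames = []
    for t, c in zip(times, contours):
        c = np.asarray(c, dtype=float)
        frames.append(pd.DataFrame(
            {"x_um": c[:, 0], "y_um": c[:, 1], "time_day": t}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_contours_csv(path):
    df = pd.read_csv(path)
    times = sorted(df["time_day"].unique())
    contours = [df[df["time_day"] == t][["x_um", "y_um"]].to_numpy()
                for t in times]
    return np.asarray(times, dtype=float), contours


def write_mesh_csv(node_path, element_path, mesh: Mesh) -> None:
    pd.DataFrame({
        "node": np.arange(mesh.n_nodes),
        "x_um": mesh.nodes[:, 0],
        "y_um": mesh.nodes[:, 1],
        "boundary": np.isin(np.arange(mesh.n_nodes), mesh.boundary_nodes),
    }).to_csv(node_path, index=False)
    rows = []
    for e, conn in enumerate(mesh.element_nodes()):
        row = {"element": e, "n_nodes": len(conn)}
        for a, j in enumerate(conn):
            row[f"n{a}"] = int(j)
        rows.append(row)
    pd.DataFrame(rows).to_csv(element_path, index=False)


def read_mesh_csv(node_path, element_path, h_z: float = 1.0) -> Mesh:
    nodes_df = pd.read_csv(node_path)
    elems_df = pd.read_csv(element_path)
    nodes = nodes_df[["x_um", "y_um"]].to_numpy()
    boundary = nodes_df.loc[nodes_df["boundary"], "node"].to_numpy()
    quads, tris = [], []
    for _, row in elems_df.iterrows():
        m = int(row["n_nodes"])
        conn = [int(row[f"n{a}"]) for a in range(m)]
        (quads if m == 4 else tris).append(conn)
    return Mesh(nodes=nodes,
                quads=np.array(quads) if quads else np.empty((0, 4), int),
                tris=np.array(tris) if tris else np.empty((0, 3), int),
                boundary_nodes=boundary, h_z=h_z)
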