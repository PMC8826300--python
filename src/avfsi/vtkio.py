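"""Minimal legacy-ASCII VTK writers for fields, contours and leaflet meshes.

Legacy VTK is a plain-text format; these writers cover the three shapes the
package emits (cell data on the uniform grid, interface polylines, leaflet
quad meshes) and open directly in ParaView.
"""

from __future__ import annotations

import numpy as np

from .grid import UniformGrid


def write_image_data(path, grid: UniformGrid, cell_fields: dict[str, np.ndarray]) -> None:
    """Cell-centred scalar fields on the uniform grid (STRUCTURED_POINTS)."""
    nx, ny = grid.nx, grid.ny
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\navfsi fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write(f"ORIGIN {grid.x0} {grid.y0} 0\n")
        fh.write(f"SPACING {grid.h} {grid.h} 1\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in cell_fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.asarray(arr, float).T.ravel().tofile(fh, sep="\n")
            fh.write("\n")


def write_polydata(path, polylines: list[np.ndarray], closed: bool = False) -> None:
    """Polylines (interface contours) as VTK POLYDATA lines."""
    pts = []
    lines = []
    off = 0
    for poly in polylines:
        poly = np.asarray(poly, float)
        n = len(poly)
        pts.append(poly)
        ids = list(range(off, off + n))
        if closed:
            ids.append(off)
        lines.append(ids)
        off += n
    allpts = np.vstack(pts) if pts else np.zeros((0, 2))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\navfsi contours\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(allpts)} float\n")
        for x, y in allpts:
            fh.write(f"{x} {y} 0\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for ids in lines:
            fh.write(" ".join([str(len(ids))] + [str(i) for i in ids]) + "\n")


def write_quad_mesh(path, nodes: np.ndarray, elements: np.ndarray,
                    point_fields: dict[str, np.ndarray] | None = None) -> None:
    """Quadrilateral mesh (leaflet) as VTK UNSTRUCTURED_GRID."""
    nodes = np.asarray(nodes, float)
    elements = np.asarray(elements, int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\navfsi leaflet\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} float\n")
        for x, y in nodes:
            fh.write(f"{x} {y} 0\n")
        fh.write(f"CELLS {len(elements)} {len(elements) * 5}\n")
        for e in elements:
            fh.write("4 " + " ".join(str(i) for i in e) + "\n")
        fh.write(f"CELL_TYPES {len(elements)}\n")
        fh.write("\n".join(["9"] * len(elements)) + "\n")
        if point_fields:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in point_fields.items():
                arr = np.asarray(arr, float)
                if arr.ndim == 2:
                    fh.write(f"VECTORS {name} float\n")
                    for vx, vy in arr:
                        fh.write(f"{vx} {vy} 0\n")
                else:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    arr.tofile(fh, sep="\n")
                    fh.write("\n")
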