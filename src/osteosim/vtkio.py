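"""Minimal legacy-ASCII VTK writer for rectilinear-grid snapshots.

Writes RECTILINEAR_GRID datasets with CELL_DATA scalar fields, which is
all the simulator needs for field snapshots (ParaView/VisIt readable).
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_rectilinear"]


def write_vtk_rectilinear(path, grid, cell_fields: dict[str, np.ndarray],
                          title: str = "osteosim snapshot") -> None:
    """Write cell-centered scalar fields on the grid to a legacy VTK file."""
    nx1, ny1 = grid.nx + 1, grid.ny + 1
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET RECTILINEAR_GRID\n")
        fh.write(f"DIMENSIONS {nx1} {ny1} 1\n")
        fh.write(f"X_COORDINATES {nx1} float\n")
        fh.write(" ".join(f"{v:.6g}" for v in grid.xf) + "\n")
        fh.write(f"Y_COORDINATES {ny1} float\n")
        fh.write(" ".join(f"{v:.6g}" for v in grid.yf) + "\n")
        fh.write("Z_COORDINATES 1 float\n0\n")
        fh.write(f"CELL_DATA {grid.n_cells}\n")
        for name, field in cell_fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.6g}" for v in
                               np.asarray(field, float).ravel()) + "\n")
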