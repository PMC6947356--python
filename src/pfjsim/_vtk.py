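"""Minimal legacy-VTK (ASCII polydata) export for triangle meshes."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import TriMesh


def write_polydata(path, mesh: TriMesh, cell_data: dict | None = None) -> None:
    """Write a triangle mesh with optional per-face scalar arrays."""
    lines = [
        "# vtk DataFile Version 3.0",
        "pfjsim surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} float",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    nf = len(mesh.faces)
    lines.append(f"POLYGONS {nf} {4 * nf}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    if cell_data:
        lines.append(f"CELL_DATA {nf}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (nf,):
                raise ValueError(f"cell array {name!r} has shape {arr.shape}, "
                                 f"expected ({nf},)")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.6g}" for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")
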