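"""File output: VTK legacy STRUCTURED_POINTS, CSV time series, JSON reports.

Snapshots go out as ASCII VTK legacy structured-points files with cell data
(one scalar array per field), which any standard VTK viewer opens directly.
A minimal reader for the same subset supports round-trip tests and
metrics-only reruns from saved snapshots.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .geometry import DomainGrid

__all__ = [
    "write_structured_points",
    "read_structured_points",
    "write_grid_vtk",
    "write_fraction_vtk",
    "write_flowfield_vtk",
    "write_csv",
    "write_json",
]


def write_structured_points(path, nx: int, ny: int, spacing_mm: float,
                            cell_data: dict[str, np.ndarray]) -> None:
    """ASCII VTK legacy structured-points file with cell-centered scalars.

    ``cell_data`` values are (nx, ny) arrays; VTK's fastest-varying axis is
    x, so arrays are flattened in Fortran order over (i, j).
    """
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "fistulaflow field snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} 2",
        "ORIGIN 0 0 0",
        f"SPACING {spacing_mm:.9g} {spacing_mm:.9g} {spacing_mm:.9g}",
        f"CELL_DATA {nx * ny}",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.shape != (nx, ny):
            raise ValueError(f"cell data {name!r} has shape {arr.shape}, "
                             f"expected {(nx, ny)}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.flatten(order="F")
        for k in range(0, flat.size, 6):
            lines.append(" ".join(f"{v:.9g}" for v in flat[k:k + 6]))
    path.write_text("\n".join(lines) + "\n")


def read_structured_points(path) -> tuple[int, int, float,
                                          dict[str, np.ndarray]]:
    """Read back a file written by :func:`write_structured_points`."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nx = ny = None
    spacing = 1.0
    data: dict[str, np.ndarray] = {}
    line = next(it)
    try:
        while True:
            if line.startswith("DIMENSIONS"):
                _, sx, sy, _ = line.split()
                nx, ny = int(sx) - 1, int(sy) - 1
            elif line.startswith("SPACING"):
                spacing = float(line.split()[1])
            elif line.startswith("SCALARS"):
                name = line.split()[1]
                next(it)  # LOOKUP_TABLE
                vals: list[float] = []
                while len(vals) < nx * ny:
                    vals.extend(float(v) for v in next(it).split())
                data[name] = np.array(vals).reshape((nx, ny), order="F")
            line = next(it)
    except StopIteration:
        pass
    if nx is None:
        raise ValueError(f"{path} is not a structured-points file")
    return nx, ny, spacing, data


def write_grid_vtk(path, grid: DomainGrid) -> None:
    """Grid labels (fluid flag and region tag) as VTK cell data."""
    write_structured_points(
        path, grid.nx, grid.ny, grid.spacing,
        {"cell_label": grid.fluid.astype(float),
         "region_tag": grid.region.astype(float)})


def write_fraction_vtk(path, grid: DomainGrid, alpha: np.ndarray) -> None:
    write_structured_points(path, grid.nx, grid.ny, grid.spacing,
                            {"alpha": alpha})


def write_flowfield_vtk(path, grid: DomainGrid, u: np.ndarray, v: np.ndarray,
                        p: np.ndarray) -> None:
    """One flow snapshot; staggered velocities interpolated to cell centers."""
    ucc = 0.5 * (u[:-1, :] + u[1:, :])
    vcc = 0.5 * (v[:, :-1] + v[:, 1:])
    write_structured_points(path, grid.nx, grid.ny, grid.spacing,
                            {"u": ucc, "v": vcc, "p": p})


def write_csv(path, header: list[str], rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow(row)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
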