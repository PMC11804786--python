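"""Readers and writers for label volumes, flow fields and run artifacts.

Label volumes travel as multi-page TIFF stacks (pages are z-slices, each
page y-by-x) with a JSON sidecar carrying spacing, origin, label scheme
and provenance.  Flow fields and lattice checkpoints use HDF5.  A minimal
legacy-ASCII VTK STRUCTURED_POINTS writer is included for quick looks in
ParaView; it emits plain text and supports scalar and 3-vector fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import VoxelGeometry
from .lbm import FlowField


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_geometry(geometry: VoxelGeometry, path) -> None:
    """Write a label volume as TIFF stack + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, geometry.labels.transpose(2, 1, 0).astype(np.uint8))
    meta = {
        "axes": "ZYX",
        "spacing_m": geometry.spacing,
        "origin_m": list(geometry.origin),
        "label_scheme": {"solid": 0, "inner_pore": 1, "external_pore": 2},
        "provenance": geometry.provenance,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_geometry(path) -> VoxelGeometry:
    """Read a TIFF label volume; spacing/origin come from the sidecar."""
    path = Path(path)
    stack = tifffile.imread(path)
    labels = np.asarray(stack).transpose(2, 1, 0)
    spacing, origin, prov = 1.0, (0.0, 0.0, 0.0), f"file:{path.name}"
    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        spacing = float(meta.get("spacing_m", 1.0))
        origin = tuple(meta.get("origin_m", (0.0, 0.0, 0.0)))
        prov = meta.get("provenance", prov)
    return VoxelGeometry(labels=labels, spacing=spacing, origin=origin, provenance=prov)


def write_field(field: FlowField, path, trace: dict | None = None) -> None:
    """Write a flow field (and optionally its convergence trace) to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("velocity", data=field.velocity, compression="gzip")
        h5.create_dataset("density", data=field.density, compression="gzip")
        h5.create_dataset("pressure", data=field.pressure, compression="gzip")
        h5.create_dataset("solid", data=field.solid.astype(np.uint8), compression="gzip")
        h5.attrs["spacing_m"] = field.spacing
        h5.attrs["time_s"] = field.time
        if trace is not None:
            g = h5.create_group("trace")
            for key in ("step", "time", "kinetic_energy"):
                g.create_dataset(key, data=np.asarray(trace[key]))
            for key in ("dt", "dl", "tau", "u_lattice"):
                g.attrs[key] = trace[key]
            g.attrs["converged"] = bool(trace["converged"])


def read_field(path) -> FlowField:
    with h5py.File(path, "r") as h5:
        return FlowField(
            velocity=h5["velocity"][...],
            density=h5["density"][...],
            pressure=h5["pressure"][...],
            solid=h5["solid"][...].astype(bool),
            spacing=float(h5.attrs["spacing_m"]),
            time=float(h5.attrs["time_s"]),
        )


def write_vtk_image(path, spacing: float, fields: dict[str, np.ndarray]) -> None:
    """Write scalar/vector voxel fields as legacy-ASCII VTK STRUCTURED_POINTS.

    ``fields`` maps names to arrays of shape ``(nx, ny, nz)`` (scalars) or
    ``(nx, ny, nz, 3)`` (vectors).  VTK expects x varying fastest, so
    arrays are emitted in Fortran order.
    """
    first = next(iter(fields.values()))
    nx, ny, nz = first.shape[:3]
    lines = [
        "# vtk DataFile Version 3.0",
        "coralflow field output",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.ravel(order="F")
            lines.extend(" ".join(f"{v:.6e}" for v in flat[i : i + 6])
                         for i in range(0, flat.size, 6))
        else:
            lines.append(f"VECTORS {name} float")
            flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
            lines.extend(f"{v[0]:.6e} {v[1]:.6e} {v[2]:.6e}" for v in flat)
    Path(path).write_text("\n".join(lines) + "\n")
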