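"""MetaImage (MHD header + RAW) I/O for dose grids.

Values are stored as little-endian 32-bit floats. The first DimSize entry
is the fastest-varying axis, so a grid with axes (x, y, z) in C order is
written as DimSize = (nz, ny, nx) with matching Offset/ElementSpacing
ordering; reading reverses the convention, so write/read round-trips are
bit-exact on the float32 values and exact on origin/spacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .scoring import VoxelDoseGrid

__all__ = ["write_dose_grid", "read_dose_grid", "write_stats_sidecar"]


def write_dose_grid(grid: VoxelDoseGrid, path: str | Path) -> Path:
    """Write the grid's energy values as an .mhd/.raw pair; returns mhd path."""
    path = Path(path)
    if path.suffix != ".mhd":
        path = path.with_suffix(".mhd")
    raw_path = path.with_suffix(".raw")
    values = np.ascontiguousarray(grid.values, dtype="<f4")
    dims = grid.dims
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = 1 0 0 0 1 0 0 0 1",
        f"Offset = {grid.origin[2]:g} {grid.origin[1]:g} {grid.origin[0]:g}",
        "CenterOfRotation = 0 0 0",
        f"ElementSpacing = {grid.voxel_size:g} {grid.voxel_size:g} {grid.voxel_size:g}",
        f"DimSize = {dims[2]} {dims[1]} {dims[0]}",
        "ElementType = MET_FLOAT",
        f"NHistories = {grid.n_histories}",  # custom key; ITK readers ignore it
        f"ElementDataFile = {raw_path.name}",
    ]
    path.write_text("\n".join(header) + "\n")
    raw_path.write_bytes(values.tobytes())
    return path


def read_dose_grid(path: str | Path) -> VoxelDoseGrid:
    """Read an .mhd/.raw pair written by :func:`write_dose_grid`."""
    path = Path(path)
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    if fields.get("ElementType") != "MET_FLOAT":
        raise ValueError(f"unsupported ElementType {fields.get('ElementType')!r}")
    dims_rev = tuple(int(v) for v in fields["DimSize"].split())
    dims = dims_rev[::-1]
    spacing = [float(v) for v in fields["ElementSpacing"].split()]
    if len(set(spacing)) != 1:
        raise ValueError("only isotropic spacing is supported")
    offset_rev = [float(v) for v in fields["Offset"].split()]
    origin = np.array(offset_rev[::-1])
    raw_path = path.parent / fields["ElementDataFile"]
    buf = raw_path.read_bytes()
    expected = int(np.prod(dims)) * 4
    if len(buf) != expected:
        raise ValueError(
            f"raw size mismatch: header implies {expected} bytes, "
            f"file has {len(buf)}"
        )
    values = np.frombuffer(buf, dtype="<f4").reshape(dims).astype(np.float64)
    grid = VoxelDoseGrid(
        origin=origin,
        voxel_size=spacing[0],
        dims=dims,
        n_batches=1,
        values=values,
        batch_accumulators=values[None].astype(np.float32),
        n_histories=int(fields.get("NHistories", 0)),
    )
    return grid


def write_stats_sidecar(stats, path: str | Path, extra: dict | None = None) -> Path:
    """JSON sidecar with run statistics and tallies (units in key names)."""
    path = Path(path)
    payload = {
        "n_histories": stats.n_histories,
        "n_batches": stats.n_batches,
        "seed": stats.seed,
        "injected_MeV": stats.injected_mev,
        "deposited_MeV": stats.deposited_mev,
        "escaped_MeV": stats.escaped_mev,
        "outside_detector_MeV": stats.outside_detector_mev,
        "conservation_residual": stats.conservation_residual(),
        "n_photons": stats.n_photons,
        "wall_time_s": stats.wall_time_s,
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
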