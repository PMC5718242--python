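"""Voxelized energy scoring, dose conversion, batch uncertainty, regions.

The grid stores deposited energy (MeV) per voxel in float64, with per-batch
float32 accumulators for the batch-variance uncertainty estimate. Deposits
outside the detector box are counted in an outside tally, never lost, so
energy bookkeeping stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryModel, REGION_MATERIALS, WATER
from .materials import get_material

__all__ = [
    "VoxelDoseGrid",
    "deposit",
    "to_dose",
    "region_dose",
    "batch_uncertainty",
    "treatment_zone",
    "normal_tissue",
    "axis_aperture",
    "MEV_TO_J",
]

MEV_TO_J = 1.602176634e-13


@dataclass
class VoxelDoseGrid:
    """Energy-deposit grid over the sensitive detector (half-open voxels).

    ``values[i,j,k]`` is total deposited energy (MeV) in the voxel whose
    centre is ``origin + (idx + 0.5) * voxel_size``.
    """

    origin: np.ndarray
    voxel_size: float
    dims: tuple[int, int, int]
    n_batches: int = 10
    values: np.ndarray = field(default=None, repr=False)
    batch_accumulators: np.ndarray = field(default=None, repr=False)
    outside_tally: float = 0.0
    n_histories: int = 0
    batch_histories: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.values is None:
            self.values = np.zeros(self.dims, dtype=np.float64)
        if self.batch_accumulators is None:
            self.batch_accumulators = np.zeros(
                (self.n_batches, *self.dims), dtype=np.float32
            )
        if self.batch_histories is None:
            self.batch_histories = np.zeros(self.n_batches, dtype=np.int64)

    # -- construction ------------------------------------------------------

    @classmethod
    def for_detector(
        cls, model: GeometryModel, voxel_size: float = 0.5, n_batches: int = 10
    ) -> "VoxelDoseGrid":
        dims = (
            int(round(model.detector_depth / voxel_size)),
            int(round(model.detector_width / voxel_size)),
            int(round(model.detector_width / voxel_size)),
        )
        if not np.allclose(
            np.array(dims) * voxel_size,
            [model.detector_depth, model.detector_width, model.detector_width],
        ):
            raise ValueError("voxel_size must tile the detector extent exactly")
        origin = np.array(
            [0.0, -model.detector_width / 2.0, -model.detector_width / 2.0]
        )
        return cls(origin=origin, voxel_size=voxel_size, dims=dims, n_batches=n_batches)

    # -- coordinates -------------------------------------------------------

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (mm)."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size / 10.0) ** 3

    def indices_of(self, positions: np.ndarray):
        """Half-open voxel indices; second return flags in-detector points."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        rel = (positions - self.origin) / self.voxel_size
        idx = np.floor(rel).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(self.dims)), axis=1)
        return idx, inside

    # -- deposits ----------------------------------------------------------

    def deposit_v(
        self, positions: np.ndarray, energies: np.ndarray, batch_ids: np.ndarray
    ) -> None:
        """Vectorized deposit of many energy packets."""
        energies = np.asarray(energies, dtype=float)
        if np.any(energies < 0):
            raise ValueError("deposited energy must be >= 0")
        idx, inside = self.indices_of(positions)
        if not np.all(inside):
            self.outside_tally += float(energies[~inside].sum())
        if np.any(inside):
            ii = idx[inside]
            e_in = energies[inside]
            flat = np.ravel_multi_index((ii[:, 0], ii[:, 1], ii[:, 2]), self.dims)
            np.add.at(self.values.ravel(), flat, e_in)
            b = np.asarray(batch_ids)[inside] if np.ndim(batch_ids) else batch_ids
            bflat = np.asarray(b, dtype=np.int64) * self.values.size + flat
            np.add.at(
                self.batch_accumulators.ravel(), bflat, e_in.astype(np.float32)
            )

    def total_energy(self) -> float:
        return float(self.values.sum())


def deposit(grid: VoxelDoseGrid, position, energy: float, batch_id: int = 0) -> None:
    """Deposit one energy packet (MeV) at a position (mm)."""
    if energy < 0:
        raise ValueError("deposited energy must be >= 0")
    grid.deposit_v(
        np.asarray(position, dtype=float)[None, :],
        np.array([energy]),
        np.array([batch_id]),
    )


# -- material / density map ------------------------------------------------


def material_ids(grid: VoxelDoseGrid, model: GeometryModel | None) -> np.ndarray:
    """Region id at every voxel centre (chunked to bound memory)."""
    if model is None:
        return np.full(grid.dims, WATER, dtype=np.int8)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    out = np.empty(grid.dims, dtype=np.int8)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    plane = np.empty((ys.size * zs.size, 3))
    plane[:, 1] = yy.ravel()
    plane[:, 2] = zz.ravel()
    for i, x in enumerate(xs):
        plane[:, 0] = x
        out[i] = model.locate_ids(plane).reshape(ys.size, zs.size)
    return out


_DENSITY_BY_REGION = {
    rid: get_material(name).density for rid, name in REGION_MATERIALS.items()
}


def density_map(grid: VoxelDoseGrid, model: GeometryModel | None) -> np.ndarray:
    ids = material_ids(grid, model)
    dens = np.full(grid.dims, _DENSITY_BY_REGION[WATER], dtype=np.float64)
    for rid, rho in _DENSITY_BY_REGION.items():
        if rid == WATER:
            continue
        dens[ids == rid] = rho
    return dens


def to_dose(
    grid: VoxelDoseGrid,
    model: GeometryModel | None = None,
    per_history: bool = False,
) -> np.ndarray:
    """Convert deposited energy to absorbed dose (Gy).

    Voxel mass comes from the material at the voxel centre. With
    ``per_history`` the result is Gy per primary history.
    """
    dens = density_map(grid, model)
    if np.any(dens <= 0):
        raise ValueError("zero density in dose conversion")
    mass_kg = dens * grid.voxel_volume_cm3() * 1e-3
    dose = grid.values * MEV_TO_J / mass_kg
    if per_history:
        if grid.n_histories <= 0:
            raise ValueError("grid has no recorded histories")
        dose = dose / grid.n_histories
    return dose


# -- regions ---------------------------------------------------------------


def treatment_zone(grid: VoxelDoseGrid, model: GeometryModel) -> np.ndarray:
    """Cylinder of collimator radius from the surface to the disc proximal plane."""
    pose = model.region_planes_pose
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    rmask = (
        ys[:, None] ** 2 + zs[None, :] ** 2
        <= (model.collimator_inner_diameter / 2.0) ** 2
    )
    xmask = xs < pose.depth
    return xmask[:, None, None] & rmask[None, :, :]


def normal_tissue(grid: VoxelDoseGrid, model: GeometryModel) -> np.ndarray:
    """All detector voxels distal to the (nominal) disc distal plane."""
    pose = model.region_planes_pose
    xs = grid.axis_coords(0)
    xmask = xs > pose.distal_plane
    out = np.zeros(grid.dims, dtype=bool)
    out[xmask] = True
    return out


def central_plane(grid: VoxelDoseGrid) -> np.ndarray:
    """The single voxel sheet closest to z = 0 (for central-plane 2D maps)."""
    zs = grid.axis_coords(2)
    iz = int(np.argmin(np.abs(zs)))
    out = np.zeros(grid.dims, dtype=bool)
    out[:, :, iz] = True
    return out


def axis_aperture(grid: VoxelDoseGrid, side_mm: float) -> np.ndarray:
    """Square column of side ``side_mm`` centred on the beam axis."""
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    ymask = np.abs(ys) <= side_mm / 2.0
    zmask = np.abs(zs) <= side_mm / 2.0
    out = np.zeros(grid.dims, dtype=bool)
    out[:, ymask[:, None] & zmask[None, :]] = True
    return out


def region_dose(
    grid: VoxelDoseGrid,
    region: np.ndarray,
    quantity: str = "energy",
    model: GeometryModel | None = None,
    per_history: bool = False,
) -> float:
    """Sum of voxel energies (default) or doses over a region mask.

    Energy sums are the default integrand for the with/without-disc dose
    comparison (proportional to dose in uniform water). ``per_history``
    divides by the recorded history count — required when integrals from
    runs of different sizes are compared (shielding factors).
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != grid.values.shape:
        raise ValueError("region mask shape mismatch")
    if not region.any():
        raise ValueError("empty region")
    if quantity == "energy":
        total = float(grid.values[region].sum())
    elif quantity == "dose":
        total = float(to_dose(grid, model)[region].sum())
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    if per_history:
        if grid.n_histories <= 0:
            raise ValueError("grid has no recorded histories")
        total /= grid.n_histories
    return total


def batch_uncertainty(grid: VoxelDoseGrid) -> np.ndarray:
    """Per-voxel relative standard error of the batch means.

    Voxels with zero mean are flagged with NaN.
    """
    nb = grid.batch_accumulators.shape[0]
    if nb < 2:
        raise ValueError("need >= 2 batches for an uncertainty estimate")
    batches = grid.batch_accumulators.astype(np.float64)
    mean = batches.mean(axis=0)
    var = batches.var(axis=0, ddof=1) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(var) / mean
    rel[mean == 0] = np.nan
    return rel
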