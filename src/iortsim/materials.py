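"""Material records and the bundled material library.

The library ships as a human-readable CSV (``data/materials.csv``) holding
frozen constants from standard compilations. Users may register additional
materials at runtime with :func:`register_material`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = ["Material", "get_material", "register_material", "available_materials"]


@dataclass(frozen=True)
class Material:
    """Immutable material record.

    Attributes
    ----------
    name : str
        Library key (lower case).
    density : float
        Mass density, g/cm^3.
    effective_Z : float
        Effective atomic number (informational).
    effective_A : float
        Effective molar mass, g/mol, consistent with ``z_over_a``.
    mean_excitation_energy : float
        Mean excitation energy I, eV.
    radiation_length : float
        Radiation length X0, g/cm^2.
    electron_energy_cutoff : float
        Electron tracking cutoff, keV.
    photon_energy_cutoff : float
        Photon tracking cutoff, keV.
    z_over_a : float
        Ratio <Z/A>, mol/g (dimensionless per unit molar mass convention).
    sternheimer : tuple
        Density-effect coefficients (cbar, x0, x1, a, k, delta0).
    is_gas : bool
        Gas at NTP (affects nothing beyond bookkeeping; the density-effect
        coefficients already encode the phase).
    """

    name: str
    density: float
    effective_Z: float
    effective_A: float
    mean_excitation_energy: float
    radiation_length: float
    electron_energy_cutoff: float
    photon_energy_cutoff: float
    z_over_a: float
    sternheimer: tuple = field(repr=False)
    is_gas: bool = False

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        if self.radiation_length <= 0:
            raise ValueError(f"material {self.name!r}: radiation_length must be > 0")
        if self.electron_energy_cutoff <= 0 or self.photon_energy_cutoff <= 0:
            raise ValueError(f"material {self.name!r}: cutoffs must be > 0")


def _load_library() -> dict[str, Material]:
    lib: dict[str, Material] = {}
    with resources.files("iortsim.data").joinpath("materials.csv").open() as fh:
        rows = [r for r in fh if not r.startswith("#")]
    for row in csv.DictReader(rows):
        z_over_a = float(row["z_over_a"])
        eff_z = float(row["effective_z"])
        mat = Material(
            name=row["name"],
            density=float(row["density_g_cm3"]),
            effective_Z=eff_z,
            effective_A=eff_z / z_over_a,
            mean_excitation_energy=float(row["mean_excitation_energy_ev"]),
            radiation_length=float(row["radiation_length_g_cm2"]),
            electron_energy_cutoff=float(row["electron_cutoff_kev"]),
            photon_energy_cutoff=float(row["photon_cutoff_kev"]),
            z_over_a=z_over_a,
            sternheimer=(
                float(row["sternheimer_cbar"]),
                float(row["sternheimer_x0"]),
                float(row["sternheimer_x1"]),
                float(row["sternheimer_a"]),
                float(row["sternheimer_k"]),
                float(row["sternheimer_delta0"]),
            ),
            is_gas=bool(int(row["is_gas"])),
        )
        lib[mat.name] = mat
    return lib


_LIBRARY: dict[str, Material] = _load_library()


def available_materials() -> list[str]:
    """Names of all registered materials."""
    return sorted(_LIBRARY)


def get_material(name: str) -> Material:
    """Look up a material by (case-insensitive) name.

    Raises
    ------
    KeyError
        If the name is unknown; the message lists available names.
    """
    key = name.strip().lower()
    try:
        return _LIBRARY[key]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {', '.join(available_materials())}"
        ) from None


def register_material(mat: Material) -> None:
    """Add a custom material to the runtime library (overwrites same name)."""
    _LIBRARY[mat.name.strip().lower()] = mat
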