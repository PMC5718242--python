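"""Gaussian electron source at the exit-window plane.

The source model has five parameters: mean kinetic energy and its standard
deviation, transverse position spreads along y and z, and an angular spread.
The angular spread sigma is interpreted as the standard deviation of the
polar deflection magnitude from +x (half-Gaussian polar angle, uniform
azimuth); this is the one place that interpretation lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BeamSourceModel", "PRESETS", "sample_primaries"]


@dataclass(frozen=True)
class BeamSourceModel:
    """Gaussian beam model sampled at the exit-window plane."""

    mean_energy: float  # MeV
    sigma_energy: float = 0.5  # MeV
    sigma_y: float = 1.0  # mm
    sigma_z: float = 1.0  # mm
    sigma_theta: float = 6.0  # degrees, polar spread about +x
    n_histories: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_energy <= 0:
            raise ValueError("mean_energy must be > 0")
        for s in (self.sigma_energy, self.sigma_y, self.sigma_z, self.sigma_theta):
            if s < 0:
                raise ValueError("all sigmas must be >= 0")
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")


#: Calibrated source presets, one per nominal accelerator energy.
PRESETS: dict[str, BeamSourceModel] = {
    "10MeV": BeamSourceModel(10.1),
    "8MeV": BeamSourceModel(8.3),
    "6MeV": BeamSourceModel(6.3),
    "4MeV": BeamSourceModel(4.8),
}


def sample_primaries(
    model: BeamSourceModel,
    n: int,
    rng: np.random.Generator,
    x_plane_mm: float = 0.0,
    energy_floor_mev: float = 0.025,
):
    """Sample ``n`` primary electrons.

    Returns ``(positions (n,3) mm, directions (n,3) unit, energies (n) MeV)``.
    Energies below ``energy_floor_mev`` are resampled (truncated Gaussian).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model.sigma_energy > 0:
        energies = rng.normal(model.mean_energy, model.sigma_energy, size=n)
        bad = energies < energy_floor_mev
        while np.any(bad):
            energies[bad] = rng.normal(
                model.mean_energy, model.sigma_energy, size=int(bad.sum())
            )
            bad = energies < energy_floor_mev
    else:
        energies = np.full(n, model.mean_energy)

    pos = np.zeros((n, 3))
    pos[:, 0] = x_plane_mm
    if model.sigma_y > 0:
        pos[:, 1] = rng.normal(0.0, model.sigma_y, size=n)
    if model.sigma_z > 0:
        pos[:, 2] = rng.normal(0.0, model.sigma_z, size=n)

    dirs = np.zeros((n, 3))
    if model.sigma_theta > 0:
        theta = np.abs(rng.normal(0.0, np.radians(model.sigma_theta), size=n))
    else:
        theta = np.zeros(n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    st = np.sin(theta)
    dirs[:, 0] = np.cos(theta)
    dirs[:, 1] = st * np.cos(phi)
    dirs[:, 2] = st * np.sin(phi)
    return pos, dirs, energies
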