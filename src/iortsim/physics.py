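"""Electron and photon interaction coefficients.

Analytic surrogates replace a full condensed-history physics list:

* collision stopping power — Moller/Bethe formula for electrons with the
  Sternheimer density-effect correction (coefficients frozen per material);
* radiative stopping power — radiation-length scaling ``(E + mc^2)/X0``
  damped at low energy by ``E/(E + 4 MeV)`` (documented crude fit);
* multiple scattering — Highland's formula for the projected-angle sigma;
* photon attenuation — log-log interpolation of frozen coarse tables.

All energies are kinetic, in MeV; lengths in cm unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from .materials import Material, get_material

__all__ = [
    "collision_stopping_power",
    "radiative_stopping_power",
    "total_stopping_power",
    "csda_range",
    "highland_sigma",
    "photon_attenuation",
    "PhysicsTables",
]

ELECTRON_MASS_MEV = 0.51099895
E_MAX_MEV = 15.0
#: Bethe formula prefactor 2*pi*r_e^2*m_e*c^2*N_A  (MeV cm^2/mol)
_K_BETHE = 0.1535374
#: Bohr straggling constant 4*pi*r_e^2*(m_e c^2)^2*N_A  (MeV^2 cm^2/mol)
_K_BOHR = 0.1569
#: Low-energy damping scale of the radiative stopping-power fit (MeV)
_RAD_DAMP_MEV = 4.0

# Total photon mass attenuation coefficients mu/rho (cm^2/g) on coarse energy
# grids (MeV), frozen from standard tabulations. Interpolated log-log. The
# lead grid carries one extra point just above the K edge; finer edge
# structure is deliberately not modelled.
_MU_RHO: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "water": (
        (0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100, 0.150,
         0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.500, 2.000, 3.000,
         4.000, 5.000, 6.000, 8.000, 10.000, 15.000),
        (5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707,
         0.1505, 0.1370, 0.1186, 0.1061, 0.0969, 0.0896, 0.0786, 0.0707,
         0.0575, 0.0494, 0.0397, 0.0340, 0.0303, 0.0277, 0.0243, 0.0222,
         0.0191),
    ),
    "air": (
        (0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100, 0.150,
         0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.500, 2.000, 3.000,
         4.000, 5.000, 6.000, 8.000, 10.000, 15.000),
        (5.120, 1.614, 0.7779, 0.3538, 0.2485, 0.2080, 0.1875, 0.1662, 0.1541,
         0.1356, 0.1233, 0.1067, 0.0955, 0.0870, 0.0806, 0.0707, 0.0636,
         0.0518, 0.0445, 0.0358, 0.0308, 0.0275, 0.0252, 0.0223, 0.0204,
         0.0178),
    ),
    "pmma": (
        (0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100, 0.150,
         0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.500, 2.000, 3.000,
         4.000, 5.000, 6.000, 8.000, 10.000, 15.000),
        (3.357, 1.101, 0.5714, 0.3032, 0.2350, 0.2074, 0.1924, 0.1751, 0.1641,
         0.1456, 0.1328, 0.1152, 0.1031, 0.0941, 0.0870, 0.0763, 0.0687,
         0.0559, 0.0480, 0.0386, 0.0329, 0.0292, 0.0266, 0.0232, 0.0211,
         0.0180),
    ),
    "aluminum": (
        (0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100, 0.150,
         0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.500, 2.000, 3.000,
         4.000, 5.000, 6.000, 8.000, 10.000, 15.000),
        (26.23, 7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704,
         0.1378, 0.1223, 0.1042, 0.0927, 0.0844, 0.0779, 0.0683, 0.0614,
         0.0500, 0.0432, 0.0353, 0.0310, 0.0284, 0.0266, 0.0244, 0.0232,
         0.0216),
    ),
    "titanium": (
        (0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.100, 0.150,
         0.200, 0.300, 0.400, 0.500, 0.600, 0.800, 1.000, 1.500, 2.000, 3.000,
         4.000, 5.000, 6.000, 8.000, 10.000, 15.000),
        (110.7, 34.79, 15.35, 4.972, 2.214, 1.213, 0.7661, 0.4052, 0.2721,
         0.1649, 0.1314, 0.1043, 0.0909, 0.0821, 0.0754, 0.0662, 0.0589,
         0.0484, 0.0420, 0.0349, 0.0312, 0.0291, 0.0279, 0.0265, 0.0260,
         0.0257),
    ),
    "lead": (
        (0.010, 0.015, 0.020, 0.030, 0.040, 0.050, 0.060, 0.080, 0.088,
         0.0881, 0.100, 0.150, 0.200, 0.300, 0.400, 0.500, 0.600, 0.800,
         1.000, 1.500, 2.000, 3.000, 4.000, 5.000, 6.000, 8.000, 10.000,
         15.000),
        (130.6, 111.6, 86.36, 30.32, 14.36, 8.041, 5.021, 2.419, 1.910,
         7.680, 5.549, 2.014, 0.9985, 0.4026, 0.2323, 0.1614, 0.1248, 0.0887,
         0.0710, 0.0522, 0.0461, 0.0421, 0.0420, 0.0426, 0.0436, 0.0459,
         0.0489, 0.0539),
    ),
}


def _as_material(m: Material | str) -> Material:
    return get_material(m) if isinstance(m, str) else m


def _check_electron_window(m: Material, E) -> None:
    emin = m.electron_energy_cutoff / 1000.0
    E = np.asarray(E, dtype=float)
    if np.any(E < emin) or np.any(E > E_MAX_MEV):
        raise ValueError(
            f"electron energy outside validity window "
            f"[{emin:g}, {E_MAX_MEV:g}] MeV for {m.name}"
        )


def density_effect(m: Material | str, E) -> np.ndarray | float:
    """Sternheimer density-effect correction delta(beta*gamma)."""
    m = _as_material(m)
    cbar, x0, x1, a, k, delta0 = m.sternheimer
    E = np.asarray(E, dtype=float)
    gamma = 1.0 + E / ELECTRON_MASS_MEV
    betagamma = np.sqrt(np.maximum(gamma * gamma - 1.0, 1e-30))
    x = np.log10(betagamma)
    two_ln10 = 2.0 * np.log(10.0)
    delta = np.where(
        x >= x1,
        two_ln10 * x - cbar,
        two_ln10 * x - cbar + a * np.maximum(x1 - x, 0.0) ** k,
    )
    below = x < x0
    if np.any(below):
        delta = np.where(below, delta0 * 10.0 ** (2.0 * (x - x0)), delta)
    delta = np.maximum(delta, 0.0)
    return delta if delta.ndim else float(delta)


def collision_stopping_power(m: Material | str, E) -> np.ndarray | float:
    """Linear collision stopping power, MeV/cm (Moller/Bethe + density effect)."""
    m = _as_material(m)
    _check_electron_window(m, E)
    E = np.asarray(E, dtype=float)
    tau = E / ELECTRON_MASS_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    i_ratio = m.mean_excitation_energy * 1e-6 / ELECTRON_MASS_MEV
    f_minus = (
        1.0
        - beta2
        + (tau * tau / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (gamma * gamma)
    )
    log_term = np.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    delta = density_effect(m, E)
    mass_sp = (_K_BETHE / beta2) * m.z_over_a * (log_term + f_minus - delta)
    out = mass_sp * m.density
    return out if out.ndim else float(out)


def radiative_stopping_power(m: Material | str, E) -> np.ndarray | float:
    """Linear radiative stopping power, MeV/cm.

    Adopted fit: ``S_rad = rho * (E + mc^2)/X0 * E/(E + 4 MeV)`` — the
    complete-screening radiation-length limit damped at low energy. Z
    dependence enters through X0.
    """
    m = _as_material(m)
    _check_electron_window(m, E)
    E = np.asarray(E, dtype=float)
    mass_sp = (E + ELECTRON_MASS_MEV) / m.radiation_length * E / (E + _RAD_DAMP_MEV)
    out = mass_sp * m.density
    return out if out.ndim else float(out)


def total_stopping_power(m: Material | str, E) -> np.ndarray | float:
    """Collision plus radiative linear stopping power, MeV/cm."""
    return collision_stopping_power(m, E) + radiative_stopping_power(m, E)


def csda_range(m: Material | str, E: float) -> float:
    """Continuous-slowing-down range from the material cutoff to ``E``, cm."""
    m = _as_material(m)
    _check_electron_window(m, E)
    emin = m.electron_energy_cutoff / 1000.0
    if E <= emin:
        return 0.0
    val, err = quad(
        lambda e: 1.0 / total_stopping_power(m, e), emin, E, limit=200
    )
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise ArithmeticError(
            f"csda_range quadrature did not converge for {m.name} at {E} MeV"
        )
    return float(val)


def highland_sigma(m: Material | str, E, step_cm) -> np.ndarray | float:
    """Highland multiple-scattering angle sigma (radians) over a step.

    ``theta0 = 13.6 MeV/(beta c p) * sqrt(t/X0) * (1 + 0.038 ln(t/X0))``
    with ``t = step * density`` in g/cm^2; clamped to >= 0.
    """
    m = _as_material(m)
    step_cm = np.asarray(step_cm, dtype=float)
    if np.any(step_cm < 0):
        raise ValueError("step must be > 0")
    _check_electron_window(m, E)
    E = np.asarray(E, dtype=float)
    pc = np.sqrt(E * (E + 2.0 * ELECTRON_MASS_MEV))
    beta_pc = pc * pc / (E + ELECTRON_MASS_MEV)  # beta * pc, MeV
    t_rel = np.maximum(step_cm * m.density / m.radiation_length, 1e-30)
    theta0 = 13.6 / beta_pc * np.sqrt(t_rel) * (1.0 + 0.038 * np.log(t_rel))
    theta0 = np.maximum(theta0, 0.0)
    return theta0 if theta0.ndim else float(theta0)


def photon_attenuation(m: Material | str, E) -> np.ndarray | float:
    """Total linear photon attenuation coefficient, 1/cm (log-log table fit)."""
    m = _as_material(m)
    E = np.asarray(E, dtype=float)
    emin = m.photon_energy_cutoff / 1000.0
    if np.any(E < emin) or np.any(E > E_MAX_MEV):
        raise ValueError(
            f"photon energy outside validity window [{emin:g}, {E_MAX_MEV:g}] "
            f"MeV for {m.name}"
        )
    try:
        grid_e, grid_mu = _MU_RHO[m.name]
    except KeyError:
        # Custom material: fall back to the water shape scaled by Z/A ratio.
        grid_e, grid_mu = _MU_RHO["water"]
        scale = m.z_over_a / 0.55509
        mu_rho = np.exp(
            np.interp(np.log(E), np.log(grid_e), np.log(np.asarray(grid_mu) * scale))
        )
        out = mu_rho * m.density
        return out if out.ndim else float(out)
    mu_rho = np.exp(np.interp(np.log(E), np.log(grid_e), np.log(grid_mu)))
    out = mu_rho * m.density
    return out if out.ndim else float(out)


class PhysicsTables:
    """Pre-tabulated coefficients for fast vectorized lookup in transport.

    One log-energy grid per material; lookups use ``np.interp`` on log(E).
    ``delta_threshold`` (MeV) splits collision losses into a restricted
    continuous part (``scol_r``) and explicit Moller delta-ray production
    with a 1/T^2 spectrum up to E/2.
    """

    def __init__(
        self,
        materials: list[Material],
        n_points: int = 400,
        delta_threshold: float = 0.25,
    ):
        self.materials = list(materials)
        self.emin = np.array(
            [m.electron_energy_cutoff / 1000.0 for m in materials]
        )
        self.pcut = np.array([m.photon_energy_cutoff / 1000.0 for m in materials])
        self.density = np.array([m.density for m in materials])
        self.bohr_coeff = np.array(
            [_K_BOHR * m.z_over_a * m.density for m in materials]
        )  # MeV^2 per cm
        self.x0_cm = np.array(
            [m.radiation_length / m.density for m in materials]
        )
        self.delta_threshold = float(delta_threshold)
        #: restricted straggling variance per cm: sub-threshold transfers only
        #: (supra-threshold fluctuations are carried by explicit delta rays)
        self.bohr_coeff_restricted = np.array(
            [_K_BETHE * m.z_over_a * m.density * delta_threshold for m in materials]
        )
        #: Rutherford-like prefactor K * rho * Z/A, MeV/cm
        self.moller_coeff = np.array(
            [_K_BETHE * m.z_over_a * m.density for m in materials]
        )
        self._loge = []
        self._scol = []
        self._scol_r = []
        self._srad = []
        self._mu = []
        td = self.delta_threshold
        for i, m in enumerate(materials):
            eg = np.geomspace(self.emin[i], E_MAX_MEV, n_points)
            self._loge.append(np.log(eg))
            scol = np.asarray(collision_stopping_power(m, eg))
            self._scol.append(scol)
            # mean energy carried off by deltas above threshold, per cm
            gamma = 1.0 + eg / ELECTRON_MASS_MEV
            beta2 = 1.0 - 1.0 / (gamma * gamma)
            prod = np.where(
                eg > 2.0 * td,
                self.moller_coeff[i] / beta2 * np.log(np.maximum(eg / (2.0 * td), 1.0)),
                0.0,
            )
            self._scol_r.append(np.maximum(scol - prod, 0.1 * scol))
            self._srad.append(np.asarray(radiative_stopping_power(m, eg)))
            pg = np.geomspace(self.pcut[i], E_MAX_MEV, n_points)
            self._mu.append(
                (np.log(pg), np.asarray(photon_attenuation(m, pg)))
            )

    def scol(self, mat_id: int, E: np.ndarray) -> np.ndarray:
        le = np.log(np.clip(E, np.exp(self._loge[mat_id][0]), E_MAX_MEV))
        return np.interp(le, self._loge[mat_id], self._scol[mat_id])

    def scol_r(self, mat_id: int, E: np.ndarray) -> np.ndarray:
        """Collision stopping power restricted to losses below the delta cut."""
        le = np.log(np.clip(E, np.exp(self._loge[mat_id][0]), E_MAX_MEV))
        return np.interp(le, self._loge[mat_id], self._scol_r[mat_id])

    def delta_rate(self, mat_id, E: np.ndarray) -> np.ndarray:
        """Delta-ray production probability per cm (1/T^2 spectrum, T in
        [threshold, E/2])."""
        td = self.delta_threshold
        gamma = 1.0 + E / ELECTRON_MASS_MEV
        beta2 = 1.0 - 1.0 / (gamma * gamma)
        rate = self.moller_coeff[mat_id] / beta2 * np.maximum(1.0 / td - 2.0 / E, 0.0)
        return np.where(E > 2.0 * td, rate, 0.0)

    def srad(self, mat_id: int, E: np.ndarray) -> np.ndarray:
        le = np.log(np.clip(E, np.exp(self._loge[mat_id][0]), E_MAX_MEV))
        return np.interp(le, self._loge[mat_id], self._srad[mat_id])

    def mu(self, mat_id: int, E: np.ndarray) -> np.ndarray:
        lg, mu = self._mu[mat_id]
        le = np.log(np.clip(E, np.exp(lg[0]), E_MAX_MEV))
        return np.interp(le, lg, mu)
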