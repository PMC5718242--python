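"""Condensed-history Monte Carlo transport of electrons and photons.

Class-I scheme: continuous collision loss along steps (optionally with
Gaussian Bohr straggling), net deflection sampled per step from Highland's
multiple-scattering sigma, and radiative loss banked along the track and
emitted as forward bremsstrahlung photons in packets once the bank exceeds
a threshold (the minimal model that gives nonzero transmission through a
stopping disc). Photons are tracked to their first interaction and deposit
there (kerma approximation).

The engine is fully vectorized over particles; scalar ``step_electron`` /
``step_photon`` wrappers expose single-particle semantics for testing. All
internal lengths are mm, energies MeV; stopping powers are MeV/cm, hence
the factor 10 at every energy-loss evaluation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from . import geometry as geo
from .geometry import GeometryModel
from .materials import get_material
from .physics import PhysicsTables
from .scoring import VoxelDoseGrid
from .source import BeamSourceModel, PRESETS, sample_primaries

__all__ = [
    "ParticleState",
    "TransportSettings",
    "RunStats",
    "step_electron",
    "step_photon",
    "run_simulation",
]

#: materials indexed by region id (AIR..DISC_PB = 0..5)
_REGION_MATERIAL_ORDER = ["air", "titanium", "pmma", "water", "aluminum", "lead"]

_MM_PER_CM = 10.0


@dataclass
class ParticleState:
    kind: str  # "electron" | "photon"
    position: np.ndarray
    direction: np.ndarray
    energy: float
    alive: bool = True
    batch: int = 0
    rad_bank: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.energy < 0:
            raise ValueError("energy must be >= 0")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be unit norm")


@dataclass(frozen=True)
class TransportSettings:
    """Step limits, cutoffs and process switches."""

    max_step: float = 0.25  # mm, in the scoring medium (half a voxel)
    max_fractional_energy_loss: float = 0.05
    brems_enabled: bool = True
    straggling_enabled: bool = True
    scattering_enabled: bool = True
    #: radiative bank emitted as one photon once it exceeds this (MeV)
    brems_pack_energy: float = 0.05
    #: explicit Moller delta-ray production above this kinetic energy (MeV);
    #: continuous losses use the correspondingly restricted stopping power
    delta_enabled: bool = True
    delta_threshold: float = 0.25
    #: electrons below this are absorbed on the spot (residual range < 0.15 mm
    #: in water); set to 0 to track down to the material cutoffs
    local_deposit_below: float = 0.10
    #: electrons deeper than this radially inside the collimator wall are
    #: absorbed where they stand (they cannot re-emerge with useful energy)
    collimator_kill_depth: float = 10.0
    #: per-region step caps (mm); None entries fall back to ``max_step``
    region_max_step: tuple = (250.0, 0.05, 1.0, None, 0.1, 0.1)
    #: optional per-material electron cutoff overrides, keV, by material name
    electron_cutoff_overrides: tuple = ()

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if not 0 < self.max_fractional_energy_loss < 1:
            raise ValueError("max_fractional_energy_loss must be in (0, 1)")

    def electron_cutoffs_mev(self) -> np.ndarray:
        over = dict(self.electron_cutoff_overrides)
        cuts = []
        for name in _REGION_MATERIAL_ORDER:
            kev = over.get(name, get_material(name).electron_energy_cutoff)
            cuts.append(kev / 1000.0)
        return np.array(cuts)

    def region_steps(self) -> np.ndarray:
        return np.array(
            [self.max_step if s is None else s for s in self.region_max_step]
        )


@dataclass
class RunStats:
    n_histories: int
    n_batches: int
    seed: int
    injected_mev: float = 0.0
    deposited_mev: float = 0.0
    escaped_mev: float = 0.0
    outside_detector_mev: float = 0.0
    n_photons: int = 0
    wall_time_s: float = 0.0

    def conservation_residual(self) -> float:
        """|injected - deposited - escaped| / injected."""
        if self.injected_mev == 0:
            return 0.0
        return abs(
            self.injected_mev - self.deposited_mev - self.escaped_mev
        ) / self.injected_mev


class _Tally:
    __slots__ = ("deposited", "escaped")

    def __init__(self) -> None:
        self.deposited = 0.0
        self.escaped = 0.0


_TABLE_CACHE: dict[float, PhysicsTables] = {}


def _default_tables(delta_threshold: float = 0.25) -> PhysicsTables:
    if delta_threshold not in _TABLE_CACHE:
        _TABLE_CACHE[delta_threshold] = PhysicsTables(
            [get_material(n) for n in _REGION_MATERIAL_ORDER],
            delta_threshold=delta_threshold,
        )
    return _TABLE_CACHE[delta_threshold]


def _per_material(tables: PhysicsTables, rid: np.ndarray, E: np.ndarray, which: str):
    """Grouped table lookup per region id."""
    out = np.empty_like(E)
    fn = getattr(tables, which)
    for m in np.unique(rid):
        sel = rid == m
        out[sel] = fn(int(m), E[sel])
    return out


def _rotate(dirs: np.ndarray, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Deflect unit vectors by polar angle theta (about themselves), azimuth phi."""
    helper = np.zeros_like(dirs)
    use_x = np.abs(dirs[:, 0]) < 0.9
    helper[use_x, 0] = 1.0
    helper[~use_x, 1] = 1.0
    e1 = np.cross(dirs, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(dirs, e1)
    ct, st = np.cos(theta), np.sin(theta)
    new = (
        ct[:, None] * dirs
        + st[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    new /= np.linalg.norm(new, axis=1, keepdims=True)
    return new


def _deposit(
    grid: VoxelDoseGrid | None,
    tally: _Tally,
    pos: np.ndarray,
    e: np.ndarray,
    batch: np.ndarray,
) -> None:
    if e.size == 0:
        return
    tally.deposited += float(e.sum())
    if grid is not None:
        grid.deposit_v(pos, e, batch)


def sample_pending_k(
    E: np.ndarray, kmin: float, rng: np.random.Generator
) -> np.ndarray:
    """Next bremsstrahlung photon energy, drawn from a 1/k spectrum on
    [kmin, E] (log-uniform)."""
    top = np.maximum(E, kmin)
    return kmin * (top / kmin) ** rng.random(np.shape(E) or None)


def _advance_electrons(
    pos: np.ndarray,
    dirs: np.ndarray,
    E: np.ndarray,
    bank: np.ndarray,
    pending: np.ndarray,
    batch: np.ndarray,
    model: GeometryModel,
    tables: PhysicsTables,
    settings: TransportSettings,
    rng: np.random.Generator,
    grid: VoxelDoseGrid | None,
    tally: _Tally,
    photon_buf: list,
    electron_buf: list | None = None,
):
    """One condensed-history step for every particle; returns surviving arrays."""
    rid = model.locate_ids(pos)

    # escape through the world boundary
    gone = rid < 0
    if np.any(gone):
        tally.escaped += float(E[gone].sum() + bank[gone].sum())

    # absorption: below cutoff / local-deposit threshold, or deep in the
    # collimator wall
    ecut = settings.electron_cutoffs_mev()
    kill_e = np.maximum(ecut[np.clip(rid, 0, None)], settings.local_deposit_below)
    absorb = ~gone & (E <= kill_e)
    if settings.collimator_kill_depth is not None:
        r = np.hypot(pos[:, 1], pos[:, 2])
        deep = (rid == geo.PMMA) & (
            r > model.collimator_inner_diameter / 2.0 + settings.collimator_kill_depth
        )
        absorb |= ~gone & deep
    if np.any(absorb):
        # flush sizable radiative banks as photons, absorb the rest locally
        flush = absorb & (bank >= settings.brems_pack_energy) & settings.brems_enabled
        if np.any(flush):
            photon_buf.append(
                (pos[flush].copy(), dirs[flush].copy(), bank[flush].copy(),
                 batch[flush].copy())
            )
        rest = np.where(flush, 0.0, bank)
        e_abs = E[absorb] + rest[absorb]
        _deposit(grid, tally, pos[absorb], e_abs, batch[absorb])

    alive = ~(gone | absorb)
    if not np.any(alive):
        return tuple(a[:0] for a in (pos, dirs, E, bank, pending, batch))

    pos, dirs, E = pos[alive], dirs[alive], E[alive]
    bank, pending, batch, rid = bank[alive], pending[alive], batch[alive], rid[alive]

    # step length: region cap, fractional-energy-loss cap, boundary
    col_kind = "scol_r" if settings.delta_enabled else "scol"
    scol = _per_material(tables, rid, E, col_kind)
    srad = _per_material(tables, rid, E, "srad")
    stot = _per_material(tables, rid, E, "scol") + srad
    s_cap = settings.region_steps()[rid]
    s_el = settings.max_fractional_energy_loss * E / stot * _MM_PER_CM
    d_bound = model.distance_to_boundary_v(pos, dirs)
    s = np.minimum(np.minimum(s_cap, s_el), d_bound)
    s = np.maximum(s, 1e-6)
    at_boundary = s >= d_bound - 1e-12

    # midpoint (RK2) energy loss for an accurate CSDA path length
    e_half = np.clip(E - stot * s / (2.0 * _MM_PER_CM), tables.emin[rid], None)
    scol2 = _per_material(tables, rid, e_half, col_kind)
    srad2 = _per_material(tables, rid, e_half, "srad")
    de_col = scol2 * s / _MM_PER_CM
    de_rad = srad2 * s / _MM_PER_CM if settings.brems_enabled else 0.0

    if settings.straggling_enabled:
        coeff = (
            tables.bohr_coeff_restricted
            if settings.delta_enabled
            else tables.bohr_coeff
        )
        sigma = np.sqrt(coeff[rid] * s / _MM_PER_CM)
        de_col = de_col + sigma * rng.standard_normal(E.size)
        de_col = np.maximum(de_col, 0.0)

    de_tot = de_col + (de_rad if settings.brems_enabled else srad2 * s / _MM_PER_CM)
    # never lose more than we have; scale both channels proportionally
    over = de_tot > E
    if np.any(over):
        scale = np.where(over, E / np.maximum(de_tot, 1e-300), 1.0)
        de_col = de_col * scale
        de_rad = de_rad * scale if settings.brems_enabled else de_rad
        de_tot = np.minimum(de_tot, E)

    mid = pos + dirs * (s / 2.0)[:, None]
    if settings.brems_enabled:
        _deposit(grid, tally, mid, de_col, batch)
        bank = bank + de_rad
        # A photon of the pre-sampled energy is emitted once the radiative
        # bank covers it; energy is conserved exactly while the emitted
        # spectrum keeps the hardness of the 1/k draw.
        emit = bank >= pending
        if np.any(emit):
            photon_buf.append(
                (mid[emit].copy(), dirs[emit].copy(), pending[emit].copy(),
                 batch[emit].copy())
            )
            bank = np.where(emit, bank - pending, bank)
            pending = np.where(
                emit, sample_pending_k(E, settings.brems_pack_energy, rng), pending
            )
    else:
        _deposit(grid, tally, mid, de_tot, batch)

    pos = pos + dirs * (s + np.where(at_boundary, 1e-6, 0.0))[:, None]
    E = E - de_tot

    if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(E)):
        bad = ~(np.all(np.isfinite(pos), axis=1) & np.isfinite(E))
        raise FloatingPointError(
            f"non-finite particle state: pos={pos[bad][:3]}, E={E[bad][:3]}"
        )

    if settings.delta_enabled and electron_buf is not None:
        td = tables.delta_threshold
        rate = tables.delta_rate(rid, np.maximum(E, 2.0 * td))
        prob = np.where(E > 2.0 * td, rate * s / _MM_PER_CM, 0.0)
        make = rng.random(E.size) < prob
        if np.any(make):
            em = E[make]
            # 1/T^2 spectrum on [td, E/2]
            u = rng.random(em.size)
            t_delta = 1.0 / (1.0 / td - u * (1.0 / td - 2.0 / em))
            t_delta = np.minimum(t_delta, em / 2.0)
            mc2 = 2.0 * 0.51099895
            cos_d = np.sqrt(
                np.clip(t_delta * (em + mc2) / (em * (t_delta + mc2)), 0.0, 1.0)
            )
            theta_d = np.arccos(cos_d)
            phi_d = rng.uniform(0.0, 2.0 * np.pi, em.size)
            d_dirs = _rotate(dirs[make], theta_d, phi_d)
            electron_buf.append(
                (pos[make].copy(), d_dirs, t_delta, batch[make].copy())
            )
            E = E.copy()
            E[make] = em - t_delta

    if settings.scattering_enabled:
        pc2 = E * (E + 1.0219979)
        beta_pc = pc2 / (E + 0.51099895)
        t_rel = np.maximum(
            s / _MM_PER_CM / tables.x0_cm[rid], 1e-30
        )
        theta0 = 13.6 / np.maximum(beta_pc, 1e-12) * np.sqrt(t_rel) * (
            1.0 + 0.038 * np.log(t_rel)
        )
        theta0 = np.maximum(theta0, 0.0)
        theta = np.abs(theta0 * rng.standard_normal(E.size))
        phi = rng.uniform(0.0, 2.0 * np.pi, E.size)
        dirs = _rotate(dirs, theta, phi)

    return pos, dirs, E, bank, pending, batch


def _advance_photons(
    pos: np.ndarray,
    dirs: np.ndarray,
    E: np.ndarray,
    batch: np.ndarray,
    model: GeometryModel,
    tables: PhysicsTables,
    settings: TransportSettings,
    rng: np.random.Generator,
    grid: VoxelDoseGrid | None,
    tally: _Tally,
):
    """One free-flight segment for every photon; returns survivors."""
    rid = model.locate_ids(pos)
    gone = rid < 0
    if np.any(gone):
        tally.escaped += float(E[gone].sum())
    absorb = ~gone & (E <= tables.pcut[np.clip(rid, 0, None)])
    if np.any(absorb):
        _deposit(grid, tally, pos[absorb], E[absorb], batch[absorb])
    alive = ~(gone | absorb)
    if not np.any(alive):
        return tuple(a[:0] for a in (pos, dirs, E, batch))
    pos, dirs, E, batch, rid = pos[alive], dirs[alive], E[alive], batch[alive], rid[alive]

    mu_mm = _per_material(tables, rid, E, "mu") / _MM_PER_CM
    s_int = rng.exponential(1.0 / np.maximum(mu_mm, 1e-300))
    d_bound = model.distance_to_boundary_v(pos, dirs)
    interact = s_int < d_bound
    if np.any(interact):
        hit = pos[interact] + dirs[interact] * s_int[interact][:, None]
        _deposit(grid, tally, hit, E[interact], batch[interact])
    cont = ~interact
    pos = pos[cont] + dirs[cont] * (d_bound[cont] + 1e-6)[:, None]
    return pos, dirs[cont], E[cont], batch[cont]


def _run_photon_buffer(
    photon_buf: list,
    model,
    tables,
    settings,
    rng,
    grid,
    tally,
    max_iter: int = 200,
) -> int:
    if not photon_buf:
        return 0
    pos = np.concatenate([b[0] for b in photon_buf])
    dirs = np.concatenate([b[1] for b in photon_buf])
    E = np.concatenate([b[2] for b in photon_buf])
    batch = np.concatenate([b[3] for b in photon_buf])
    photon_buf.clear()
    n = E.size
    it = 0
    while E.size and it < max_iter:
        pos, dirs, E, batch = _advance_photons(
            pos, dirs, E, batch, model, tables, settings, rng, grid, tally
        )
        it += 1
    if E.size:  # pathological stragglers: absorb where they stand
        _deposit(grid, tally, pos, E, batch)
    return n


# -- public single-particle operations -------------------------------------


def step_electron(
    state: ParticleState,
    settings: TransportSettings,
    physics: PhysicsTables,
    geometry: GeometryModel,
    rng: np.random.Generator,
):
    """Advance one electron by one condensed-history step.

    Returns ``(new_state, deposited_energy, photon_or_None, delta_rays)``.
    A state at or below the cutoff is absorbed on the spot (killed, full
    local deposit).
    """
    if state.kind != "electron":
        raise ValueError("step_electron requires an electron")
    grid = None
    tally = _Tally()
    buf: list = []
    ebuf: list = []
    out = _advance_electrons(
        state.position[None, :].copy(),
        state.direction[None, :].copy(),
        np.array([state.energy]),
        np.array([state.rad_bank]),
        sample_pending_k(np.array([state.energy]), settings.brems_pack_energy, rng),
        np.array([state.batch]),
        geometry,
        physics,
        settings,
        rng,
        grid,
        tally,
        buf,
        ebuf,
    )
    photon = None
    if buf:
        p, d, e, b = buf[0]
        photon = ParticleState("photon", p[0], d[0], float(e[0]), batch=int(b[0]))
    deltas = [
        ParticleState("electron", p[i], d[i], float(e[i]), batch=int(b[i]))
        for p, d, e, b in ebuf
        for i in range(len(e))
    ]
    if out[2].size == 0:
        new = replace_state(state, alive=False, energy=0.0, rad_bank=0.0)
    else:
        pos, dirs, E, bank, _, _ = out
        new = ParticleState(
            "electron", pos[0], dirs[0], float(E[0]), True, state.batch, float(bank[0])
        )
    return new, tally.deposited + tally.escaped * 0.0, photon, deltas


def replace_state(state: ParticleState, **kw) -> ParticleState:
    d = dict(
        kind=state.kind,
        position=state.position.copy(),
        direction=state.direction.copy(),
        energy=state.energy,
        alive=state.alive,
        batch=state.batch,
        rad_bank=state.rad_bank,
    )
    d.update(kw)
    return ParticleState(**d)


def step_photon(
    state: ParticleState,
    settings: TransportSettings,
    physics: PhysicsTables,
    geometry: GeometryModel,
    rng: np.random.Generator,
):
    """Track one photon to absorption or escape; returns list of (pos, MeV)."""
    if state.kind != "photon":
        raise ValueError("step_photon requires a photon")

    events: list[tuple[np.ndarray, float]] = []

    class _RecTally(_Tally):
        pass

    tally = _RecTally()

    class _Rec:
        def deposit_v(self, p, e, b):
            for i in range(len(e)):
                events.append((p[i].copy(), float(e[i])))

    pos = state.position[None, :].copy()
    dirs = state.direction[None, :].copy()
    E = np.array([state.energy])
    batch = np.array([state.batch])
    it = 0
    while E.size and it < 200:
        pos, dirs, E, batch = _advance_photons(
            pos, dirs, E, batch, geometry, physics, settings, rng, _Rec(), tally
        )
        it += 1
    return events


# -- full simulation -------------------------------------------------------


def run_simulation(
    config=None,
    *,
    source: BeamSourceModel | str | None = None,
    geometry: GeometryModel | None = None,
    settings: TransportSettings | None = None,
    n_histories: int | None = None,
    n_batches: int = 10,
    voxel_size: float = 0.5,
    seed: int | None = None,
    chunk_size: int = 100_000,
) -> tuple[VoxelDoseGrid, RunStats]:
    """Transport a full run and return the scored grid plus run statistics.

    Either pass a :class:`iortsim.config.RunConfig` or the individual pieces.
    Deterministic for a fixed seed (single worker); batches use spawned
    sub-seeds so the batch structure is reproducible.
    """
    if config is not None:
        source = config.source_model()
        geometry = config.geometry_model()
        settings = config.transport_settings()
        n_histories = config.transport.n_histories
        n_batches = config.transport.n_batches
        voxel_size = config.scoring.voxel_size
        seed = config.seed
    if isinstance(source, str):
        source = PRESETS[source]
    if geometry is None:
        geometry = GeometryModel()
    if settings is None:
        settings = TransportSettings(max_step=min(0.25, voxel_size / 2.0))
    if n_histories is None:
        n_histories = source.n_histories
    if seed is None:
        seed = source.seed
    if n_histories < n_batches:
        raise ValueError("n_histories must be >= number of batches")

    tables = _default_tables()
    grid = VoxelDoseGrid.for_detector(geometry, voxel_size, n_batches)
    tally = _Tally()
    stats = RunStats(n_histories=n_histories, n_batches=n_batches, seed=seed)
    t0 = time.perf_counter()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_batches)
    sizes = np.full(n_batches, n_histories // n_batches)
    sizes[: n_histories % n_batches] += 1

    source_plane = -geometry.ssd
    for b in range(n_batches):
        rng = np.random.default_rng(children[b])
        remaining = int(sizes[b])
        grid.batch_histories[b] += remaining
        while remaining > 0:
            m = min(chunk_size, remaining)
            remaining -= m
            pos, dirs, E = sample_primaries(source, m, rng, x_plane_mm=source_plane)
            stats.injected_mev += float(E.sum())
            bank = np.zeros(m)
            pending = sample_pending_k(E, settings.brems_pack_energy, rng)
            batch = np.full(m, b, dtype=np.int64)
            photon_buf: list = []
            electron_buf: list = []
            it = 0
            while E.size and it < 20_000:
                pos, dirs, E, bank, pending, batch = _advance_electrons(
                    pos, dirs, E, bank, pending, batch,
                    geometry, tables, settings, rng, grid, tally,
                    photon_buf, electron_buf,
                )
                if electron_buf:
                    sp, sd, se, sb = (np.concatenate(a) for a in zip(*electron_buf))
                    electron_buf.clear()
                    pos = np.concatenate([pos, sp])
                    dirs = np.concatenate([dirs, sd])
                    E = np.concatenate([E, se])
                    bank = np.concatenate([bank, np.zeros(se.size)])
                    pending = np.concatenate(
                        [pending, sample_pending_k(se, settings.brems_pack_energy, rng)]
                    )
                    batch = np.concatenate([batch, sb])
                it += 1
                if sum(x[2].size for x in photon_buf) > 400_000:
                    stats.n_photons += _run_photon_buffer(
                        photon_buf, geometry, tables, settings, rng, grid, tally
                    )
            if E.size:
                _deposit(grid, tally, pos, E + bank, batch)
            stats.n_photons += _run_photon_buffer(
                photon_buf, geometry, tables, settings, rng, grid, tally
            )

    grid.n_histories = n_histories
    stats.deposited_mev = tally.deposited
    stats.escaped_mev = tally.escaped
    stats.outside_detector_mev = grid.outside_tally
    stats.wall_time_s = time.perf_counter() - t0
    return grid, stats
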