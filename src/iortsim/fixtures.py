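"""Synthetic fixture generator.

Stands in for full Monte Carlo output when testing the analysis operations:
analytic depth-dose curves (build-up, sigmoid falloff, flat tail), flat-top
lateral profiles with controllable asymmetry, leakage grids with a known
hot spot, and top-hat film maps. Generator parameters are the ground truth
for the tests that consume them. Deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np

from .analysis import DepthDoseCurve, LateralProfile
from .scoring import VoxelDoseGrid

__all__ = ["generate_fixture", "analytic_pdd_function"]


def analytic_pdd_function(
    r100: float,
    r50: float,
    rp: float,
    tail_percent: float = 1.5,
    surface: float = 85.0,
    shoulder_sigma: float = 0.4,
):
    """Return ``f(x)`` in percent with exact 50% crossing at ``r50`` and a
    tangent/tail-line intercept at ``rp``.

    The distal falloff is a linear ramp ending at ``rp`` (where it meets the
    constant bremsstrahlung tail), convolved with a narrow Gaussian so the
    shoulders are smooth; on the linear section the tangent at the steepest
    point is the ramp itself, so the practical-range construction recovers
    ``rp``, and the 50% crossing sits on the ramp at ``r50`` exactly.
    """
    if not 0 < r100 < r50 < rp:
        raise ValueError("need 0 < r100 < r50 < rp")
    if not 0 <= tail_percent < 50:
        raise ValueError("tail_percent must be in [0, 50)")
    t = tail_percent
    g50 = (50.0 - t) / (100.0 - t)
    b = rp
    a = b - (rp - r50) / g50
    if a <= r100:
        raise ValueError("falloff ramp would start before the dose maximum")
    sig = shoulder_sigma
    sqrt2 = np.sqrt(2.0)

    def _phi(u):
        return np.exp(-(u * u) / 2.0) / np.sqrt(2.0 * np.pi)

    def _cdf(u):
        from scipy.special import erf

        return 0.5 * (1.0 + erf(u / sqrt2))

    def f(x):
        x = np.asarray(x, dtype=float)
        alpha = (a - x) / sig
        beta = (b - x) / sig
        p_ab = _cdf(beta) - _cdf(alpha)
        # smoothed clipped ramp: E[R(Y)], Y ~ N(x, sig^2)
        g = _cdf(alpha) + ((b - x) * p_ab - sig * (_phi(alpha) - _phi(beta))) / (b - a)
        fall = t + (100.0 - t) * g
        build = surface + (100.0 - surface) * np.clip(x / r100, 0.0, 1.0) ** 2
        return np.where(x <= r100, build, fall)

    return f, a, b


def _fixture_analytic_pdd(params: dict, rng: np.random.Generator):
    r100 = params.get("r100", 15.0)
    r50 = params.get("r50", 34.8)
    rp = params.get("rp", 1.3 * r50)
    tail = params.get("tail_percent", 1.5)
    step = params.get("step", 0.25)
    depth_max = params.get("depth_max", max(70.0, rp + 15.0))
    noise = params.get("noise", 0.0)
    f, _, _ = analytic_pdd_function(r100, r50, rp, tail)
    depths = np.arange(step / 2.0, depth_max, step)
    vals = f(depths)
    if noise:
        vals = np.maximum(vals + rng.normal(0.0, noise, vals.shape), 0.0)
    if params.get("as_grid"):
        width = params.get("width", 40.0)
        vox = params.get("voxel_size", step)
        dims = (len(depths), int(width / vox), int(width / vox))
        grid = VoxelDoseGrid(
            origin=np.array([0.0, -width / 2, -width / 2]),
            voxel_size=vox,
            dims=dims,
            n_batches=1,
        )
        ys = grid.axis_coords(1)
        zs = grid.axis_coords(2)
        # cone beam: lateral Gaussian widening with depth
        sigma0 = params.get("sigma0", 3.0)
        spread = params.get("spread", 0.15)
        sig = sigma0 + spread * depths
        r2 = ys[:, None] ** 2 + zs[None, :] ** 2
        grid.values[:] = (
            vals[:, None, None] * np.exp(-r2[None] / (2.0 * sig[:, None, None] ** 2))
        )
        grid.batch_accumulators[0] = grid.values.astype(np.float32)
        grid.n_histories = 1
        return grid
    return DepthDoseCurve(depths, vals / vals.max() * 100.0, aperture=2.0, raw=vals)


def _fixture_flat_profile(params: dict, rng: np.random.Generator):
    width = params.get("width", 100.0)
    penumbra = params.get("penumbra", 3.0)
    asymmetry = params.get("asymmetry", 0.0)
    noise = params.get("noise", 0.0)
    step = params.get("step", 0.5)
    half_extent = params.get("half_extent", 75.0)
    offsets = np.arange(-half_extent + step / 2.0, half_extent, step)
    edge = 1.0 / (1.0 + np.exp((np.abs(offsets) - width / 2.0) / penumbra))
    vals = 100.0 * edge * (1.0 + asymmetry * offsets / width)
    if noise:
        vals = np.maximum(vals + rng.normal(0.0, noise, vals.shape), 0.0)
    center = vals[np.argmin(np.abs(offsets))]
    return LateralProfile(offsets, vals / center * 100.0, depth=params.get("depth", 15.0))


def _fixture_disc_leak(params: dict, rng: np.random.Generator):
    dims = tuple(params.get("dims", (40, 40, 40)))
    vox = params.get("voxel_size", 0.5)
    background = params.get("background", 0.01)
    amp = params.get("amplitude", 1.0)
    center = np.asarray(params.get("center", (5.0, 0.0, 0.0)), dtype=float)
    sigma = params.get("sigma", 2.0)
    noise = params.get("noise", 0.0)
    grid = VoxelDoseGrid(
        origin=np.array([0.0, -dims[1] * vox / 2, -dims[2] * vox / 2]),
        voxel_size=vox,
        dims=dims,
        n_batches=1,
    )
    xs, ys, zs = (grid.axis_coords(i) for i in range(3))
    r2 = (
        (xs[:, None, None] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[None, None, :] - center[2]) ** 2
    )
    grid.values[:] = background + amp * np.exp(-r2 / (2.0 * sigma**2))
    if noise:
        grid.values += np.abs(rng.normal(0.0, noise, grid.values.shape))
    grid.batch_accumulators[0] = grid.values.astype(np.float32)
    grid.n_histories = 1
    return grid


def _fixture_film_tophat(params: dict, rng: np.random.Generator):
    radius = params.get("radius", 30.0)
    cy, cz = params.get("center", (0.0, 0.0))
    pixel = params.get("pixel", 0.5)
    half = params.get("half_extent", 60.0)
    noise = params.get("noise", 0.0)
    ys = np.arange(-half + pixel / 2.0, half, pixel)
    zs = ys.copy()
    r2 = (ys[:, None] - cy) ** 2 + (zs[None, :] - cz) ** 2
    film = np.where(r2 <= radius**2, 100.0, 0.0)
    if noise:
        film = np.maximum(film + rng.normal(0.0, noise, film.shape), 0.0)
    return film, ys, zs


_KINDS = {
    "analytic_pdd": _fixture_analytic_pdd,
    "flat_profile": _fixture_flat_profile,
    "disc_leak": _fixture_disc_leak,
    "film_tophat": _fixture_film_tophat,
}


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Build a synthetic grid/curve/film whose parameters are ground truth."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](dict(params or {}), np.random.default_rng(seed))
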