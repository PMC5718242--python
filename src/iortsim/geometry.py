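"""Beamline, phantom and shielding-disc geometry.

Coordinate convention: ``x`` is the beam axis in mm, 0 at the phantom
surface, positive downstream (into the water); ``y`` and ``z`` are
transverse. The source plane sits at ``x = -ssd``.

Regions, walking downstream:

* titanium exit window: ``-ssd <= x < -ssd + window_thickness``, ``r <= ri``
* air column inside the collimator bore: up to ``x = 0``, ``r <= ri``
* PMMA collimating structure: ``ri < r <= ro`` for ``x < 0`` (the accelerator
  head internals and the secondary collimator are modelled as one PMMA tube;
  exact manufacturer drawings are proprietary, so the wall thickness is a
  configurable assumption)
* water phantom: box ``0 <= x <= phantom_size``, ``|y|,|z| <= phantom_size/2``
* two-layer Al-Pb disc, arbitrary pose, inside the phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .materials import Material, get_material

__all__ = [
    "DiscPose",
    "GeometryModel",
    "build_geometry",
    "locate",
    "distance_to_boundary",
    "REGION_LABELS",
    "REGION_MATERIALS",
]

# region ids used by the vectorized transport kernels
OUTSIDE, AIR, WINDOW, PMMA, WATER, DISC_AL, DISC_PB = -1, 0, 1, 2, 3, 4, 5

REGION_LABELS = {
    OUTSIDE: "outside",
    AIR: "air gap",
    WINDOW: "window",
    PMMA: "PMMA",
    WATER: "water",
    DISC_AL: "disc-Al",
    DISC_PB: "disc-Pb",
}

REGION_MATERIALS = {
    AIR: "air",
    WINDOW: "titanium",
    PMMA: "pmma",
    WATER: "water",
    DISC_AL: "aluminum",
    DISC_PB: "lead",
}

_EPS = 1e-9


@dataclass(frozen=True)
class DiscPose:
    """Pose of the two-layer shielding disc inside the phantom.

    ``depth`` is the x coordinate (mm, from the phantom surface) of the
    proximal face for the untilted pose; tilt rotates the disc about its
    geometric centre, around the diameter parallel to z. ``flipped`` means
    the lead face is toward the beam (180 degree orientation error).
    """

    depth: float
    lateral_shift: float = 0.0
    tilt: float = 0.0
    flipped: bool = False
    al_thickness: float = 4.0
    pb_thickness: float = 2.0
    diameter: float = 120.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("disc diameter must be > 0")
        if self.al_thickness <= 0 or self.pb_thickness <= 0:
            raise ValueError("disc layer thicknesses must be > 0")
        if abs(self.tilt) > 90:
            raise ValueError("|tilt| must be <= 90 degrees")

    @property
    def thickness(self) -> float:
        return self.al_thickness + self.pb_thickness

    @property
    def center(self) -> np.ndarray:
        """Disc centre in world coordinates (mm)."""
        return np.array(
            [self.depth + self.thickness / 2.0, self.lateral_shift, 0.0]
        )

    @property
    def distal_plane(self) -> float:
        """x of the distal face for the nominal (untilted) pose, mm."""
        return self.depth + self.thickness

    def to_local(self, pts: np.ndarray) -> np.ndarray:
        """World -> disc-local coordinates (u along disc normal, w = z)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        th = math.radians(self.tilt)
        c, s = math.cos(th), math.sin(th)
        dx = pts[:, 0] - self.center[0]
        dy = pts[:, 1] - self.center[1]
        out = np.empty_like(pts)
        out[:, 0] = c * dx + s * dy
        out[:, 1] = -s * dx + c * dy
        out[:, 2] = pts[:, 2]
        return out

    def to_world(self, local: np.ndarray) -> np.ndarray:
        local = np.atleast_2d(np.asarray(local, dtype=float))
        th = math.radians(self.tilt)
        c, s = math.cos(th), math.sin(th)
        out = np.empty_like(local)
        out[:, 0] = c * local[:, 0] - s * local[:, 1] + self.center[0]
        out[:, 1] = s * local[:, 0] + c * local[:, 1] + self.center[1]
        out[:, 2] = local[:, 2]
        return out

    def rotate_dirs(self, dirs: np.ndarray) -> np.ndarray:
        """World direction -> disc-local direction."""
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        th = math.radians(self.tilt)
        c, s = math.cos(th), math.sin(th)
        out = np.empty_like(dirs)
        out[:, 0] = c * dirs[:, 0] + s * dirs[:, 1]
        out[:, 1] = -s * dirs[:, 0] + c * dirs[:, 1]
        out[:, 2] = dirs[:, 2]
        return out


@dataclass(frozen=True)
class GeometryModel:
    """World model: beamline components, phantom, detector and disc."""

    ssd: float = 1000.0
    collimator_inner_diameter: float = 100.0
    collimator_outer_diameter: float = 140.0
    window_thickness: float = 0.06
    phantom_size: float = 200.0
    detector_depth: float = 70.0
    detector_width: float = 150.0
    disc: DiscPose | None = None
    reference_disc: DiscPose | None = None

    def __post_init__(self) -> None:
        if self.ssd <= 0:
            raise ValueError("ssd must be > 0")
        if not 0 < self.collimator_inner_diameter < self.collimator_outer_diameter:
            raise ValueError("collimator diameters inconsistent (overlapping solids)")
        if self.window_thickness <= 0 or self.window_thickness >= self.ssd:
            raise ValueError("window thickness inconsistent with SSD")
        if self.detector_depth > self.phantom_size or (
            self.detector_width > self.phantom_size
        ):
            raise ValueError("detector must fit inside the phantom")
        for pose in (self.disc, self.reference_disc):
            if pose is None:
                continue
            if pose.diameter <= self.collimator_inner_diameter:
                raise ValueError(
                    "disc diameter must exceed the collimator inner diameter"
                )
            if pose.distal_plane > self.phantom_size or pose.depth < 0:
                raise ValueError("disc does not fit inside the phantom")

    @property
    def region_planes_pose(self) -> DiscPose:
        """Pose defining the treatment / normal-tissue planes.

        The normal-tissue zone is fixed by the nominal (untilted, unshifted)
        reference pose so that with/without-disc pairs share regions.
        """
        pose = self.reference_disc or self.disc
        if pose is None:
            raise ValueError("no disc or reference pose configured")
        return pose

    def with_disc(self, pose: DiscPose | None) -> "GeometryModel":
        ref = self.reference_disc or self.disc
        return replace(self, disc=pose, reference_disc=ref)

    # -- queries -----------------------------------------------------------

    def locate_ids(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized region classification; pts shape (N, 3), mm."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r2 = y * y + z * z
        ri = self.collimator_inner_diameter / 2.0
        ro = self.collimator_outer_diameter / 2.0
        half = self.phantom_size / 2.0
        out = np.full(len(pts), OUTSIDE, dtype=np.int8)

        upstream = (x >= -self.ssd) & (x < 0.0)
        bore = upstream & (r2 <= ri * ri)
        out[bore & (x < -self.ssd + self.window_thickness)] = WINDOW
        out[bore & (x >= -self.ssd + self.window_thickness)] = AIR
        out[upstream & (r2 > ri * ri) & (r2 <= ro * ro)] = PMMA

        in_phantom = (
            (x >= 0.0)
            & (x <= self.phantom_size)
            & (np.abs(y) <= half)
            & (np.abs(z) <= half)
        )
        out[in_phantom] = WATER

        if self.disc is not None:
            d = self.disc
            idx = np.nonzero(in_phantom)[0]
            if idx.size:
                q = d.to_local(pts[idx])
                h = d.thickness / 2.0
                rad2 = (d.diameter / 2.0) ** 2
                inside = (
                    (np.abs(q[:, 0]) <= h)
                    & (q[:, 1] ** 2 + q[:, 2] ** 2 <= rad2)
                )
                # proximal layer boundary in local u
                if d.flipped:
                    u_b = -h + d.pb_thickness
                    lead = q[:, 0] < u_b
                else:
                    u_b = -h + d.al_thickness
                    lead = q[:, 0] >= u_b
                sel = idx[inside]
                out[sel] = np.where(lead[inside], DISC_PB, DISC_AL)
        return out

    def distance_to_boundary_v(
        self, pts: np.ndarray, dirs: np.ndarray
    ) -> np.ndarray:
        """Vectorized distance (mm) to the nearest material boundary."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        ri = self.collimator_inner_diameter / 2.0
        ro = self.collimator_outer_diameter / 2.0
        half = self.phantom_size / 2.0
        best = np.full(len(pts), np.inf)
        errstate = np.errstate(over="ignore", invalid="ignore")
        errstate.__enter__()

        def consider(t, ok):
            np.minimum(best, np.where(ok & (t > _EPS), t, np.inf), out=best)

        safe_dx = np.where(np.abs(dx) < 1e-300, 1e-300, dx)
        # axial planes: world entry, window back, phantom surface, phantom back
        for xp, kind in (
            (-self.ssd, "bore"),
            (-self.ssd + self.window_thickness, "bore"),
            (0.0, "any"),
            (self.phantom_size, "box"),
        ):
            t = (xp - x) / safe_dx
            yh = y + t * dy
            zh = z + t * dz
            if kind == "bore":
                ok = yh * yh + zh * zh <= ro * ro
            elif kind == "box":
                ok = (np.abs(yh) <= half) & (np.abs(zh) <= half)
            else:
                ok = np.ones_like(t, dtype=bool)
            consider(t, ok)

        # phantom lateral faces
        safe_dy = np.where(np.abs(dy) < 1e-300, 1e-300, dy)
        safe_dz = np.where(np.abs(dz) < 1e-300, 1e-300, dz)
        for yp in (-half, half):
            t = (yp - y) / safe_dy
            xh = x + t * dx
            zh = z + t * dz
            consider(t, (xh >= 0) & (xh <= self.phantom_size) & (np.abs(zh) <= half))
        for zp in (-half, half):
            t = (zp - z) / safe_dz
            xh = x + t * dx
            yh = y + t * dy
            consider(t, (xh >= 0) & (xh <= self.phantom_size) & (np.abs(yh) <= half))

        # collimator cylinders (relevant upstream of the phantom only)
        a = dy * dy + dz * dz
        b = 2.0 * (y * dy + z * dz)
        safe_a = np.where(a < 1e-300, 1e-300, a)
        for r in (ri, ro):
            c = y * y + z * z - r * r
            disc = b * b - 4.0 * safe_a * c
            sq = np.sqrt(np.maximum(disc, 0.0))
            for sign in (-1.0, 1.0):
                t = (-b + sign * sq) / (2.0 * safe_a)
                xh = x + t * dx
                consider(t, (disc > 0) & (a > 1e-300) & (xh >= -self.ssd) & (xh <= 0.0))

        if self.disc is not None:
            d = self.disc
            q = d.to_local(pts)
            v = d.rotate_dirs(dirs)
            h = d.thickness / 2.0
            rad = d.diameter / 2.0
            safe_vu = np.where(np.abs(v[:, 0]) < 1e-300, 1e-300, v[:, 0])
            # the two faces plus the internal layer interface
            u_b = (-h + d.pb_thickness) if d.flipped else (-h + d.al_thickness)
            for up in (-h, u_b, h):
                t = (up - q[:, 0]) / safe_vu
                vh = q[:, 1] + t * v[:, 1]
                wh = q[:, 2] + t * v[:, 2]
                consider(t, vh * vh + wh * wh <= rad * rad)
            # lateral cylinder of the disc
            a2 = v[:, 1] ** 2 + v[:, 2] ** 2
            b2 = 2.0 * (q[:, 1] * v[:, 1] + q[:, 2] * v[:, 2])
            c2 = q[:, 1] ** 2 + q[:, 2] ** 2 - rad * rad
            disc2 = b2 * b2 - 4.0 * a2 * c2
            safe_a2 = np.where(a2 < 1e-300, 1e-300, a2)
            sq2 = np.sqrt(np.maximum(disc2, 0.0))
            for sign in (-1.0, 1.0):
                t = (-b2 + sign * sq2) / (2.0 * safe_a2)
                uh = q[:, 0] + t * v[:, 0]
                consider(t, (disc2 > 0) & (a2 > 1e-300) & (np.abs(uh) <= h))
        errstate.__exit__(None, None, None)
        return best

    def describe(self) -> list[dict]:
        """Component table (name, material, axial extent along x in mm)."""
        rows = [
            {
                "component": "exit window",
                "material": "titanium",
                "x_from_mm": -self.ssd,
                "x_to_mm": -self.ssd + self.window_thickness,
            },
            {
                "component": "collimator bore (air)",
                "material": "air",
                "x_from_mm": -self.ssd + self.window_thickness,
                "x_to_mm": 0.0,
            },
            {
                "component": "head + collimator structure",
                "material": "pmma",
                "x_from_mm": -self.ssd,
                "x_to_mm": 0.0,
            },
            {
                "component": "water phantom",
                "material": "water",
                "x_from_mm": 0.0,
                "x_to_mm": self.phantom_size,
            },
            {
                "component": "sensitive detector",
                "material": "water",
                "x_from_mm": 0.0,
                "x_to_mm": self.detector_depth,
            },
        ]
        if self.disc is not None:
            d = self.disc
            rows.append(
                {
                    "component": (
                        f"shielding disc (Al {d.al_thickness} mm + "
                        f"Pb {d.pb_thickness} mm"
                        + (", flipped)" if d.flipped else ")")
                    ),
                    "material": "aluminum+lead",
                    "x_from_mm": d.depth,
                    "x_to_mm": d.distal_plane,
                }
            )
        return rows


def build_geometry(config) -> GeometryModel:
    """Build a :class:`GeometryModel` from a mapping or RunConfig-like object.

    With no disc block the phantom is homogeneous water.
    """
    if hasattr(config, "geometry_model"):
        return config.geometry_model()
    cfg = dict(config or {})
    disc_cfg = cfg.pop("disc", None)
    ref_cfg = cfg.pop("reference_disc", None)
    disc = DiscPose(**disc_cfg) if disc_cfg else None
    ref = DiscPose(**ref_cfg) if ref_cfg else None
    return GeometryModel(disc=disc, reference_disc=ref, **cfg)


def locate(model: GeometryModel, point) -> tuple[str, Material | None]:
    """Classify a single point; returns (region label, material or None)."""
    point = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("point must be finite")
    rid = int(model.locate_ids(point[None, :])[0])
    label = REGION_LABELS[rid]
    mat = get_material(REGION_MATERIALS[rid]) if rid != OUTSIDE else None
    return label, mat


def distance_to_boundary(model: GeometryModel, point, direction) -> float:
    """Distance (mm) from ``point`` to the nearest boundary along ``direction``."""
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    if int(model.locate_ids(point[None, :])[0]) == OUTSIDE:
        raise ValueError("point outside the world")
    return float(model.distance_to_boundary_v(point[None, :], direction[None, :])[0])
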