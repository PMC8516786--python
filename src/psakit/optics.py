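"""Two-dimensional corneal-refraction model of the optical pupil-size artefact.

A pupil-based video eye tracker locates the pupil *as imaged through the
cornea* (the entrance pupil).  Because the cornea is a curved refracting
surface, the rays leaving the two in-plane pupil-perimeter points (the *near*
and *far* pupil rays) are bent by different amounts whenever the optic axis of
the eye is rotated away from the camera.  The midpoint of their image
positions — the perceived pupil center — then shifts as the pupil dilates or
constricts even though the eye does not rotate.  Converting that perceived
center back to an eye orientation through a calibration built at a single
reference pupil diameter turns the shift into an apparent gaze deviation: the
optical pupil-size artefact (PSA).

The model lives entirely in the horizontal plane: the eye rotates about a
fixed rotation center (one angular degree of freedom), the cornea is a
circular or elliptical arc, the pupil is a chord of length ``d`` in the pupil
plane, and the camera is an ideal pinhole projecting onto a 1-D image line.

Geometry and conventions
------------------------
* The eye rotation center sits at the origin; the camera pinhole on the
  positive x-axis at ``pinhole_distance`` (default 530 mm).
* Viewing angle ``theta`` is positive when the gaze point is to the right of
  the camera from the participant's perspective; positive ``theta`` rotates
  the optic axis towards positive y.
* Image positions increase with ``theta`` (mirror-corrected pinhole
  projection), so the calibration lookup table is increasing.

All lengths are in millimetres and all angles in degrees unless stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "EyeGeometry",
    "EyeState",
    "CameraModel",
    "RayTraceResult",
    "CalibrationLUT",
    "PsaSimResult",
    "TotalInternalReflectionError",
    "RayTraceError",
    "refract",
    "trace_pupil_ray",
    "perceived_pupil_center",
    "build_calibration_lut",
    "apparent_angle",
    "simulate_psa",
    "ellipsoidal_variant",
    "brute_force_surface_param",
    "DEFAULT_VIEWING_ANGLES",
    "DEFAULT_PUPIL_GRID",
]

DEFAULT_VIEWING_ANGLES = (-12.0, -6.0, 0.0, 6.0, 12.0)
DEFAULT_PUPIL_GRID = tuple(np.round(np.arange(2.0, 6.0 + 1e-9, 0.1), 10))


class RayTraceError(RuntimeError):
    """A pupil-perimeter ray could not be traced to the camera."""


class TotalInternalReflectionError(RayTraceError):
    """Snell's law has no real solution at the corneal intersection."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EyeGeometry:
    """Reduced schematic eye for the 2-D refraction model.

    The default values are a Le Grand-style reduced eye: a spherical corneal
    surface of radius 7.8 mm, aqueous refractive index 1.336, pupil plane
    3.6 mm behind the corneal apex and the eye rotation center 13.5 mm behind
    the apex.  An elliptical corneal cross-section (conic cornea) is selected
    by ``corneal_semi_axes``; see :func:`ellipsoidal_variant`.

    Parameters
    ----------
    corneal_radius
        Radius of the spherical corneal surface (mm).  Ignored when
        ``corneal_semi_axes`` is given.
    corneal_semi_axes
        ``(axial, transverse)`` semi-axes (mm) of an elliptical corneal
        cross-section whose apex lies on the optic axis.  ``None`` selects the
        spherical surface.
    n_outside, n_inside
        Refractive indices of air and of the medium behind the cornea.
    pupil_plane_depth
        Distance (mm) from the corneal apex to the pupil plane, along the
        optic axis.
    rotation_center_offset
        Distance (mm) from the corneal apex to the eye rotation center.
    limbus_radius
        Transverse half-width (mm) of the modelled corneal cap; rays that
        would have to exit beyond it are flagged occluded.
    """

    corneal_radius: float = 7.8
    corneal_semi_axes: tuple[float, float] | None = None
    n_outside: float = 1.0
    n_inside: float = 1.336
    pupil_plane_depth: float = 3.6
    rotation_center_offset: float = 13.5
    limbus_radius: float = 5.85

    def __post_init__(self) -> None:
        if self.corneal_semi_axes is not None:
            a, b = self.corneal_semi_axes
            if not (a > 0 and b > 0):
                raise ValueError("corneal semi-axes must be positive")
            if self.limbus_radius >= b:
                raise ValueError("limbus_radius must be smaller than the "
                                 "transverse corneal semi-axis")
        else:
            if not self.corneal_radius > 0:
                raise ValueError("corneal_radius must be positive")
            if self.limbus_radius >= self.corneal_radius:
                raise ValueError("limbus_radius must be smaller than the "
                                 "corneal radius")
        if not self.n_inside > self.n_outside >= 1.0:
            raise ValueError("require n_inside > n_outside >= 1")
        axial = (self.corneal_semi_axes[0] if self.corneal_semi_axes
                 else self.corneal_radius)
        if not 0 < self.pupil_plane_depth < self.rotation_center_offset:
            raise ValueError("pupil plane must lie between the corneal apex "
                             "and the rotation center")
        if self.rotation_center_offset <= 0:
            raise ValueError("rotation_center_offset must be positive")
        # the pupil plane must sit behind the corneal surface
        sag = axial - np.sqrt(max(axial**2 - self.limbus_radius**2, 0.0))
        if self.pupil_plane_depth <= sag:
            raise ValueError("pupil plane lies inside the corneal sag")

    # -- corneal surface in the *eye frame* (theta = 0, optic axis = +x) ----

    @property
    def is_elliptical(self) -> bool:
        return self.corneal_semi_axes is not None

    @property
    def _semi_axes(self) -> tuple[float, float]:
        if self.corneal_semi_axes is not None:
            return self.corneal_semi_axes
        return (self.corneal_radius, self.corneal_radius)

    @property
    def _surface_center_x(self) -> float:
        # apex at x = rotation_center_offset; surface center one axial
        # semi-axis behind it
        return self.rotation_center_offset - self._semi_axes[0]

    @property
    def cap_half_angle(self) -> float:
        """Angular extent (radians) of the corneal cap in surface parameter."""
        return float(np.arcsin(self.limbus_radius / self._semi_axes[1]))

    @property
    def pupil_center_x(self) -> float:
        return self.rotation_center_offset - self.pupil_plane_depth


@dataclass(frozen=True)
class EyeState:
    """An :class:`EyeGeometry` at one viewing angle with one pupil diameter."""

    geometry: EyeGeometry
    viewing_angle: float  # degrees, positive = gaze right of camera
    pupil_diameter: float  # mm

    def __post_init__(self) -> None:
        if abs(self.viewing_angle) > 20.0 + 1e-12:
            raise ValueError("|viewing_angle| must be <= 20 degrees")
        if not 0 < self.pupil_diameter < 2 * self.geometry.limbus_radius:
            raise ValueError("pupil_diameter outside the iris aperture")


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera projecting onto a 1-D image line.

    ``pinhole_distance`` is measured from the eye rotation center (530 mm by
    default, i.e. a camera distance of 53 cm).  ``image_plane_distance`` sets
    an arbitrary image scale; the calibration lookup removes it.
    """

    pinhole_distance: float = 530.0
    image_plane_distance: float = 25.0

    def __post_init__(self) -> None:
        if self.pinhole_distance <= 0 or self.image_plane_distance <= 0:
            raise ValueError("camera distances must be positive")


@dataclass(frozen=True)
class RayTraceResult:
    """Image positions of the two pupil-perimeter rays."""

    far_ray_image_pos: float
    near_ray_image_pos: float
    occluded: bool = False
    no_solution: bool = False

    @property
    def perceived_center(self) -> float:
        """Mean of the far- and near-ray image positions."""
        return 0.5 * (self.far_ray_image_pos + self.near_ray_image_pos)

    @property
    def ok(self) -> bool:
        return not (self.occluded or self.no_solution)


@dataclass(frozen=True)
class CalibrationLUT:
    """Monotone map between perceived pupil-center position and viewing angle.

    Built by rotating the model eye over a dense angle grid at one fixed
    calibration pupil diameter and recording the perceived pupil center for
    each orientation.
    """

    angle_grid: np.ndarray  # degrees, ascending
    center_positions: np.ndarray  # image units, strictly monotone
    calibration_pupil_diameter: float = 4.0

    @property
    def step(self) -> float:
        return float(self.angle_grid[1] - self.angle_grid[0])

    def apparent_angle(self, center_position: float | np.ndarray):
        return apparent_angle(self, center_position)


@dataclass(frozen=True)
class PsaSimResult:
    """Simulated optical PSA: deviations over a pupil sweep per viewing angle.

    ``deviations[i, j]`` is the apparent-minus-true eye orientation (degrees)
    at ``viewing_angles[i]`` and ``pupil_grid[j]``; ``slopes[i]`` is the
    least-squares slope of deviation versus pupil diameter (deg/mm).
    """

    viewing_angles: np.ndarray
    pupil_grid: np.ndarray
    deviations: np.ndarray  # (n_angles, n_pupils), degrees
    slopes: np.ndarray  # deg/mm
    intercepts: np.ndarray  # degrees
    calibration_pupil_diameter: float
    geometry: EyeGeometry = field(repr=False, default_factory=EyeGeometry)

    def summary(self) -> str:
        lines = ["Optical pupil-size artefact simulation",
                 "=" * 44,
                 f"corneal surface : "
                 f"{'ellipse ' + str(self.geometry.corneal_semi_axes) if self.geometry.is_elliptical else f'sphere r={self.geometry.corneal_radius} mm'}",
                 f"calibration pupil: {self.calibration_pupil_diameter} mm",
                 f"pupil sweep     : {self.pupil_grid[0]:.1f}-"
                 f"{self.pupil_grid[-1]:.1f} mm ({self.pupil_grid.size} steps)",
                 "",
                 f"{'angle [deg]':>12} {'slope [deg/mm]':>16} "
                 f"{'intercept [deg]':>16}"]
        for th, s, b in zip(self.viewing_angles, self.slopes, self.intercepts):
            lines.append(f"{th:>12.1f} {s:>16.6f} {b:>16.6f}")
        return "\n".join(lines)

    def to_frame(self):
        """Long-format DataFrame of (viewing_angle, pupil_diameter, deviation)."""
        import pandas as pd

        a, p = np.meshgrid(self.viewing_angles, self.pupil_grid, indexing="ij")
        return pd.DataFrame({
            "viewing_angle_deg": a.ravel(),
            "pupil_diameter_mm": p.ravel(),
            "deviation_deg": self.deviations.ravel(),
        })

    def plot(self, axes=None):
        """Deviation-vs-pupil curves (left) and slope-vs-angle (right)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3.6))
        ax0, ax1 = axes
        for i, th in enumerate(self.viewing_angles):
            ax0.plot(self.pupil_grid, self.deviations[i], label=f"{th:g}°")
        ax0.set_xlabel("pupil diameter [mm]")
        ax0.set_ylabel("deviation [deg]")
        ax0.legend(fontsize="small", title="viewing angle")
        ax1.plot(self.viewing_angles, self.slopes, "o-")
        ax1.axhline(0.0, color="0.7", lw=0.8)
        ax1.set_xlabel("viewing angle [deg]")
        ax1.set_ylabel("PSA slope [deg/mm]")
        return axes


# ---------------------------------------------------------------------------
# refraction
# ---------------------------------------------------------------------------


def _refract_vec(incident: np.ndarray, normal: np.ndarray,
                 n1: float, n2: float) -> np.ndarray:
    """Vectorized Snell refraction; NaN rows on total internal reflection.

    ``incident`` and ``normal`` have shape (..., 2) and must be unit vectors.
    The normal may point to either side; it is flipped internally so that it
    opposes the incident direction.
    """
    incident = np.asarray(incident, dtype=float)
    normal = np.asarray(normal, dtype=float)
    cos_i = -np.sum(incident * normal, axis=-1, keepdims=True)
    flip = np.where(cos_i < 0, -1.0, 1.0)
    normal = normal * flip
    cos_i = cos_i * flip
    eta = n1 / n2
    k = 1.0 - eta**2 * (1.0 - cos_i**2)
    with np.errstate(invalid="ignore"):
        cos_t = np.sqrt(k)
        t = eta * incident + (eta * cos_i - cos_t) * normal
    t = np.where(k < 0, np.nan, t)
    return t


def refract(incident_direction: Sequence[float],
            surface_normal: Sequence[float],
            n1: float, n2: float) -> np.ndarray:
    """Refract a unit direction vector at a surface (Snell's law).

    Parameters
    ----------
    incident_direction, surface_normal
        2-D unit vectors; the normal's sign is immaterial.
    n1, n2
        Refractive indices on the incident and transmitted sides.

    Returns
    -------
    numpy.ndarray
        Unit transmitted direction.

    Raises
    ------
    TotalInternalReflectionError
        If ``n1 > n2`` and the angle of incidence exceeds the critical angle.
    """
    inc = np.asarray(incident_direction, dtype=float)
    nrm = np.asarray(surface_normal, dtype=float)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    for v, name in ((inc, "incident_direction"), (nrm, "surface_normal")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-9:
            raise ValueError(f"{name} must be a unit vector")
    out = _refract_vec(inc, nrm, n1, n2)
    if np.any(np.isnan(out)):
        raise TotalInternalReflectionError(
            "total internal reflection: no transmitted ray")
    return out


# ---------------------------------------------------------------------------
# ray solve
# ---------------------------------------------------------------------------


def _surface_point(geometry: EyeGeometry, phi: np.ndarray,
                   theta_rad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Corneal surface point and outward normal in the *world* frame.

    ``phi`` is the surface parameter (radians; 0 at the apex); ``theta_rad``
    the eye rotation.  Shapes broadcast.
    """
    a, b = geometry._semi_axes
    cx = geometry._surface_center_x
    # eye frame
    sx = cx + a * np.cos(phi)
    sy = b * np.sin(phi)
    nx = np.cos(phi) / a
    ny = np.sin(phi) / b
    norm = np.hypot(nx, ny)
    nx, ny = nx / norm, ny / norm
    # rotate to world frame
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    Sx = c * sx - s * sy
    Sy = s * sx + c * sy
    Nx = c * nx - s * ny
    Ny = s * nx + c * ny
    return np.stack([Sx, Sy], axis=-1), np.stack([Nx, Ny], axis=-1)


def _pupil_point(geometry: EyeGeometry, theta_rad: np.ndarray,
                 offset: np.ndarray) -> np.ndarray:
    """World position of the pupil point at signed in-plane ``offset`` (mm)."""
    px = geometry.pupil_center_x
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    # eye frame point (px, offset) rotated by theta
    return np.stack([c * px - s * offset, s * px + c * offset], axis=-1)


def _miss(geometry: EyeGeometry, camera: CameraModel, phi: np.ndarray,
          theta_rad: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Signed perpendicular miss distance (mm) of the refracted ray at the
    camera pinhole, as a function of the surface parameter ``phi``.

    NaN where the candidate surface point is unusable (ray would travel
    backwards through the surface, or total internal reflection).
    """
    S, N = _surface_point(geometry, phi, theta_rad)
    P = _pupil_point(geometry, theta_rad, offset)
    inc = S - P
    inc_norm = np.linalg.norm(inc, axis=-1, keepdims=True)
    inc = inc / inc_norm
    # the ray must exit through the surface (outward component positive)
    exiting = np.sum(inc * N, axis=-1) > 0
    t = _refract_vec(inc, N, geometry.n_inside, geometry.n_outside)
    C = np.array([camera.pinhole_distance, 0.0])
    rel = C - S
    miss = t[..., 0] * rel[..., 1] - t[..., 1] * rel[..., 0]
    miss = np.where(exiting, miss, np.nan)
    # refracted ray must head towards the camera, not away from it
    towards = np.sum(t * rel, axis=-1) > 0
    miss = np.where(towards, miss, np.nan)
    return miss


_N_COARSE = 721
_N_BISECT = 64
_MISS_TOL = 1e-10


_CHUNK = 4096


def _solve_chunk(geometry: EyeGeometry, camera: CameraModel,
                 theta: np.ndarray, offset: np.ndarray,
                 ) -> tuple[np.ndarray, np.ndarray]:
    n = theta.size
    cap = geometry.cap_half_angle
    phi_grid = np.linspace(-cap, cap, _N_COARSE)

    m = _miss(geometry, camera, phi_grid[None, :], theta[:, None],
              offset[:, None])  # (n, N_COARSE)
    sign = np.sign(m)
    change = (sign[:, :-1] * sign[:, 1:]) < 0  # finite & opposite signs
    absm = np.where(np.isnan(m), np.inf, np.abs(m))
    best = np.argmin(absm, axis=1)
    # per row: the sign-change interval nearest the global |miss| minimum
    # (the root is unique for sane geometry; this guards against spurious
    # grazing sign flips near the cap edges)
    cols = np.arange(_N_COARSE - 1)
    dist = np.where(change, np.abs(cols[None, :] - best[:, None]), np.inf)
    j = np.argmin(dist, axis=1)
    status = np.where(np.isinf(dist[np.arange(n), j]), 1, 0)

    ok = status == 0
    lo = phi_grid[j[ok]]
    hi = phi_grid[j[ok] + 1]
    flo = m[np.flatnonzero(ok), j[ok]]
    th_ok, off_ok = theta[ok], offset[ok]
    for _ in range(_N_BISECT):
        mid = 0.5 * (lo + hi)
        fm = _miss(geometry, camera, mid, th_ok, off_ok)
        same = np.sign(fm) == np.sign(flo)
        lo = np.where(same, mid, lo)
        flo = np.where(same, fm, flo)
        hi = np.where(same, hi, mid)
    phi = np.full(n, np.nan)
    phi[ok] = 0.5 * (lo + hi)
    resid = np.abs(_miss(geometry, camera, phi[ok], th_ok, off_ok))
    status[np.flatnonzero(ok)[resid > _MISS_TOL]] = 2
    return phi, status


def _solve_surface_params(geometry: EyeGeometry, camera: CameraModel,
                          theta_deg: np.ndarray, offset: np.ndarray,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Solve, per element, for the surface parameter whose refracted ray hits
    the pinhole.  Vectorized bisection after a coarse bracketing scan,
    processed in chunks to bound memory on dense calibration grids.

    Returns ``(phi, status)`` with status 0 = ok, 1 = no bracket found
    (no_solution), 2 = residual miss above tolerance.
    """
    theta = np.deg2rad(np.atleast_1d(np.asarray(theta_deg, dtype=float)))
    offset = np.broadcast_to(np.asarray(offset, dtype=float), theta.shape)
    n = theta.size
    phi = np.empty(n)
    status = np.empty(n, dtype=int)
    for start in range(0, n, _CHUNK):
        sl = slice(start, min(start + _CHUNK, n))
        phi[sl], status[sl] = _solve_chunk(geometry, camera,
                                           theta[sl], offset[sl])
    return phi, status


def _image_position(geometry: EyeGeometry, camera: CameraModel,
                    phi: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
    """Mirror-corrected pinhole image position of the ray leaving ``phi``.

    The refracted ray passes through the pinhole, so the image position
    follows from the line joining the corneal exit point and the pinhole.
    """
    S, _ = _surface_point(geometry, phi, theta_rad)
    D = camera.pinhole_distance
    return camera.image_plane_distance * S[..., 1] / (D - S[..., 0])


def _trace_offsets(geometry: EyeGeometry, camera: CameraModel,
                   theta_deg: np.ndarray, offsets: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Image positions (same shape as broadcast inputs) plus status codes."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), theta.shape)
    phi, status = _solve_surface_params(geometry, camera, theta, offsets)
    pos = _image_position(geometry, camera, phi, np.deg2rad(theta))
    return pos, status


def brute_force_surface_param(geometry: EyeGeometry, camera: CameraModel,
                              theta_deg: float, offset: float,
                              levels: int = 4, n_grid: int = 801) -> float:
    """Independent dense-grid search for the corneal exit point.

    Repeatedly evaluates the pinhole miss distance on a dense grid of surface
    parameters, keeps the grid point with the smallest \\|miss\\| and zooms in
    around it.  Resolution after ``levels`` passes is far below 1e-6 rad.
    Used as an oracle for the bisection solver; shares only the forward miss
    evaluation with it, not the root-finding.
    """
    theta = np.atleast_1d(float(theta_deg))
    off = np.atleast_1d(float(offset))
    cap = geometry.cap_half_angle
    lo, hi = -cap, cap
    best = np.nan
    for _ in range(levels):
        grid = np.linspace(lo, hi, n_grid)
        m = _miss(geometry, camera, grid[None, :],
                  np.deg2rad(theta)[:, None], off[:, None])[0]
        absm = np.where(np.isnan(m), np.inf, np.abs(m))
        j = int(np.argmin(absm))
        if not np.isfinite(absm[j]):
            raise RayTraceError("no usable surface point on the corneal cap")
        best = grid[j]
        span = (hi - lo) / (n_grid - 1)
        lo, hi = best - 2 * span, best + 2 * span
    return float(best)


# ---------------------------------------------------------------------------
# public tracing operations
# ---------------------------------------------------------------------------


def _near_far_offsets(eye: EyeState, camera: CameraModel,
                      ) -> tuple[float, float]:
    """Signed pupil offsets of the (near, far) perimeter points.

    Near/far is decided by distance to the nodal ray — the line through the
    camera pinhole and the corneal surface center.  At ``theta = 0`` the two
    distances tie; the tie breaks towards the negative-offset point.
    """
    g = eye.geometry
    th = np.deg2rad(eye.viewing_angle)
    half = eye.pupil_diameter / 2.0
    C = np.array([camera.pinhole_distance, 0.0])
    cx = g._surface_center_x
    center_w = np.array([np.cos(th) * cx, np.sin(th) * cx])
    axis = C - center_w
    axis = axis / np.linalg.norm(axis)
    dists = []
    for off in (-half, half):
        P = _pupil_point(g, np.atleast_1d(th), np.atleast_1d(off))[0]
        rel = P - center_w
        dists.append(abs(axis[0] * rel[1] - axis[1] * rel[0]))
    if dists[0] <= dists[1]:
        return -half, half
    return half, -half


def trace_pupil_ray(eye: EyeState, camera: CameraModel,
                    perimeter_point: str) -> float:
    """Image position of one pupil-perimeter ray (``"near"`` or ``"far"``).

    The ray leaves the stated in-plane pupil-perimeter point, refracts once at
    the corneal surface and passes through the camera pinhole.

    Raises
    ------
    RayTraceError
        If no refracted path to the pinhole exists.
    """
    if perimeter_point not in ("near", "far"):
        raise ValueError("perimeter_point must be 'near' or 'far'")
    near_off, far_off = _near_far_offsets(eye, camera)
    off = near_off if perimeter_point == "near" else far_off
    pos, status = _trace_offsets(eye.geometry, camera,
                                 np.array([eye.viewing_angle]),
                                 np.array([off]))
    if status[0] == 1:
        raise RayTraceError(
            f"no refracted path to the pinhole for the {perimeter_point} ray "
            f"at theta={eye.viewing_angle} deg")
    if status[0] == 2:
        raise RayTraceError("ray solver did not reach the miss tolerance")
    return float(pos[0])


def perceived_pupil_center(eye: EyeState, camera: CameraModel,
                           ) -> RayTraceResult:
    """Trace both perimeter rays and average their image positions."""
    near_off, far_off = _near_far_offsets(eye, camera)
    pos, status = _trace_offsets(eye.geometry, camera,
                                 np.array([eye.viewing_angle] * 2),
                                 np.array([near_off, far_off]))
    if np.any(status != 0):
        return RayTraceResult(np.nan, np.nan,
                              no_solution=bool(np.any(status == 1)),
                              occluded=bool(np.any(status == 2)))
    return RayTraceResult(near_ray_image_pos=float(pos[0]),
                          far_ray_image_pos=float(pos[1]))


def build_calibration_lut(geometry: EyeGeometry, camera: CameraModel,
                          d_cal: float = 4.0, angle_min: float = -20.0,
                          angle_max: float = 20.0, step: float = 0.001,
                          ) -> CalibrationLUT:
    """Build the perceived-center-to-angle lookup table.

    The eye is rotated over ``[angle_min, angle_max]`` in increments of
    ``step`` at the fixed calibration pupil diameter ``d_cal`` (defaults:
    -20 to 20 degrees, step 0.001, 4 mm pupil) and the perceived pupil center
    is recorded for every orientation.

    Raises
    ------
    RayTraceError
        If any grid orientation is untraceable.
    ValueError
        If the resulting center positions are not strictly monotone.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((angle_max - angle_min) / step)) + 1
    angles = angle_min + step * np.arange(n)
    half = d_cal / 2.0
    centers = np.zeros(n)
    for off in (-half, half):
        pos, status = _trace_offsets(geometry, camera, angles,
                                     np.full(n, off))
        if np.any(status != 0):
            k = int(np.argmax(status != 0))
            raise RayTraceError(
                f"LUT build failed at angle {angles[k]:.4f} deg "
                f"(status {status[k]})")
        centers += 0.5 * pos
    if not np.all(np.diff(centers) > 0):
        raise ValueError("perceived center positions are not strictly "
                         "monotone over the angle grid")
    return CalibrationLUT(angle_grid=angles, center_positions=centers,
                          calibration_pupil_diameter=d_cal)


def apparent_angle(lut: CalibrationLUT,
                   center_position: float | np.ndarray):
    """Invert the lookup table by linear interpolation.

    Raises
    ------
    ValueError
        If a position falls outside the tabulated range.
    """
    pos = np.asarray(center_position, dtype=float)
    lo, hi = lut.center_positions[0], lut.center_positions[-1]
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError("center position outside the calibrated range")
    out = np.interp(pos, lut.center_positions, lut.angle_grid)
    if np.isscalar(center_position) or pos.ndim == 0:
        return float(out)
    return out


def simulate_psa(geometry: EyeGeometry | None = None,
                 camera: CameraModel | None = None,
                 viewing_angles: Sequence[float] = DEFAULT_VIEWING_ANGLES,
                 pupil_grid: Sequence[float] = DEFAULT_PUPIL_GRID,
                 d_cal: float = 4.0,
                 lut: CalibrationLUT | None = None,
                 lut_step: float = 0.001) -> PsaSimResult:
    """Simulate the optical PSA: calibrate at ``d_cal``, sweep pupil size.

    For each viewing angle the eye is held fixed while the pupil diameter is
    swept over ``pupil_grid`` (default 2-6 mm); the perceived pupil center is
    converted to an apparent orientation through the calibration lookup table
    and the deviation is apparent minus true orientation.  The PSA slope per
    angle is the least-squares line through (pupil diameter, deviation).
    """
    from .signal import fit_slope

    geometry = geometry or EyeGeometry()
    camera = camera or CameraModel()
    if lut is None:
        lut = build_calibration_lut(geometry, camera, d_cal=d_cal,
                                    step=lut_step)
    angles = np.asarray(viewing_angles, dtype=float)
    pupils = np.asarray(pupil_grid, dtype=float)
    dev = np.empty((angles.size, pupils.size))
    for i, th in enumerate(angles):
        th_rep = np.full(2 * pupils.size, th)
        offs = np.concatenate([-pupils / 2.0, pupils / 2.0])
        pos, status = _trace_offsets(geometry, camera, th_rep, offs)
        if np.any(status != 0):
            raise RayTraceError(f"trace failed during sweep at theta={th}")
        centers = 0.5 * (pos[:pupils.size] + pos[pupils.size:])
        dev[i] = apparent_angle(lut, centers) - th
    slopes = np.empty(angles.size)
    intercepts = np.empty(angles.size)
    for i in range(angles.size):
        slopes[i], intercepts[i] = fit_slope(pupils, dev[i])
    return PsaSimResult(viewing_angles=angles, pupil_grid=pupils,
                        deviations=dev, slopes=slopes, intercepts=intercepts,
                        calibration_pupil_diameter=lut.calibration_pupil_diameter,
                        geometry=geometry)


def ellipsoidal_variant(semi_axis_axial: float = 10.43,
                        semi_axis_transverse: float = 8.97,
                        base: EyeGeometry | None = None) -> EyeGeometry:
    """Eye geometry with an elliptical (conic) corneal cross-section.

    The defaults correspond to a prolate conic cornea with apical radius of
    curvature b²/a ≈ 7.7 mm and asphericity Q ≈ -0.26, typical of schematic
    eyes with aspheric corneas.  The apex lies on the optic axis (no apex
    rotation) and the pupil is centered on the axis (no decentration), so the
    variant plugs into every tracing operation unchanged.
    """
    if semi_axis_axial <= 0 or semi_axis_transverse <= 0:
        raise ValueError("semi-axes must be positive")
    base = base or EyeGeometry()
    return replace(base,
                   corneal_semi_axes=(float(semi_axis_axial),
                                      float(semi_axis_transverse)))


def snell_residual(geometry: EyeGeometry, camera: CameraModel,
                   theta_deg: float, offset: float, phi: float) -> float:
    """|n_in·sin(i) − n_out·sin(t)| at a solved corneal intersection.

    Recomputes the incident and transmitted angles at the local normal from
    scratch, treating the line from the exit point to the pinhole as the
    transmitted ray.
    """
    th = np.atleast_1d(np.deg2rad(theta_deg))
    S, N = _surface_point(geometry, np.atleast_1d(phi), th)
    P = _pupil_point(geometry, th, np.atleast_1d(offset))
    inc = (S - P)[0]
    inc = inc / np.linalg.norm(inc)
    out = np.array([camera.pinhole_distance, 0.0]) - S[0]
    out = out / np.linalg.norm(out)
    nrm = N[0]
    sin_i = abs(inc[0] * nrm[1] - inc[1] * nrm[0])
    sin_t = abs(out[0] * nrm[1] - out[1] * nrm[0])
    return float(abs(geometry.n_inside * sin_i - geometry.n_outside * sin_t))
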