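"""Sequential geometric ray tracing for ball-lens phone microscopes.

The optical train is a list of axially-aligned surfaces (refracting spheres,
planar apertures, ideal thin lenses) followed by a flat sensor.  The tracer is
exact (vector Snell refraction, no paraxial approximation) and fully
deterministic: ray fans are concentric-ring samples, never random.

Conventions: the optical axis is +z, the object sits at negative z, all
distances are millimetres and angles at the API surface are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "Ray",
    "SphericalSurface",
    "SensorModel",
    "SourceModel",
    "OpticalTrain",
    "SpotDiagram",
    "SystemMetrics",
    "TraceResult",
    "refract_ray",
    "trace",
    "ray_fan",
    "spot_metrics",
    "find_best_focus",
    "numerical_aperture",
    "system_metrics",
    "usaf_frequency",
    "ball_lens_efl",
    "build_iphone2g_microscope",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Ray:
    """A single ray: origin (mm), unit direction, wavelength (nm).

    ``alive`` is cleared when the ray is vignetted, totally internally
    reflected, or misses a surface; ``reason`` records why.
    """

    origin: np.ndarray
    direction: np.ndarray
    wavelength_nm: float = 550.0
    alive: bool = True
    reason: str | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            if norm < _EPS:
                raise ValueError("ray direction must be non-zero")
            self.direction = self.direction / norm
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class SphericalSurface:
    """One surface of the train.

    ``curvature_radius`` is signed (+ centre behind vertex, 0 = planar).
    ``n_before == n_after`` with no focal length encodes a pure aperture
    stop; a non-None ``focal_length`` encodes an ideal thin lens at
    ``vertex_z`` (planar geometry, slope kick u' = u - h/f).
    """

    vertex_z: float
    curvature_radius: float
    aperture_radius: float
    n_before: float = 1.0
    n_after: float = 1.0
    focal_length: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.aperture_radius <= 0:
            raise ValueError("aperture_radius must be positive")
        if self.n_before < 1 or self.n_after < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.focal_length is not None and self.curvature_radius != 0:
            raise ValueError("thin lens surfaces must be planar")


@dataclass(frozen=True)
class SensorModel:
    """Flat sensor: physical size (mm) and pixel pitch (µm)."""

    width_mm: float = 3.55
    height_mm: float = 2.68
    pixel_pitch_um: float = 2.2

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.pixel_pitch_um) <= 0:
            raise ValueError("sensor dimensions must be positive")

    @property
    def limiting_dimension_mm(self) -> float:
        return min(self.width_mm, self.height_mm)


@dataclass(frozen=True)
class SourceModel:
    """Point-source fan: object-plane field height (mm), divergence
    half-angle (deg) and ray count."""

    field_height_mm: float = 0.0
    divergence_half_angle_deg: float = 5.0
    n_rays: int = 200

    def __post_init__(self) -> None:
        if self.divergence_half_angle_deg < 0:
            raise ValueError("divergence must be non-negative")


@dataclass
class OpticalTrain:
    """Ordered surfaces (object side -> sensor) plus sensor plane.

    ``reference_z`` marks the point that object distances are quoted
    against (the ball-lens centre for the stock microscope).
    """

    surfaces: list[SphericalSurface]
    sensor: SensorModel
    sensor_z: float
    object_z: float
    reference_z: float = 0.0

    def __post_init__(self) -> None:
        if not self.surfaces:
            raise ValueError("train must contain at least one surface")
        zs = [s.vertex_z for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("surface vertices must be strictly increasing in z")
        if self.sensor_z <= zs[-1]:
            raise ValueError("sensor must lie behind the last surface")
        if self.object_z >= zs[0]:
            raise ValueError("object plane must lie before the first surface")


@dataclass
class TraceResult:
    """Per-surface intersection points and the final sensor hit."""

    ray: Ray
    path: list[np.ndarray]
    sensor_hit: np.ndarray | None  # (x, y) on sensor, mm


@dataclass
class SpotDiagram:
    hit_points: np.ndarray  # (n, 2) mm
    rms_radius_mm: float
    centroid_mm: np.ndarray
    n_vignetted: int
    n_launched: int


@dataclass
class SystemMetrics:
    magnification: float
    field_of_view_diameter_mm: float
    best_focus_object_distance_mm: float  # from reference_z (ball centre)
    best_focus_from_front_surface_mm: float
    depth_of_field_um: float
    depth_of_field_diffraction_um: float
    numerical_aperture: float
    numerical_aperture_real: float
    rayleigh_resolution_um: float
    wavelength_nm: float


# ---------------------------------------------------------------------------
# core tracing


def _refract_direction(d: np.ndarray, normal: np.ndarray, n1: float, n2: float):
    """Vector Snell refraction; returns None on total internal reflection."""
    cos_i = -float(np.dot(d, normal))
    if cos_i < 0:
        normal = -normal
        cos_i = -cos_i
    mu = n1 / n2
    k = 1.0 - mu * mu * (1.0 - cos_i * cos_i)
    if k < 0:
        return None
    out = mu * d + (mu * cos_i - math.sqrt(k)) * normal
    return out / np.linalg.norm(out)


def _intersect(ray: Ray, surface: SphericalSurface):
    """Propagation distance to the surface, or None if it is missed."""
    p, d = ray.origin, ray.direction
    R = surface.curvature_radius
    if R == 0.0 or surface.focal_length is not None:
        if abs(d[2]) < _EPS:
            return None
        t = (surface.vertex_z - p[2]) / d[2]
        return t if t > _EPS else None
    centre = np.array([0.0, 0.0, surface.vertex_z + R])
    oc = p - centre
    b = float(np.dot(d, oc))
    c = float(np.dot(oc, oc)) - R * R
    disc = b * b - c
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    # pick the root on the vertex-side cap: convex (R>0) front cap is the
    # near root, concave (R<0) rear cap the far root
    t = -b - sq if R > 0 else -b + sq
    return t if t > _EPS else None


def refract_ray(ray: Ray, surface: SphericalSurface) -> Ray:
    """Propagate ``ray`` to ``surface`` and refract it.

    Returns a new ray at the intersection point.  The returned ray is dead
    (``alive=False``) if the surface is missed, the hit lies outside the
    clear aperture, or total internal reflection occurs.
    """
    if not ray.alive:
        return ray
    t = _intersect(ray, surface)
    if t is None:
        return replace(ray, alive=False, reason="no intersection")
    hit = ray.origin + t * ray.direction
    r = math.hypot(hit[0], hit[1])
    if r > surface.aperture_radius:
        return replace(ray, origin=hit, alive=False, reason="vignetted")
    if surface.focal_length is not None:
        # ideal thin lens: kick the tangent slope by -h/f
        d = ray.direction
        ux = d[0] / d[2] - hit[0] / surface.focal_length
        uy = d[1] / d[2] - hit[1] / surface.focal_length
        new_d = np.array([ux, uy, 1.0])
        new_d /= np.linalg.norm(new_d)
        return replace(ray, origin=hit, direction=new_d)
    if surface.n_before == surface.n_after:
        return replace(ray, origin=hit)  # plain stop / dummy plane
    if surface.curvature_radius == 0.0:
        normal = np.array([0.0, 0.0, -1.0])
    else:
        centre = np.array([0.0, 0.0, surface.vertex_z + surface.curvature_radius])
        normal = (hit - centre) / surface.curvature_radius
    new_d = _refract_direction(ray.direction, normal, surface.n_before, surface.n_after)
    if new_d is None:
        return replace(ray, origin=hit, alive=False, reason="total internal reflection")
    return replace(ray, origin=hit, direction=new_d)


def trace(train: OpticalTrain, ray: Ray) -> TraceResult:
    """Trace one ray through every surface to the sensor plane.

    Dead rays carry the partial path up to the surface that killed them.
    """
    path = [ray.origin.copy()]
    current = ray
    for surface in train.surfaces:
        current = refract_ray(current, surface)
        path.append(current.origin.copy())
        if not current.alive:
            return TraceResult(current, path, None)
    if abs(current.direction[2]) < _EPS:
        return TraceResult(
            replace(current, alive=False, reason="parallel to sensor"), path, None
        )
    t = (train.sensor_z - current.origin[2]) / current.direction[2]
    if t < 0:
        return TraceResult(
            replace(current, alive=False, reason="sensor behind ray"), path, None
        )
    hit = current.origin + t * current.direction
    path.append(hit.copy())
    current = replace(current, origin=hit)
    return TraceResult(current, path, hit[:2].copy())


# ---------------------------------------------------------------------------
# fans and spot metrics


def ray_fan(
    object_point: np.ndarray,
    half_angle_deg: float,
    n_rays: int,
    wavelength_nm: float = 550.0,
) -> list[Ray]:
    """Deterministic concentric-ring fan of ~``n_rays`` rays.

    Rings are uniform in angle with 8·k azimuthal samples on ring k, plus
    the axial ray, so the fan is reproducible bit-for-bit.
    """
    object_point = np.asarray(object_point, dtype=float)
    rays = [Ray(object_point, np.array([0.0, 0.0, 1.0]), wavelength_nm)]
    if half_angle_deg <= 0 or n_rays <= 1:
        return rays
    n_rings = max(1, int(round(math.sqrt(max(n_rays - 1, 1) / 4.0))))
    theta_max = math.radians(half_angle_deg)
    u_max = theta_max**2
    norm = n_rings * (n_rings + 1)
    for k in range(1, n_rings + 1):
        # ring k carries 8k rays; place it at the solid-angle midpoint of
        # its equal-count annulus so equal-weight rays sample the cone
        # uniformly in area (midpoint rule, no rim bias)
        u_lo = u_max * (k - 1) * k / norm
        u_hi = u_max * k * (k + 1) / norm
        theta = math.sqrt(0.5 * (u_lo + u_hi))
        n_az = 8 * k
        for j in range(n_az):
            phi = 2 * math.pi * j / n_az
            d = np.array(
                [
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi),
                    math.cos(theta),
                ]
            )
            rays.append(Ray(object_point, d, wavelength_nm))
    return rays


def spot_metrics(train: OpticalTrain, source: SourceModel) -> SpotDiagram:
    """Sensor-plane spot diagram for a point source fan.

    RMS radius is computed about the centroid of the surviving rays only.
    Raises if every ray is vignetted ("no throughput").
    """
    if source.n_rays < 50:
        raise ValueError("need at least 50 rays for stable spot statistics")
    origin = np.array([source.field_height_mm, 0.0, train.object_z])
    rays = ray_fan(origin, source.divergence_half_angle_deg, source.n_rays)
    hits = []
    n_dead = 0
    for r in rays:
        res = trace(train, r)
        if res.sensor_hit is None:
            n_dead += 1
        else:
            hits.append(res.sensor_hit)
    if not hits:
        raise RuntimeError("no throughput: all rays vignetted")
    pts = np.array(hits)
    centroid = pts.mean(axis=0)
    rms = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
    return SpotDiagram(pts, rms, centroid, n_dead, len(rays))


def _onaxis_rms(train: OpticalTrain, object_z: float, half_angle_deg: float) -> float:
    t = replace_object_z(train, object_z)
    return spot_metrics(
        t, SourceModel(0.0, half_angle_deg, n_rays=200)
    ).rms_radius_mm


def replace_object_z(train: OpticalTrain, object_z: float) -> OpticalTrain:
    return OpticalTrain(
        train.surfaces, train.sensor, train.sensor_z, object_z, train.reference_z
    )


def find_best_focus(
    train: OpticalTrain,
    search_range: tuple[float, float],
    divergence_half_angle_deg: float = 5.0,
    tol_mm: float = 1e-4,
) -> float:
    """Object-plane z minimising the on-axis RMS spot radius.

    The fan divergence defaults to the 5 degree illumination cone the stock
    instrument is simulated with.  Raises if the minimum sits on the search
    boundary (no bracketed interior minimum).
    """
    lo, hi = sorted(search_range)
    res = minimize_scalar(
        lambda z: _onaxis_rms(train, z, divergence_half_angle_deg),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": min(tol_mm, 1e-4)},
    )
    z = float(res.x)
    if z - lo < 10 * tol_mm or hi - z < 10 * tol_mm:
        raise ValueError("no interior minimum inside search range")
    return z


# ---------------------------------------------------------------------------
# paraxial machinery and numerical aperture


def _paraxial_heights(train: OpticalTrain, object_z: float) -> list[tuple[float, float]]:
    """Heights at each surface of the unit-slope paraxial ray from the
    on-axis object point, as (height, aperture_radius) pairs."""
    y, u, z, n = 0.0, 1.0, object_z, 1.0
    out = []
    for s in train.surfaces:
        y = y + u * (s.vertex_z - z)
        z = s.vertex_z
        out.append((y, s.aperture_radius))
        if s.focal_length is not None:
            u = u - y / s.focal_length
        elif s.curvature_radius != 0.0 and s.n_before != s.n_after:
            c = 1.0 / s.curvature_radius
            u = (s.n_before * u - y * c * (s.n_after - s.n_before)) / s.n_after
            n = s.n_after
    return out


def numerical_aperture(
    train: OpticalTrain, object_z: float, mode: str = "paraxial"
) -> float:
    """NA of the accepted on-axis bundle.

    ``paraxial`` (default): sine of the first-order marginal-ray angle — the
    steepest ray of the paraxial bundle that clears every aperture.  This is
    the aperture measure of the image-forming bundle; strongly aberrated
    peripheral rays that happen to thread the stop are excluded.

    ``real``: sine of the steepest exactly-traced ray that survives to the
    sensor (bisection on the survival boundary).  Reported alongside for
    transparency; for a heavily aberrated ball lens it exceeds the paraxial
    value substantially.
    """
    if mode == "paraxial":
        heights = _paraxial_heights(train, object_z)
        u_max = min(a / abs(y) for y, a in heights if abs(y) > _EPS)
        return u_max / math.sqrt(1.0 + u_max * u_max)
    if mode == "real":
        t = replace_object_z(train, object_z)

        def survives(theta: float) -> bool:
            d = np.array([math.sin(theta), 0.0, math.cos(theta)])
            r = Ray(np.array([0.0, 0.0, object_z]), d)
            return trace(t, r).sensor_hit is not None

        lo, hi = 0.0, math.pi / 2 - 1e-6
        if not survives(lo):
            raise RuntimeError("axial ray blocked")
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if survives(mid):
                lo = mid
            else:
                hi = mid
        return math.sin(lo)
    raise ValueError(f"unknown NA mode {mode!r}")


def _chief_ray_sensor_height(
    train: OpticalTrain, object_z: float, field_height_mm: float
) -> float | None:
    """Sensor x of the chief ray (through the stop centre) from a field point."""
    stop_idx = min(
        range(len(train.surfaces)), key=lambda i: train.surfaces[i].aperture_radius
    )
    stop_z = train.surfaces[stop_idx].vertex_z

    def stop_height(slope: float):
        d = np.array([slope, 0.0, 1.0])
        d /= np.linalg.norm(d)
        r = Ray(np.array([field_height_mm, 0.0, object_z]), d)
        current = r
        for s in train.surfaces[: stop_idx + 1]:
            current = refract_ray(current, s)
            if not current.alive and current.reason != "vignetted":
                return None
        if abs(current.origin[2] - stop_z) > 1e-9:
            t = (stop_z - current.origin[2]) / current.direction[2]
            return float((current.origin + t * current.direction)[0])
        return float(current.origin[0])

    # paraxial chief slope: zero of the (linear) paraxial stop height
    def parax_stop_height(u0: float) -> float:
        y, u, z = field_height_mm, u0, object_z
        for s in train.surfaces[: stop_idx + 1]:
            y = y + u * (s.vertex_z - z)
            z = s.vertex_z
            if s.focal_length is not None:
                u = u - y / s.focal_length
            elif s.curvature_radius != 0.0 and s.n_before != s.n_after:
                c = 1.0 / s.curvature_radius
                u = (s.n_before * u - y * c * (s.n_after - s.n_before)) / s.n_after
        return y

    h0, h1 = parax_stop_height(0.0), parax_stop_height(1.0)
    u_chief = -h0 / (h1 - h0)

    # bracket the exact-ray crossing nearest the paraxial chief slope
    # (spherical aberration can create spurious outer crossings)
    slopes = np.linspace(-0.8, 0.8, 129)
    vals = [stop_height(s) for s in slopes]
    brackets = [
        (s1, s2)
        for (s1, v1), (s2, v2) in zip(zip(slopes, vals), zip(slopes[1:], vals[1:]))
        if v1 is not None and v2 is not None and v1 * v2 <= 0
    ]
    if not brackets:
        return None
    bracket = min(brackets, key=lambda b: abs(0.5 * (b[0] + b[1]) - u_chief))
    slope = brentq(lambda s: stop_height(s), *bracket, xtol=1e-12)
    d = np.array([slope, 0.0, 1.0])
    d /= np.linalg.norm(d)
    res = trace(
        replace_object_z(train, object_z),
        Ray(np.array([field_height_mm, 0.0, object_z]), d),
    )
    return None if res.sensor_hit is None else float(res.sensor_hit[0])


def _unvignetted_field_radius(train: OpticalTrain, object_z: float) -> float:
    """Largest field height whose chief ray still reaches the sensor."""
    lo, hi = 0.0, 2.0
    if _chief_ray_sensor_height(train, object_z, lo) is None:
        return 0.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _chief_ray_sensor_height(train, object_z, mid) is not None:
            lo = mid
        else:
            hi = mid
    return lo


def system_metrics(
    train: OpticalTrain,
    wavelength_nm: float = 550.0,
    dof_criterion_mm: float | None = None,
    best_focus_z: float | None = None,
    search_range: tuple[float, float] | None = None,
) -> SystemMetrics:
    """First-order and traced metrics of the train at its best focus.

    Magnification is the chief-ray sensor height over the object field
    height; FOV is the lesser of the sensor-limited and unvignetted object
    field; NA is the paraxial marginal-ray sine; depth of field is the
    axial object range over which the defocus-added RMS blur (in quadrature
    above the best-focus floor) stays below one pixel pitch, evaluated over
    the NA-limited fan.  The diffraction estimate λ/NA² is reported
    alongside.
    """
    front_vertex = train.surfaces[0].vertex_z
    if search_range is None:
        width = front_vertex - train.object_z
        search_range = (train.object_z - width, front_vertex - 0.05 * width)
    if best_focus_z is None:
        best_focus_z = find_best_focus(train, search_range)

    na = numerical_aperture(train, best_focus_z, "paraxial")
    na_real = numerical_aperture(train, best_focus_z, "real")

    h_field = 0.05
    chief = _chief_ray_sensor_height(train, best_focus_z, h_field)
    if chief is None:
        raise RuntimeError("chief ray vignetted at reference field height")
    magnification = abs(chief) / h_field

    sensor_limited = train.sensor.limiting_dimension_mm / magnification
    unvignetted = 2.0 * _unvignetted_field_radius(train, best_focus_z)
    fov = min(sensor_limited, unvignetted) if unvignetted > 0 else sensor_limited

    if dof_criterion_mm is None:
        dof_criterion_mm = train.sensor.pixel_pitch_um * 1e-3

    # depth of field: NA-limited fan, blur added in quadrature above floor
    half_angle = math.degrees(math.asin(na))
    res = minimize_scalar(
        lambda z: _onaxis_rms(train, z, half_angle),
        bounds=search_range,
        method="bounded",
        options={"xatol": 1e-5},
    )
    z0, rms0 = float(res.x), float(res.fun)

    def excess(z: float) -> float:
        r = _onaxis_rms(train, z, half_angle)
        return math.sqrt(max(r * r - rms0 * rms0, 0.0)) - dof_criterion_mm

    span = 0.05
    lo = brentq(excess, z0 - span, z0, xtol=1e-7)
    hi = brentq(excess, z0, z0 + span, xtol=1e-7)
    dof_um = (hi - lo) * 1e3

    dof_diffraction_um = (wavelength_nm / (na * na)) * 1e-3

    return SystemMetrics(
        magnification=magnification,
        field_of_view_diameter_mm=fov,
        best_focus_object_distance_mm=train.reference_z - best_focus_z,
        best_focus_from_front_surface_mm=front_vertex - best_focus_z,
        depth_of_field_um=dof_um,
        depth_of_field_diffraction_um=dof_diffraction_um,
        numerical_aperture=na,
        numerical_aperture_real=na_real,
        rayleigh_resolution_um=0.61 * wavelength_nm / na * 1e-3,
        wavelength_nm=wavelength_nm,
    )


# ---------------------------------------------------------------------------
# helpers


def rayleigh_resolution_um(wavelength_nm: float, na: float) -> float:
    """Rayleigh diffraction limit 0.61 λ / NA, in µm."""
    if na <= 0 or wavelength_nm <= 0:
        raise ValueError("wavelength and NA must be positive")
    return 0.61 * wavelength_nm / na * 1e-3


def usaf_frequency(group: int, element: int) -> float:
    """Spatial frequency (lp/mm) of a 1951 USAF chart element:
    2^(group + (element-1)/6)."""
    if not 1 <= element <= 6:
        raise ValueError("USAF element must be in 1..6")
    return 2.0 ** (group + (element - 1) / 6.0)


def ball_lens_efl(diameter_mm: float, n: float) -> float:
    """Effective focal length of a ball lens measured from its centre:
    nD / 4(n-1)."""
    if n <= 1:
        raise ValueError("ball index must exceed 1")
    return n * diameter_mm / (4.0 * (n - 1.0))


def build_iphone2g_microscope(
    ball_diameter_mm: float = 1.0,
    n_ball: float = 1.5168,
    aperture_diameter_mm: float = 0.8,
    phone_efl_mm: float = 3.36,
    phone_f_number: float = 2.8,
    sensor: SensorModel | None = None,
) -> OpticalTrain:
    """The stock attachment: ball lens + field aperture in front of the
    phone camera (ideal thin lens at its published EFL), sensor at the
    phone lens's focal plane.  z = 0 is the ball centre and the object
    plane starts at the paraxial front focal point.
    """
    if min(ball_diameter_mm, aperture_diameter_mm, phone_efl_mm) <= 0:
        raise ValueError("all dimensions must be positive")
    R = ball_diameter_mm / 2.0
    sensor = sensor or SensorModel()
    stop_z = R + 0.01
    phone_z = R + 0.5
    surfaces = [
        SphericalSurface(-R, R, R, 1.0, n_ball, name="ball front"),
        SphericalSurface(R, -R, R, n_ball, 1.0, name="ball rear"),
        SphericalSurface(
            stop_z, 0.0, aperture_diameter_mm / 2.0, name="field aperture"
        ),
        SphericalSurface(
            phone_z,
            0.0,
            phone_efl_mm / phone_f_number / 2.0,
            focal_length=phone_efl_mm,
            name="phone lens",
        ),
    ]
    efl = ball_lens_efl(ball_diameter_mm, n_ball)
    return OpticalTrain(
        surfaces=surfaces,
        sensor=sensor,
        sensor_z=phone_z + phone_efl_mm,
        object_z=-efl,
        reference_z=0.0,
    )
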