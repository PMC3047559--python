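"""Seeded synthetic fixtures emulating the instrument's degradations.

Everything downstream is scored against these generators: resolution
targets (Ronchi rulings, three-bar elements), blood-smear scenes with
ground truth, field-curvature focal stacks, and dispersed slit images of
line/continuum sources.  All generators are pure functions of their spec
and seed — reruns are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .restore import ImageStack, RadialDistortionModel, distort_image
from .spectro import SpectrometerGeometry, predict_resolution

__all__ = [
    "SmearSceneSpec",
    "AberrationSpec",
    "SpectralSceneSpec",
    "make_ronchi",
    "make_three_bar_target",
    "make_texture",
    "make_blood_smear",
    "apply_aberrations",
    "render_spectral_image",
]

# object-side NA of the stock microscope (paraxial marginal ray); ties the
# defocus-to-blur conversion to the simulated instrument
DEFAULT_NA = 0.48


# ---------------------------------------------------------------------------
# resolution targets


def make_ronchi(
    lp_per_mm: float, pixel_size_um: float, shape: tuple[int, int] = (512, 512)
) -> np.ndarray:
    """Binary square-wave ruling (vertical bars), values {0, 1}.

    Raises if the period is sampled by fewer than 4 pixels.
    """
    period_um = 1000.0 / lp_per_mm
    if period_um / pixel_size_um < 4:
        raise ValueError("undersampled ruling: period below 4 px")
    x_um = np.arange(shape[1]) * pixel_size_um
    bars = (np.floor(2.0 * x_um / period_um).astype(int) % 2 == 0).astype(float)
    return np.tile(bars, (shape[0], 1))


def make_three_bar_target(
    lp_per_mm: float, pixel_size_um: float, pad_px: int = 8
) -> np.ndarray:
    """One USAF-style element: three dark bars (5:1 aspect, spacing equal
    to the bar width) plus the orthogonal triplet, on a bright field."""
    bar_w_um = 1000.0 / (2.0 * lp_per_mm)
    w = bar_w_um / pixel_size_um
    if w < 2:
        raise ValueError("undersampled element: bar width below 2 px")
    wi = max(int(round(w)), 2)
    length = 5 * wi
    block = 5 * wi  # 3 bars + 2 gaps
    h = length + pad_px * 2
    img = np.ones((h, 2 * block + pad_px * 3), dtype=float)
    # vertical bars
    x0 = pad_px
    for k in range(3):
        img[pad_px : pad_px + length, x0 + 2 * k * wi : x0 + (2 * k + 1) * wi] = 0.0
    # horizontal triplet
    y0 = pad_px + (length - block) // 2
    x1 = pad_px * 2 + block
    for k in range(3):
        img[y0 + 2 * k * wi : y0 + (2 * k + 1) * wi, x1 : x1 + length] = 0.0
    return img


def make_texture(
    shape: tuple[int, int] = (512, 512),
    period_px: float = 8.0,
    seed: int = 0,
) -> np.ndarray:
    """Crossed sinusoidal grating in [0, 1] with seeded orientation and
    phases — the standard scene for focus-stack experiments.

    Local contrast is stationary by construction, so the local sharpness
    statistic of a uniformly focused frame is flat across the field and
    any fall-off measures the applied defocus, not the scene."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, math.pi / 2.0)
    ph1, ph2 = rng.uniform(0.0, 2 * math.pi, 2)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    u = xx * math.cos(theta) + yy * math.sin(theta)
    v = -xx * math.sin(theta) + yy * math.cos(theta)
    k = 2 * math.pi / period_px
    tex = 0.5 + 0.25 * (np.sin(k * u + ph1) + np.sin(k * v + ph2))
    return tex


# ---------------------------------------------------------------------------
# blood smear


@dataclass(frozen=True)
class SmearSceneSpec:
    """Protocol for the standard synthetic smear.

    ~115 cells of RBC-scale radius, a tenth of them in touching pairs,
    platelet-scale distractors, a linear illumination ramp and
    Poisson + Gaussian noise with 8-bit quantisation.
    """

    n_cells: int = 115
    clump_fraction: float = 0.10
    cell_radius_mean_um: float = 3.9
    cell_radius_sd_um: float = 0.3
    platelet_count: int = 15
    platelet_radius_um: float = 1.0
    background_ramp: float = 0.15
    poisson_scale: float = 800.0
    gaussian_sd: float = 0.008
    pixel_size_um: float = 0.5
    shape: tuple[int, int] = (512, 512)
    background_level: float = 0.85
    pallor: float = 0.45  # centre absorbance relative to rim (1 = flat disk)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.platelet_count < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.clump_fraction <= 1:
            raise ValueError("clump_fraction must lie in [0, 1]")


def _place_disks(rng, shape, radii_px, pair_of, margin, max_attempts=20000):
    """Rejection-sample non-overlapping centres; paired cells touch."""
    centres: list[tuple[float, float]] = []
    h, w = shape
    for i, r in enumerate(radii_px):
        partner = pair_of[i]
        for attempt in range(max_attempts):
            if partner is not None and partner < i:
                # place touching the partner, overlapping by ~30% of radius
                ang = rng.uniform(0, 2 * math.pi)
                d = 1.7 * 0.5 * (r + radii_px[partner])
                cy = centres[partner][0] + d * math.sin(ang)
                cx = centres[partner][1] + d * math.cos(ang)
            else:
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
            if not (margin <= cy <= h - margin and margin <= cx <= w - margin):
                continue
            ok = True
            for j, (oy, ox) in enumerate(centres):
                if j == partner:
                    continue
                lim = 1.15 * (r + radii_px[j])
                if (cy - oy) ** 2 + (cx - ox) ** 2 < lim * lim:
                    ok = False
                    break
            if ok:
                centres.append((cy, cx))
                break
        else:
            raise RuntimeError("could not place cells within the overlap budget")
    return centres


def make_blood_smear(spec: SmearSceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the smear and its ground truth.

    Cells are absorbing disks with central pallor (annulus profile),
    clumped cells are overlapping pairs the watershed must split,
    platelets are small dense dots below the counting area cut-off.
    Returns (image in [0, 1], truth table with one row per object).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px = spec.pixel_size_um

    n_clumped = int(round(spec.n_cells * spec.clump_fraction))
    n_pairs = n_clumped // 2

    radii_um = np.clip(
        rng.normal(spec.cell_radius_mean_um, spec.cell_radius_sd_um, spec.n_cells),
        0.5 * spec.cell_radius_mean_um,
        1.5 * spec.cell_radius_mean_um,
    )
    radii_px = list(radii_um / px)
    pair_of: list[int | None] = [None] * spec.n_cells
    for p in range(n_pairs):
        a, b = 2 * p, 2 * p + 1
        pair_of[a], pair_of[b] = b, a
    # platelets placed last, allowed anywhere not inside a cell
    radii_px += [spec.platelet_radius_um / px] * spec.platelet_count
    pair_of += [None] * spec.platelet_count

    margin = max(radii_px) * 2 + 2
    centres = _place_disks(rng, spec.shape, radii_px, pair_of, margin)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    absorb = np.zeros((h, w))
    rows = []
    for i, ((cy, cx), r_px) in enumerate(zip(centres, radii_px)):
        is_cell = i < spec.n_cells
        y0, y1 = int(max(cy - r_px - 2, 0)), int(min(cy + r_px + 3, h))
        x0, x1 = int(max(cx - r_px - 2, 0)), int(min(cx + r_px + 3, w))
        rr = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx) / r_px
        edge = np.clip((1.0 - rr) * r_px + 0.5, 0.0, 1.0)  # ~1 px soft rim
        if is_cell:
            profile = spec.pallor + (1.0 - spec.pallor) * np.clip(rr, 0, 1) ** 2
            depth = 0.55
        else:
            profile = np.ones_like(rr)
            depth = 0.75  # optically dense platelet
        absorb[y0:y1, x0:x1] += depth * profile * edge
        clump = pair_of[i] if i < spec.n_cells else None
        rows.append(
            {
                "x_px": cx,
                "y_px": cy,
                "radius_um": r_px * px,
                "kind": "cell" if is_cell else "platelet",
                "clump_partner": -1 if clump is None else clump,
            }
        )

    theta = rng.uniform(0, 2 * math.pi)
    ramp_coord = (
        (xx - w / 2) * math.cos(theta) + (yy - h / 2) * math.sin(theta)
    ) / max(h, w)
    illumination = 1.0 + spec.background_ramp * ramp_coord
    img = spec.background_level * illumination * np.exp(-absorb)

    if spec.poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    img = np.round(img * 255.0) / 255.0  # 8-bit quantisation, phone sensor
    return img, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# field curvature + distortion


@dataclass(frozen=True)
class AberrationSpec:
    """Ball-lens field degradations.

    The focal surface is a sphere of radius ``field_curvature_radius_mm``
    (defocus Δz(r) = r²/2R grows quadratically with field radius); defocus
    maps to Gaussian blur at ``blur_per_defocus_px_per_um`` = NA / pixel
    size, keeping the fixture tethered to the simulated instrument.  An
    optional radial distortion model adds the pincushion warp.
    """

    field_curvature_radius_mm: float = 0.734  # ball-lens EFL from centre
    pixel_size_um: float = 0.5
    blur_per_defocus_px_per_um: float = DEFAULT_NA / 0.5
    distortion: RadialDistortionModel | None = None

    def defocus_um(self, r_um: np.ndarray) -> np.ndarray:
        if math.isinf(self.field_curvature_radius_mm):
            return np.zeros_like(np.asarray(r_um, dtype=float))
        return np.asarray(r_um, dtype=float) ** 2 / (
            2.0 * self.field_curvature_radius_mm * 1000.0
        )


def _variable_blur(img: np.ndarray, sigma_map: np.ndarray, step: float = 0.5):
    """Spatially-varying Gaussian blur by interpolating between uniformly
    blurred copies at quantised sigma levels."""
    smax = float(sigma_map.max())
    if smax < 1e-3:
        return img.copy()
    levels = np.arange(0.0, smax + step, step)
    stack = [img if s == 0 else ndimage.gaussian_filter(img, s, mode="reflect") for s in levels]
    idx = np.clip(sigma_map / step, 0, len(levels) - 1)
    lo = np.floor(idx).astype(int)
    hi = np.minimum(lo + 1, len(levels) - 1)
    frac = idx - lo
    out = np.empty_like(img)
    flat_lo = np.take_along_axis(np.stack(stack), lo[None], axis=0)[0]
    flat_hi = np.take_along_axis(np.stack(stack), hi[None], axis=0)[0]
    out = flat_lo * (1 - frac) + flat_hi * frac
    return out


def apply_aberrations(
    image: np.ndarray,
    spec: AberrationSpec,
    focal_offsets_um: tuple[float, ...] = (0.0, 2.0),
) -> ImageStack:
    """Emit one frame per focal offset.

    Each frame is blurred with σ(r) = blur_per_defocus · |Δz(r) − offset|
    (only the ring of the field intersecting the focal sphere is sharp),
    then warped by the distortion model if present.  With an infinite
    curvature radius, no distortion and zero offset the frame is returned
    unchanged.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    r_um = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0) * spec.pixel_size_um
    dz = spec.defocus_um(r_um)
    frames = []
    for off in focal_offsets_um:
        sigma = spec.blur_per_defocus_px_per_um * np.abs(dz - off)
        frame = _variable_blur(img, sigma)
        if spec.distortion is not None:
            frame = distort_image(frame, spec.distortion)
        frames.append(frame)
    return ImageStack(frames, list(focal_offsets_um))


# ---------------------------------------------------------------------------
# dispersed slit images


@dataclass(frozen=True)
class SpectralSceneSpec:
    """Scene for the spectrometer fixture.

    ``lines`` are (wavelength nm, amplitude, intrinsic FWHM nm); fixture
    lamp lines default to the fluorescent triplet 436/546/611 nm.
    ``pixel_map`` are ascending polynomial coefficients of the nm→px
    mapping.  ``continuum_K`` adds a Planck continuum at that temperature.
    """

    lines: tuple[tuple[float, float, float], ...] = (
        (436.0, 1.0, 0.0),
        (546.0, 1.0, 0.0),
        (611.0, 0.7, 0.0),
    )
    continuum_K: float | None = None
    continuum_amplitude: float = 0.0
    geometry: SpectrometerGeometry = field(default_factory=SpectrometerGeometry)
    pixel_map: tuple[float, ...] = (-640.0, 2.0)  # px = -640 + 2·λ  (400→160)
    shape: tuple[int, int] = (120, 640)
    slit_rows: tuple[int, int] = (20, 100)
    gaussian_sd: float = 0.003
    seed: int = 0


def _planck(wl_nm: np.ndarray, T: float) -> np.ndarray:
    wl = wl_nm * 1e-9
    h, c, kb = 6.626e-34, 2.998e8, 1.381e-23
    return (1.0 / wl**5) / np.expm1(h * c / (wl * kb * T))


def render_spectral_image(spec: SpectralSceneSpec):
    """Render the dispersed slit image and its ground truth.

    Each line sits at its mapped pixel and carries the two-slit triangular
    acceptance profile (FWHM from the forward model at that wavelength)
    convolved with its intrinsic Gaussian width; the continuum is a Planck
    curve times the mapping Jacobian.  Returns (image, truth dict).
    """
    h, w = spec.shape
    coeffs = np.array(spec.pixel_map, dtype=float)
    # wavelength axis per column: invert the monotonic nm->px polynomial
    wl_grid = np.linspace(200.0, 1200.0, 20001)
    px_grid = np.polynomial.polynomial.polyval(wl_grid, coeffs)
    if np.any(np.diff(px_grid) <= 0):
        raise ValueError("pixel_map must be strictly increasing")
    cols = np.arange(w, dtype=float)
    wl_cols = np.interp(cols, px_grid, wl_grid)
    dldp = np.gradient(wl_cols)  # nm per pixel

    profile = np.zeros(w)
    truth_lines = []
    for wl0, amp, intrinsic_fwhm in spec.lines:
        px0 = float(np.polynomial.polynomial.polyval(wl0, coeffs))
        if not 0 <= px0 <= w - 1:
            raise ValueError(f"line {wl0} nm maps outside the pixel range")
        slit_fwhm = predict_resolution(spec.geometry, wl0)
        dl = wl_cols - wl0
        tri = np.clip(1.0 - np.abs(dl) / slit_fwhm, 0.0, 1.0)
        if intrinsic_fwhm > 0:
            sig_px = intrinsic_fwhm / 2.3548 / abs(dldp[int(round(px0))])
            tri = ndimage.gaussian_filter1d(tri, sig_px, mode="constant")
            total_fwhm = math.hypot(slit_fwhm, intrinsic_fwhm)
        else:
            total_fwhm = slit_fwhm
        profile += amp * tri
        truth_lines.append(
            {"wavelength_nm": wl0, "pixel": px0, "fwhm_nm": total_fwhm}
        )

    if spec.continuum_K is not None and spec.continuum_amplitude > 0:
        planck = _planck(wl_cols, spec.continuum_K) * np.abs(dldp)
        profile += spec.continuum_amplitude * planck / planck.max()

    img = np.zeros((h, w))
    r0, r1 = spec.slit_rows
    img[r0:r1, :] = profile
    # soft one-pixel vertical roll-off at the slit-image edges
    img = ndimage.gaussian_filter1d(img, 1.0, axis=0, mode="constant")

    rng = np.random.default_rng(spec.seed)
    if spec.gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.gaussian_sd, img.shape)
    img = np.clip(img, 0.0, None)
    truth = {"lines": truth_lines, "wavelength_per_column": wl_cols}
    return img, truth
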