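"""Forward model, calibration and spectrum extraction for a slit-grating
phone spectrometer.

The instrument is a transmission grating taped over the camera window with a
baffled tube carrying an entrance slit at its far end; the two slits define
an angular acceptance and the grating disperses it across the sensor.  The
spectral resolution is set by the convolution of the two slit acceptance
functions: for equal slits a triangle of FWHM w/L, in general the FWHM of
the rect*rect trapezoid, max(w1, w2)/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectrometerGeometry",
    "WavelengthCalibration",
    "SpectrumTrace",
    "diffraction_angle",
    "predict_resolution",
    "extract_spectrum",
    "apply_calibration",
    "calibrate",
    "fwhm",
    "transmission_ratio",
]


@dataclass(frozen=True)
class SpectrometerGeometry:
    """Physical dispersion geometry.

    Defaults are the stock build: 1000 lp/mm grating, 77.5 mm tube, ~1 mm
    slits, first order, normal incidence along the tube axis.
    """

    groove_density_lpmm: float = 1000.0
    tube_length_mm: float = 77.5
    entrance_slit_mm: float = 1.0
    detector_slit_mm: float = 1.0
    diffraction_order: int = 1
    incidence_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.groove_density_lpmm <= 0:
            raise ValueError("groove density must be positive")
        if min(self.entrance_slit_mm, self.detector_slit_mm) <= 0:
            raise ValueError("slit widths must be positive")
        if abs(self.diffraction_order) < 1:
            raise ValueError("|diffraction order| must be >= 1")

    @property
    def groove_spacing_nm(self) -> float:
        return 1e6 / self.groove_density_lpmm


@dataclass
class SpectrumTrace:
    """Calibrated spectrum: ascending wavelengths (nm) and intensities."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity lengths differ")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class WavelengthCalibration:
    """Fitted pixel -> nm polynomial (ascending coefficients)."""

    coefficients: np.ndarray
    degree: int
    residual_rms_nm: float
    valid_pixel_range: tuple[float, float]

    def __call__(self, pixels) -> np.ndarray:
        return np.polynomial.polynomial.polyval(
            np.asarray(pixels, dtype=float), self.coefficients
        )


def diffraction_angle(wavelength_nm: float, geometry: SpectrometerGeometry) -> float:
    """First-principles grating equation: sin θi + sin θm = mλ/d.

    Returns the diffracted angle θm in degrees; raises for evanescent
    orders (|sin θm| > 1).
    """
    d = geometry.groove_spacing_nm
    s = (
        geometry.diffraction_order * wavelength_nm / d
        - math.sin(math.radians(geometry.incidence_angle_deg))
    )
    if abs(s) > 1.0:
        raise ValueError("evanescent diffraction order")
    return math.degrees(math.asin(s))


def slit_acceptance_fwhm_rad(geometry: SpectrometerGeometry) -> float:
    """FWHM of the two-slit angular acceptance (rect * rect convolution)."""
    if geometry.tube_length_mm <= 0:
        raise ValueError("tube length must be positive")
    return (
        max(geometry.entrance_slit_mm, geometry.detector_slit_mm)
        / geometry.tube_length_mm
    )


def predict_resolution(
    geometry: SpectrometerGeometry, wavelength_nm: float
) -> float:
    """Predicted spectral FWHM (nm): Δλ = d · cos θm · Δθ.

    Δθ is the slit-acceptance FWHM; scales linearly with the wider slit and
    inversely with tube length.
    """
    theta_m = math.radians(diffraction_angle(wavelength_nm, geometry))
    return (
        geometry.groove_spacing_nm
        * math.cos(theta_m)
        * slit_acceptance_fwhm_rad(geometry)
    )


def extract_spectrum(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    channel_mode: str = "sum",
    background_roi: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Collapse the dispersed slit image to a pixel-indexed trace.

    ``roi`` is (x, y, w, h), origin top-left, half-open; the dispersion
    axis is horizontal and rows inside the ROI are averaged.  RGB frames
    are reduced per ``channel_mode``: "sum" (default), "luminance", or an
    integer channel index.  If ``background_roi`` is given, its row-average
    is subtracted.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        if channel_mode == "sum":
            img = img.sum(axis=2)
        elif channel_mode == "luminance":
            img = img[..., 0] * 0.2126 + img[..., 1] * 0.7152 + img[..., 2] * 0.0722
        else:
            img = img[..., int(channel_mode)]
    elif img.ndim != 2:
        raise ValueError("image must be 2-D or RGB")

    def roi_mean(r):
        x, y, w, h = r
        if w <= 0 or h <= 0:
            raise ValueError("empty ROI")
        if x < 0 or y < 0 or x + w > img.shape[1] or y + h > img.shape[0]:
            raise ValueError("ROI outside image")
        return img[y : y + h, x : x + w].mean(axis=0)

    if roi is None:
        roi = (0, 0, img.shape[1], img.shape[0])
    tr = roi_mean(roi)
    if background_roi is not None:
        bg = roi_mean(
            (roi[0], background_roi[1], roi[2], background_roi[3])
            if background_roi[0] is None
            else background_roi
        )
        tr = tr - bg
    return tr


def apply_calibration(
    trace_px: np.ndarray, calib: WavelengthCalibration, pixel_offset: int = 0
) -> SpectrumTrace:
    """Attach wavelengths to a pixel-indexed trace."""
    px = np.arange(len(trace_px), dtype=float) + pixel_offset
    wl = calib(px)
    if wl[0] > wl[-1]:
        wl, trace_px = wl[::-1], np.asarray(trace_px)[::-1]
    return SpectrumTrace(wl, np.asarray(trace_px, dtype=float))


def calibrate(
    peak_pixels,
    peak_wavelengths_nm,
    degree: int = 1,
    valid_pixel_range: tuple[float, float] | None = None,
) -> WavelengthCalibration:
    """Least-squares pixel→nm polynomial from lamp-line positions.

    Pairing is order-invariant (pairs are sorted by pixel).  The fitted
    mapping must be strictly monotonic over the valid pixel range.
    """
    px = np.asarray(peak_pixels, dtype=float)
    wl = np.asarray(peak_wavelengths_nm, dtype=float)
    if px.shape != wl.shape or px.ndim != 1:
        raise ValueError("pixel and wavelength lists must match")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(px) < degree + 1:
        raise ValueError("need at least degree+1 calibration lines")
    order = np.argsort(px)
    px, wl = px[order], wl[order]
    coeffs = np.polynomial.polynomial.polyfit(px, wl, degree)
    fit = np.polynomial.polynomial.polyval(px, coeffs)
    residual = float(np.sqrt(np.mean((fit - wl) ** 2)))
    if valid_pixel_range is None:
        valid_pixel_range = (float(px.min()), float(px.max()))
    grid = np.linspace(*valid_pixel_range, 257)
    deriv = np.polynomial.polynomial.polyval(
        grid, np.polynomial.polynomial.polyder(coeffs)
    )
    if not (np.all(deriv > 0) or np.all(deriv < 0)):
        raise ValueError("fitted mapping is not monotonic over the valid range")
    return WavelengthCalibration(coeffs, degree, residual, valid_pixel_range)


def find_peak_pixels(trace_px: np.ndarray, n_peaks: int, min_separation_px: int = 10):
    """Sub-pixel positions of the ``n_peaks`` strongest local maxima of a
    pixel-indexed trace (parabolic refinement), sorted by pixel."""
    from scipy.signal import find_peaks

    y = np.asarray(trace_px, dtype=float)
    idx, props = find_peaks(y, distance=min_separation_px, prominence=0.0)
    if len(idx) < n_peaks:
        raise ValueError(f"found only {len(idx)} peaks, need {n_peaks}")
    top = idx[np.argsort(props["prominences"])[::-1][:n_peaks]]
    out = []
    for i in sorted(top):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if abs(denom) > 1e-12 else 0.0
        else:
            delta = 0.0
        out.append(i + float(np.clip(delta, -1, 1)))
    return np.array(out)


def fwhm(trace: SpectrumTrace, peak_wavelength_nm: float) -> float:
    """Linear-interpolated full width at half maximum of the line nearest
    ``peak_wavelength_nm``, above the local background.

    Background is taken as the mean of the valley minima flanking the
    peak.  Raises if the half level is not crossed on both sides.
    """
    wl, y = trace.wavelength_nm, trace.intensity
    i0 = int(np.argmin(np.abs(wl - peak_wavelength_nm)))
    # climb to the local maximum
    while 0 < i0 < len(y) - 1:
        if y[i0 + 1] > y[i0]:
            i0 += 1
        elif y[i0 - 1] > y[i0]:
            i0 -= 1
        else:
            break
    # walk down both flanks to the bounding minima
    il = i0
    while il > 0 and y[il - 1] <= y[il]:
        il -= 1
    ir = i0
    while ir < len(y) - 1 and y[ir + 1] <= y[ir]:
        ir += 1
    background = 0.5 * (y[il] + y[ir])
    peak = y[i0]
    if peak <= background:
        raise ValueError("peak is not a local maximum above background")
    half = background + 0.5 * (peak - background)

    def crossing(a: int, b: int, step: int) -> float:
        i = a
        while i != b:
            j = i + step
            if (y[i] - half) * (y[j] - half) <= 0 and y[i] != y[j]:
                f = (half - y[i]) / (y[j] - y[i])
                return float(wl[i] + f * (wl[j] - wl[i]))
            i = j
        raise ValueError("half level not crossed on both sides of the peak")

    left = crossing(i0, il, -1)
    right = crossing(i0, ir, +1)
    return abs(right - left)


def transmission_ratio(
    sample: SpectrumTrace,
    reference: SpectrumTrace,
    noise_floor_fraction: float = 0.02,
) -> SpectrumTrace:
    """Sample/reference ratio on the reference wavelength grid.

    The sample is linearly interpolated to the reference grid over the
    overlapping range; wavelengths where the reference falls below
    ``noise_floor_fraction`` of its maximum are masked (NaN), never
    divided.  The result is relative — phone cameras autoscale, so no
    absolute transmission is claimed.
    """
    lo = max(sample.wavelength_nm[0], reference.wavelength_nm[0])
    hi = min(sample.wavelength_nm[-1], reference.wavelength_nm[-1])
    if lo >= hi:
        raise ValueError("wavelength ranges do not overlap")
    sel = (reference.wavelength_nm >= lo) & (reference.wavelength_nm <= hi)
    wl = reference.wavelength_nm[sel]
    ref = reference.intensity[sel]
    smp = np.interp(wl, sample.wavelength_nm, sample.intensity)
    floor = noise_floor_fraction * ref.max()
    ratio = np.full_like(ref, np.nan)
    ok = ref > floor
    ratio[ok] = smp[ok] / ref[ok]
    return SpectrumTrace(wl, ratio, metadata={"masked": int((~ok).sum())})
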