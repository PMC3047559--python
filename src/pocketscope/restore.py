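"""Field-of-view restoration for ball-lens micrographs.

A single ball lens images a curved focal surface onto a flat sensor, so
sharpness falls off radially; it also shows pincushion distortion
(field-dependent magnification).  Two remedies live here:

* multifocus fusion — several frames at different sample heights are merged
  in a multiscale transform domain, each coefficient taken from the frame
  with the largest local sum-modified Laplacian (SML) focus measure;
* radial distortion fitting and resampling against a known grid target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.transform import resize

__all__ = [
    "ImageStack",
    "DecisionMap",
    "RadialDistortionModel",
    "sml_map",
    "fuse_multifocus",
    "usable_fov",
    "fit_pincushion",
    "undistort",
    "distort_image",
]


@dataclass
class ImageStack:
    """Co-registered focal series: frames of identical shape, optional
    per-frame focal offsets (µm) as metadata."""

    frames: list[np.ndarray]
    focal_offsets_um: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("stack needs at least one frame")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share one shape")


@dataclass
class DecisionMap:
    """Which frame won each transform coefficient.

    ``subbands`` mirrors the transform layout; ``pixel`` is a full-resolution
    winner map (from the finest decision level) for inspection and for
    chrominance selection.
    """

    subbands: list[tuple[str, np.ndarray]]
    pixel: np.ndarray
    n_frames: int


# ---------------------------------------------------------------------------
# focus measure


def sml_map(image: np.ndarray, step: int = 1, window: int = 3) -> np.ndarray:
    """Sum-modified Laplacian focus map.

    ML(x,y) = |2I − I(x−s,·) − I(x+s,·)| + |2I − I(·,y−s) − I(·,y+s)|,
    summed over a ``window``×``window`` neighbourhood; borders reflect.
    Non-negative everywhere; identically zero for a constant image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("sml_map expects a 2-D grayscale image")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > min(img.shape):
        raise ValueError("window larger than image")
    p = np.pad(img, step, mode="reflect")
    c = p[step:-step, step:-step]
    up = p[: -2 * step, step:-step]
    dn = p[2 * step :, step:-step]
    lf = p[step:-step, : -2 * step]
    rt = p[step:-step, 2 * step :]
    ml = np.abs(2 * c - up - dn) + np.abs(2 * c - lf - rt)
    if window == 1:
        return ml
    return ndimage.uniform_filter(ml, size=window, mode="reflect") * window**2


def _majority_filter(winner: np.ndarray, n_frames: int, size: int = 3) -> np.ndarray:
    """Single-pass majority vote over a size×size neighbourhood."""
    votes = np.stack(
        [
            ndimage.uniform_filter((winner == k).astype(float), size=size, mode="nearest")
            for k in range(n_frames)
        ]
    )
    return np.argmax(votes, axis=0).astype(np.int32)


# ---------------------------------------------------------------------------
# multiscale transforms (pluggable: separable wavelet default, Laplacian
# pyramid alternative)


def _laplacian_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = []
    current = img
    for _ in range(levels):
        down = resize(
            current,
            (max(current.shape[0] // 2, 1), max(current.shape[1] // 2, 1)),
            order=1,
            mode="reflect",
            anti_aliasing=True,
        )
        up = resize(down, current.shape, order=1, mode="reflect")
        pyr.append(current - up)
        current = down
    pyr.append(current)
    return pyr


def _laplacian_reconstruct(pyr: list[np.ndarray]) -> np.ndarray:
    current = pyr[-1]
    for band in reversed(pyr[:-1]):
        current = resize(current, band.shape, order=1, mode="reflect") + band
    return current


def _decompose(img: np.ndarray, transform: str, levels: int, wavelet: str):
    if transform == "wavelet":
        return pywt.wavedec2(img, wavelet, level=levels, mode="symmetric")
    if transform == "laplacian":
        return _laplacian_pyramid(img, levels)
    raise ValueError(f"unknown transform {transform!r}")


def _reconstruct(coeffs, transform: str, wavelet: str) -> np.ndarray:
    if transform == "wavelet":
        return pywt.waverec2(coeffs, wavelet, mode="symmetric")
    return _laplacian_reconstruct(coeffs)


# ---------------------------------------------------------------------------
# fusion


def _select(arrays: list[np.ndarray], winner: np.ndarray) -> np.ndarray:
    out = arrays[0].copy()
    for k in range(1, len(arrays)):
        out[winner == k] = arrays[k][winner == k]
    return out


def fuse_multifocus(
    stack: ImageStack,
    levels: int = 3,
    window: int = 3,
    transform: str = "wavelet",
    wavelet: str = "db2",
) -> tuple[np.ndarray, DecisionMap]:
    """Fuse a focal series coefficient-by-coefficient.

    Each transform coefficient is taken from the frame whose subband has
    the largest local SML there (ties go to the lowest frame index), after
    a single-pass 3×3 majority vote smooths the per-subband decision maps.
    The inverse transform returns a fused image of the input shape with the
    pixel range clipped to the input envelope.

    Grayscale frames fuse directly; RGB frames fuse on luminance with
    chrominance copied per pixel from the winning frame.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(stack.frames) < 2:
        raise ValueError("fusion needs at least two frames")
    frames = [np.asarray(f, dtype=float) for f in stack.frames]
    color = frames[0].ndim == 3
    if color:
        gray = [
            f[..., 0] * 0.2126 + f[..., 1] * 0.7152 + f[..., 2] * 0.0722
            for f in frames
        ]
    else:
        gray = frames

    decomps = [_decompose(g, transform, levels, wavelet) for g in gray]
    n = len(frames)
    fused_coeffs = []
    subband_maps: list[tuple[str, np.ndarray]] = []
    pixel_map = None

    for li, band in enumerate(zip(*decomps)):
        if isinstance(band[0], tuple):  # wavelet detail triple (cH, cV, cD)
            fused_band = []
            for bi, sub in enumerate(zip(*band)):
                acts = [sml_map(s, 1, min(window, _odd_cap(s))) for s in sub]
                winner = _majority_filter(np.argmax(np.stack(acts), axis=0), n)
                fused_band.append(_select(list(sub), winner))
                subband_maps.append((f"L{li}.{'HVD'[bi]}", winner))
                if li == len(decomps[0]) - 1 and bi == 0:
                    pixel_map = winner
            fused_coeffs.append(tuple(fused_band))
        else:
            sub = band
            acts = [sml_map(s, 1, min(window, _odd_cap(s))) for s in sub]
            winner = _majority_filter(np.argmax(np.stack(acts), axis=0), n)
            fused_coeffs.append(_select(list(sub), winner))
            subband_maps.append((f"L{li}.A", winner))
            if pixel_map is None:
                pixel_map = winner

    fused_gray = _reconstruct(fused_coeffs, transform, wavelet)
    fused_gray = fused_gray[: gray[0].shape[0], : gray[0].shape[1]]
    lo = np.minimum.reduce([g.min() for g in gray])
    hi = np.maximum.reduce([g.max() for g in gray])
    fused_gray = np.clip(fused_gray, lo, hi)

    pixel = resize(
        pixel_map.astype(float), gray[0].shape, order=0, mode="edge"
    ).astype(np.int32)
    dm = DecisionMap(subband_maps, pixel, n)

    if not color:
        return fused_gray, dm

    # luminance from the fusion, chrominance from the per-pixel winner
    fused = np.empty_like(frames[0])
    win_lum = _select(gray, pixel)
    scale = np.where(win_lum > 1e-9, fused_gray / np.maximum(win_lum, 1e-9), 1.0)
    for c in range(frames[0].shape[2]):
        chroma = _select([f[..., c] for f in frames], pixel)
        fused[..., c] = np.clip(chroma * scale, 0, max(f.max() for f in frames))
    return fused, dm


def _odd_cap(arr: np.ndarray) -> int:
    m = min(arr.shape)
    return m if m % 2 == 1 else m - 1


# ---------------------------------------------------------------------------
# usable field of view


def usable_fov(
    image: np.ndarray,
    sharpness_threshold_fraction: float = 0.5,
    block_px: int = 16,
    pixel_size_um: float | None = None,
) -> dict:
    """Largest centred square over which the image stays locally sharp.

    The image is tiled into ``block_px`` squares, block-mean SML is
    compared against ``threshold × peak block SML``, and the largest
    centred square whose blocks all pass is returned (side in px, and in
    µm when the object-plane pixel size is supplied).
    """
    if not 0 < sharpness_threshold_fraction < 1:
        raise ValueError("threshold must lie in (0, 1)")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    s = sml_map(img, 1, 3)
    nb_r, nb_c = img.shape[0] // block_px, img.shape[1] // block_px
    if nb_r < 1 or nb_c < 1:
        raise ValueError("block size exceeds image")
    blocks = (
        s[: nb_r * block_px, : nb_c * block_px]
        .reshape(nb_r, block_px, nb_c, block_px)
        .mean(axis=(1, 3))
    )
    peak = blocks.max()
    ok = blocks >= sharpness_threshold_fraction * peak
    best = 0
    for s in range(1, min(nb_r, nb_c) + 1):
        r0, c0 = (nb_r - s) // 2, (nb_c - s) // 2
        if ok[r0 : r0 + s, c0 : c0 + s].all():
            best = s
        else:
            break
    side_px = best * block_px
    out = {"side_px": side_px, "side_blocks": best, "block_px": block_px}
    if pixel_size_um is not None:
        out["side_um"] = side_px * pixel_size_um
    return out


# ---------------------------------------------------------------------------
# radial distortion


@dataclass
class RadialDistortionModel:
    """Polynomial radial distortion about a fitted centre.

    Distorted radius r_d = r · (1 + k1·ρ² + k2·ρ⁴) with ρ = r / norm_radius
    (normalised-radius convention, so k1 and k2 are scale-free).  Positive
    k1 is pincushion, negative barrel.
    """

    center: np.ndarray
    k1: float
    k2: float = 0.0
    norm_radius: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)

    def distort_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        v = pts - self.center
        rho2 = (v**2).sum(axis=-1) / self.norm_radius**2
        f = 1.0 + self.k1 * rho2 + self.k2 * rho2**2
        return self.center + v * f[..., None]

    def undistort_points(self, pts: np.ndarray, iterations: int = 20) -> np.ndarray:
        """Invert the radial map by fixed-point iteration on the radius."""
        pts = np.asarray(pts, dtype=float)
        v = pts - self.center
        ideal = v.copy()
        for _ in range(iterations):
            rho2 = (ideal**2).sum(axis=-1) / self.norm_radius**2
            f = 1.0 + self.k1 * rho2 + self.k2 * rho2**2
            ideal = v / f[..., None]
        return self.center + ideal


def fit_pincushion(
    observed: np.ndarray,
    ideal: np.ndarray,
    norm_radius: float | None = None,
    fit_center: bool = True,
) -> tuple[RadialDistortionModel, float]:
    """Least-squares radial-distortion fit from point correspondences.

    ``observed`` are distorted image coordinates of features whose true
    (undistorted) positions are ``ideal``; both (n, 2), n ≥ 12, spanning
    the field.  Returns the model and the RMS residual in pixels.
    """
    obs = np.asarray(observed, dtype=float)
    idl = np.asarray(ideal, dtype=float)
    if obs.shape != idl.shape or obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("correspondence arrays must both be (n, 2)")
    if len(obs) < 12:
        raise ValueError("need at least 12 correspondences")
    spread = idl.std(axis=0)
    if min(spread) < 1e-6 or np.linalg.matrix_rank(idl - idl.mean(0)) < 2:
        raise ValueError("degenerate correspondences (collinear or central-only)")
    if norm_radius is None:
        norm_radius = float(np.linalg.norm(idl - idl.mean(0), axis=1).max())

    c0 = idl.mean(axis=0)

    def linear_k(center):
        """k1, k2 by linear least squares at a fixed centre."""
        v = idl - center
        rho2 = (v**2).sum(axis=1) / norm_radius**2
        A = np.concatenate([v * rho2[:, None], v * (rho2**2)[:, None]]).reshape(
            2, -1, 2
        )
        A = np.stack([A[0].ravel(), A[1].ravel()], axis=1)
        b = (obs - center - v).ravel()
        k, *_ = np.linalg.lstsq(A, b, rcond=None)
        return k

    k_init = linear_k(c0)

    if fit_center:

        def residual(p):
            cx, cy, k1, k2 = p
            m = RadialDistortionModel(np.array([cx, cy]), k1, k2, norm_radius)
            return (m.distort_points(idl) - obs).ravel()

        # keep the centre inside the field: a far-away centre is a
        # degenerate local minimum of the radial model
        half = 0.75 * norm_radius
        sol = least_squares(
            residual,
            np.array([c0[0], c0[1], k_init[0], k_init[1]]),
            bounds=(
                [c0[0] - half, c0[1] - half, -10.0, -10.0],
                [c0[0] + half, c0[1] + half, 10.0, 10.0],
            ),
            xtol=1e-14,
            ftol=1e-14,
        )
        cx, cy, k1, k2 = sol.x
        model = RadialDistortionModel(np.array([cx, cy]), k1, k2, norm_radius)
    else:

        def residual(p):
            m = RadialDistortionModel(c0, p[0], p[1], norm_radius)
            return (m.distort_points(idl) - obs).ravel()

        sol = least_squares(residual, k_init, xtol=1e-14, ftol=1e-14)
        model = RadialDistortionModel(c0, sol.x[0], sol.x[1], norm_radius)
    rms = float(np.sqrt((sol.fun**2).reshape(-1, 2).sum(axis=1).mean()))
    return model, rms


def _warp(image: np.ndarray, mapper) -> np.ndarray:
    img = np.asarray(image, dtype=float)

    def warp_plane(plane):
        rows, cols = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
        pts = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
        src = mapper(pts)
        coords = np.stack(
            [src[:, 1].reshape(plane.shape), src[:, 0].reshape(plane.shape)]
        )
        return ndimage.map_coordinates(plane, coords, order=1, mode="reflect")

    if img.ndim == 3:
        return np.stack([warp_plane(img[..., c]) for c in range(img.shape[2])], axis=-1)
    return warp_plane(img)


def undistort(image: np.ndarray, model: RadialDistortionModel) -> np.ndarray:
    """Resample the image onto the ideal (undistorted) grid.

    For each ideal output pixel the distorted source position is computed
    with the forward model and sampled bilinearly, so straight scene lines
    (e.g. a Ronchi ruling) become straight.
    """
    return _warp(image, model.distort_points)


def distort_image(image: np.ndarray, model: RadialDistortionModel) -> np.ndarray:
    """Apply the distortion to a clean image (synthesis direction)."""
    return _warp(image, model.undistort_points)
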