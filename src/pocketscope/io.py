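"""Shared readers/writers: images, YAML configs, CSV spectra, JSON reports.

Conventions used everywhere: image origin top-left, x = column, y = row,
0-based, half-open ROIs; config keys carry units as suffixes (``_mm``,
``_um``, ``_nm``) so quantities cannot drift silently.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, is_dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .optics import OpticalTrain, SensorModel, SphericalSurface
from .restore import RadialDistortionModel
from .spectro import SpectrometerGeometry, SpectrumTrace, WavelengthCalibration

__all__ = [
    "read_image",
    "write_image",
    "read_yaml",
    "write_json_atomic",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "load_prescription",
    "load_geometry",
    "save_calibration",
    "load_calibration",
    "save_distortion",
    "load_distortion",
    "provenance",
]


def read_image(path: str, as_float: bool = True) -> np.ndarray:
    img = iio.imread(path)
    if as_float:
        img = np.asarray(img, dtype=float)
        if img.max() > 1.0:
            img = img / (65535.0 if img.max() > 255 else 255.0)
    return img


def write_image(path: str, image: np.ndarray, bit_depth: int = 8) -> None:
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi > 1.0 or lo < 0.0:
        img = (img - lo) / max(hi - lo, 1e-12)
    if bit_depth == 16:
        iio.imwrite(path, (img * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, (img * 255).astype(np.uint8))


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json_atomic(path: str, payload: dict) -> None:
    """Write JSON via a temp file + rename so partial artifacts never land."""

    def default(o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    d = os.path.dirname(os.path.abspath(path)) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, default=default)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def read_spectrum_csv(path: str) -> SpectrumTrace:
    df = pd.read_csv(path)
    return SpectrumTrace(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def write_spectrum_csv(path: str, trace: SpectrumTrace) -> None:
    pd.DataFrame(
        {"wavelength_nm": trace.wavelength_nm, "intensity": trace.intensity}
    ).to_csv(path, index=False)


def load_prescription(path: str) -> OpticalTrain:
    """Lens prescription YAML → OpticalTrain.

    Layout: ``surfaces`` (list of vertex_z_mm, radius_mm, aperture_mm,
    n_before, n_after, optional focal_length_mm), ``sensor`` block,
    ``object_z_mm``, optional ``reference_z_mm``.
    """
    cfg = read_yaml(path)
    surfaces = [
        SphericalSurface(
            vertex_z=s["vertex_z_mm"],
            curvature_radius=s.get("radius_mm", 0.0),
            aperture_radius=s["aperture_mm"] / 2.0,
            n_before=s.get("n_before", 1.0),
            n_after=s.get("n_after", 1.0),
            focal_length=s.get("focal_length_mm"),
            name=s.get("name", ""),
        )
        for s in cfg["surfaces"]
    ]
    sensor_cfg = cfg.get("sensor", {})
    sensor = SensorModel(
        width_mm=sensor_cfg.get("width_mm", 3.55),
        height_mm=sensor_cfg.get("height_mm", 2.68),
        pixel_pitch_um=sensor_cfg.get("pixel_pitch_um", 2.2),
    )
    return OpticalTrain(
        surfaces=surfaces,
        sensor=sensor,
        sensor_z=cfg["sensor_z_mm"],
        object_z=cfg["object_z_mm"],
        reference_z=cfg.get("reference_z_mm", 0.0),
    )


def load_geometry(path: str) -> SpectrometerGeometry:
    cfg = read_yaml(path)
    return SpectrometerGeometry(
        groove_density_lpmm=cfg.get("groove_density_lpmm", 1000.0),
        tube_length_mm=cfg.get("tube_length_mm", 77.5),
        entrance_slit_mm=cfg.get("entrance_slit_mm", 1.0),
        detector_slit_mm=cfg.get("detector_slit_mm", 1.0),
        diffraction_order=cfg.get("diffraction_order", 1),
        incidence_angle_deg=cfg.get("incidence_angle_deg", 0.0),
    )


def save_calibration(path: str, calib: WavelengthCalibration) -> None:
    write_json_atomic(
        path,
        {
            "coefficients": list(calib.coefficients),
            "degree": calib.degree,
            "residual_rms_nm": calib.residual_rms_nm,
            "valid_pixel_range": list(calib.valid_pixel_range),
        },
    )


def load_calibration(path: str) -> WavelengthCalibration:
    with open(path) as fh:
        d = json.load(fh)
    return WavelengthCalibration(
        np.array(d["coefficients"]),
        d["degree"],
        d["residual_rms_nm"],
        tuple(d["valid_pixel_range"]),
    )


def save_distortion(path: str, model: RadialDistortionModel) -> None:
    write_json_atomic(
        path,
        {
            "center": list(model.center),
            "k1": model.k1,
            "k2": model.k2,
            "norm_radius": model.norm_radius,
        },
    )


def load_distortion(path: str) -> RadialDistortionModel:
    with open(path) as fh:
        d = json.load(fh)
    return RadialDistortionModel(
        np.array(d["center"]), d["k1"], d["k2"], d["norm_radius"]
    )


def provenance(subcommand: str, config: dict, seed: int | None = None) -> dict:
    from . import __version__

    return {
        "tool": "pocketscope",
        "version": __version__,
        "subcommand": subcommand,
        "seed": seed,
        "config": config,
    }
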