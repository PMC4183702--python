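"""File formats: raw float arrays with JSON sidecars, windowed PNG export,
and YAML run configuration.

Images and sinograms are stored as little-endian 32-bit float raw arrays
(`.raw`) next to a JSON metadata sidecar (`.json`) describing shape,
dtype, physical spacing / geometry and, for sinograms, the noise spec.
Raw round-trips are exact at 32-bit precision; PNG export is
presentation-only (16-bit, window/level applied) and is never read back
for computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .geometry import FanBeamGeometry, Sinogram
from .grids import ImageGrid

__all__ = [
    "save_image",
    "load_image",
    "save_png",
    "save_sinogram",
    "load_sinogram",
    "load_config",
    "save_config",
    "validate_config",
]

_DTYPE = "<f4"


def _write_raw(path: Path, values: np.ndarray, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values.astype(_DTYPE).tofile(path)
    meta = dict(meta, dtype=_DTYPE, shape=list(values.shape), order="C")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def _read_raw(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    expected = int(np.prod(shape)) * np.dtype(meta["dtype"]).itemsize
    actual = path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"{path}: truncated or inconsistent raw file — expected {expected} bytes "
            f"for shape {shape} {meta['dtype']}, found {actual}"
        )
    return np.fromfile(path, dtype=meta["dtype"]).reshape(shape), meta


def save_image(path, image: ImageGrid) -> None:
    """32-bit float raw + JSON sidecar (kind, shape, pixel size in cm)."""
    _write_raw(Path(path), image.values, {"kind": "image", "pixel_size_cm": image.pixel_size})


def load_image(path) -> ImageGrid:
    values, meta = _read_raw(Path(path))
    if meta.get("kind") != "image":
        raise ValueError(f"{path}: sidecar kind is {meta.get('kind')!r}, expected 'image'")
    return ImageGrid(values.astype(float), float(meta["pixel_size_cm"]))


def save_png(path, image: ImageGrid, window: tuple[float, float] = (1.03, 1.08)) -> None:
    """16-bit grayscale PNG with the given display window (presentation only)."""
    import imageio.v3 as iio

    lo, hi = window
    if not hi > lo:
        raise ValueError(f"window must have hi > lo, got {window}")
    scaled = np.clip((image.values - lo) / (hi - lo), 0.0, 1.0)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


def save_sinogram(path, sino: Sinogram, noise_meta: dict | None = None) -> None:
    """Raw float sinogram + sidecar recording the full acquisition geometry."""
    g = sino.geometry
    meta = {
        "kind": "sinogram",
        "views": g.n_views,
        "bins": g.detector_bins,
        "source_to_axis_cm": g.source_to_axis,
        "bin_aperture_cm": g.bin_aperture,
        "angles_rad": [float(a) for a in g.angles],
        "units": "cm * density",
    }
    if noise_meta:
        meta["noise"] = noise_meta
    _write_raw(Path(path), sino.values, meta)


def load_sinogram(path) -> Sinogram:
    values, meta = _read_raw(Path(path))
    if meta.get("kind") != "sinogram":
        raise ValueError(f"{path}: sidecar kind is {meta.get('kind')!r}, expected 'sinogram'")
    geom = FanBeamGeometry(
        source_to_axis=float(meta["source_to_axis_cm"]),
        detector_bins=int(meta["bins"]),
        bin_aperture=float(meta["bin_aperture_cm"]),
        angles=np.asarray(meta["angles_rad"], dtype=float),
    )
    return Sinogram(values.astype(float), geom)


# configuration schema: field -> (type, validator, message)
_CONFIG_SCHEMA = {
    "n": (int, lambda v: v >= 2, "must be >= 2"),
    "pixel_size": ((int, float), lambda v: v > 0, "must be positive"),
    "views": (int, lambda v: v >= 1, "must be >= 1"),
    "bins": (int, lambda v: v >= 1, "must be >= 1"),
    "bin_aperture": ((int, float), lambda v: v > 0, "must be positive"),
    "source_to_axis": ((int, float), lambda v: v > 0, "must be positive"),
    "lam": ((int, float), lambda v: 0 < v < 2, "must lie in the open interval (0, 2)"),
    "alpha": ((int, float), lambda v: v >= 0, "must be >= 0"),
    "w0": ((int, float), lambda v: v >= 0, "must be >= 0"),
    "decay": ((int, float), lambda v: 0 < v <= 1, "must lie in (0, 1]"),
    "iterations": (int, lambda v: v >= 0, "must be >= 0"),
    "noise_percent": ((int, float), lambda v: v >= 0, "must be >= 0"),
    "seed": (int, lambda v: True, ""),
    "algorithm": (str, lambda v: v in ("sart", "tdm-stf", "wtdm-stf"),
                  "must be one of sart, tdm-stf, wtdm-stf"),
}


def validate_config(cfg: dict, path: str = "config") -> dict:
    """Validate known fields, reporting offending field paths."""
    errors = []
    for key, value in cfg.items():
        if key not in _CONFIG_SCHEMA:
            continue
        typ, check, msg = _CONFIG_SCHEMA[key]
        if isinstance(value, bool) or not isinstance(value, typ):
            errors.append(f"{path}.{key}: expected {typ}, got {type(value).__name__}")
        elif not check(value):
            errors.append(f"{path}.{key}: value {value!r} invalid — {msg}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def load_config(path) -> dict:
    """Load and validate a YAML run configuration."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return validate_config(cfg, path=str(path))


def save_config(path, cfg: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
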