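"""Image-quality measures and 1-D profiles for phantom studies.

Four standard measures of a reconstruction f against the ground truth f*:

  RMSE   sqrt( sum (f - f*)^2 / N )
  PSNR   20 log10( max(f*) / RMSE )                         [dB]
  NRMSD  sqrt( sum (f - f*)^2 / sum (f* - mean f*)^2 )      [Herman]
  NMAD   sum |f - f*| / sum |f*|                            [Herman]

sums over a region of interest (default: the whole image).  NRMSD is 1.0
for a uniform image at the correct mean density and is dominated by a few
large errors; NMAD is 1.0 for a uniformly zero image and emphasizes many
small errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ImageGrid

__all__ = ["MetricsReport", "rmse", "psnr", "nrmsd", "nmad", "evaluate", "extract_profile"]


def _pair(f, truth, roi=None) -> tuple[np.ndarray, np.ndarray]:
    fv = f.values if isinstance(f, ImageGrid) else np.asarray(f, dtype=float)
    tv = truth.values if isinstance(truth, ImageGrid) else np.asarray(truth, dtype=float)
    if fv.shape != tv.shape:
        raise ValueError(f"shape mismatch: {fv.shape} vs {tv.shape}")
    if roi is None:
        return fv.ravel().astype(float), tv.ravel().astype(float)
    roi = np.asarray(roi)
    if roi.dtype == bool:
        if roi.shape != fv.shape:
            raise ValueError("boolean ROI mask must match image shape")
        return fv[roi].astype(float), tv[roi].astype(float)
    return fv.ravel()[roi].astype(float), tv.ravel()[roi].astype(float)


def rmse(f, truth, roi=None) -> float:
    """Root-mean-square error over the ROI (default whole image)."""
    fv, tv = _pair(f, truth, roi)
    return float(np.sqrt(np.mean((fv - tv) ** 2)))


def psnr(f, truth, roi=None) -> float:
    """Peak signal-to-noise ratio in dB, peak = max(truth) over the ROI.

    Returns ``inf`` (perfect match) when the RMSE is zero.
    """
    fv, tv = _pair(f, truth, roi)
    err = float(np.sqrt(np.mean((fv - tv) ** 2)))
    peak = float(np.max(tv))
    if err == 0.0:
        return float("inf")
    if peak <= 0.0:
        raise ValueError("PSNR undefined: truth maximum is not positive")
    return float(20.0 * np.log10(peak / err))


def nrmsd(f, truth, roi=None) -> float:
    """Herman's normalized root-mean-square distance over the ROI."""
    fv, tv = _pair(f, truth, roi)
    denom = float(np.sum((tv - tv.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("NRMSD undefined: truth is constant over the ROI")
    return float(np.sqrt(np.sum((fv - tv) ** 2) / denom))


def nmad(f, truth, roi=None) -> float:
    """Herman's normalized mean absolute distance over the ROI."""
    fv, tv = _pair(f, truth, roi)
    denom = float(np.sum(np.abs(tv)))
    if denom == 0.0:
        raise ValueError("NMAD undefined: truth is zero over the ROI")
    return float(np.sum(np.abs(fv - tv)) / denom)


@dataclass(frozen=True)
class MetricsReport:
    """The four measures for one reconstruction, plus the ROI used."""

    rmse: float
    psnr: float
    nrmsd: float
    nmad: float
    roi: str = "whole-image"

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "psnr": self.psnr, "nrmsd": self.nrmsd, "nmad": self.nmad}


def evaluate(f, truth, roi=None, roi_label: str = "whole-image") -> MetricsReport:
    """All four measures at once."""
    return MetricsReport(
        rmse=rmse(f, truth, roi),
        psnr=psnr(f, truth, roi),
        nrmsd=nrmsd(f, truth, roi),
        nmad=nmad(f, truth, roi),
        roi=roi_label if roi is not None else "whole-image",
    )


def extract_profile(
    image: ImageGrid | np.ndarray,
    axis: str,
    index: int,
    span: tuple[int, int],
    one_based: bool = True,
) -> np.ndarray:
    """Pixel values along part of a row or column.

    ``axis`` is ``"row"`` (profile runs along columns) or ``"column"``;
    ``index`` selects the row/column and ``span = (start, stop)`` is
    inclusive.  Indices are 1-based by default, matching the usual
    "240th row" phrasing of phantom studies.
    """
    values = image.values if isinstance(image, ImageGrid) else np.asarray(image)
    if axis not in ("row", "column"):
        raise ValueError(f"axis must be 'row' or 'column', got {axis!r}")
    off = 1 if one_based else 0
    idx = index - off
    start, stop = span[0] - off, span[1] - off
    if start > stop:
        raise ValueError(f"span start {span[0]} exceeds stop {span[1]}")
    nr, nc = values.shape
    lim_idx, lim_run = (nr, nc) if axis == "row" else (nc, nr)
    if not 0 <= idx < lim_idx:
        raise IndexError(f"{axis} index {index} out of range")
    if start < 0 or stop >= lim_run:
        raise IndexError(f"span {span} out of range for {axis} profile")
    if axis == "row":
        return values[idx, start : stop + 1].copy()
    return values[start : stop + 1, idx].copy()
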