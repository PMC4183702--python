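"""Iterative few-view reconstructors: SART and its TD/WTD soft-threshold
filtered variants.

All three algorithms share one alternating loop started from a zero image:

  1. data constraint — one relaxed SART pass over the views,
  2. regularization — one soft-threshold filtering step reducing the TD
     (alpha = 0) or WTD (alpha > 0) of the image,
  3. acceleration — FISTA-style momentum extrapolation,

with the filtering threshold following the geometric schedule
w_k = w0 * decay^k.  Plain SART skips steps 2 and 3.  The TD-filtered
variant is exactly the WTD-filtered variant with alpha = 0 and shares its
code path.  The loop stops on reaching the iteration budget.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Sinogram, SystemMatrix
from .grids import ImageGrid
from . import metrics as _metrics
from .transforms import ThresholdState, stf_filter_step

__all__ = [
    "ALGORITHMS",
    "ReconstructionConfig",
    "ReconstructionResult",
    "sart_sweep",
    "fista_step",
    "reconstruct",
]

logger = logging.getLogger(__name__)

ALGORITHMS = ("sart", "tdm-stf", "wtdm-stf")


@dataclass(frozen=True)
class ReconstructionConfig:
    """Algorithm choice and hyper-parameters for :func:`reconstruct`.

    ``lam`` is the SART relaxation parameter (must lie in (0, 2));
    ``alpha`` the WTD balance weight (ignored for ``sart``, forced to 0 for
    ``tdm-stf``); ``w0``/``decay`` the threshold schedule; ``order`` the
    SART view ordering (``sequential`` view-by-view sweep or
    ``simultaneous`` all-views update).
    """

    algorithm: str = "wtdm-stf"
    lam: float = 1.0
    alpha: float = 1.0
    w0: float = 0.02
    decay: float = 0.995
    max_iterations: int = 400
    nonnegativity: bool = False
    order: str = "sequential"
    trace_every: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if not 0.0 < self.lam < 2.0:
            raise ValueError(f"relaxation parameter lam must lie in (0, 2), got {self.lam}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.order not in ("sequential", "simultaneous"):
            raise ValueError(f"order must be 'sequential' or 'simultaneous', got {self.order!r}")

    @property
    def effective_alpha(self) -> float:
        """The WTD weight actually used (0 for the TD variant)."""
        return 0.0 if self.algorithm == "tdm-stf" else self.alpha


@dataclass
class ReconstructionResult:
    """Reconstructed image plus the per-iteration evaluation trace."""

    image: ImageGrid
    trace: pd.DataFrame
    iterations: int
    config: ReconstructionConfig
    checkpoints: dict[int, ImageGrid] = field(default_factory=dict)


def sart_sweep(
    A: SystemMatrix,
    p: Sinogram | np.ndarray,
    f: np.ndarray,
    lam: float = 1.0,
    order: str = "sequential",
) -> np.ndarray:
    """One full SART pass over all views.

    For each view v (in angle order), every pixel j receives the update

        f_j += lam * [ sum_{i in v} a_ij (p_i - <a_i, f>) / rowsum_i ] / colsum_j^v

    where rowsum/colsum are the per-ray and per-pixel length sums of the
    view block; rays and pixels with zero sums are skipped.  The
    ``simultaneous`` order applies a single update using all rays at once.
    """
    if not 0.0 < lam < 2.0:
        warnings.warn(f"relaxation parameter lam={lam} outside (0, 2)", stacklevel=2)
    pvec = p.values if isinstance(p, Sinogram) else np.asarray(p)
    pvec = pvec.reshape(A.geometry.n_views, A.geometry.detector_bins)
    if not np.all(np.isfinite(pvec)):
        raise ValueError("projection data contain non-finite values")
    f = np.asarray(f).ravel().copy()
    if f.size != A.N:
        raise ValueError(f"image has {f.size} pixels, matrix expects {A.N}")

    if order == "simultaneous":
        with np.errstate(divide="ignore"):
            inv_row = np.where(A.row_sums > 0, 1.0 / np.where(A.row_sums > 0, A.row_sums, 1.0), 0.0)
            inv_col = np.where(A.col_sums > 0, 1.0 / np.where(A.col_sums > 0, A.col_sums, 1.0), 0.0)
        r = (pvec.ravel() - A.matrix @ f) * inv_row
        return f + lam * (A.matrix.T @ r) * inv_col

    for v, blk in enumerate(A.per_view):
        r = (pvec[v] - blk["A"] @ f) * blk["inv_row"]
        f += lam * (blk["AT"] @ r) * blk["inv_col"]
    return f


def fista_step(
    t_k: float, x_k: np.ndarray, x_km1: np.ndarray
) -> tuple[float, np.ndarray]:
    """One momentum update: t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2 and the
    extrapolated image x_k + ((t_k - 1) / t_{k+1}) (x_k - x_km1)."""
    if t_k < 1.0:
        raise ValueError("momentum scalar t_k must be >= 1")
    t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_k * t_k))
    y = x_k + ((t_k - 1.0) / t_next) * (x_k - x_km1)
    return t_next, y


def reconstruct(
    A: SystemMatrix,
    p: Sinogram,
    cfg: ReconstructionConfig,
    truth: ImageGrid | None = None,
    checkpoints: tuple[int, ...] = (),
) -> ReconstructionResult:
    """Run the configured algorithm from a zero initial image.

    If ``truth`` is given, RMSE/PSNR/NRMSD/NMAD against it are recorded in
    the trace every ``cfg.trace_every`` iterations (0 disables the trace;
    the data residual ||Af - p|| costs one extra forward projection per
    traced iteration).  ``checkpoints`` are iteration numbers at which a
    copy of the current image is kept.
    """
    dtype = A.matrix.dtype
    f = np.zeros(A.N, dtype=dtype)
    x_prev = f
    y = f
    t_k = 1.0
    filtered = cfg.algorithm != "sart"
    state = ThresholdState.initial(cfg.effective_alpha, cfg.w0, cfg.decay)
    pvec = p.values.astype(dtype, copy=False).ravel()
    p_norm = float(np.linalg.norm(pvec))
    shape = A.grid.values.shape

    rows = []
    snapshots: dict[int, ImageGrid] = {}
    for k in range(1, cfg.max_iterations + 1):
        f = sart_sweep(A, pvec, y, cfg.lam, cfg.order)
        if filtered:
            f = stf_filter_step(A.grid.with_values(f.reshape(shape)), state).values.ravel()
            state = state.advanced()
        if cfg.nonnegativity:
            np.maximum(f, 0.0, out=f)
        if filtered:
            t_k, y = fista_step(t_k, f, x_prev)
            x_prev = f
        else:
            y = f
        if cfg.trace_every and (k % cfg.trace_every == 0 or k == cfg.max_iterations):
            row = {"iteration": k, "residual": float(np.linalg.norm(A.matrix @ f - pvec)),
                   "relative_residual": np.nan, "w": state.w if filtered else np.nan}
            if p_norm > 0:
                row["relative_residual"] = row["residual"] / p_norm
            if truth is not None:
                img = truth.with_values(f.reshape(shape))
                row.update(_metrics.evaluate(img, truth).as_dict())
            rows.append(row)
        if k in checkpoints:
            snapshots[k] = A.grid.with_values(f.reshape(shape).astype(float).copy())

    image = A.grid.with_values(f.reshape(shape).astype(float))
    if not np.all(np.isfinite(image.values)):
        raise FloatingPointError("reconstruction diverged to non-finite values")
    trace = pd.DataFrame(rows)
    logger.info(
        "%s finished after %d iterations%s", cfg.algorithm, cfg.max_iterations,
        f", final residual {rows[-1]['residual']:.3e}" if rows else "",
    )
    return ReconstructionResult(image, trace, cfg.max_iterations, cfg, snapshots)
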