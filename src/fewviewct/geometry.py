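"""Fan-beam acquisition geometry and the sparse intersection-length projector.

The scanner model is a point source on a circle of radius ``source_to_axis``
around the grid centre with an equi-distance *virtual* detector: a uniformly
sampled line through the rotation axis, perpendicular to the source-axis
direction.  Each (view, bin) pair defines one ray; the system matrix entry
a_ij is the intersection length (cm) of ray i with pixel j, computed by
Siddon's parametric traversal.  Rows are ordered view-major, bin-minor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp

from .grids import ImageGrid

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "SystemMatrix",
    "view_angles",
    "ray_segment",
    "siddon_trace",
    "build_system_matrix",
    "forward_project",
    "back_project",
]


def view_angles(count: int) -> np.ndarray:
    """``count`` view angles uniformly spaced over the full circle.

    Starts at 0, ascending: beta_k = 2 pi k / count.
    """
    if count < 1:
        raise ValueError(f"view count must be >= 1, got {count}")
    return 2.0 * np.pi * np.arange(count) / count


@dataclass(frozen=True)
class FanBeamGeometry:
    """Circular fan-beam geometry with a virtual detector through the axis.

    ``source_to_axis`` cm; ``detector_bins`` equi-distant bins of width
    ``bin_aperture`` cm centred on the axis line; ``angles`` in radians.
    """

    source_to_axis: float
    detector_bins: int
    bin_aperture: float
    angles: np.ndarray

    def __post_init__(self) -> None:
        if not self.source_to_axis > 0:
            raise ValueError("source_to_axis must be positive")
        if self.detector_bins < 1:
            raise ValueError("detector_bins must be >= 1")
        if not self.bin_aperture > 0:
            raise ValueError("bin_aperture must be positive")
        angles = np.atleast_1d(np.asarray(self.angles, dtype=float)) % (2.0 * np.pi)
        object.__setattr__(self, "angles", angles)

    @property
    def n_views(self) -> int:
        return len(self.angles)

    @property
    def n_rays(self) -> int:
        return self.n_views * self.detector_bins

    @property
    def detector_span(self) -> float:
        """Physical width of the virtual detector at the axis, in cm."""
        return self.detector_bins * self.bin_aperture

    def source_position(self, view: int) -> np.ndarray:
        beta = self.angles[view]
        return self.source_to_axis * np.array([math.cos(beta), math.sin(beta)])

    def bin_offsets(self) -> np.ndarray:
        """Signed bin-centre offsets along the detector line, in cm."""
        k = np.arange(self.detector_bins)
        return (k - (self.detector_bins - 1) / 2.0) * self.bin_aperture

    def detector_position(self, view: int, bin: int) -> np.ndarray:
        """Centre of a detector bin on the virtual detector line."""
        beta = self.angles[view]
        u = np.array([-math.sin(beta), math.cos(beta)])  # detector direction
        return self.bin_offsets()[bin] * u


@dataclass(frozen=True)
class Sinogram:
    """Ray-sum measurements p arranged (views, bins), with geometry."""

    values: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        expected = (self.geometry.n_views, self.geometry.detector_bins)
        if values.shape != expected:
            raise ValueError(f"sinogram shape {values.shape} != geometry shape {expected}")
        if not np.all(np.isfinite(values)):
            raise ValueError("sinogram values must be finite")
        object.__setattr__(self, "values", values)

    def as_vector(self) -> np.ndarray:
        """Row-major flattening: view-major, bin-minor ray order."""
        return self.values.ravel()

    def with_values(self, values: np.ndarray) -> "Sinogram":
        values = np.asarray(values)
        if values.ndim == 1:
            values = values.reshape(self.values.shape)
        return Sinogram(values, self.geometry)


def _clip_to_box(p0: np.ndarray, d: np.ndarray, half: float) -> tuple[float, float] | None:
    """Parametric [tmin, tmax] of the line p0 + t d inside the square box
    [-half, half]^2, or None if it misses the box (slab method)."""
    tmin, tmax = -np.inf, np.inf
    for axis in range(2):
        if d[axis] != 0.0:
            t1 = (-half - p0[axis]) / d[axis]
            t2 = (half - p0[axis]) / d[axis]
            lo, hi = (t1, t2) if t1 <= t2 else (t2, t1)
            tmin = max(tmin, lo)
            tmax = min(tmax, hi)
            if tmin >= tmax:
                return None
        elif abs(p0[axis]) > half:
            return None
    if not (np.isfinite(tmin) and np.isfinite(tmax)) or tmax <= tmin:
        return None
    return tmin, tmax


def ray_segment(
    geom: FanBeamGeometry, grid: ImageGrid, view: int, bin: int
) -> tuple[np.ndarray, np.ndarray]:
    """The (view, bin) ray as a physical segment spanning the grid box.

    Runs from the source position through the bin centre on the virtual
    detector and is extended until it exits the image bounding box (or, if
    it misses the box, to twice the source distance past the detector).
    """
    if not 0 <= view < geom.n_views:
        raise IndexError(f"view index {view} out of range [0, {geom.n_views})")
    if not 0 <= bin < geom.detector_bins:
        raise IndexError(f"bin index {bin} out of range [0, {geom.detector_bins})")
    src = geom.source_position(view)
    det = geom.detector_position(view, bin)
    d = det - src
    clip = _clip_to_box(src, d, grid.half_extent)
    t_end = 2.0 if clip is None else max(2.0, clip[1] + 1e-9)
    return src, src + t_end * d


def siddon_trace(
    grid: ImageGrid, segment: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels crossed by a segment and the intersection lengths, via the
    parametric traversal of Siddon.

    Returns ``(indices, lengths)``: row-major pixel indices and lengths in
    cm, one entry per pixel crossed with positive length.  Segment endpoints
    must lie outside or on the grid bounding box.
    """
    p0 = np.asarray(segment[0], dtype=float)
    p1 = np.asarray(segment[1], dtype=float)
    d = p1 - p0
    length = math.hypot(d[0], d[1])
    if length == 0.0:
        raise ValueError("degenerate zero-length segment")
    n, h, half = grid.n, grid.pixel_size, grid.half_extent

    empty = (np.empty(0, dtype=np.int64), np.empty(0))
    clip = _clip_to_box(p0, d, half)
    if clip is None:
        return empty
    tmin, tmax = clip
    tmin = max(tmin, 0.0)
    tmax = min(tmax, 1.0)
    if tmax <= tmin:
        return empty

    # crossing parameters with the pixel-boundary planes, merged and sorted
    planes = -half + h * np.arange(n + 1)
    ts = [np.array([tmin, tmax])]
    for axis in range(2):
        if d[axis] != 0.0:
            t = (planes - p0[axis]) / d[axis]
            ts.append(t[(t > tmin) & (t < tmax)])
    t_all = np.sort(np.concatenate(ts))
    seg = np.diff(t_all) * length
    mids = 0.5 * (t_all[:-1] + t_all[1:])
    keep = seg > 1e-12 * h
    if not np.any(keep):
        return empty
    seg, mids = seg[keep], mids[keep]
    xm = p0[0] + mids * d[0]
    ym = p0[1] + mids * d[1]
    col = np.clip(((xm + half) / h).astype(np.int64), 0, n - 1)
    row = np.clip(((half - ym) / h).astype(np.int64), 0, n - 1)
    return row * n + col, seg


@dataclass
class SystemMatrix:
    """Sparse M x N intersection-length matrix with cached ray/pixel sums.

    M = views x bins rays (view-major order), N = n^2 pixels (row-major).
    Per-view row blocks and their transposes are cached lazily for the
    view-sequential SART sweep.
    """

    matrix: sp.csr_matrix
    geometry: FanBeamGeometry
    grid: ImageGrid

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.geometry.n_rays, self.grid.n_pixels):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with geometry "
                f"({self.geometry.n_rays} rays) and grid ({self.grid.n_pixels} pixels)"
            )

    @property
    def M(self) -> int:
        return self.matrix.shape[0]

    @property
    def N(self) -> int:
        return self.matrix.shape[1]

    @cached_property
    def row_sums(self) -> np.ndarray:
        """Per-ray total intersection length (the chord length in the box)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()

    @cached_property
    def col_sums(self) -> np.ndarray:
        """Per-pixel total length over all rays."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    @cached_property
    def per_view(self) -> list[dict]:
        """Cached per-view blocks for the SART sweep: the row block A_v, its
        transpose, and reciprocal ray/pixel sums (0 where the sum is 0)."""
        bins = self.geometry.detector_bins
        blocks = []
        for v in range(self.geometry.n_views):
            Av = self.matrix[v * bins : (v + 1) * bins]
            row = np.asarray(Av.sum(axis=1)).ravel()
            col = np.asarray(Av.sum(axis=0)).ravel()
            with np.errstate(divide="ignore"):
                inv_row = np.where(row > 0, 1.0 / np.where(row > 0, row, 1.0), 0.0)
                inv_col = np.where(col > 0, 1.0 / np.where(col > 0, col, 1.0), 0.0)
            blocks.append(
                {
                    "A": Av,
                    "AT": Av.T.tocsr(),
                    "inv_row": inv_row.astype(self.matrix.dtype),
                    "inv_col": inv_col.astype(self.matrix.dtype),
                }
            )
        return blocks


def build_system_matrix(
    geom: FanBeamGeometry,
    grid: ImageGrid,
    dtype=np.float64,
    nnz_cap: int = 400_000_000,
) -> SystemMatrix:
    """Build the sparse system matrix by tracing every (view, bin) ray.

    Deterministic; rays that miss the grid produce empty rows so that M
    stays views x bins.  ``nnz_cap`` guards against accidental huge builds.
    """
    est_nnz = geom.n_rays * int(1.5 * grid.n)
    if est_nnz > nnz_cap:
        raise MemoryError(
            f"estimated {est_nnz:.2e} nonzeros exceeds cap {nnz_cap:.2e}; "
            "reduce the grid size n or the number of rays"
        )
    n, half = grid.n, grid.half_extent
    offsets = geom.bin_offsets()
    indptr = np.zeros(geom.n_rays + 1, dtype=np.int64)
    idx_parts: list[np.ndarray] = []
    len_parts: list[np.ndarray] = []
    ray = 0
    for v in range(geom.n_views):
        beta = geom.angles[v]
        src = geom.source_position(v)
        u = np.array([-math.sin(beta), math.cos(beta)])
        for k in range(geom.detector_bins):
            det = offsets[k] * u
            d = det - src
            # extend well past the box so the trace is never cut short
            t_end = 1.0 + (geom.source_to_axis + 4.0 * half) / math.hypot(d[0], d[1])
            idx, ln = siddon_trace(grid, (src, src + t_end * d))
            idx_parts.append(idx)
            len_parts.append(ln)
            ray += 1
            indptr[ray] = indptr[ray - 1] + len(idx)
    data = np.concatenate(len_parts).astype(dtype, copy=False)
    indices = np.concatenate(idx_parts).astype(np.int32, copy=False)
    matrix = sp.csr_matrix((data, indices, indptr), shape=(geom.n_rays, grid.n_pixels))
    return SystemMatrix(matrix, geom, grid)


def forward_project(A: SystemMatrix, image: ImageGrid | np.ndarray) -> Sinogram:
    """p = A f: line integrals of the image along every ray."""
    f = image.as_vector() if isinstance(image, ImageGrid) else np.asarray(image).ravel()
    if f.size != A.N:
        raise ValueError(f"image has {f.size} pixels, matrix expects {A.N}")
    p = A.matrix @ f
    return Sinogram(p.reshape(A.geometry.n_views, A.geometry.detector_bins), A.geometry)


def back_project(A: SystemMatrix, sino: Sinogram | np.ndarray) -> np.ndarray:
    """A^T p: the unweighted adjoint, as an (n, n) image array."""
    p = sino.as_vector() if isinstance(sino, Sinogram) else np.asarray(sino).ravel()
    if p.size != A.M:
        raise ValueError(f"sinogram has {p.size} rays, matrix expects {A.M}")
    return (A.matrix.T @ p).reshape(A.grid.values.shape)
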