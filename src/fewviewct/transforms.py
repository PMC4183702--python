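"""Total-difference (TD) and weighted-total-difference (WTD) measures and
the soft-threshold filtering step that reduces them.

The TD of an image is the anisotropic l1 measure of its horizontal and
vertical pixel differences; the WTD adds the two diagonal differences with
weight alpha, so that it penalizes both gradient sparsity (axial terms)
and directional gradient continuity (diagonal terms):

    WTD(f) = sum |D1 f| + |D2 f|  +  alpha * ( |D3 f| + |D4 f| )

with D1..D4 the horizontal, vertical and two diagonal partial-difference
operators.  Differences that would reference a pixel outside the grid are
defined to be 0 (border convention).

The filtering step is the pseudo-inverse construction for difference
operators: every neighbour n of a pixel proposes the candidate value
g_n = f_n + S_w(f - f_n), where S_w is soft-thresholding; the output pixel
is the weighted mean of the candidates, axial neighbours with weight 1 and
diagonal neighbours with weight alpha, normalized by the weights of the
neighbours actually present at borders.  At w = 0 the step is the
identity; as w -> inf it tends to the alpha-weighted 8-neighbourhood mean;
at alpha = 0 it reduces to the 4-neighbour TD filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grids import ImageGrid

__all__ = [
    "GradientFields",
    "ThresholdState",
    "partial_gradients",
    "td_measure",
    "wtd_measure",
    "soft_threshold",
    "stf_filter_step",
]


@dataclass(frozen=True)
class GradientFields:
    """The four partial-difference fields of an image, same shape as it.

    d1 horizontal: f(i,j) - f(i,j-1); d2 vertical: f(i,j) - f(i-1,j);
    d3 diagonal:   f(i,j) - f(i-1,j-1); d4 anti-diagonal: f(i,j) - f(i-1,j+1).
    Entries whose reference pixel falls outside the grid are 0.
    """

    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    d4: np.ndarray


@dataclass(frozen=True)
class ThresholdState:
    """Soft-threshold filtering state: current threshold and balance weight.

    ``w`` is the current threshold in density units; ``alpha`` weighs the
    diagonal (gradient-continuity) terms; ``w0`` and ``decay`` define the
    geometric schedule w_k = w0 * decay^k.
    """

    w: float
    alpha: float
    w0: float = 0.02
    decay: float = 0.995

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("threshold w must be >= 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    @classmethod
    def initial(cls, alpha: float, w0: float = 0.02, decay: float = 0.995) -> "ThresholdState":
        return cls(w=w0, alpha=alpha, w0=w0, decay=decay)

    def advanced(self) -> "ThresholdState":
        """The state after one schedule step (w multiplied by decay)."""
        return replace(self, w=self.w * self.decay)


def _values(image: ImageGrid | np.ndarray) -> np.ndarray:
    return image.values if isinstance(image, ImageGrid) else np.asarray(image, dtype=float)


def partial_gradients(image: ImageGrid | np.ndarray) -> GradientFields:
    """The four partial-difference fields under the zero-border convention."""
    f = _values(image)
    if f.shape[0] < 2 or f.shape[1] < 2:
        raise ValueError("image must be at least 2 x 2")
    d1 = np.zeros_like(f)
    d2 = np.zeros_like(f)
    d3 = np.zeros_like(f)
    d4 = np.zeros_like(f)
    d1[:, 1:] = f[:, 1:] - f[:, :-1]
    d2[1:, :] = f[1:, :] - f[:-1, :]
    d3[1:, 1:] = f[1:, 1:] - f[:-1, :-1]
    d4[1:, :-1] = f[1:, :-1] - f[:-1, 1:]
    return GradientFields(d1, d2, d3, d4)


def td_measure(image: ImageGrid | np.ndarray) -> float:
    """Total difference: sum |d1| + |d2| (axial l1 gradient measure)."""
    g = partial_gradients(image)
    return float(np.abs(g.d1).sum() + np.abs(g.d2).sum())


def wtd_measure(image: ImageGrid | np.ndarray, alpha: float) -> float:
    """Weighted total difference: TD + alpha * (sum |d3| + |d4|)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    g = partial_gradients(image)
    axial = np.abs(g.d1).sum() + np.abs(g.d2).sum()
    diag = np.abs(g.d3).sum() + np.abs(g.d4).sum()
    return float(axial + alpha * diag)


def soft_threshold(x, w: float):
    """S_w(x) = sign(x) * max(|x| - w, 0), elementwise."""
    if w < 0:
        raise ValueError("threshold w must be >= 0")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - w, 0.0)
    return out if out.ndim else float(out)


# neighbour offsets (drow, dcol) and whether the neighbour is diagonal
_NEIGHBOURS = [
    (0, -1, False), (0, 1, False), (-1, 0, False), (1, 0, False),
    (-1, -1, True), (-1, 1, True), (1, -1, True), (1, 1, True),
]


def stf_filter_step(image: ImageGrid, state: ThresholdState) -> ImageGrid:
    """One soft-threshold filtering pass reducing the WTD of the image.

    Each neighbour n proposes g_n = f_n + S_w(f - f_n); the output pixel is
    the mean of the candidates with axial weight 1 and diagonal weight
    alpha, normalized by the weight of the neighbours present at borders.
    """
    f = image.values
    if f.shape[0] < 3 or f.shape[1] < 3:
        raise ValueError("image must be at least 3 x 3 for the 8-neighbourhood filter")
    w, alpha = state.w, state.alpha
    num = np.zeros_like(f)
    den = np.zeros_like(f)
    nr, nc = f.shape
    for dr, dc, diagonal in _NEIGHBOURS:
        weight = alpha if diagonal else 1.0
        if weight == 0.0:
            continue
        # slices of the centre region having a (dr, dc) neighbour in-grid
        r0, r1 = max(0, -dr), nr - max(0, dr)
        c0, c1 = max(0, -dc), nc - max(0, dc)
        centre = f[r0:r1, c0:c1]
        neighbour = f[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        diff = centre - neighbour
        cand = neighbour + np.sign(diff) * np.maximum(np.abs(diff) - w, 0.0)
        num[r0:r1, c0:c1] += weight * cand
        den[r0:r1, c0:c1] += weight
    return image.with_values(num / den)
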