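"""Analytic phantoms rasterized onto pixel grids.

Phantoms are ordered lists of elliptical primitives carrying *additive*
signed densities: later shapes add on top of earlier ones, which lets a
low-density cavity be carved out of a high-density shell by adding a
negative ellipse.  Rasterization is deterministic anti-aliased sampling:
every pixel is the mean of supersample^2 sub-sample points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids import ImageGrid

__all__ = [
    "Ellipse",
    "AnalyticPhantomSpec",
    "rasterize",
    "build_forbild_head_slice",
    "make_test_phantom",
    "FORBILD_HEAD_SLICE",
]


@dataclass(frozen=True)
class Ellipse:
    """Elliptical primitive with an additive signed density.

    ``cx, cy`` centre in cm (origin at grid centre, y up); ``a, b``
    semi-axes in cm; ``angle_deg`` counter-clockwise rotation of the a-axis
    from +x; ``density`` the signed value added inside the ellipse.
    """

    cx: float
    cy: float
    a: float
    b: float
    angle_deg: float
    density: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"semi-axes must be strictly positive, got a={self.a}, b={self.b}")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        t = math.radians(self.angle_deg)
        ct, st = math.cos(t), math.sin(t)
        dx, dy = x - self.cx, y - self.cy
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        return (u / self.a) ** 2 + (v / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class AnalyticPhantomSpec:
    """Named, ordered list of elliptical primitives (additive composition)."""

    name: str
    shapes: tuple[Ellipse, ...]

    def __add__(self, other: "AnalyticPhantomSpec") -> "AnalyticPhantomSpec":
        return AnalyticPhantomSpec(f"{self.name}+{other.name}", self.shapes + other.shapes)


def rasterize(
    spec: AnalyticPhantomSpec,
    n: int,
    pixel_size: float,
    supersample: int = 4,
) -> ImageGrid:
    """Rasterize an analytic phantom onto an n x n grid.

    Each pixel value is the mean additive density over ``supersample^2``
    uniformly placed sub-sample points, which anti-aliases ellipse
    boundaries; interior pixels are exact for any supersample.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    if supersample < 1:
        raise ValueError(f"supersample must be >= 1, got {supersample}")

    s = int(supersample)
    m = n * s
    sub = pixel_size / s
    half = 0.5 * n * pixel_size
    # sub-sample point centres, x rightward / y upward, row 0 at top
    coords = (np.arange(m) + 0.5) * sub - half
    acc = np.zeros((m, m))
    for shape in spec.shapes:
        # evaluate only inside the shape's axis-aligned bounding box
        r = math.hypot(shape.a, shape.b)
        j0 = max(0, int(np.searchsorted(coords, shape.cx - r)) - 1)
        j1 = min(m, int(np.searchsorted(coords, shape.cx + r)) + 1)
        i0 = max(0, int(np.searchsorted(coords, -(shape.cy + r))) - 1)
        i1 = min(m, int(np.searchsorted(coords, -(shape.cy - r))) + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        x = coords[None, j0:j1]
        y = -coords[i0:i1, None]
        acc[i0:i1, j0:j1] += shape.density * shape.contains(x, y)
    values = acc.reshape(n, s, n, s).mean(axis=(1, 3))
    return ImageGrid(values, pixel_size)


def _mirror(shapes: Sequence[Ellipse]) -> tuple[Ellipse, ...]:
    """Left-right mirrored copies (x -> -x) of a list of ellipses."""
    return tuple(
        Ellipse(-e.cx, e.cy, e.a, e.b, -e.angle_deg, e.density) for e in shapes
    )


# Head-slice constant table in the style of the public FORBILD head phantom
# (skull 1.800, brain 1.050, CSF 1.045, air 0.0, low-contrast structures at
# +0.005/+0.010 above brain).  SYNTHETIC TRANSCRIPTION: the original
# definition mixes ellipses with drop shapes and clipped solids; this table
# re-expresses the slice with elliptical primitives only, keeping the
# documented densities, the overall skull/brain/CSF anatomy, the fine
# high-contrast petrous (inner-ear) bone-air structure that drives streak
# artifacts, and low-contrast lesions inside the [1.03, 1.08] display
# window.  Geometry in cm; additive composition, outermost shape first.
_petrous_left = (
    Ellipse(-5.2, -3.2, 1.9, 0.85, 35.0, +0.750),      # petrous bone ridge -> 1.800
    Ellipse(-5.65, -2.88, 0.15, 0.15, 0.0, -1.800),    # inner-ear air cells -> 0.0
    Ellipse(-5.2, -3.2, 0.15, 0.15, 0.0, -1.800),
    Ellipse(-4.75, -3.52, 0.15, 0.15, 0.0, -1.800),
)

FORBILD_HEAD_SLICE = AnalyticPhantomSpec(
    name="forbild-head-slice",
    shapes=(
        Ellipse(0.0, 0.0, 9.6, 12.0, 0.0, +1.800),     # cranium (skull bone)
        Ellipse(0.0, 0.0, 9.0, 11.4, 0.0, -0.755),     # subarachnoid CSF -> 1.045
        Ellipse(0.0, 0.0, 8.7, 11.1, 0.0, +0.005),     # brain -> 1.050
        Ellipse(0.0, 8.6, 1.5, 1.1, 0.0, -1.050),      # frontal sinus (air) -> 0.0
        Ellipse(0.0, -7.6, 1.8, 1.2, 0.0, -1.050),     # pharyngeal air cavity -> 0.0
        Ellipse(-1.25, 1.5, 0.75, 2.3, -12.0, -0.005), # lateral ventricle (CSF)
        Ellipse(1.25, 1.5, 0.75, 2.3, 12.0, -0.005),
        *_petrous_left,
        *_mirror(_petrous_left),
        Ellipse(-3.4, 4.4, 0.9, 0.9, 0.0, +0.010),     # low-contrast lesions
        Ellipse(3.4, 4.4, 0.9, 0.9, 0.0, +0.005),
        Ellipse(0.2, 5.2, 0.8, 0.8, 0.0, +0.010),
        Ellipse(-1.0, 1.65, 0.6, 0.6, 0.0, +0.005),
    ),
)


def build_forbild_head_slice(
    n: int = 512, pixel_size: float = 0.1, supersample: int = 4
) -> ImageGrid:
    """Rasterize the embedded head-slice table as the ground-truth image f*.

    Defaults give the 512 x 512 image with 0.1 cm pixels used for the
    full-scale experiments; smaller n at proportionally larger pixel_size
    gives the same anatomy at coarser resolution.
    """
    if n < 64:
        raise ValueError(f"n must be >= 64 for meaningful head structure, got {n}")
    return rasterize(FORBILD_HEAD_SLICE, n, pixel_size, supersample)


def make_test_phantom(kind: str, n: int, pixel_size: float = 1.0) -> ImageGrid:
    """Small piecewise-constant phantoms with known analytic properties.

    kinds: ``uniform-disc`` (density-1 disc of radius 0.4 * n * h on zero
    background), ``two-rect`` (two gray levels), ``checker`` (unit checkerboard).
    """
    if kind == "uniform-disc":
        spec = AnalyticPhantomSpec(
            "disc", (Ellipse(0.0, 0.0, 0.4 * n * pixel_size, 0.4 * n * pixel_size, 0.0, 1.0),)
        )
        return rasterize(spec, n, pixel_size, supersample=1)
    if kind == "two-rect":
        values = np.zeros((n, n))
        values[: n // 2, :] = 0.5
        values[n // 2 :, :] = 1.5
        return ImageGrid(values, pixel_size)
    if kind == "checker":
        r, c = np.indices((n, n))
        return ImageGrid(((r + c) % 2).astype(float), pixel_size)
    raise ValueError(f"unknown test phantom kind: {kind!r}")
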