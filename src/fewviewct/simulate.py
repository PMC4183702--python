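"""Projection-data simulation: noise-free ray sums and Gaussian noise.

Noise-free data are generated by applying the system matrix to the
discrete phantom, i.e. with the same forward model the reconstructors use
(the deliberate "inverse crime" that makes noise-free data exactly
consistent).  Measurement noise is i.i.d. zero-mean Gaussian with standard
deviation given as a fraction of the global sinogram maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import Sinogram, SystemMatrix, forward_project
from .grids import ImageGrid

__all__ = ["NoiseSpec", "simulate_projections", "add_gaussian_noise"]

logger = logging.getLogger(__name__)

#: RNG algorithm used for noise; recorded in sinogram metadata on save.
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian noise with sigma = percent_of_max * max(p).

    ``percent_of_max`` is a fraction (0.0005 means 0.05% of the sinogram
    maximum); ``seed`` fixes the realization.
    """

    percent_of_max: float = 0.0005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.percent_of_max < 0:
            raise ValueError("percent_of_max must be >= 0")


def simulate_projections(phantom: ImageGrid, A: SystemMatrix) -> Sinogram:
    """Noise-free data p = A f* (alias of forward projection)."""
    logger.info(
        "simulating %d x %d noise-free projections of a %d^2 phantom",
        A.geometry.n_views, A.geometry.detector_bins, phantom.n,
    )
    return forward_project(A, phantom)


def add_gaussian_noise(sino: Sinogram, spec: NoiseSpec) -> Sinogram:
    """p + eps with eps ~ N(0, sigma^2), sigma = percent_of_max * max(p).

    Reproducible for a fixed seed.  An all-zero sinogram has sigma = 0 and
    is returned unchanged (with a warning).
    """
    if sino.values.size == 0:
        raise ValueError("sinogram is empty")
    sigma = spec.percent_of_max * float(np.max(sino.values))
    if sigma == 0.0:
        if spec.percent_of_max > 0:
            logger.warning("sinogram maximum is 0; noise sigma is 0, returning input")
        return sino.with_values(sino.values.copy())
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, sigma, size=sino.values.shape)
    return sino.with_values(sino.values + noise)
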