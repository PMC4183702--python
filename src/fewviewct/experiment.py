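"""Experiment runner: the full phantom -> projections -> reconstruction ->
evaluation pipeline, with on-disk artifacts.

One :class:`ExperimentSpec` describes a complete comparison study: the
phantom resolution, the acquisition geometry, the noise level and the list
of algorithms.  :func:`run_comparison` executes it in memory (building the
system matrix once and reusing it across algorithms and noise seeds);
:func:`run_experiment` additionally writes checkpoint images (raw +
windowed PNG), per-iteration metric traces, a summary table and the
relative-gain table to an artifact directory that is self-describing
enough to re-run.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import FanBeamGeometry, build_system_matrix, view_angles
from .grids import ImageGrid
from .io import save_config, save_image, save_png, save_sinogram
from .metrics import evaluate
from .phantom import build_forbild_head_slice
from .reconstruct import ReconstructionConfig, ReconstructionResult, reconstruct
from .simulate import NoiseSpec, add_gaussian_noise, simulate_projections

__all__ = ["ExperimentSpec", "run_comparison", "run_experiment", "gain_table"]

logger = logging.getLogger(__name__)

#: the display window used for all exported head-slice PNGs
DISPLAY_WINDOW = (1.03, 1.08)


@dataclass(frozen=True)
class ExperimentSpec:
    """A complete comparison study at full or reduced scale.

    Defaults are the full-scale study: 512^2 phantom with 0.1 cm pixels,
    40 views over the full circle, 1025 detector bins of 0.05 cm,
    source-to-axis 293.1 cm, 400 iterations.  ``noise_percent`` > 0 adds
    Gaussian noise (sigma = noise_percent * max p) per seed in ``seeds``.
    """

    n: int = 512
    pixel_size: float = 0.1
    views: int = 40
    bins: int = 1025
    bin_aperture: float = 0.05
    source_to_axis: float = 293.1
    supersample: int = 4
    noise_percent: float = 0.0
    seeds: tuple[int, ...] = (0,)
    algorithms: tuple[ReconstructionConfig, ...] = (
        ReconstructionConfig(algorithm="sart"),
        ReconstructionConfig(algorithm="tdm-stf"),
        ReconstructionConfig(algorithm="wtdm-stf"),
    )
    checkpoints: tuple[int, ...] = (50, 100, 200, 400)
    matrix_dtype: str = "float32"

    def __post_init__(self) -> None:
        caps = [c.max_iterations for c in self.algorithms]
        bad = [k for k in self.checkpoints if k > max(caps, default=0)]
        if list(self.checkpoints) != sorted(self.checkpoints) or bad:
            raise ValueError(
                f"checkpoints must be ascending and <= max_iterations; got {self.checkpoints}"
            )

    def geometry(self) -> FanBeamGeometry:
        return FanBeamGeometry(
            source_to_axis=self.source_to_axis,
            detector_bins=self.bins,
            bin_aperture=self.bin_aperture,
            angles=view_angles(self.views),
        )


def gain_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Relative improvement (%) of the WTD variant over the TD variant.

    For error measures the gain is (m_TD - m_WTD) / m_TD * 100; for PSNR,
    where larger is better, (PSNR_WTD - PSNR_TD) / PSNR_TD * 100.
    """
    td = summary.loc[summary["algorithm"] == "tdm-stf"].iloc[0]
    wtd = summary.loc[summary["algorithm"] == "wtdm-stf"].iloc[0]
    rows = {}
    for m in ("rmse", "nrmsd", "nmad"):
        rows[m] = (td[m] - wtd[m]) / td[m] * 100.0
    rows["psnr"] = (wtd["psnr"] - td["psnr"]) / td["psnr"] * 100.0
    return pd.DataFrame([rows])


def run_comparison(
    spec: ExperimentSpec,
    truth: ImageGrid | None = None,
    system=None,
) -> dict:
    """Run all configured algorithms; returns phantom, sinograms, results
    and the final-iteration summary table (one row per algorithm x seed).

    A prebuilt phantom / system matrix can be passed in to share work
    across experiments.
    """
    if truth is None:
        truth = build_forbild_head_slice(spec.n, spec.pixel_size, spec.supersample)
    if system is None:
        system = build_system_matrix(
            spec.geometry(), truth, dtype=np.dtype(spec.matrix_dtype)
        )
    clean = simulate_projections(truth, system)

    sinograms: dict[int | None, object] = {}
    if spec.noise_percent > 0:
        for seed in spec.seeds:
            sinograms[seed] = add_gaussian_noise(
                clean, NoiseSpec(percent_of_max=spec.noise_percent, seed=seed)
            )
    else:
        sinograms[None] = clean

    results: dict[tuple[str, int | None], ReconstructionResult] = {}
    rows = []
    for seed, sino in sinograms.items():
        for cfg in spec.algorithms:
            logger.info("running %s (seed=%s)", cfg.algorithm, seed)
            res = reconstruct(system, sino, cfg, truth=truth, checkpoints=spec.checkpoints)
            results[(cfg.algorithm, seed)] = res
            rows.append({"algorithm": cfg.algorithm, "seed": seed,
                         **evaluate(res.image, truth).as_dict()})
    summary = pd.DataFrame(rows)
    return {
        "truth": truth,
        "system": system,
        "clean_sinogram": clean,
        "sinograms": sinograms,
        "results": results,
        "summary": summary,
    }


def run_experiment(spec: ExperimentSpec, out_dir) -> Path:
    """Execute a comparison study and write its artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run = run_comparison(spec)
    truth, summary = run["truth"], run["summary"]

    save_image(out / "phantom.raw", truth)
    save_png(out / "phantom.png", truth, DISPLAY_WINDOW)
    save_sinogram(out / "sinogram_clean.raw", run["clean_sinogram"])
    for seed, sino in run["sinograms"].items():
        if seed is not None:
            save_sinogram(
                out / f"sinogram_noisy_seed{seed}.raw", sino,
                noise_meta={"percent_of_max": spec.noise_percent, "seed": seed,
                            "rng": "numpy.random.Generator(PCG64)"},
            )

    for (alg, seed), res in run["results"].items():
        tag = alg if seed is None else f"{alg}_seed{seed}"
        if not res.trace.empty:
            res.trace.to_csv(out / f"trace_{tag}.csv", index=False)
        save_image(out / f"recon_{tag}.raw", res.image)
        save_png(out / f"recon_{tag}.png", res.image, DISPLAY_WINDOW)
        for k, img in res.checkpoints.items():
            save_png(out / f"recon_{tag}_iter{k:04d}.png", img, DISPLAY_WINDOW)

    summary.to_csv(out / "summary.csv", index=False)
    algs = set(summary["algorithm"])
    if {"tdm-stf", "wtdm-stf"} <= algs:
        gains = (
            summary.groupby("algorithm").mean(numeric_only=True).reset_index()
            if spec.noise_percent > 0 else summary
        )
        gain_table(gains).to_csv(out / "gains.csv", index=False)

    provenance = {
        "spec": {**asdict(spec),
                 "algorithms": [asdict(c) for c in spec.algorithms]},
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    save_config(out / "experiment.yaml", json.loads(json.dumps(provenance)))
    logger.info("experiment artifacts written to %s", out)
    return out
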