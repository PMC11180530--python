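"""End-to-end comparison experiments: MLEM vs TV vs POCS on the disc phantom.

Two presets are shipped:

``"full"``
    The full-scale reference configuration: 256 x 256 grid, 256 bins,
    8 views over 180 degrees, 1009 POCS iterations with 5000 TV steps of
    size 2e-7 each, a snap every 100 iterations, Gaussian noise variance 5.
    This run takes on the order of hours on one core and is meant for
    batch/nightly use.

``"reduced"``
    A desk-scale replica preserving every structural feature of the
    schedule: 64 x 64 grid, 64 bins, 8 views, 209 iterations (not a
    multiple of the snap period 20, so the run does not end on a snap),
    500 TV steps with the step size scaled by the 4x grid ratio, and noise
    variance 5 / 16 so the per-ray signal-to-noise ratio matches the full
    phantom, whose line integrals are 4x longer.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import Image2D, make_geometry
from .io import write_png, write_sinogram_text, write_tiff
from .metrics import DEFAULT_PEAK, MetricsReport, evaluate, format_table
from .phantom import (
    DiscPhantomSpec,
    add_gaussian_noise,
    analytic_sinogram,
    make_reference_phantom,
    rasterize_phantom,
)
from .projector import build_system_model
from .recon import PocsConfig, SnapRule, mlem_reconstruct, pocs_reconstruct

__all__ = ["ExperimentConfig", "preset", "run_comparison"]

METHODS = ("mlem", "tv", "pocs")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one comparison table."""

    image_size: int = 256
    n_bins: int = 256
    n_views: int = 8
    n_iterations: int = 1009
    tv_steps: int = 5000
    tv_eta: float = 2e-7
    snap_period: int = 100
    noise: bool = False
    noise_variance: float = 5.0
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    peak: float = DEFAULT_PEAK
    out_dir: str | None = None
    label: str = "full"

    def __post_init__(self) -> None:
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")


def preset(name: str, noise: bool = False, seed: int = 0,
           out_dir: str | None = None) -> ExperimentConfig:
    """The ``"full"`` (full-scale) or ``"reduced"`` (desk-scale) preset."""
    if name == "full":
        return ExperimentConfig(noise=noise, seed=seed, out_dir=out_dir)
    if name == "reduced":
        return ExperimentConfig(
            image_size=64, n_bins=64, n_iterations=209, tv_steps=500,
            tv_eta=8e-7, snap_period=20, noise=noise,
            noise_variance=5.0 / 16.0, seed=seed, out_dir=out_dir,
            label="reduced",
        )
    raise ValueError(f"unknown preset {name!r} (expected 'full' or 'reduced')")


def _pocs_config(config: ExperimentConfig, method: str) -> PocsConfig:
    if method == "mlem":
        return PocsConfig(n_iterations=config.n_iterations, tv_steps=0,
                          snap_rule=None)
    if method == "tv":
        return PocsConfig(n_iterations=config.n_iterations,
                          tv_steps=config.tv_steps, tv_eta=config.tv_eta,
                          snap_rule=None)
    return PocsConfig(n_iterations=config.n_iterations,
                      tv_steps=config.tv_steps, tv_eta=config.tv_eta,
                      snap_period=config.snap_period, snap_rule=SnapRule())


def run_comparison(
    config: ExperimentConfig,
    phantom_spec: DiscPhantomSpec | None = None,
    verbose: bool = False,
) -> tuple[list[MetricsReport], dict[str, Image2D]]:
    """Reconstruct the phantom with every selected method and tabulate metrics.

    All methods see the identical sinogram (same noise realization).  The
    returned table starts with an "Ideal case" row (truth against itself);
    reconstructions and the table are also written to ``config.out_dir``
    when one is set.
    """
    geom = make_geometry(config.n_views, config.n_bins, config.image_size)
    spec = phantom_spec or make_reference_phantom(field_of_view=geom.field_of_view)
    truth = rasterize_phantom(spec, geom)
    sino = analytic_sinogram(spec, geom)
    if config.noise:
        sino = add_gaussian_noise(sino, config.noise_variance, config.seed)
    model = build_system_model(geom)

    suffix = "w/ noise" if config.noise else "w/o noise"
    reports = [evaluate(truth, truth, "Ideal case", peak=config.peak)]
    images: dict[str, Image2D] = {"truth": truth}
    for method in config.methods:
        if verbose:
            print(f"[{config.label}] reconstructing: {method} ({suffix})",
                  file=sys.stderr, flush=True)
        if method == "mlem":
            state = mlem_reconstruct(sino, model, config.n_iterations)
            name = "MLEM"
        else:
            state = pocs_reconstruct(sino, model, _pocs_config(config, method))
            name = "TV" if method == "tv" else "Proposed POCS"
        images[method] = state.image
        reports.append(evaluate(state.image, truth, f"{name} {suffix}",
                                peak=config.peak))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = "noisy" if config.noise else "noiseless"
        write_sinogram_text(out / f"sinogram_{tag}.txt", sino)
        for key, img in images.items():
            write_tiff(out / f"{key}_{tag}.tif", img)
            write_png(out / f"{key}_{tag}.png", img, window=(0.0, config.peak))
        (out / f"metrics_{tag}.tsv").write_text(format_table(reports) + "\n")
        (out / f"run_{tag}.log").write_text(_describe(config))
    return reports, images


def _describe(config: ExperimentConfig) -> str:
    lines = [f"{k} = {v}" for k, v in vars(config).items()]
    return "\n".join(lines) + "\n"
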