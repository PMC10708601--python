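"""End-to-end orchestration: register, crop, sinograms, reconstruct, assemble.

This is the library entry point behind the ``tiltomo pipeline`` command; it
operates purely in memory so tests and scripts can run it without touching
disk.  All stages are deterministic given the input series (randomness lives
only in the simulator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reconstruct import ReconConfig, Slice2D, reconstruct_slice
from .registration import Shift, TiltSeries, crop_common, register_series
from .sinogram import build_all_sinograms
from .volume import Volume, assemble_volume

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("tiltomo")


@dataclass
class PipelineResult:
    """Everything the pipeline produces, keyed by reconstruction method."""

    registered: TiltSeries
    shifts: list[Shift]
    volumes: dict[str, Volume] = field(default_factory=dict)


def run_pipeline(
    series: TiltSeries,
    methods: tuple[str, ...] = ("fbp", "art"),
    config: ReconConfig | None = None,
    subpixel: bool = True,
) -> PipelineResult:
    """Run registration, cropping, sinogram extraction and reconstruction.

    ``config`` supplies the shared reconstruction options (filter,
    iterations, relaxation, angle subsampling); the ``method`` field of the
    config is overridden per entry of ``methods``.
    """
    base = config or ReconConfig()
    if len(series) == 1:
        logger.warning(
            "single-angle series: reconstruction is a degenerate one-angle "
            "backprojection"
        )
    elif series.angles_deg.max() - series.angles_deg.min() < 30.0:
        logger.info(
            "severely limited angular range (%.1f deg): expect wedge artifacts",
            series.angles_deg.max() - series.angles_deg.min(),
        )

    logger.info("registering %d images to the 0-degree reference", len(series))
    aligned, shifts = register_series(series, subpixel=subpixel)
    cropped = crop_common(aligned, shifts)
    logger.info(
        "cropped to %dx%d; building %d sinograms",
        cropped.images.shape[1],
        cropped.images.shape[2],
        cropped.images.shape[2],
    )
    sinos = build_all_sinograms(cropped)

    result = PipelineResult(registered=cropped, shifts=shifts)
    for method in methods:
        cfg = ReconConfig(
            method=method,
            filter_name=base.filter_name,
            n_iterations=base.n_iterations,
            relaxation=base.relaxation,
            clamp_nonnegative=base.clamp_nonnegative,
            angle_subsample_step_deg=base.angle_subsample_step_deg,
        )
        logger.info("reconstructing %d slices with %s", len(sinos), method)
        slices: list[Slice2D] = [reconstruct_slice(s, cfg) for s in sinos]
        result.volumes[method] = assemble_volume(slices, method=method)
    return result


def normalized(a: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant array maps to zeros."""
    a = np.asarray(a, dtype=float)
    span = float(a.max()) - float(a.min())
    if span == 0:
        return np.zeros_like(a)
    return (a - a.min()) / span
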