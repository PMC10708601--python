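"""Column-as-projection sinogram extraction.

After alignment and cropping, the pixel values along the detector direction
of each tilt image are, for every fixed rotation-axis position, 1D parallel
projections of the corresponding tissue cross-section.  Extracting the same
image column across all angles therefore yields a limited-angle sinogram
p(theta, s) for that slice, with no resampling whatsoever — the operation is
a lossless rearrangement of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .registration import TiltSeries

__all__ = ["Sinogram", "build_sinogram", "build_all_sinograms"]


@dataclass
class Sinogram:
    """Projection matrix for one slice: ``values[k, s] = p(theta_k, s)``.

    Rows are ordered by strictly increasing angle; ``n_detector`` equals the
    cropped image extent along the detector (row) direction.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    slice_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.values.ndim != 2:
            raise ContractError("sinogram values must be 2D (n_angles, n_detector)")
        if len(self.values) != len(self.angles_deg):
            raise ContractError("one angle per sinogram row required")
        if len(self.angles_deg) > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ContractError("sinogram angles must be strictly increasing")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_detector(self) -> int:
        return self.values.shape[1]


def negative_log(values: np.ndarray, i_max: float | None = None) -> np.ndarray:
    """Beer-Lambert transform ``p = -ln(I / I_max)`` of intensity values.

    ``i_max`` defaults to the maximum of ``values``; non-positive intensities
    are clipped to a tiny fraction of ``i_max``.  Off by default throughout
    the pipeline — grayscale values are used directly as projections.
    """
    values = np.asarray(values, dtype=float)
    if i_max is None:
        i_max = float(values.max())
    if i_max <= 0:
        raise ContractError("negative-log transform needs a positive maximum")
    return -np.log(np.clip(values, 1e-9 * i_max, None) / i_max)


def build_sinogram(
    series: TiltSeries, slice_index: int, log_transform: bool = False
) -> Sinogram:
    """Sinogram of the slice at ``slice_index`` along the rotation axis.

    Row ``k`` is the image column at ``slice_index`` of the image at the
    ``k``-th angle, copied bit-exactly.  With ``log_transform=True`` the
    intensities are first converted to absorbances via :func:`negative_log`
    using the per-series maximum.
    """
    if len(series) == 0:
        raise ContractError("empty series")
    n_axis = series.images.shape[2]
    if not 0 <= slice_index < n_axis:
        raise ContractError(
            f"slice_index {slice_index} out of range [0, {n_axis})"
        )
    values = series.images[:, :, slice_index].copy()
    if log_transform:
        values = negative_log(values, i_max=float(series.images.max()))
    return Sinogram(values, series.angles_deg.copy(), slice_index)


def build_all_sinograms(series: TiltSeries) -> list[Sinogram]:
    """One sinogram per rotation-axis position, in index order."""
    if len(series) == 0:
        raise ContractError("empty series")
    n_axis = series.images.shape[2]
    return [build_sinogram(series, j) for j in range(n_axis)]
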