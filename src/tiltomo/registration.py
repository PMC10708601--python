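"""Phase-correlation alignment of a tilt series to its 0-degree reference.

Small deviations of the mechanical rotation axis from the ideal one displace
the tissue in each tilted image.  Because the misalignment is translational,
it is estimated by phase correlation: the normalized cross-power spectrum of
the reference and moving images is inverse-transformed, and its peak sits at
the relative offset.  Every image is then translated back onto the reference
and the stack is cropped to the common field of view, removing the black
border that the translation leaves behind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ContractError, DegenerateCropError, DegenerateInputError

__all__ = [
    "Shift",
    "TiltSeries",
    "apply_shift",
    "crop_common",
    "phase_correlate",
    "register_series",
    "to_grayscale",
]

_EPS = 1e-12


class Shift(NamedTuple):
    """Displacement (rows, columns) of a moving image relative to the reference.

    ``moving(r, c) ~= reference(r - d_row, c - d_col)``; translating the
    moving image by ``(-d_row, -d_col)`` aligns it to the reference.
    """

    d_row: float
    d_col: float


@dataclass
class TiltSeries:
    """An ordered tilt stack: ``images`` (n_angles, H, W), ``angles_deg``."""

    images: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.images.ndim != 3:
            raise ContractError("images must be a (n_angles, H, W) stack")
        if len(self.images) != len(self.angles_deg):
            raise ContractError("one angle per image required")
        if len(self.angles_deg) > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ContractError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)

    def reference_index(self) -> int:
        """Index of the 0-degree reference image."""
        hits = np.flatnonzero(np.isclose(self.angles_deg, 0.0, atol=1e-9))
        if len(hits) == 0:
            raise ContractError("series has no 0-degree reference image")
        return int(hits[0])


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of a (H, W, 3) 8-bit image, at float precision."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ContractError(f"expected (H, W, 3) RGB input, got shape {rgb.shape}")
    return rgb @ np.array([0.299, 0.587, 0.114])


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    """Vertex offset of the parabola through (-1, ym), (0, y0), (+1, yp)."""
    denom = ym - 2.0 * y0 + yp
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (ym - yp) / denom
    # subpixel refinement can never legitimately move past the neighbours
    return float(np.clip(delta, -0.5, 0.5))


def phase_correlate(
    reference: np.ndarray,
    moving: np.ndarray,
    subpixel: bool = True,
    window: bool = False,
) -> Shift:
    """Estimate the translation of ``moving`` relative to ``reference``.

    Both images are FFT-transformed; the cross-power spectrum
    ``conj(F(ref)) * F(mov)`` is normalized to unit magnitude elementwise
    (guarded by eps = 1e-12), inverse-transformed, and the correlation peak
    located (first occurrence in row-major order on ties).  Peak indices past
    n/2 wrap to negative offsets.  With ``subpixel=True`` a 3-point parabolic
    fit per axis refines the peak; integer mode is exact for circular shifts.
    ``window=True`` applies a Hann window first, for scenes with strong
    wraparound edges.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ContractError(
            f"shape mismatch: {reference.shape} vs {moving.shape}"
        )
    if reference.ndim != 2 or min(reference.shape) < 8:
        raise ContractError("images must be 2D and at least 8x8")
    if np.ptp(reference) == 0:
        raise DegenerateInputError("reference image is constant")

    if window:
        wr = np.hanning(reference.shape[0])[:, None]
        wc = np.hanning(reference.shape[1])[None, :]
        reference = reference * wr * wc
        moving = moving * wr * wc

    f_ref = np.fft.fft2(reference)
    f_mov = np.fft.fft2(moving)
    cross = np.conj(f_ref) * f_mov
    corr = np.fft.ifft2(cross / np.maximum(np.abs(cross), _EPS)).real

    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    offsets = []
    for axis, p in enumerate(peak):
        n = corr.shape[axis]
        d = float(p)
        if subpixel:
            line = corr.take(peak[1 - axis], axis=1 - axis)
            d += _parabolic_offset(line[(p - 1) % n], line[p], line[(p + 1) % n])
        if d > n / 2:
            d -= n
        offsets.append(d)
    return Shift(offsets[0], offsets[1])


def apply_shift(image: np.ndarray, shift: Shift) -> np.ndarray:
    """Translate ``image`` by the negated measured shift, aligning it to the
    reference.  Vacated pixels are zero-filled (the black peripheral band);
    subpixel components use linear interpolation, integer shifts are exact.
    """
    image = np.asarray(image, dtype=float)
    dr, dc = float(shift[0]), float(shift[1])
    if not (math.isfinite(dr) and math.isfinite(dc)):
        raise ContractError("shift components must be finite")
    if dr == 0.0 and dc == 0.0:
        return image.copy()
    order = 0 if (dr == int(dr) and dc == int(dc)) else 1
    return ndimage.shift(image, (-dr, -dc), order=order, cval=0.0, prefilter=False)


def register_series(
    series: TiltSeries, subpixel: bool = True, window: bool = False
) -> tuple[TiltSeries, list[Shift]]:
    """Align every image of the series to the 0-degree reference.

    Returns the aligned series and the measured shifts in acquisition order;
    the reference's shift is exactly (0, 0).
    """
    ref_idx = series.reference_index()
    reference = series.images[ref_idx]
    aligned = np.empty_like(series.images)
    shifts: list[Shift] = []
    for k, img in enumerate(series.images):
        if k == ref_idx:
            s = Shift(0.0, 0.0)
        else:
            s = phase_correlate(reference, img, subpixel=subpixel, window=window)
        shifts.append(s)
        aligned[k] = apply_shift(img, s)
    return TiltSeries(aligned, series.angles_deg.copy()), shifts


def crop_common(aligned: TiltSeries, shifts: list[Shift]) -> TiltSeries:
    """Crop the aligned stack to the field shared by every image.

    The crop rectangle shrinks the original extent by ``ceil(max |d_row|)``
    on top and bottom and ``ceil(max |d_col|)`` on left and right, so no
    zero-filled border pixel survives and all outputs share one shape.
    """
    if len(shifts) != len(aligned):
        raise ContractError("need exactly one shift per image")
    n_angles, h, w = aligned.images.shape
    m_r = int(math.ceil(max(abs(float(s[0])) for s in shifts)))
    m_c = int(math.ceil(max(abs(float(s[1])) for s in shifts)))
    if h - 2 * m_r <= 0 or w - 2 * m_c <= 0:
        raise DegenerateCropError(
            f"shifts ({m_r}, {m_c}) leave no common field in {h}x{w} images"
        )
    cropped = aligned.images[:, m_r : h - m_r, m_c : w - m_c].copy()
    return TiltSeries(cropped, aligned.angles_deg.copy())
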