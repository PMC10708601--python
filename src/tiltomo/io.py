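"""Reading and writing tilt stacks on disk.

A stack directory contains numbered grayscale images (``img_000.tif`` ...)
plus ``angles.txt`` with one ``index,angle_deg`` pair per line.  Simulated
stacks additionally carry ``truth.npz`` (true shifts, phantom, noise sigma,
seed) so registration and reconstruction can be scored against ground truth.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ContractError
from .phantoms import SimulatedSeries
from .registration import Shift, TiltSeries, to_grayscale

__all__ = [
    "read_stack",
    "write_stack",
    "write_series_archive",
    "read_series_archive",
    "write_shifts_csv",
]


def _scale_to_uint16(images: np.ndarray) -> np.ndarray:
    lo = float(images.min())
    span = float(images.max()) - lo
    if span == 0:
        return np.zeros(images.shape, dtype=np.uint16)
    return np.round((images - lo) / span * 65535).astype(np.uint16)


def write_stack(series: TiltSeries, directory: str | Path) -> list[Path]:
    """Write a tilt series as numbered 16-bit TIFFs plus ``angles.txt``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scaled = _scale_to_uint16(series.images)
    width = max(3, len(str(len(series) - 1)))
    paths = []
    for k, img in enumerate(scaled):
        path = directory / f"img_{k:0{width}d}.tif"
        tifffile.imwrite(path, img)
        paths.append(path)
    lines = [f"{k},{a:g}" for k, a in enumerate(series.angles_deg)]
    (directory / "angles.txt").write_text("\n".join(lines) + "\n")
    return paths


def read_stack(directory: str | Path) -> TiltSeries:
    """Read a numbered TIFF/PNG stack and its ``angles.txt``.

    RGB frames are converted to luminance; frames are ordered by the index
    column of the angles file.
    """
    directory = Path(directory)
    angles_file = directory / "angles.txt"
    if not angles_file.exists():
        raise ContractError(f"no angles.txt in {directory}")
    pairs = []
    for line in angles_file.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        idx, ang = line.split(",")
        pairs.append((int(idx), float(ang)))
    pairs.sort()
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
    if len(files) != len(pairs):
        raise ContractError(
            f"{len(files)} image files but {len(pairs)} angle entries in {directory}"
        )
    images = []
    for path in files:
        img = np.asarray(iio.imread(path), dtype=float)
        if img.ndim == 3:
            img = to_grayscale(img[..., :3])
        images.append(img)
    return TiltSeries(np.stack(images), np.array([a for _, a in pairs]))


def write_series_archive(series: SimulatedSeries, directory: str | Path) -> Path:
    """Write a simulated series: TIFF stack, angles file and truth sidecar."""
    directory = Path(directory)
    write_stack(TiltSeries(series.images, series.angles_deg), directory)
    truth = directory / "truth.npz"
    np.savez(
        truth,
        true_shifts=series.true_shifts,
        phantom=series.phantom,
        noise_sigma=series.noise_sigma,
        seed=series.seed,
        angles_deg=series.angles_deg,
    )
    return truth


def read_series_archive(directory: str | Path) -> SimulatedSeries:
    """Load a simulated series written by :func:`write_series_archive`.

    Images come back min-max normalized to [0, 1] (16-bit quantization is
    part of the simulated acquisition).
    """
    directory = Path(directory)
    stack = read_stack(directory)
    with np.load(directory / "truth.npz") as truth:
        return SimulatedSeries(
            images=stack.images / 65535.0,
            angles_deg=stack.angles_deg,
            true_shifts=truth["true_shifts"],
            phantom=truth["phantom"],
            noise_sigma=float(truth["noise_sigma"]),
            seed=int(truth["seed"]),
        )


def write_shifts_csv(
    path: str | Path, angles_deg: np.ndarray, shifts: list[Shift]
) -> Path:
    """Write the registration report: index, angle, measured shift."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "angle_deg", "d_row", "d_col"])
        for k, (a, s) in enumerate(zip(angles_deg, shifts)):
            writer.writerow([k, f"{a:g}", f"{s[0]:.4f}", f"{s[1]:.4f}"])
    return path
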