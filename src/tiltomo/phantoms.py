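"""Synthetic tissue phantoms and the tilting-slide acquisition simulator.

The forward model mirrors the "step and shoot" geometry of the physical
stage: the illumination and camera are fixed, the slide rotates about an axis
parallel to the image *columns*, and at every tilt angle a parallel projection
of the absorbing tissue slab is recorded.  Tilting therefore displaces
features along the image *rows* (the detector direction) while each column
position selects an independent cross-section ("slab") of the sample.

Array conventions
-----------------
phantom        ``(n_axis, n_depth, n_s)`` — rotation-axis position, optical
               depth, detector position.  ``phantom[j]`` is the 2D slab whose
               reconstruction is slice ``j`` of the final volume.
slab / slice   ``(n_depth, n_s)`` — rows are depth, columns are the detector.
tilt image     ``(n_s, n_axis)`` — rows are the detector direction, columns
               run along the rotation axis.

Grayscale pixel values are used directly as projection values (no
Beer-Lambert exponentiation); the stained tissue is modelled as an additive
absorbance field.  An optional attenuation mode converts line integrals to
transmitted intensity ``I = I0 * exp(-integral)`` for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidGridError, InvalidParameterError, InvalidSpecError

__all__ = [
    "AngleGrid",
    "Ellipsoid",
    "PhantomSpec",
    "SimulatedSeries",
    "angle_sequence",
    "default_phantom_spec",
    "make_phantom",
    "oracle_project_slice",
    "simulate_tilt_series",
]

_TOL = 1e-9


@dataclass(frozen=True)
class AngleGrid:
    """Inclusive, evenly spaced tilt-angle range in degrees.

    The default matches the acquisition protocol of the tilting stage:
    -10 to +10 degrees in 0.5-degree steps, i.e. 41 images.
    """

    start_deg: float = -10.0
    end_deg: float = 10.0
    step_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.step_deg <= 0:
            raise InvalidGridError(f"step_deg must be > 0, got {self.step_deg}")
        if self.end_deg < self.start_deg:
            raise InvalidGridError(
                f"end_deg ({self.end_deg}) < start_deg ({self.start_deg})"
            )
        span = self.end_deg - self.start_deg
        k = span / self.step_deg
        if abs(k - round(k)) > _TOL * max(1.0, abs(k)):
            raise InvalidGridError(
                f"span {span} is not an integer multiple of step {self.step_deg}"
            )

    @property
    def n_angles(self) -> int:
        return int(round((self.end_deg - self.start_deg) / self.step_deg)) + 1


def angle_sequence(grid: AngleGrid) -> np.ndarray:
    """Expand an :class:`AngleGrid` into its ordered angle list (degrees).

    Both endpoints are included; the length is
    ``round((end - start) / step) + 1``.
    """
    n = grid.n_angles
    return grid.start_deg + grid.step_deg * np.arange(n)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in phantom voxel coordinates (axis, depth, s)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    intensity: float = 1.0


@dataclass
class PhantomSpec:
    """Recipe for a 3D absorbance phantom standing in for a stained section.

    Parameters
    ----------
    n_s, n_depth, n_axis
        Grid extent along the detector, depth and rotation-axis directions.
    ellipsoids
        Explicit primitives; voxel value = background + sum of intensities of
        the ellipsoids containing the voxel.
    background
        Constant absorbance added everywhere.
    n_random
        Number of additional randomly placed ellipsoids (seeded).  Random
        primitives are confined to the central region so that tilting up to
        ~10 degrees never carries structure across the field border.
    seed
        Seed for the random primitives; the phantom is deterministic given it.
    """

    n_s: int = 64
    n_depth: int = 64
    n_axis: int = 32
    ellipsoids: list[Ellipsoid] = field(default_factory=list)
    background: float = 0.0
    n_random: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_s, self.n_depth, self.n_axis) <= 0:
            raise InvalidSpecError(
                f"grid shape must be positive, got "
                f"({self.n_s}, {self.n_depth}, {self.n_axis})"
            )
        shape = (self.n_axis, self.n_depth, self.n_s)
        for e in self.ellipsoids:
            if min(e.semi_axes) <= 0:
                raise InvalidSpecError(f"semi-axes must be > 0: {e}")
            if e.intensity < 0:
                raise InvalidSpecError(f"intensity must be >= 0: {e}")
            for c, n in zip(e.center, shape):
                if not (0 <= c < n):
                    raise InvalidSpecError(f"center {e.center} outside grid {shape}")
        if self.background < 0:
            raise InvalidSpecError("background must be >= 0")
        if self.n_random < 0:
            raise InvalidSpecError("n_random must be >= 0")


def _random_ellipsoids(spec: PhantomSpec) -> list[Ellipsoid]:
    rng = np.random.default_rng(spec.seed)
    shape = np.array([spec.n_axis, spec.n_depth, spec.n_s], dtype=float)
    out = []
    for _ in range(spec.n_random):
        # stay in the central half so tilt excursions never clip structure
        center = tuple(rng.uniform(0.3, 0.7) * shape)
        semi = tuple(rng.uniform(0.04, 0.12) * shape)
        out.append(Ellipsoid(center, semi, float(rng.uniform(0.5, 1.5))))
    return out


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a :class:`PhantomSpec` to a float64 grid (n_axis, n_depth, n_s)."""
    shape = (spec.n_axis, spec.n_depth, spec.n_s)
    vol = np.full(shape, float(spec.background))
    a, d, s = np.meshgrid(
        np.arange(spec.n_axis),
        np.arange(spec.n_depth),
        np.arange(spec.n_s),
        indexing="ij",
    )
    for e in list(spec.ellipsoids) + _random_ellipsoids(spec):
        ca, cd, cs = e.center
        ra, rd, rs = e.semi_axes
        inside = ((a - ca) / ra) ** 2 + ((d - cd) / rd) ** 2 + ((s - cs) / rs) ** 2 <= 1.0
        vol[inside] += e.intensity
    return vol


def default_phantom_spec(n: int = 64, n_axis: int = 32) -> PhantomSpec:
    """The standard synthetic fixture: three nested/offset ellipsoids.

    Structures sit well inside the field so that rotations up to the maximum
    tilt never push intensity across the border (required for the
    mass-conservation property of the simulator).
    """
    c = (n - 1) / 2.0
    ca = (n_axis - 1) / 2.0
    return PhantomSpec(
        n_s=n,
        n_depth=n,
        n_axis=n_axis,
        ellipsoids=[
            Ellipsoid((ca, c, c), (0.42 * n_axis, 0.30 * n, 0.30 * n), 1.0),
            Ellipsoid((ca, c - 0.12 * n, c + 0.10 * n), (0.25 * n_axis, 0.10 * n, 0.08 * n), 1.0),
            Ellipsoid((0.35 * n_axis, c + 0.10 * n, c - 0.12 * n), (0.15 * n_axis, 0.06 * n, 0.10 * n), 2.0),
        ],
    )


def oracle_project_slice(slab: np.ndarray, angle_deg: float) -> np.ndarray:
    """Parallel projection of a 2D slab by rotate-then-sum.

    The slab is resampled rotated by ``-angle_deg`` about its center (linear
    interpolation) and summed along the depth axis (rows).  At angle 0 this is
    exactly the column-wise sum.  Non-square slabs are zero-padded to square
    first, so the projection length equals the (padded) slab side.

    This routine is intentionally independent of the ray-driven projector in
    :mod:`tiltomo.reconstruct`; the two serve as cross-checking oracles.
    """
    slab = np.asarray(slab, dtype=float)
    if slab.ndim != 2:
        raise InvalidParameterError("slab must be 2D")
    nr, nc = slab.shape
    if nr != nc:
        side = max(nr, nc)
        pad_r, pad_c = side - nr, side - nc
        slab = np.pad(
            slab,
            ((pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)),
        )
    if angle_deg == 0.0:
        return slab.sum(axis=0)
    rot = ndimage.rotate(slab, -angle_deg, reshape=False, order=1, prefilter=False)
    return rot.sum(axis=0)


@dataclass
class SimulatedSeries:
    """A simulated tilt series plus the ground truth used to generate it.

    ``images`` has shape (n_angles, n_s, n_axis); ``true_shifts`` holds the
    per-angle (d_row, d_col) misalignments (the 0-degree image is never
    shifted) so registration can be scored against truth.
    """

    images: np.ndarray
    angles_deg: np.ndarray
    true_shifts: np.ndarray
    phantom: np.ndarray
    noise_sigma: float
    seed: int


def simulate_tilt_series(
    phantom: np.ndarray,
    grid: AngleGrid,
    noise_sigma: float = 0.0,
    max_misalignment: int = 0,
    seed: int = 0,
    attenuation: bool = False,
    i0: float = 1.0,
    depth_blur_sigma: float = 0.0,
) -> SimulatedSeries:
    """Simulate one image per tilt angle of ``grid``.

    For each angle every rotation-axis slab ``phantom[j]`` is projected with
    :func:`oracle_project_slice`; the 1D projections are stacked into a 2D
    image with the detector coordinate down the rows and the rotation-axis
    coordinate across the columns.  A uniform integer misalignment in
    ``[-max_misalignment, max_misalignment]^2`` is then applied (zero at the
    0-degree reference) and zero-mean Gaussian noise of ``noise_sigma`` is
    added.  Identical seeds give bit-identical output.

    ``attenuation=True`` converts the absorbance line integral to transmitted
    intensity ``I = i0 * exp(-p)`` (off by default: the method uses grayscale
    values directly as projections).  ``depth_blur_sigma > 0`` applies a
    Gaussian weighting along depth before projection, a crude stand-in for
    limited depth of focus; also off by default.
    """
    phantom = np.asarray(phantom, dtype=float)
    if phantom.ndim != 3 or phantom.size == 0:
        raise InvalidParameterError("phantom must be a nonempty 3D grid")
    if noise_sigma < 0:
        raise InvalidParameterError(f"noise_sigma must be >= 0, got {noise_sigma}")
    if max_misalignment < 0:
        raise InvalidParameterError("max_misalignment must be >= 0")

    angles = angle_sequence(grid)
    n_axis, n_depth, n_s = phantom.shape
    rng = np.random.default_rng(seed)

    if depth_blur_sigma > 0:
        d = np.arange(n_depth) - (n_depth - 1) / 2.0
        w = np.exp(-0.5 * (d / depth_blur_sigma) ** 2)
        phantom_eff = phantom * w[None, :, None]
    else:
        phantom_eff = phantom

    side = max(n_depth, n_s)
    images = np.empty((len(angles), side, n_axis))
    true_shifts = np.zeros((len(angles), 2), dtype=int)
    for k, theta in enumerate(angles):
        img = np.empty((side, n_axis))
        for j in range(n_axis):
            img[:, j] = oracle_project_slice(phantom_eff[j], theta)
        if attenuation:
            img = i0 * np.exp(-img)
        if max_misalignment > 0 and theta != 0.0:
            dr, dc = rng.integers(-max_misalignment, max_misalignment + 1, size=2)
            true_shifts[k] = (dr, dc)
            img = ndimage.shift(img, (dr, dc), order=0, cval=0.0)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        images[k] = img
    return SimulatedSeries(
        images=images,
        angles_deg=angles,
        true_shifts=true_shifts,
        phantom=phantom,
        noise_sigma=noise_sigma,
        seed=seed,
    )
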