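"""Shared fixtures: phantoms, simulated series, and oracle helpers.

All fixtures are generated programmatically and seeded, so the suite is
fully deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from tiltomo.phantoms import (
    AngleGrid,
    Ellipsoid,
    PhantomSpec,
    default_phantom_spec,
    make_phantom,
    simulate_tilt_series,
)
from tiltomo.registration import TiltSeries


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231209)


@pytest.fixture(scope="session")
def phantom48():
    """Small 3D phantom for end-to-end runs: 24 slabs of 48x48."""
    return make_phantom(default_phantom_spec(48, 24))


@pytest.fixture(scope="session")
def phantom_slice64():
    """One 64x64 cross-section of the standard fixture."""
    ph = make_phantom(default_phantom_spec(64, 3))
    return ph[1]


@pytest.fixture(scope="session")
def clean_series48(phantom48):
    """Noise-free, perfectly aligned tilt series of the small phantom."""
    sim = simulate_tilt_series(phantom48, AngleGrid(-10, 10, 1.0))
    return sim


@pytest.fixture(scope="session")
def misaligned_series48(phantom48):
    """Noise-free series with integer misalignments up to 5 px."""
    return simulate_tilt_series(
        phantom48, AngleGrid(-10, 10, 1.0), max_misalignment=5, seed=3
    )


def interior_random_slice(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random field supported in the central region of an n x n slice.

    Keeps all mass well away from the border so the rotate-then-sum oracle
    (which clips corners when resampling) and the ray-driven projector see
    the same object.
    """
    yy, xx = np.mgrid[0:n, 0:n]
    c0 = (n - 1) / 2
    mask = (np.abs(yy - c0) < 0.30 * n) & (np.abs(xx - c0) < 0.30 * n)
    return rng.random((n, n)) * mask


def spotted_slice(n: int = 256) -> np.ndarray:
    """Detector-realistic slice: smooth body plus compact bright features.

    Features sit at a range of radii from the rotation center so that
    coarser angular sampling produces measurable view-aliasing streaks
    (aliasing scales with step x radius).
    """
    c = (n - 1) / 2
    spots = []
    for r, ang in [(40, 0.3), (60, 2.1), (80, 4.0), (95, 1.2),
                   (70, 5.5), (50, 3.3), (88, 0.9), (30, 4.8)]:
        dy, dx = r * np.sin(ang), r * np.cos(ang)
        spots.append(Ellipsoid((0, c + 0.4 * dy, c + dx), (1, 2.5, 2.5), 3.0))
    spec = PhantomSpec(
        n_s=n, n_depth=n, n_axis=1,
        ellipsoids=[Ellipsoid((0, c, c), (1, 0.28 * n, 0.30 * n), 1.0)] + spots,
    )
    return make_phantom(spec)[0]


def rmse_affine(rec: np.ndarray, truth: np.ndarray) -> float:
    """RMSE to truth after a least-squares affine intensity match.

    Reconstruction intensity is on an arbitrary scale, so the comparison
    fits gain and offset first; the residual then measures structure only.
    """
    a = np.stack([rec.ravel(), np.ones(rec.size)], axis=1)
    coef, *_ = np.linalg.lstsq(a, truth.ravel(), rcond=None)
    return float(np.sqrt(np.mean((a @ coef - truth.ravel()) ** 2)))


@pytest.fixture(scope="session")
def series_factory(phantom48):
    """Build a TiltSeries view of a SimulatedSeries."""

    def _make(sim):
        return TiltSeries(sim.images, sim.angles_deg)

    return _make
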