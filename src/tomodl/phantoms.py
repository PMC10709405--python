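"""Synthetic slices and simulated OPT acquisitions with known ground truth.

Stands in for resampled transmission-OPT slices of small transparent
organisms: values in [0, 1], support inside the inscribed circle, acquired
over a full turn at a fixed angular step with optional detector-axis
misalignment (centre-of-rotation shift) and noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .preprocessing import shift_sinogram
from .radon import Geometry, inscribed_circle_mask, radon_forward

__all__ = ["PhantomSpec", "AcquisitionSpec", "make_phantom", "simulate_acquisition"]

PHANTOM_KINDS = ("shepp_logan", "random_ellipses")
NOISE_MODELS = ("none", "gaussian", "poisson")


@dataclass(frozen=True)
class PhantomSpec:
    size_px: int = 100
    kind: str = "shepp_logan"
    n_ellipses: int = 8
    intensity_range: tuple = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.size_px < 16:
            raise ValueError("size_px must be >= 16")
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.n_ellipses < 0:
            raise ValueError("n_ellipses must be >= 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Full-turn acquisition: ``n_angles_full * angle_step_deg == 360``."""

    n_angles_full: int = 720
    angle_step_deg: float = 0.5
    noise_model: str = "none"
    noise_level: float = 0.0
    cor_shift_px: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_angles_full < 1:
            raise ValueError("n_angles_full must be positive")
        if abs(self.n_angles_full * self.angle_step_deg - 360.0) > 1e-9:
            raise ValueError("n_angles_full * angle_step_deg must equal 360")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles_full) * self.angle_step_deg

    def geometry(self, size_px: int) -> Geometry:
        return Geometry.uniform(size_px, self.n_angles_full)


def _random_ellipses(spec: PhantomSpec) -> np.ndarray:
    """Overlapping soft ellipses mimicking organ cross-sections.

    Centres uniform in a 0.8-radius disk, semi-axes uniform in [3%, 30%] of
    the side length, orientation uniform; intensities add and are clipped.
    """
    n = spec.size_px
    rng = np.random.default_rng(spec.seed)
    img = np.zeros((n, n))
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    xx = xx - c
    yy = yy - c
    lo, hi = spec.intensity_range
    for _ in range(spec.n_ellipses):
        r = 0.8 * (n / 2.0) * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cx, cy = r * np.cos(th), r * np.sin(th)
        a = rng.uniform(0.03, 0.30) * n
        b = rng.uniform(0.03, 0.30) * n
        phi = rng.uniform(0, np.pi)
        amp = rng.uniform(lo, hi)
        xr = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
        yr = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
        img += amp * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return np.clip(img, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a deterministic phantom slice in [0, 1] on circular support."""
    if spec.kind == "shepp_logan":
        img = resize(
            shepp_logan_phantom(),
            (spec.size_px, spec.size_px),
            order=1,
            anti_aliasing=True,
        )
        img = np.clip(img, 0.0, 1.0)
    else:
        img = _random_ellipses(spec)
    img[~inscribed_circle_mask(spec.size_px)] = 0.0
    return img


def simulate_acquisition(x: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    """Forward-project ``x`` on the full angle grid, then apply the
    centre-of-rotation shift and, last, the noise model."""
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("phantom slice must be square")
    b = radon_forward(x, acq.geometry(x.shape[0]))
    if acq.cor_shift_px != 0.0:
        b = shift_sinogram(b, acq.cor_shift_px)
    if acq.noise_model == "none" or acq.noise_level == 0.0:
        return b
    rng = np.random.default_rng(acq.seed)
    peak = float(b.max())
    if peak <= 0:
        return b
    if acq.noise_model == "gaussian":
        return b + rng.normal(0.0, acq.noise_level * peak, size=b.shape)
    # poisson: scale so the maximum expected photon count is 1 / noise_level^2
    counts = b / peak * (1.0 / acq.noise_level**2)
    noisy = rng.poisson(np.clip(counts, 0, None)).astype(np.float64)
    return noisy * peak * acq.noise_level**2
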