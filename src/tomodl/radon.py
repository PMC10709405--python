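"""Parallel-beam forward model ``A = S R``.

``R`` is the discrete Radon transform (pixel-driven, linear detector splat),
``S`` an equispaced angular subsampling operator.  ``R`` is materialised as a
scipy sparse matrix, so the adjoint (unfiltered backprojection) is its exact
transpose and the pair satisfies the inner-product identity to machine
precision.  Filtered backprojection is per-row frequency-domain filtering
followed by the adjoint.

Conventions
-----------
* Pixel centres sit on an integer grid centred on the image midpoint; the
  reconstruction support is the inscribed circle (pixels outside it are
  excluded from the operator and forced to zero in every image).
* Angle 0 projects along image columns; detector coordinate of a pixel at
  centred coordinates (x, y) under angle phi is ``t = x cos(phi) + y sin(phi)``.
* Detector bins are unit-width with centres on the same integer grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Geometry",
    "SamplingScheme",
    "ForwardModel",
    "inscribed_circle_mask",
    "radon_forward",
    "radon_adjoint",
    "fbp",
    "build_sampling",
    "apply_zero_pad_mask",
]

FBP_FILTERS = ("ramp", "shepp_logan", "hann")


def inscribed_circle_mask(n: int) -> np.ndarray:
    """Boolean mask of pixel centres strictly inside the inscribed circle."""
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 < (n / 2.0) ** 2


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry: image side, detector length and angle grid."""

    image_size_px: int
    angles_deg: tuple
    n_detector: int = 0

    def __post_init__(self):
        if self.image_size_px < 1:
            raise ValueError("image_size_px must be positive")
        object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
        if self.n_detector == 0:
            object.__setattr__(self, "n_detector", self.image_size_px)
        if self.n_detector < 1:
            raise ValueError("n_detector must be >= 1")
        a = np.asarray(self.angles_deg)
        if a.size == 0:
            raise ValueError("need at least one angle")
        if np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing")
        if a[0] < 0 or a[-1] >= 360:
            raise ValueError("angles must lie in [0, 360)")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @staticmethod
    def uniform(image_size_px: int, n_angles: int, span_deg: float = 360.0,
                n_detector: int = 0) -> "Geometry":
        angles = np.arange(n_angles) * (span_deg / n_angles)
        return Geometry(image_size_px, tuple(angles), n_detector)


@lru_cache(maxsize=4)
def _system_matrix(n: int, n_det: int, angles_deg: tuple) -> sp.csr_matrix:
    """Sparse Radon matrix, shape (n_angles * n_det, n * n).

    Joseph's method: each ray is traversed along its driving axis (the image
    axis it is most aligned with), sampling the image by linear interpolation
    between the two pixels adjacent to the ray at every step and weighting by
    the path length per step, ``1/max(|cos|, |sin|)``.  Pixels outside the
    inscribed circle are excluded (reconstruction support).
    """
    mask = inscribed_circle_mask(n)
    half = (n - 1) / 2.0
    t_det = np.arange(n_det) - (n_det - 1) / 2.0  # detector bin centres

    rows_all, cols_all, vals_all = [], [], []
    axis = np.arange(n) - half  # pixel-centre coordinate along the driving axis
    for i, ang in enumerate(angles_deg):
        phi = np.deg2rad(ang)
        c, s = np.cos(phi), np.sin(phi)
        # ray: x cos(phi) + y sin(phi) = t  (x: columns, y: rows)
        if abs(c) >= abs(s):
            # drive over rows y; interpolate between adjacent columns
            x = (t_det[:, None] - axis[None, :] * s) / c  # (n_det, n)
            pos = x + half
            drive_idx = np.broadcast_to(np.arange(n)[None, :], pos.shape)
            length = 1.0 / abs(c)

            def pixel_index(drive, other):
                return drive * n + other  # row * n + col
        else:
            # drive over columns x; interpolate between adjacent rows
            y = (t_det[:, None] - axis[None, :] * c) / s
            pos = y + half
            drive_idx = np.broadcast_to(np.arange(n)[None, :], pos.shape)
            length = 1.0 / abs(s)

            def pixel_index(drive, other):
                return other * n + drive  # row * n + col

        det_idx = np.broadcast_to(np.arange(n_det, dtype=np.int64)[:, None],
                                  pos.shape)
        lo = np.floor(pos).astype(np.int64)
        frac = pos - lo
        for off, wt in ((0, 1.0 - frac), (1, frac)):
            other = lo + off
            ok = (other >= 0) & (other < n) & (wt > 1e-12)
            pix = pixel_index(drive_idx[ok], other[ok])
            keep = mask.ravel()[pix]
            rows_all.append(i * n_det + det_idx[ok][keep])
            cols_all.append(pix[keep])
            vals_all.append(wt[ok][keep] * length)
    mat = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(len(angles_deg) * n_det, n * n),
    )
    return mat.tocsr()


@dataclass(frozen=True)
class SamplingScheme:
    """Equispaced angular subsampling ``S``: which sinogram rows are kept."""

    n_angles_full: int
    acceleration_R: int
    initial_index: int
    retained_indices: tuple

    def __post_init__(self):
        if not (0 <= self.initial_index < self.n_angles_full):
            raise ValueError("initial_index out of range")
        if any(not (0 <= i < self.n_angles_full) for i in self.retained_indices):
            raise ValueError("retained index out of range")

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)


def build_sampling(n_angles_full: int, R: int, initial_index=0,
                   seed: int | None = None) -> SamplingScheme:
    """Equispaced retained-angle index set for acceleration factor ``R``.

    ``n_retained = floor(n_angles_full / R)``; indices are spaced by
    ``n_angles_full / n_retained`` starting from ``initial_index`` (drawn
    uniformly from the seeded generator when ``initial_index='random'``),
    rounded to the nearest integer grid position with ties toward the
    smaller index.
    """
    if not (1 <= R <= n_angles_full):
        raise ValueError(f"acceleration factor R={R} outside [1, {n_angles_full}]")
    if initial_index == "random":
        rng = np.random.default_rng(seed)
        initial_index = int(rng.integers(0, n_angles_full))
    initial_index = int(initial_index)
    n_ret = n_angles_full // R
    spacing = n_angles_full / n_ret
    raw = np.arange(n_ret) * spacing
    # round half toward the smaller index
    idx = np.ceil(raw - 0.5).astype(np.int64)
    idx = (initial_index + idx) % n_angles_full
    return SamplingScheme(n_angles_full, R, initial_index, tuple(int(i) for i in idx))


def apply_zero_pad_mask(b_full: np.ndarray, scheme: SamplingScheme) -> np.ndarray:
    """Zero every sinogram row not retained by the scheme; shape unchanged."""
    b_full = np.asarray(b_full)
    if b_full.shape[0] != scheme.n_angles_full:
        raise ValueError(
            f"sinogram has {b_full.shape[0]} rows, scheme expects {scheme.n_angles_full}"
        )
    out = np.zeros_like(b_full)
    idx = list(scheme.retained_indices)
    out[idx] = b_full[idx]
    return out


@dataclass
class ForwardModel:
    """``A = S R`` over a fixed geometry; optional subsampling scheme.

    ``project`` maps an image to the retained-angle sinogram; ``backproject``
    is its exact adjoint.  Without a scheme the model is fully sampled.
    """

    geometry: Geometry
    scheme: SamplingScheme | None = None
    _mat: sp.csr_matrix = field(init=False, repr=False)
    _mat_T: sp.spmatrix = field(init=False, repr=False)

    def __post_init__(self):
        g = self.geometry
        if self.scheme is not None:
            if self.scheme.n_angles_full != g.n_angles:
                raise ValueError("scheme/geometry angle count mismatch")
            angles = tuple(g.angles_deg[i] for i in sorted(self.scheme.retained_indices))
        else:
            angles = g.angles_deg
        self.angles_deg = angles
        full = _system_matrix(g.image_size_px, g.n_detector, g.angles_deg)
        if self.scheme is None:
            self._mat = full
        else:
            keep = np.zeros(g.n_angles, dtype=bool)
            keep[list(self.scheme.retained_indices)] = True
            row_sel = np.repeat(keep, g.n_detector)
            self._mat = full[row_sel]
        # CSC view of the transpose: shares the CSR buffers, no extra memory
        self._mat_T = self._mat.T

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)

    @property
    def shape(self):
        n = self.geometry.image_size_px
        return (self.n_angles * self.geometry.n_detector, n * n)

    def project(self, x: np.ndarray) -> np.ndarray:
        n = self.geometry.image_size_px
        x = np.asarray(x)
        if x.shape != (n, n):
            raise ValueError(f"image shape {x.shape} != ({n}, {n})")
        b = self._mat @ x.ravel()
        return b.reshape(self.n_angles, self.geometry.n_detector)

    def backproject(self, b: np.ndarray) -> np.ndarray:
        g = self.geometry
        b = np.asarray(b)
        if b.shape != (self.n_angles, g.n_detector):
            raise ValueError(
                f"sinogram shape {b.shape} != ({self.n_angles}, {g.n_detector})"
            )
        x = self._mat_T @ b.ravel()
        return x.reshape(g.image_size_px, g.image_size_px)


def radon_forward(x: np.ndarray, geom: Geometry) -> np.ndarray:
    """Line integrals of ``x`` along parallel rays at each geometry angle."""
    return ForwardModel(geom).project(x)


def radon_adjoint(b: np.ndarray, geom: Geometry) -> np.ndarray:
    """Exact adjoint of :func:`radon_forward` (unfiltered backprojection)."""
    return ForwardModel(geom).backproject(b)


def _fourier_filter(m: int, name: str) -> np.ndarray:
    f = np.fft.fftfreq(m)  # cycles / sample
    ramp = 2.0 * np.abs(f)  # peak 1 at Nyquist
    if name == "ramp":
        return ramp
    if name == "shepp_logan":
        return ramp * np.sinc(f)
    if name == "hann":
        return ramp * 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
    raise ValueError(f"unknown FBP filter {name!r}; choose from {FBP_FILTERS}")


def filter_sinogram(b: np.ndarray, filter: str = "ramp") -> np.ndarray:
    """Apply the FBP frequency-domain filter to each sinogram row."""
    b = np.asarray(b, dtype=np.float64)
    n_det = b.shape[1]
    m = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    h = _fourier_filter(m, filter)
    bp = np.zeros((b.shape[0], m))
    bp[:, :n_det] = b
    q = np.fft.ifft(np.fft.fft(bp, axis=1) * h, axis=1).real
    return q[:, :n_det]


def fbp(b: np.ndarray, geom: Geometry, filter: str = "ramp") -> np.ndarray:
    """Filtered backprojection, scaled by ``pi / (2 n_angles)``.

    Valid for uniformly spaced angles spanning 180 or 360 degrees (a full
    circle contains each ray twice; the scaling averages the redundancy).
    Output is masked to the inscribed circle.
    """
    q = filter_sinogram(b, filter)
    x = radon_adjoint(q, geom) * (np.pi / (2.0 * geom.n_angles))
    x[~inscribed_circle_mask(geom.image_size_px)] = 0.0
    return x
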