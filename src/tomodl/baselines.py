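"""Comparison reconstructors: TwIST with a total-variation prior.

TwIST (two-step iterative shrinkage/thresholding) solves the regularised
least-squares problem  min_x ||A x - b||^2 + lambda_tv TV(x)  with the
two-step recursion

    x_{t+1} = (1 - alpha) x_{t-1} + (alpha - beta) x_t
              + beta Psi(x_t + A^T (b - A x_t)),

where Psi is the proximal operator of the TV term, here computed by
Chambolle's dual projection.  The operator is rescaled so the spectrum of
A^T A lies in (0, 1], as the two-step parameters assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radon import ForwardModel, inscribed_circle_mask

__all__ = ["TwISTConfig", "tv_norm", "tv_denoise", "twist_reconstruct"]


@dataclass(frozen=True)
class TwISTConfig:
    lambda_tv: float = 0.01
    max_iter: int = 200
    rel_tol: float = 1e-5
    # spectral bounds of the (rescaled) normal operator; alpha/beta follow
    # the TwIST stability recipe from these
    xi_min: float = 1e-3
    xi_max: float = 1.0
    prox_iter: int = 20

    def __post_init__(self):
        if self.lambda_tv <= 0:
            raise ValueError("lambda_tv must be > 0")
        if self.max_iter < 1 or self.rel_tol <= 0:
            raise ValueError("invalid stopping rule")
        if not (0 < self.xi_min <= self.xi_max):
            raise ValueError("invalid spectral bounds")

    @property
    def alpha(self) -> float:
        # two-step over-relaxation from the spectral bounds:
        # rho = (1 - sqrt(kappa)) / (1 + sqrt(kappa)), kappa = xi_min/xi_max
        sk = np.sqrt(self.xi_min / self.xi_max)
        rho = (1.0 - sk) / (1.0 + sk)
        return 2.0 / (1.0 + np.sqrt(1.0 - rho**2))

    @property
    def beta(self) -> float:
        return self.alpha * 2.0 / (self.xi_min + self.xi_max)


def _forward_diff(x: np.ndarray):
    """Forward differences with zero-gradient (replicate) boundary."""
    dh = np.zeros_like(x)
    dv = np.zeros_like(x)
    dh[:, :-1] = x[:, 1:] - x[:, :-1]
    dv[:-1, :] = x[1:, :] - x[:-1, :]
    return dh, dv


def tv_norm(x: np.ndarray) -> float:
    """Isotropic total variation: sum of sqrt(dh^2 + dv^2) over pixels."""
    dh, dv = _forward_diff(np.asarray(x, dtype=np.float64))
    return float(np.sqrt(dh**2 + dv**2).sum())


def _divergence(ph: np.ndarray, pv: np.ndarray) -> np.ndarray:
    """Backward divergence, the negative adjoint of :func:`_forward_diff`."""
    div = np.zeros_like(ph)
    div[:, :-1] += ph[:, :-1]
    div[:, 1:] -= ph[:, :-1]
    div[:-1, :] += pv[:-1, :]
    div[1:, :] -= pv[:-1, :]
    return div


def tv_denoise(y: np.ndarray, weight: float, n_iter: int = 20) -> np.ndarray:
    """Proximal operator of ``weight * TV`` at ``y``:
    argmin_x 0.5 ||x - y||^2 + weight * TV(x), by projected gradient ascent
    on Chambolle's dual (step 0.125, the stability bound for the discrete
    Laplacian)."""
    y = np.asarray(y, dtype=np.float64)
    if weight <= 0:
        return y.copy()
    ph = np.zeros_like(y)
    pv = np.zeros_like(y)
    tau = 0.125
    for _ in range(n_iter):
        gh, gv = _forward_diff(y + weight * _divergence(ph, pv))
        ph_new = ph + (tau / weight) * gh
        pv_new = pv + (tau / weight) * gv
        norm = np.maximum(1.0, np.sqrt(ph_new**2 + pv_new**2))
        ph, pv = ph_new / norm, pv_new / norm
    return y + weight * _divergence(ph, pv)


def _operator_norm(A: ForwardModel, n_iter: int = 30, seed: int = 0) -> float:
    """Largest eigenvalue of A^T A by power iteration."""
    n = A.geometry.image_size_px
    rng = np.random.default_rng(seed)
    v = rng.normal(size=n * n)
    v /= np.linalg.norm(v)
    mat, mat_T = A._mat, A._mat_T
    lam = 1.0
    for _ in range(n_iter):
        w = mat_T @ (mat @ v)
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 1.0
        v = w / lam
    return lam


def twist_reconstruct(b: np.ndarray, A: ForwardModel,
                      cfg: TwISTConfig = TwISTConfig(),
                      return_objective: bool = False):
    """TwIST reconstruction of a slice from (possibly retained-angle) data.

    Accepts the retained-angle sinogram matching ``A`` or the full-size
    zero-padded one when ``A`` carries a sampling scheme.  Stops when the
    relative objective change falls below ``rel_tol`` or at ``max_iter``;
    raises if the objective increases persistently (divergence).
    """
    b = np.asarray(b, dtype=np.float64)
    if A.scheme is not None and b.shape[0] == A.scheme.n_angles_full:
        b = b[sorted(A.scheme.retained_indices)]
    n = A.geometry.image_size_px
    mask = inscribed_circle_mask(n)

    # rescale so the spectrum of the normal operator is <= 1
    s2 = _operator_norm(A)
    scale = 1.0 / np.sqrt(s2)
    bs = b * scale

    def Af(x):
        return A.project(x) * scale

    def At(r):
        return A.backproject(r) * scale

    lam = cfg.lambda_tv
    prox_w = lam / 2.0  # prox of lam*TV w.r.t. ||Ax-b||^2 (factor-2 gradient)

    def objective(x):
        r = Af(x) - bs
        return float((r**2).sum()) + lam * tv_norm(x)

    def psi(u):
        v = tv_denoise(u, prox_w, cfg.prox_iter)
        return np.where(mask, v, 0.0)

    x_prev = np.zeros((n, n))
    x = psi(At(bs))  # IST first step
    obj = objective(x)
    objectives = [obj]
    alpha, beta = cfg.alpha, cfg.beta
    n_bad = 0
    for _ in range(cfg.max_iter):
        grad_step = x + At(bs - Af(x))
        prox = psi(grad_step)
        x_new = (1.0 - alpha) * x_prev + (alpha - beta) * x + beta * prox
        new_obj = objective(x_new)
        if new_obj > obj:
            # monotone variant: fall back to the plain IST step, which is
            # non-increasing for the rescaled operator (spectrum <= 1)
            x_new = prox
            new_obj = objective(x_new)
        x_prev, x = x, x_new
        objectives.append(new_obj)
        if new_obj > obj * (1 + 1e-8):
            n_bad += 1
            if n_bad >= 10:
                raise RuntimeError(
                    f"TwIST diverging: objective rose for {n_bad} consecutive "
                    f"iterations (last {new_obj:.4g} > {obj:.4g})")
        else:
            n_bad = 0
        if abs(new_obj - obj) <= cfg.rel_tol * max(obj, 1e-30):
            obj = new_obj
            break
        obj = new_obj
    if return_objective:
        return x, objectives
    return x
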