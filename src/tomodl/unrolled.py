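"""The unrolled model-based reconstructor (ToMoDL).

Reconstruction alternates, for K unrolled iterations, a data-consistency
update

    x_k = (A^T A + lambda I)^{-1} (A^T b + lambda z_{k-1}),

solved by conjugate gradients, with a learned residual denoiser

    z_k = D_theta(x_k) = x_k - N_theta(x_k),

where N_theta is a stack of N_L 3x3 convolutional layers (ReLU + batch norm
on all but the first and last) estimating the streak/noise component, and the
same weights are shared by every iteration.  Because the Radon operator is
not norm-preserving, each data-consistency output is rescaled to [0, 1] over
the inscribed circle (internal normalisation) to keep iterate magnitudes —
and hence gradients — stable.  lambda is trained in log-space so it stays
positive.  The whole map is differentiable with respect to theta and lambda.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import grad
from .grad import Tensor
from .radon import ForwardModel, inscribed_circle_mask

__all__ = [
    "UnrolledConfig",
    "DenoiserParams",
    "normal_operator",
    "cg_solve",
    "data_consistency",
    "denoiser_forward",
    "tomodl_reconstruct",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UnrolledConfig:
    K: int = 8
    N_L: int = 8
    n_filters: int = 64
    kernel: int = 3
    lambda_init: float = 0.05
    lambda_learnable: bool = True
    cg_tol: float = 1e-6
    cg_max_iter: int = 30
    use_batchnorm: bool = True

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.N_L < 2:
            raise ValueError("N_L must be >= 2 (first and last layers are distinct)")
        if self.n_filters < 1 or self.kernel != 3:
            raise ValueError("n_filters must be >= 1 and kernel 3x3")
        if self.lambda_init <= 0:
            raise ValueError("lambda_init must be positive")
        if self.cg_tol <= 0 or self.cg_max_iter < 1:
            raise ValueError("invalid CG settings")


class DenoiserParams:
    """Trainable state of the shared denoiser: conv kernels and biases,
    batch-norm affine terms and running statistics, and log-lambda.

    The identical object is used by every unrolled iteration, which is what
    makes the weights "shared".
    """

    def __init__(self, cfg: UnrolledConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        f, k = cfg.n_filters, cfg.kernel
        channels = [1] + [f] * (cfg.N_L - 1) + [1]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        self.bn_gamma: list[Tensor] = []
        self.bn_beta: list[Tensor] = []
        self.bn_running: list[dict] = []
        for layer in range(cfg.N_L):
            cin, cout = channels[layer], channels[layer + 1]
            # He-normal fan-in initialisation
            std = np.sqrt(2.0 / (cin * k * k))
            w = rng.normal(0.0, std, size=(k, k, cin, cout)).astype(dtype)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(cout, dtype=dtype), requires_grad=True))
            if cfg.use_batchnorm and 0 < layer < cfg.N_L - 1:
                self.bn_gamma.append(Tensor(np.ones(cout, dtype=dtype), requires_grad=True))
                self.bn_beta.append(Tensor(np.zeros(cout, dtype=dtype), requires_grad=True))
                self.bn_running.append({"mean": np.zeros(cout), "var": np.ones(cout)})
            else:
                self.bn_gamma.append(None)
                self.bn_beta.append(None)
                self.bn_running.append(None)
        self.log_lambda = Tensor(np.asarray(np.log(cfg.lambda_init), dtype=np.float64),
                                 requires_grad=cfg.lambda_learnable)
        self.training = False

    # -- bookkeeping --------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = []
        for layer in range(self.cfg.N_L):
            ps += [self.weights[layer], self.biases[layer]]
            if self.bn_gamma[layer] is not None:
                ps += [self.bn_gamma[layer], self.bn_beta[layer]]
        if self.cfg.lambda_learnable:
            ps.append(self.log_lambda)
        return ps

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lambda.data))

    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def state_arrays(self) -> dict:
        st = {"log_lambda": np.asarray(self.log_lambda.data)}
        for i in range(self.cfg.N_L):
            st[f"w{i}"] = self.weights[i].data
            st[f"b{i}"] = self.biases[i].data
            if self.bn_gamma[i] is not None:
                st[f"g{i}"] = self.bn_gamma[i].data
                st[f"beta{i}"] = self.bn_beta[i].data
                st[f"rm{i}"] = self.bn_running[i]["mean"]
                st[f"rv{i}"] = self.bn_running[i]["var"]
        return st

    def load_state_arrays(self, st: dict):
        self.log_lambda.data = np.asarray(st["log_lambda"], dtype=np.float64)
        for i in range(self.cfg.N_L):
            self.weights[i].data = np.asarray(st[f"w{i}"])
            self.biases[i].data = np.asarray(st[f"b{i}"])
            if self.bn_gamma[i] is not None:
                self.bn_gamma[i].data = np.asarray(st[f"g{i}"])
                self.bn_beta[i].data = np.asarray(st[f"beta{i}"])
                self.bn_running[i] = {"mean": np.asarray(st[f"rm{i}"]),
                                      "var": np.asarray(st[f"rv{i}"])}


def count_parameters(theta: DenoiserParams) -> int:
    """Exact number of trainable scalars (conv kernels, biases, batch-norm
    affine terms, and lambda when learnable)."""
    return int(sum(p.data.size for p in theta.parameters()))


# -- linear-algebra building blocks -------------------------------------------

def normal_operator(x: np.ndarray, A: ForwardModel, lam: float) -> np.ndarray:
    """``A^T A x + lam x`` — symmetric, positive definite for lam > 0."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return A.backproject(A.project(np.asarray(x, dtype=np.float64))) + lam * np.asarray(x)


def cg_solve(rhs: np.ndarray, A: ForwardModel, lam: float,
             tol: float = 1e-6, max_iter: int = 30) -> np.ndarray:
    """Solve ``(A^T A + lam I) x = rhs`` by conjugate gradients."""
    if lam <= 0:
        raise ValueError("lambda must be > 0 for a definite system")
    rhs = np.asarray(rhs, dtype=np.float64)
    n = A.geometry.image_size_px
    if rhs.shape != (n, n):
        raise ValueError(f"rhs shape {rhs.shape} != ({n}, {n})")
    mat, mat_T = A._mat, A._mat_T

    def matvec(v):
        return mat_T @ (mat @ v) + lam * v

    x = grad._cg(matvec, rhs.ravel(), tol, max_iter)
    return x.reshape(n, n)


def _normalize_image(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    v = x[mask]
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return x * mask
    return np.where(mask, (x - lo) / (hi - lo), 0.0)


def data_consistency(z_prev: np.ndarray, Atb: np.ndarray, A: ForwardModel,
                     lam: float, cfg: UnrolledConfig) -> np.ndarray:
    """One data-consistency update followed by the internal normalisation."""
    x = cg_solve(Atb + lam * np.asarray(z_prev), A, lam,
                 tol=cfg.cg_tol, max_iter=cfg.cg_max_iter)
    return _normalize_image(x, inscribed_circle_mask(A.geometry.image_size_px))


# -- network forward ----------------------------------------------------------

def _noise_learner(x: Tensor, theta: DenoiserParams) -> Tensor:
    """The stacked-convolution noise estimator N_theta."""
    cfg = theta.cfg
    h = grad.conv2d(x, theta.weights[0], theta.biases[0])
    h = grad.relu(h)
    for layer in range(1, cfg.N_L - 1):
        h = grad.conv2d(h, theta.weights[layer], theta.biases[layer])
        if theta.bn_gamma[layer] is not None:
            h = grad.batch_norm(h, theta.bn_gamma[layer], theta.bn_beta[layer],
                                theta.bn_running[layer], theta.training)
        h = grad.relu(h)
    # final layer: no ReLU, so negative noise patterns survive
    return grad.conv2d(h, theta.weights[-1], theta.biases[-1])


def denoiser_forward(x, theta: DenoiserParams):
    """Residual denoiser ``D_theta(x) = x - N_theta(x)``.

    Accepts a 2-D array (returns a 2-D array) or a (B, H, W, 1) Tensor
    (returns a Tensor on the tape).  Fully convolutional: any spatial size.
    """
    if isinstance(x, Tensor):
        return x - _noise_learner(x, theta)
    arr = np.asarray(x)
    t = Tensor(arr[None, :, :, None].astype(theta.weights[0].data.dtype))
    out = t - _noise_learner(t, theta)
    return out.data[0, :, :, 0]


def _unroll(z0: Tensor, atb: np.ndarray, A: ForwardModel, theta: DenoiserParams,
            cfg: UnrolledConfig, mask: np.ndarray) -> Tensor:
    """K iterations of [data consistency -> denoiser] on the tape; returns
    the final data-consistency output x_K (the last denoise does not feed
    the output and is skipped)."""
    mat, mat_T = A._mat, A._mat_T

    def matvec_AtA(v):
        return mat_T @ (mat @ v)

    lam = theta.log_lambda.exp()
    z = z0
    for k in range(cfg.K):
        x = grad.cg_solve_op(z, atb, lam, matvec_AtA,
                             tol=cfg.cg_tol, max_iter=cfg.cg_max_iter)
        x = grad.minmax_normalize(x, mask)
        if np.isnan(x.data).any():
            raise FloatingPointError(f"NaN in unrolled iterate at k={k + 1}")
        if k < cfg.K - 1:
            z = denoiser_forward(x, theta)
    return x if cfg.K > 0 else z0


def tomodl_reconstruct(b: np.ndarray, A: ForwardModel, theta: DenoiserParams,
                       cfg: UnrolledConfig | None = None) -> np.ndarray:
    """Reconstruct a slice from a (possibly undersampled) sinogram.

    ``b`` may be the retained-angle sinogram matching ``A`` or, when ``A``
    carries a sampling scheme, the full-size zero-padded sinogram.  The
    initialisation z_0 is the normalised unfiltered backprojection A^T b.
    """
    cfg = cfg or theta.cfg
    out = tomodl_reconstruct_batch(b[None], A, theta, cfg)
    return out.data[0, :, :, 0]


def tomodl_reconstruct_batch(bs: np.ndarray, A: ForwardModel, theta: DenoiserParams,
                             cfg: UnrolledConfig) -> Tensor:
    """Batched differentiable reconstruction; ``bs`` has shape
    (B, n_angles, n_det) (full zero-padded rows accepted, as for
    :func:`tomodl_reconstruct`)."""
    n = A.geometry.image_size_px
    mask = inscribed_circle_mask(n)
    dtype = theta.weights[0].data.dtype
    batch = bs.shape[0]
    z0 = np.empty((batch, n, n, 1), dtype=dtype)
    atb = np.empty((batch, n, n, 1), dtype=np.float64)
    for i in range(batch):
        bi = np.asarray(bs[i], dtype=np.float64)
        if A.scheme is not None and bi.shape[0] == A.scheme.n_angles_full:
            bi = bi[sorted(A.scheme.retained_indices)]
        a = A.backproject(bi)
        atb[i, :, :, 0] = a
        z0[i, :, :, 0] = _normalize_image(a, mask)
    return _unroll(Tensor(z0), atb, A, theta, cfg, mask)


# -- checkpoints --------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, theta: DenoiserParams, extra: dict | None = None):
    """Single-archive checkpoint: config JSON + weight arrays (npz inside zip)."""
    meta = {"version": CHECKPOINT_VERSION, "cfg": asdict(theta.cfg),
            "seed": theta.seed, "extra": extra or {}}
    buf = io.BytesIO()
    np.savez(buf, **theta.state_arrays())
    with zipfile.ZipFile(path, "w") as z:
        z.writestr("meta.json", json.dumps(meta, indent=2))
        z.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> DenoiserParams:
    with zipfile.ZipFile(path) as z:
        meta = json.loads(z.read("meta.json"))
        with z.open("weights.npz") as f:
            arrays = dict(np.load(io.BytesIO(f.read())))
    cfg = UnrolledConfig(**meta["cfg"])
    theta = DenoiserParams(cfg, seed=meta.get("seed", 0))
    theta.load_state_arrays(arrays)
    return theta
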