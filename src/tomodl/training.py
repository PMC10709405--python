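"""Training of the unrolled reconstructor on input/reference image pairs.

Each training pair couples the normalised unfiltered backprojection of an
undersampled (zero-pad-masked, random initial angle) sinogram with the
filtered-backprojection reconstruction of the same slice's fully sampled
sinogram, which serves as the reference image.  The loss is the mean squared
error between the unrolled output x_K and the reference.  Cross-validation
splits volumes (never slices) between train and test folds.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import grad
from .evaluation import psnr, ssim
from .phantoms import AcquisitionSpec, simulate_acquisition
from .radon import (ForwardModel, apply_zero_pad_mask, build_sampling, fbp,
                    inscribed_circle_mask)
from .unrolled import (DenoiserParams, UnrolledConfig, _normalize_image,
                       tomodl_reconstruct_batch)

__all__ = ["TrainingPair", "CVPlan", "OptSettings", "make_pairs", "mse_loss",
           "train", "make_cv_plan", "subsample_training"]


@dataclass
class TrainingPair:
    input_recon: np.ndarray      # normalised A^T b of the masked sinogram
    target: np.ndarray           # FBP of the fully sampled sinogram b*
    masked_sinogram: np.ndarray  # zero-padded undersampled measurements
    R: int
    slice_id: int
    volume_id: int = 0
    seed: int = 0
    initial_index: int = 0


@dataclass(frozen=True)
class CVPlan:
    n_folds: int
    folds: tuple  # tuple of (train_volumes, test_volumes) tuples
    val_fraction: float = 0.2

    def __post_init__(self):
        tests = [v for _, te in self.folds for v in te]
        if len(tests) != len(set(tests)):
            raise ValueError("test volumes must be disjoint across folds")


@dataclass(frozen=True)
class OptSettings:
    lr: float = 1e-4
    epochs: int = 50
    batch_size: int = 5
    betas: tuple = (0.9, 0.999)


def make_pairs(volume: np.ndarray, R: int, seed: int,
               acq: AcquisitionSpec | None = None, volume_id: int = 0,
               normalize_target: bool = True) -> list[TrainingPair]:
    """Build (undersampled input, fully-sampled FBP target) pairs per slice.

    The initial retained angle is drawn uniformly per slice from the seeded
    generator; the fully sampled reference is never undersampled.  When
    ``normalize_target`` the reference is min-max rescaled over the inscribed
    circle, the same internal normalisation the network applies.
    """
    volume = np.asarray(volume)
    if volume.ndim == 2:
        volume = volume[None]
    if volume.shape[0] == 0:
        raise ValueError("empty volume")
    acq = acq or AcquisitionSpec()
    if R > acq.n_angles_full:
        raise ValueError("R exceeds the number of acquired angles")
    n = volume.shape[1]
    geom = acq.geometry(n)
    rng = np.random.default_rng(seed)
    mask = inscribed_circle_mask(n)
    A_full = ForwardModel(geom)
    pairs = []
    for s in range(volume.shape[0]):
        b_star = simulate_acquisition(volume[s], acq)
        init = int(rng.integers(0, acq.n_angles_full))
        scheme = build_sampling(acq.n_angles_full, R, init)
        b_masked = apply_zero_pad_mask(b_star, scheme)
        atb = A_full.backproject(b_masked)
        target = fbp(b_star, geom)
        if normalize_target:
            target = _normalize_image(target, mask)
        pairs.append(TrainingPair(
            input_recon=_normalize_image(atb, mask),
            target=target,
            masked_sinogram=b_masked,
            R=R, slice_id=s, volume_id=volume_id, seed=seed,
            initial_index=init,
        ))
    return pairs


def mse_loss(outputs, targets, reduction: str = "sum") -> float:
    """Sum over examples of squared Euclidean norms of the differences
    (``reduction='mean'`` gives the per-element batch mean instead)."""
    outputs, targets = list(outputs), list(targets)
    if len(outputs) != len(targets):
        raise ValueError("outputs/targets length mismatch")
    total, count = 0.0, 0
    for o, t in zip(outputs, targets):
        o, t = np.asarray(o), np.asarray(t)
        if o.shape != t.shape:
            raise ValueError("shape mismatch in loss")
        total += float(((o - t) ** 2).sum())
        count += o.size
    return total / count if reduction == "mean" else total


def _schemes_for(pairs: list[TrainingPair], acq_angles: int):
    out = []
    for p in pairs:
        out.append(build_sampling(acq_angles, p.R, p.initial_index))
    return out


def train(pairs: list[TrainingPair], cfg: UnrolledConfig,
          opt: OptSettings = OptSettings(), seed: int = 0,
          val_fraction: float = 0.2, geom=None, verbose: bool = False):
    """Minimise the MSE of the unrolled output over theta (and lambda).

    Splits ``pairs`` into train/validation (seeded shuffle), runs Adam for
    ``opt.epochs`` epochs, records per-epoch train loss and validation
    loss/PSNR/SSIM, and returns ``(best_theta, history)`` where ``best_theta``
    carries the lowest-validation-loss weights.  Deterministic under ``seed``.
    """
    if not pairs:
        raise ValueError("no training pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_val = max(1, int(round(val_fraction * len(pairs))))
    if len(pairs) - n_val < 1:
        raise ValueError("not enough pairs for a train/validation split")
    val_idx, tr_idx = order[:n_val], order[n_val:]
    n = pairs[0].input_recon.shape[0]
    if geom is None:
        from .radon import Geometry
        geom = Geometry.uniform(n, pairs[0].masked_sinogram.shape[0])
    mask = inscribed_circle_mask(n)

    # bounded cache of subset models: one per distinct (R, initial angle);
    # random initial angles make most schemes unique, so an unbounded cache
    # would hold hundreds of sparse matrices
    models: dict = {}

    def model_for(p: TrainingPair) -> ForwardModel:
        key = (p.R, p.initial_index)
        if key not in models:
            if len(models) >= 16:
                models.pop(next(iter(models)))
            scheme = build_sampling(geom.n_angles, p.R, p.initial_index)
            models[key] = ForwardModel(geom, scheme)
        return models[key]

    theta = DenoiserParams(cfg, seed=seed)
    optimizer = grad.Adam(theta.parameters(), lr=opt.lr, betas=opt.betas)
    history = []
    best_state, best_val = None, np.inf

    def evaluate_val():
        theta.eval()
        losses, psnrs, ssims = [], [], []
        for i in val_idx:
            p = pairs[i]
            out = tomodl_reconstruct_batch(p.masked_sinogram[None], model_for(p),
                                           theta, cfg).data[0, :, :, 0]
            losses.append(float(((out - p.target) ** 2).sum()))
            psnrs.append(psnr(out, p.target))
            ssims.append(ssim(out, p.target))
        return float(np.mean(losses)), float(np.mean(psnrs)), float(np.mean(ssims))

    for epoch in range(opt.epochs):
        theta.train()
        perm = rng.permutation(tr_idx)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), opt.batch_size):
            batch = [pairs[i] for i in perm[start:start + opt.batch_size]]
            # group by scheme so each sub-batch shares one forward model
            groups: dict = {}
            for p in batch:
                groups.setdefault((p.R, p.initial_index), []).append(p)
            optimizer.zero_grad()
            batch_loss = 0.0
            for key, ps in groups.items():
                A = model_for(ps[0])
                bs = np.stack([p.masked_sinogram for p in ps])
                tg = np.stack([p.target for p in ps])[..., None]
                out = tomodl_reconstruct_batch(bs, A, theta, cfg)
                loss = grad.mse(out, tg.astype(out.data.dtype), reduction="mean")
                loss.backward(np.asarray(len(ps) / len(batch)))
                batch_loss += loss.item() * len(ps) / len(batch)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the inputs")
            optimizer.step()
            epoch_loss += batch_loss
            n_batches += 1
        val_loss, val_psnr, val_ssim = evaluate_val()
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_loss": val_loss, "val_psnr_db": val_psnr,
                        "val_ssim": val_ssim, "lambda": theta.lam})
        if verbose:
            print(f"epoch {epoch:3d}  train {epoch_loss / n_batches:.5f}  "
                  f"val {val_loss:.3f}  psnr {val_psnr:.2f}  ssim {val_ssim:.3f}")
        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(theta.state_arrays())
    if best_state is not None:
        theta.load_state_arrays(best_state)
    theta.eval()
    return theta, pd.DataFrame(history)


def make_cv_plan(volume_ids, n_folds: int = 4, seed: int = 0,
                 val_fraction: float = 0.2) -> CVPlan:
    """Seeded fold assignment: each volume appears in exactly one test set."""
    volume_ids = list(volume_ids)
    if len(volume_ids) < n_folds:
        raise ValueError("need at least one volume per fold")
    rng = np.random.default_rng(seed)
    perm = [volume_ids[i] for i in rng.permutation(len(volume_ids))]
    chunks = [perm[i::n_folds] for i in range(n_folds)]
    folds = tuple(
        (tuple(v for c in chunks[:i] + chunks[i + 1:] for v in c), tuple(chunks[i]))
        for i in range(n_folds)
    )
    return CVPlan(n_folds=n_folds, folds=folds, val_fraction=val_fraction)


def subsample_training(pairs: list, fraction: float, seed: int = 0) -> list:
    """Seeded uniform subsample of size ``round(fraction * len(pairs))``.

    Nested by construction: the seeded permutation is fixed, so smaller
    fractions select prefixes of the same ordering.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(pairs)
    k = int(round(fraction * len(pairs)))
    if k == 0:
        raise ValueError("fraction too small: empty subsample")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order[:k]]
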