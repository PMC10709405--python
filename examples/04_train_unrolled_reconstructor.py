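"""Train a small unrolled model-based reconstructor and compare it to FBP.

This is a reduced version of the full experiment (fewer training slices and
epochs) so it finishes in about a minute; `tomodl.experiments.
scaled_training_experiment` runs the full benchmark configuration.
"""

import numpy as np

from tomodl import (AcquisitionSpec, OptSettings, PhantomSpec, UnrolledConfig,
                    count_parameters, make_pairs, make_phantom, train)
from tomodl.experiments import _fbp_subset
from tomodl.evaluation import psnr
from tomodl.radon import ForwardModel, apply_zero_pad_mask, build_sampling, \
    fbp, inscribed_circle_mask
from tomodl.phantoms import simulate_acquisition
from tomodl.unrolled import _normalize_image, tomodl_reconstruct

rng = np.random.default_rng(0)
acq = AcquisitionSpec(n_angles_full=720, angle_step_deg=0.5)
volume = np.stack([
    make_phantom(PhantomSpec(size_px=64, kind="random_ellipses",
                             seed=int(rng.integers(2**31))))
    for _ in range(30)
])
pairs = make_pairs(volume, R=20, seed=0, acq=acq)
print(f"{len(pairs)} training pairs at R=20 "
      f"({int((pairs[0].masked_sinogram.sum(axis=1) > 0).sum())} projections each)")

cfg = UnrolledConfig(K=4, N_L=4, n_filters=32, cg_tol=1e-5, cg_max_iter=10)
theta, history = train(pairs, cfg, OptSettings(lr=1e-3, epochs=4, batch_size=5),
                       seed=0, verbose=True)
print(f"denoiser parameters: {count_parameters(theta)}, "
      f"trained lambda: {theta.lam:.4f}")

# held-out comparison
geom = acq.geometry(64)
mask = inscribed_circle_mask(64)
ph = make_phantom(PhantomSpec(size_px=64, kind="random_ellipses", seed=999))
b_star = simulate_acquisition(ph, acq)
ref = _normalize_image(fbp(b_star, geom), mask)
scheme = build_sampling(720, 20, 0)
model = ForwardModel(geom, scheme)
rec_net = tomodl_reconstruct(apply_zero_pad_mask(b_star, scheme), model, theta, cfg)
rec_fbp = _normalize_image(_fbp_subset(b_star, geom, scheme), mask)
print(f"held-out slice, R=20: unrolled {psnr(rec_net, ref):.2f} dB "
      f"vs FBP {psnr(rec_fbp, ref):.2f} dB (reference: fully sampled FBP)")
# Even this short training leaves the unrolled reconstruction several dB
# above streaky 36-projection FBP, because the conjugate-gradient data
# consistency step already constrains the image to the measurements.
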