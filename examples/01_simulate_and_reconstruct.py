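"""Simulate an OPT acquisition of a phantom slice and reconstruct it.

Builds a 100x100 Shepp-Logan slice, projects it over a full turn at
0.5-degree steps (720 projections), then compares filtered and unfiltered
backprojection from the fully sampled sinogram.
"""

import numpy as np

from tomodl import (AcquisitionSpec, Geometry, PhantomSpec, fbp,
                    inscribed_circle_mask, make_phantom, psnr, radon_adjoint,
                    simulate_acquisition, ssim)
from tomodl.unrolled import _normalize_image

phantom = make_phantom(PhantomSpec(size_px=100, kind="shepp_logan"))
acq = AcquisitionSpec(n_angles_full=720, angle_step_deg=0.5)
sinogram = simulate_acquisition(phantom, acq)
print(f"sinogram: {sinogram.shape[0]} angles x {sinogram.shape[1]} detector bins")

geom = acq.geometry(100)
mask = inscribed_circle_mask(100)
rec_fbp = fbp(sinogram, geom)
rec_bp = _normalize_image(radon_adjoint(sinogram, geom), mask)

for name, rec in (("filtered backprojection", rec_fbp),
                  ("unfiltered backprojection", rec_bp)):
    print(f"{name:>26}: PSNR {psnr(rec, phantom):6.2f} dB, "
          f"SSIM {ssim(rec, phantom):.3f}")

# The ramp filter restores the high frequencies the adjoint blurs away:
# FBP should sit near 28 dB against the phantom, the unfiltered
# backprojection far below it despite using the same measurements.
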