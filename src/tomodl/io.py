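"""Sinogram and slice I/O: float32 TIFF and HDF5.

Sinograms are stored either as a TIFF stack (one page per angle) or as an
HDF5 dataset ``/sinogram`` with attributes ``angles_deg`` and, when known,
``cor_shift_px`` and ``seed``.  Images are single-page float32 TIFF.
"""

from __future__ import annotations

import h5py
import numpy as np
import tifffile

__all__ = ["write_image", "read_image", "write_sinogram", "read_sinogram"]


def write_image(path, x: np.ndarray):
    tifffile.imwrite(str(path), np.asarray(x, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def write_sinogram(path, b: np.ndarray, angles_deg, cor_shift_px: float = 0.0,
                   seed: int | None = None):
    """Write a sinogram; format chosen by extension (.h5/.hdf5 vs .tif)."""
    path = str(path)
    b = np.asarray(b, dtype=np.float32)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("sinogram", data=b)
            d.attrs["angles_deg"] = np.asarray(angles_deg, dtype=np.float64)
            d.attrs["cor_shift_px"] = float(cor_shift_px)
            if seed is not None:
                d.attrs["seed"] = int(seed)
    else:
        # one page per angle
        tifffile.imwrite(path, b[:, None, :], metadata={
            "angles_deg": list(map(float, angles_deg)),
            "cor_shift_px": float(cor_shift_px),
            "seed": seed,
        })


def read_sinogram(path):
    """Returns ``(sinogram, angles_deg)``; angles may be None for a bare TIFF."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            d = f["sinogram"]
            return d[()].astype(np.float64), np.asarray(d.attrs["angles_deg"])
    with tifffile.TiffFile(path) as t:
        b = t.asarray().astype(np.float64)
        meta = t.shaped_metadata[0] if t.shaped_metadata else {}
    if b.ndim == 3:
        b = b[:, 0, :]
    angles = meta.get("angles_deg")
    return b, (np.asarray(angles, dtype=np.float64) if angles is not None else None)
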