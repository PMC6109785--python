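"""Per-subject preprocessing: temporal high-pass, spatial smoothing,
variance normalization.

The high-pass is implemented as removal of a discrete-cosine drift basis
(all DCT-II components with frequency below the cutoff, including the
constant), which makes it deterministic and phase-free.  Smoothing is a
per-timepoint 3D Gaussian convolution with reflective boundaries so the
spatial sum is preserved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.fft import dct, idct

from .containers import Volume4D

__all__ = ["highpass_filter", "spatial_smooth", "variance_normalize"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def highpass_filter(vol: Volume4D, cutoff_seconds: float) -> Volume4D:
    """Remove fluctuations slower than ``cutoff_seconds`` from each voxel.

    DCT-II components with frequency ``k / (2 T tr) < 1 / cutoff`` are
    projected out, along with the mean (k = 0), so each output series has
    zero mean and intact passband content.
    """
    if cutoff_seconds <= 2.0 * vol.tr:
        raise ValueError(
            f"cutoff {cutoff_seconds}s must exceed twice the TR ({vol.tr}s)"
        )
    T = vol.n_timepoints
    k = np.arange(T)
    drop = k / (2.0 * T * vol.tr) < 1.0 / cutoff_seconds  # includes k = 0
    coef = dct(vol.data, type=2, norm="ortho", axis=-1)
    coef[..., drop] = 0.0
    out = idct(coef, type=2, norm="ortho", axis=-1)
    out[~vol.mask] = 0.0
    return vol.with_data(out)


def spatial_smooth(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Per-timepoint 3D Gaussian smoothing with the given FWHM in mm.

    ``fwhm_mm = 0`` is the identity.  The kernel sigma is converted to
    voxels through the affine; sheared affines are rejected.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    A = vol.affine[:3, :3]
    gram = A.T @ A
    off = gram - np.diag(np.diag(gram))
    if np.abs(off).max() > 1e-6 * np.abs(np.diag(gram)).max():
        raise ValueError("affine has shear; unsupported geometry for smoothing")
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / vol.voxel_sizes()
    out = ndimage.gaussian_filter(
        vol.data, sigma=(*sigma_vox, 0.0), mode="reflect"
    )
    return vol.with_data(out)


def variance_normalize(vol: Volume4D) -> Volume4D:
    """Scale each in-mask voxel series to unit sample variance.

    All-zero (or constant) series are left untouched; the mean is not
    removed (the high-pass already handles that).
    """
    sd = vol.data.std(axis=-1, ddof=1)
    scale = np.ones_like(sd)
    ok = vol.mask & (sd > 0)
    scale[ok] = 1.0 / sd[ok]
    out = vol.data * scale[..., None]
    out[~vol.mask] = 0.0
    return vol.with_data(out)
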