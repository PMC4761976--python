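"""Per-subject preprocessing: masking, smoothing, detrend, bandpass.

The temporal chain mirrors the standard resting-state recipe: voxelwise
polynomial detrend followed by a zero-phase "ideal" (DFT-mask) bandpass at
0.002-0.1 Hz; spatial smoothing is a 3D Gaussian specified by its FWHM in
mm and converted per axis to a sigma in voxels. Both temporal stages are
orthogonal projections, so they are linear and idempotent — properties the
test suite relies on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BrainMask, Image4D

__all__ = [
    "PreprocConfig",
    "compute_brain_mask",
    "detrend",
    "bandpass",
    "fwhm_to_sigma_voxels",
    "gaussian_smooth",
    "preprocess_subject",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing parameters.

    band : (low, high) pass band in Hz, bounds inclusive. Default 0.002-0.1.
    fwhm_mm : Gaussian smoothing kernel FWHM in mm (0 disables smoothing).
    detrend_order : polynomial order removed voxelwise (1 = linear + mean).
    mask_fraction : brain-mask threshold as a fraction of the robust maximum.
    order : stage order applied inside the mask.
    """

    band: tuple[float, float] = (0.002, 0.1)
    fwhm_mm: float = 1.0
    detrend_order: int = 1
    mask_fraction: float = 0.2
    order: tuple[str, ...] = ("smooth", "detrend", "bandpass")

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 <= low < high):
            raise ValueError(f"need 0 <= low < high, got band={self.band}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.detrend_order < 0:
            raise ValueError("detrend_order must be >= 0")
        unknown = set(self.order) - {"smooth", "detrend", "bandpass"}
        if unknown:
            raise ValueError(f"unknown preprocessing stages: {sorted(unknown)}")

    def validate_band(self, tr: float) -> None:
        if self.band[1] > 0.5 / tr + 1e-12:
            raise ValueError(
                f"band high {self.band[1]} Hz exceeds Nyquist {0.5 / tr} Hz at tr={tr}"
            )


def compute_brain_mask(img: Image4D, mask_fraction: float = 0.2) -> BrainMask:
    """Threshold the temporal-mean image to delimit the brain.

    A voxel is in-brain iff its temporal mean exceeds ``mask_fraction``
    times the robust maximum (98th percentile) of the temporal-mean image.
    """
    tmean = img.data.mean(axis=3, dtype=np.float64)
    robust_max = np.percentile(tmean, 98)
    mask = tmean > mask_fraction * robust_max
    if not mask.any():
        raise ValueError(
            "brain mask is empty; lower mask_fraction or check image intensities"
        )
    return BrainMask(mask)


def detrend(ts: np.ndarray, order: int = 1) -> np.ndarray:
    """Remove a least-squares polynomial of the given order (with intercept).

    Accepts a 1D series or an (n_series, T) array; operates along the last
    axis. The residual has zero mean to numerical tolerance.
    """
    ts = np.asarray(ts, dtype=np.float64)
    n = ts.shape[-1]
    if n < order + 2:
        raise ValueError(f"series length {n} too short for detrend order {order}")
    t = np.linspace(-1.0, 1.0, n)  # scaled abscissa for conditioning
    design = np.vander(t, order + 1, increasing=True)  # columns 1, t, t^2, ...
    coef, *_ = np.linalg.lstsq(design, ts.reshape(-1, n).T, rcond=None)
    resid = ts.reshape(-1, n) - (design @ coef).T
    return resid.reshape(ts.shape)


def bandpass(ts: np.ndarray, band: tuple[float, float], tr: float) -> np.ndarray:
    """Zero-phase ideal bandpass via DFT masking.

    Fourier coefficients at frequencies f with low <= f <= high (inclusive)
    are retained; all others, including DC, are zeroed. Real input yields
    real output. Operates along the last axis.
    """
    ts = np.asarray(ts, dtype=np.float64)
    low, high = band
    nyq = 0.5 / tr
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got band={band}")
    if high > nyq + 1e-12:
        raise ValueError(f"band high {high} Hz exceeds Nyquist {nyq} Hz")
    n = ts.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low - 1e-12) & (freqs <= high + 1e-12)
    keep &= freqs > 0  # DC never passes
    if low == 0:
        keep |= freqs == 0
    spec = np.fft.rfft(ts, axis=-1)
    spec[..., ~keep] = 0
    return np.fft.irfft(spec, n=n, axis=-1)


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_dims) -> tuple[float, ...]:
    """Per-axis Gaussian sigma in voxels for a kernel FWHM given in mm."""
    return tuple(fwhm_mm * _FWHM_TO_SIGMA / d for d in voxel_dims)


def gaussian_smooth(img: Image4D, fwhm_mm: float) -> Image4D:
    """Volume-wise 3D Gaussian smoothing.

    The kernel has unit sum; at the grid boundary the truncated kernel is
    renormalized (division by the in-grid kernel mass) so a uniform field
    passes through unchanged. ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return Image4D(img.data.copy(), img.voxel_dims, img.tr)
    sigma = fwhm_to_sigma_voxels(fwhm_mm, img.voxel_dims)
    smoothed = ndimage.gaussian_filter(
        np.asarray(img.data, dtype=np.float64), sigma=(*sigma, 0.0), mode="constant"
    )
    norm = ndimage.gaussian_filter(
        np.ones(img.spatial_shape), sigma=sigma, mode="constant"
    )
    smoothed /= norm[..., None]
    return Image4D(smoothed, img.voxel_dims, img.tr)


def preprocess_subject(
    img: Image4D, cfg: PreprocConfig | None = None
) -> tuple[Image4D, BrainMask]:
    """Run the per-subject chain: mask, then smooth/detrend/bandpass.

    Temporal stages are applied voxelwise inside the mask; out-of-mask
    voxels are set to 0 in the returned image.
    """
    cfg = cfg or PreprocConfig()
    cfg.validate_band(img.tr)
    mask = compute_brain_mask(img, cfg.mask_fraction)

    current = img
    flat: np.ndarray | None = None  # (n_in_mask, T) working copy

    def _to_flat() -> np.ndarray:
        nonlocal flat
        if flat is None:
            flat = np.asarray(current.data, dtype=np.float64)[mask.data]
        return flat

    for stage in cfg.order:
        if stage == "smooth":
            if flat is not None:  # fold temporal results back before smoothing
                vol = np.zeros(img.shape)
                vol[mask.data] = flat
                current = Image4D(vol, img.voxel_dims, img.tr)
                flat = None
            current = gaussian_smooth(current, cfg.fwhm_mm)
        elif stage == "detrend":
            flat = detrend(_to_flat(), cfg.detrend_order)
        elif stage == "bandpass":
            flat = bandpass(_to_flat(), cfg.band, img.tr)

    out = np.zeros(img.shape)
    out[mask.data] = _to_flat()
    return Image4D(out, img.voxel_dims, img.tr), mask
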