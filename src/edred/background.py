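"""Radially symmetric background estimation and subtraction.

Inelastically scattered electrons are not removed from the beam, so combined
elastic/inelastic scattering produces a pronounced, radially symmetric
background in unfiltered electron diffraction patterns.  The four-step
rejection scheme: (1) azimuthal averaging around the found pattern center,
excluding a generous area around each found Bragg spot; (2) median filtering
of the profile to suppress noise and residual ripple from weak, unidentified
peaks; (3) synthesis of the expected background image by interpolating the
profile at each pixel's sub-pixel radius; (4) subtraction.  Negative
residuals are kept (not clipped) so downstream summation integration stays
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class RadialProfile:
    """Azimuthally averaged background profile over integer-radius bins."""

    mean: np.ndarray            # counts per bin, bins 0..n-1 (px)
    n_pixels: np.ndarray
    interpolated: np.ndarray    # True where a bin had no pixels and was filled
    radii_mean: np.ndarray | None = None  # mean sub-pixel radius per bin

    @property
    def radii(self) -> np.ndarray:
        """Abscissa for interpolation: the mean radius of each bin's pixels
        (falls back to the integer bin index where unavailable)."""
        if self.radii_mean is not None:
            return self.radii_mean
        return np.arange(len(self.mean), dtype=float)


def radial_profile(image, center, peaks=None, exclusion_radius: float = 5.0,
                   mask=None) -> RadialProfile:
    """Per-integer-radius mean of background pixels.

    Pixels within ``exclusion_radius`` px of any found peak, and masked
    pixels, are excluded.  Bins left with zero pixels are filled by linear
    interpolation from their neighbours and flagged.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - center[0], yy - center[1])
    rbin = np.rint(r).astype(int)
    live = ~np.asarray(mask, bool) if mask is not None else np.ones_like(img, bool)
    if peaks is not None and len(peaks) > 0:
        px = np.asarray(peaks.x if hasattr(peaks, "x") else peaks[:, 0], dtype=float)
        py = np.asarray(peaks.y if hasattr(peaks, "y") else peaks[:, 1], dtype=float)
        for x0, y0 in zip(px, py):
            x_lo, x_hi = int(x0 - exclusion_radius - 1), int(x0 + exclusion_radius + 2)
            y_lo, y_hi = int(y0 - exclusion_radius - 1), int(y0 + exclusion_radius + 2)
            x_lo, y_lo = max(x_lo, 0), max(y_lo, 0)
            sub = (xx[y_lo:y_hi, x_lo:x_hi] - x0) ** 2 + (yy[y_lo:y_hi, x_lo:x_hi] - y0) ** 2
            live[y_lo:y_hi, x_lo:x_hi] &= sub > exclusion_radius**2
    nbins = rbin.max() + 1
    cnt = np.bincount(rbin[live], minlength=nbins).astype(float)
    s1 = np.bincount(rbin[live], weights=img[live], minlength=nbins)
    sr = np.bincount(rbin[live], weights=r[live], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        rmean = sr / cnt
    empty = cnt == 0
    if empty.any():
        idx = np.arange(nbins, dtype=float)
        if empty.all():
            raise ValueError("no live pixels in any radius bin")
        rmean[empty] = idx[empty]
        mean[empty] = np.interp(rmean[empty], rmean[~empty], mean[~empty])
    # interpolation abscissa must be strictly increasing
    rmean = np.maximum.accumulate(rmean + 1e-9 * np.arange(nbins))
    return RadialProfile(mean=mean, n_pixels=cnt, interpolated=empty,
                         radii_mean=rmean)


def smooth_profile(profile: RadialProfile, window: int = 9) -> RadialProfile:
    """Running median of the profile; edges handled by a shrinking window."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and positive")
    m = profile.mean
    half = window // 2
    out = np.empty_like(m)
    for i in range(len(m)):
        lo = max(0, i - half)
        hi = min(len(m), i + half + 1)
        out[i] = np.median(m[lo:hi])
    return RadialProfile(mean=out, n_pixels=profile.n_pixels.copy(),
                         interpolated=profile.interpolated.copy(),
                         radii_mean=None if profile.radii_mean is None
                         else profile.radii_mean.copy())


def background_image(profile: RadialProfile, shape, center) -> np.ndarray:
    """Synthesize the expected background image from a radial profile.

    The background value at each pixel is the linear interpolation of the
    profile at that pixel's sub-pixel radius from the center.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - center[0], yy - center[1])
    return np.interp(r, profile.radii, profile.mean)


def subtract_background(image, profile: RadialProfile, center) -> np.ndarray:
    """Subtract the interpolated radial background; negatives preserved."""
    img = np.asarray(image, dtype=float)
    return img - background_image(profile, img.shape, center)


def correct_background(image, center, peaks=None, exclusion_radius: float = 5.0,
                       median_window: int = 9, mask=None) -> np.ndarray:
    """Convenience chain: profile -> median smoothing -> subtraction."""
    prof = radial_profile(image, center, peaks=peaks,
                          exclusion_radius=exclusion_radius, mask=mask)
    prof = smooth_profile(prof, window=median_window)
    return subtract_background(image, prof, center)
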