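"""Detector artifact corrections: dead pixels, flat-field, count-rate saturation.

Real electron detectors (in particular hybrid-pixel counting detectors) show
faulty pixels, non-uniform flat-field response and coincidence-loss
saturation at high count *rates*.  All three are corrected here, per image,
before any further analysis; the fixed order is dead pixels -> flat-field ->
saturation, since the dead-time inversion needs true per-pixel gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class DetectorModel:
    """Detector correction parameters.

    dead_map : bool image, True where a pixel is faulty.
    flatfield : relative-gain image (mean ~ 1), strictly positive where live.
    dead_time : paralyzable dead time tau in seconds (0 disables).
    exposure : exposure time per image in seconds.
    saturation_mode : "paralyzable", "cutoff" or "none".
    cutoff_level : counts above which a pixel is excluded in cutoff mode.
    """

    dead_map: np.ndarray | None = None
    flatfield: np.ndarray | None = None
    dead_time: float = 0.0
    exposure: float = 1.0
    saturation_mode: str = "none"
    cutoff_level: float = np.inf

    def __post_init__(self):
        if self.dead_time < 0:
            raise ValueError("dead time must be >= 0")
        if self.saturation_mode not in ("paralyzable", "cutoff", "none"):
            raise ValueError(f"unknown saturation mode {self.saturation_mode!r}")
        if self.flatfield is not None:
            ff = np.asarray(self.flatfield, dtype=float)
            live = ~self.dead_map if self.dead_map is not None else np.ones_like(ff, bool)
            if np.any(ff[live] <= 0):
                raise ValueError("flat-field gains must be strictly positive at live pixels")


def _as_stack(images) -> tuple[np.ndarray, bool]:
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        return arr[None], True
    if arr.ndim == 3:
        return arr, False
    raise ValueError("expected a 2-D image or 3-D stack")


def correct_dead_pixels(images, model: DetectorModel, mode: str = "interpolate"):
    """Replace or flag faulty pixels.

    ``mode="interpolate"``: each dead pixel is replaced by the mean of its
    non-dead 8-neighbours, iterated until every dead pixel is filled (so
    interior holes of any size converge).  ``mode="flag"``: pixel values are
    left untouched and a boolean exclusion mask is returned instead.

    Returns ``(stack, mask)``; the mask is all-False in interpolate mode.
    """
    if model.dead_map is None:
        stack, squeeze = _as_stack(images)
        mask = np.zeros(stack.shape[1:], dtype=bool)
        return (stack[0] if squeeze else stack), mask
    dead = np.asarray(model.dead_map, dtype=bool)
    stack, squeeze = _as_stack(images)
    if dead.shape != stack.shape[1:]:
        raise ValueError("dead map shape does not match images")
    if mode == "flag":
        return (stack[0] if squeeze else stack), dead.copy()
    if mode != "interpolate":
        raise ValueError(f"unknown mode {mode!r}")
    if dead.all():
        raise ValueError("image is fully dead; cannot interpolate")

    kernel = np.ones((3, 3))
    out = stack.copy()
    for img in out:
        remaining = dead.copy()
        img[remaining] = 0.0
        while remaining.any():
            live = ~remaining
            s = ndimage.convolve(img * live, kernel, mode="constant")
            n = ndimage.convolve(live.astype(float), kernel, mode="constant")
            fillable = remaining & (n > 0)
            img[fillable] = s[fillable] / n[fillable]
            remaining &= ~fillable
    mask = np.zeros_like(dead)
    return (out[0] if squeeze else out), mask


def flatfield_correct(images, model: DetectorModel):
    """Divide each image by the relative-gain (flat-field) map."""
    if model.flatfield is None:
        stack, squeeze = _as_stack(images)
        return stack[0] if squeeze else stack
    ff = np.asarray(model.flatfield, dtype=float)
    live = ~model.dead_map if model.dead_map is not None else np.ones_like(ff, bool)
    if np.any(ff[live] <= 0):
        raise ValueError("nonpositive flat-field gain at a live pixel")
    stack, squeeze = _as_stack(images)
    safe = np.where(ff > 0, ff, 1.0)
    out = stack / safe
    return out[0] if squeeze else out


def _invert_paralyzable(m: np.ndarray, tau: float, tol: float = 1e-12,
                        max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Solve m = n exp(-n tau) for n on the physical branch n tau < 1.

    Newton iteration from n0 = m; the measured rate m has its maximum
    ``1/(e tau)`` at ``n = 1/tau``; rates above that have no solution and
    are flagged saturated.
    """
    m = np.asarray(m, dtype=float)
    m_max = 1.0 / (np.e * tau)
    saturated = m > m_max * (1 + 1e-12)
    at_cap = np.isclose(m, m_max, rtol=1e-12, atol=0.0)
    n = m.copy()
    solvable = ~saturated
    for _ in range(max_iter):
        e = np.exp(-n * tau)
        f = n * e - m
        fp = e * (1.0 - n * tau)
        step = np.where(solvable & (np.abs(fp) > 1e-300), f / np.where(fp == 0, 1, fp), 0.0)
        # keep iterates on the lower branch
        n_new = np.clip(n - step, 0.0, 1.0 / tau)
        if np.all(np.abs(n_new - n) <= tol * np.maximum(1.0, np.abs(n))):
            n = n_new
            break
        n = n_new
    n = np.where(at_cap, 1.0 / tau, n)
    n = np.where(saturated, m, n)  # leave unsolvable pixels uncorrected
    return n, saturated | at_cap


def saturation_correct(images, model: DetectorModel):
    """Undo count-rate saturation.

    ``paralyzable``: per pixel the measured rate ``m = counts / t_exp`` is
    inverted through the paralyzable dead-time response ``m = n exp(-n tau)``
    (lower branch, ``n tau < 1``) and the counts replaced by ``n t_exp``.
    Pixels whose rate exceeds the model maximum ``1/(e tau)`` cannot be
    inverted and are flagged instead.  ``cutoff``: pixels at or above
    ``cutoff_level`` are added to the exclusion mask, values untouched.

    Returns ``(stack, saturated_mask)`` with a per-image mask.
    """
    stack, squeeze = _as_stack(images)
    if model.saturation_mode == "none" or (
            model.saturation_mode == "paralyzable" and model.dead_time == 0):
        mask = np.zeros_like(stack, dtype=bool)
        return (stack[0] if squeeze else stack), (mask[0] if squeeze else mask)
    if model.saturation_mode == "cutoff":
        mask = stack >= model.cutoff_level
        return (stack[0] if squeeze else stack), (mask[0] if squeeze else mask)
    if model.exposure <= 0:
        raise ValueError("exposure must be positive for dead-time correction")
    m = stack / model.exposure
    n, flagged = _invert_paralyzable(m, model.dead_time)
    out = n * model.exposure
    return (out[0] if squeeze else out), (flagged[0] if squeeze else flagged)


def correct_image(images, model: DetectorModel, dead_mode: str = "interpolate"):
    """Full detector correction chain: dead pixels -> flat-field -> saturation.

    Returns ``(stack, exclusion_mask)`` where the mask combines flagged dead
    pixels (flag mode only) and saturated pixels.
    """
    stack, dead_mask = correct_dead_pixels(images, model, mode=dead_mode)
    stack = flatfield_correct(stack, model)
    stack, sat_mask = saturation_correct(stack, model)
    mask = np.broadcast_to(dead_mask, sat_mask.shape) | sat_mask
    return stack, mask
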