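"""Spot prediction on still patterns and summation integration.

Given a per-crystal indexing solution (reciprocal basis in the laboratory
frame) the positions of all Bragg reflections that could reasonably be
present in a still are predicted: reciprocal-lattice points whose excitation
error — the distance from the Ewald sphere of radius 1/lambda — is smaller
than the reciprocal spot radius.  Because of the tiny Bragg angles of
high-energy electrons the sphere is nearly flat, so many reflections are
(partially) excited at once.  Intensities are then extracted by simple
summation within a disk around each prediction; partiality is deliberately
not modeled — every retained prediction enters merging as one unweighted
observation (the Monte-Carlo pathway).

Sign convention: excitation error zeta > 0 for reciprocal points *outside*
the Ewald sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distortion import distort_ellipticity


@dataclass
class Prediction:
    """A predicted reflection on the detector."""

    hkl: tuple[int, int, int]
    fs: float                   # x, px (sub-pixel)
    ss: float                   # y, px
    excitation_error: float     # zeta, 1/A
    q: float                    # |g|, 1/A
    partial: bool = False       # in the outer half of the excitation band


@dataclass
class Observation:
    """One integrated intensity observation of a reflection."""

    hkl: tuple[int, int, int]
    intensity: float
    sigma: float
    shot_key: object = None
    crystal_key: object = None


def predict_spots(basis: np.ndarray, geometry, center=None, beam_shift=(0.0, 0.0),
                  spot_radius_recip: float = 2e-3, dmin: float = 3.0,
                  paraxial: bool = True, apply_ellipticity: bool = True) -> list[Prediction]:
    """Predict reflections excited in one still pattern.

    ``basis`` is a 3x3 matrix whose rows are a*, b*, c* in 1/A in the
    laboratory frame (beam along +z); ``g = (h, k, l) @ basis``.  All
    lattice points with ``|g| <= 1/dmin`` are enumerated and those with
    ``|zeta| < spot_radius_recip`` retained.  The detector position follows
    from the transverse components, ``r_px = g_xy L lambda / p``, about
    ``center`` (detector center by default) plus ``beam_shift``; if the
    geometry carries an elliptical distortion and ``apply_ellipticity`` is
    set, positions are distorted into the raw detector frame.
    """
    basis = np.asarray(basis, dtype=float)
    if abs(np.linalg.det(basis)) < 1e-15:
        raise ValueError("reciprocal basis is singular")
    if center is None:
        center = geometry.detector_center
    lam = geometry.wavelength
    qmax = 1.0 / dmin

    real = np.linalg.inv(basis.T)       # rows are the real-space basis vectors
    bounds = [int(np.ceil(qmax * np.linalg.norm(real[i]))) + 1 for i in range(3)]
    h, k, l = np.meshgrid(*[np.arange(-b, b + 1) for b in bounds], indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g = hkl @ basis
    qabs = np.linalg.norm(g, axis=1)
    keep = qabs <= qmax
    hkl, g, qabs = hkl[keep], g[keep], qabs[keep]

    gxy2 = g[:, 0] ** 2 + g[:, 1] ** 2
    if paraxial:
        zeta = g[:, 2] + lam * gxy2 / 2.0
    else:
        k0 = np.array([0.0, 0.0, 1.0 / lam])
        zeta = np.linalg.norm(g + k0, axis=1) - 1.0 / lam
    keep = np.abs(zeta) < spot_radius_recip
    hkl, g, qabs, zeta = hkl[keep], g[keep], qabs[keep], zeta[keep]

    scale = geometry.camera_length * lam / geometry.pixel_size
    fs = center[0] + beam_shift[0] + g[:, 0] * scale
    ss = center[1] + beam_shift[1] + g[:, 1] * scale
    eta, theta = geometry.ellipticity
    if apply_ellipticity and eta > 1.0:
        fs, ss = distort_ellipticity(fs, ss, center, eta, theta)

    preds = []
    for i in range(len(hkl)):
        preds.append(Prediction(hkl=tuple(int(v) for v in hkl[i]), fs=float(fs[i]),
                                ss=float(ss[i]), excitation_error=float(zeta[i]),
                                q=float(qabs[i]),
                                partial=bool(abs(zeta[i]) > spot_radius_recip / 2)))
    return preds


def integrate_spots(image, predictions, r_int: float = 4.0,
                    r_bg: tuple[float, float] | None = None, mask=None,
                    shot_key=None, crystal_key=None):
    """Summation integration at predicted positions.

    ``I`` is the pixel sum inside the disk of radius ``r_int``; if an
    annulus ``r_bg = (inner, outer)`` is given (for non-background-subtracted
    images) the annulus median times the disk area is subtracted.
    ``sigma(I) = sqrt(sum |pixels|)`` floored at 1.  Predictions whose disk
    leaves the detector or touches a masked pixel are dropped and counted.

    Returns ``(observations, n_dropped)``.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    live = ~np.asarray(mask, bool) if mask is not None else None
    obs: list[Observation] = []
    n_dropped = 0
    r_out = r_bg[1] if r_bg is not None else r_int
    for p in predictions:
        x0, y0 = p.fs, p.ss
        if not (r_out <= x0 <= nx - 1 - r_out and r_out <= y0 <= ny - 1 - r_out):
            n_dropped += 1
            continue
        x_lo, x_hi = int(np.floor(x0 - r_out)), int(np.ceil(x0 + r_out)) + 1
        y_lo, y_hi = int(np.floor(y0 - r_out)), int(np.ceil(y0 + r_out)) + 1
        sub = img[y_lo:y_hi, x_lo:x_hi]
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        disk = d2 <= r_int**2
        if live is not None and np.any(~live[y_lo:y_hi, x_lo:x_hi] & disk):
            n_dropped += 1
            continue
        inten = float(sub[disk].sum())
        if r_bg is not None:
            ann = (d2 >= r_bg[0] ** 2) & (d2 <= r_bg[1] ** 2)
            if live is not None:
                ann &= live[y_lo:y_hi, x_lo:x_hi]
            if ann.any():
                inten -= float(np.median(sub[ann])) * disk.sum()
        sigma = max(float(np.sqrt(np.abs(sub[disk]).sum())), 1.0)
        obs.append(Observation(hkl=p.hkl, intensity=inten, sigma=sigma,
                               shot_key=shot_key, crystal_key=crystal_key))
    return obs, n_dropped


def observations_to_table(observations):
    """Collect Observation objects into a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "h": [o.hkl[0] for o in observations],
        "k": [o.hkl[1] for o in observations],
        "l": [o.hkl[2] for o in observations],
        "intensity": [o.intensity for o in observations],
        "sigma": [o.sigma for o in observations],
        "shot": [o.shot_key for o in observations],
        "crystal": [o.crystal_key for o in observations],
    })
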