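"""Elliptical-distortion estimation and correction.

Electron optics imprint a slight (few percent) elliptical distortion on the
diffraction pattern.  It is estimated from the data themselves: all found
peaks, pooled over shots, are histogrammed in polar coordinates relative to
their own shot centers; in an ideal geometry the virtual powder rings show
no azimuth dependence, so any cos(2 phi) modulation of a ring radius betrays
the ellipse.  Peak positions are iteratively corrected until the modulation
vanishes.  The model is a two-parameter, area-preserving distortion: axis
ratio eta (>= 1) and major-axis angle theta.  Only peak/prediction
coordinates are corrected — images are never resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PolarPeakHistogram:
    """2-D histogram of peak positions in (radius, azimuth)."""

    counts: np.ndarray          # (n_r, n_phi)
    r_edges: np.ndarray
    phi_edges: np.ndarray

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def phi_centers(self) -> np.ndarray:
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def radial_profile(self) -> np.ndarray:
        """Azimuth-integrated radial profile."""
        return self.counts.sum(axis=1)


def _pool_polar(peak_lists, centers):
    rs, phis = [], []
    n_skipped = 0
    for pk, ctr in zip(peak_lists, centers):
        if ctr is None or np.any(~np.isfinite(ctr)):
            n_skipped += 1
            continue
        x = np.asarray(pk.x if hasattr(pk, "x") else pk[:, 0], dtype=float)
        y = np.asarray(pk.y if hasattr(pk, "y") else pk[:, 1], dtype=float)
        dx, dy = x - ctr[0], y - ctr[1]
        rs.append(np.hypot(dx, dy))
        phis.append(np.arctan2(dy, dx))
    r = np.concatenate(rs) if rs else np.empty(0)
    phi = np.concatenate(phis) if phis else np.empty(0)
    return r, phi, n_skipped


def polar_histogram(peak_lists, centers, r_bin: float = 1.0, n_phi: int = 64,
                    r_max: float | None = None) -> tuple[PolarPeakHistogram, int]:
    """Histogram all peaks in polar coordinates about their shot centers.

    Each peak contributes exactly once; shots without a valid center are
    skipped and counted.  Returns ``(histogram, n_skipped_shots)``.
    """
    r, phi, n_skipped = _pool_polar(peak_lists, centers)
    if r_max is None:
        r_max = float(r.max()) + r_bin if r.size else 1.0
    r_edges = np.arange(0.0, r_max + r_bin, r_bin)
    phi_edges = np.linspace(-np.pi, np.pi, n_phi + 1)
    counts, _, _ = np.histogram2d(r, phi, bins=[r_edges, phi_edges])
    return PolarPeakHistogram(counts=counts, r_edges=r_edges, phi_edges=phi_edges), n_skipped


# ----------------------------------------------------------------------


def correct_ellipticity(x, y, center, eta: float, theta: float):
    """Undo the elliptical distortion on coordinates (area-preserving).

    Coordinates relative to ``center`` are scaled by ``1/sqrt(eta)`` along
    the major axis and ``sqrt(eta)`` along the minor axis, then returned to
    the detector frame.  Applying the model with ``eta -> 1/eta`` at the
    same angle inverts the correction exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = x - center[0], y - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy           # along major axis
    v = -st * dx + ct * dy          # along minor axis
    s = np.sqrt(eta)
    u, v = u / s, v * s
    return center[0] + ct * u - st * v, center[1] + st * u + ct * v


def distort_ellipticity(x, y, center, eta: float, theta: float):
    """Forward model: apply the distortion that ``correct_ellipticity`` removes."""
    return correct_ellipticity(x, y, center, 1.0 / eta, theta)


def _ring_modulation(r, phi, r_lo, r_hi):
    """Fit r(phi) = rbar (1 + A cos 2phi + B sin 2phi) on peaks in a radius band."""
    sel = (r >= r_lo) & (r <= r_hi)
    if sel.sum() < 8:
        return None
    rr, pp = r[sel], phi[sel]
    design = np.column_stack([np.ones_like(pp), np.cos(2 * pp), np.sin(2 * pp)])
    coef, *_ = np.linalg.lstsq(design, rr, rcond=None)
    rbar, a, b = coef
    return rbar, a / rbar, b / rbar


def fit_ellipticity(peak_lists, centers, r_window: tuple[float, float] | None = None,
                    r_bin: float = 1.0, n_phi: int = 32, eps_tol: float = 1e-4,
                    max_iter: int = 10) -> tuple[float, float]:
    """Estimate (eta, theta) from pooled peak positions.

    Iterates: locate the strongest virtual powder ring (global maximum of
    the azimuth-integrated radial profile, optionally within ``r_window``);
    fit the cos(2 phi) modulation of the ring radius; fold the fitted
    ellipse into the cumulative model; correct the peak radii and repeat
    until the residual modulation amplitude drops below ``eps_tol``.
    Azimuthal coverage of at least half the circle is required.
    """
    r, phi, _ = _pool_polar(peak_lists, centers)
    if r.size < 8:
        raise ValueError("too few peaks to fit ellipticity")
    # coverage check: peaks must span at least half the azimuth range
    occupied = np.unique(np.floor((phi + np.pi) / (2 * np.pi) * 16).astype(int))
    if occupied.size < 8:
        raise ValueError("insufficient azimuthal coverage for ellipticity fit")

    # cumulative model in tensor form M = R(th) diag(1/sqrt(eta), sqrt(eta)) R(-th)
    M = np.eye(2)
    xy = np.stack([r * np.cos(phi), r * np.sin(phi)])
    for _ in range(max_iter):
        rr = np.hypot(xy[0], xy[1])
        pp = np.arctan2(xy[1], xy[0])
        # strongest ring
        r_max_all = rr.max()
        edges = np.arange(0.0, r_max_all + r_bin, r_bin)
        prof, _ = np.histogram(rr, bins=edges)
        centers_r = 0.5 * (edges[:-1] + edges[1:])
        if r_window is not None:
            sel = (centers_r >= r_window[0]) & (centers_r <= r_window[1])
            if not sel.any():
                raise ValueError("no histogram bins inside r_window")
            i0 = np.flatnonzero(sel)[np.argmax(prof[sel])]
        else:
            i0 = int(np.argmax(prof))
        r0 = centers_r[i0]
        band = max(3 * r_bin, 0.03 * r0)
        fit = _ring_modulation(rr, pp, r0 - band, r0 + band)
        if fit is None:
            raise ValueError("strongest ring too sparse for modulation fit")
        _, a, b = fit
        eps = np.hypot(a, b)            # r(phi) ~ rbar (1 + eps cos 2(phi - th))
        theta_i = 0.5 * np.arctan2(b, a)
        if eps < eps_tol:
            break
        eta_i = (1 + eps) / (1 - eps)
        ct, st = np.cos(theta_i), np.sin(theta_i)
        rot = np.array([[ct, -st], [st, ct]])
        s = np.sqrt(eta_i)
        step = rot @ np.diag([1 / s, s]) @ rot.T
        M = step @ M
        xy = step @ xy

    # decompose cumulative M (symmetric positive definite, det 1) into (eta, theta)
    sym = 0.5 * (M + M.T)
    w, v = np.linalg.eigh(sym)
    # smaller eigenvalue direction = major axis (it was shrunk by 1/sqrt(eta))
    eta = float((w[1] / w[0]) ** 1)
    major = v[:, 0]
    theta = float(np.arctan2(major[1], major[0]))
    # normalize angle to (-pi/2, pi/2]
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return eta, theta
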