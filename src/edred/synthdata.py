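"""Synthetic SerialED datasets with full ground truth.

Emulates a serial still-diffraction experiment: for each nanocrystal a known
random orientation, for each shot a jittered beam center, a radially
symmetric inelastic background, Gaussian Bragg spots at the positions of all
reflections excited on the near-flat Ewald sphere, optional elliptical
distortion, per-frame dose-fraction fading of high-resolution intensities,
Poisson counting noise (optionally after a paralyzable dead-time forward
model) and dead pixels.  Every pipeline stage can thus be tested against
exact truth without any experimental download.

What it does *not* emulate: dynamical (multiple elastic) scattering,
mosaicity / partiality structure within a spot, and detector module gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cell import UnitCell, enumerate_lattice
from .dataset import Dataset, peaklists_to_cxi
from .distortion import distort_ellipticity
from .geometry import Geometry
from .integrate import predict_spots
from .merge import PointGroup, map_to_asu
from .peaks import PeakList

import h5py
import pandas as pd


@dataclass
class GroundTruth:
    """Everything the simulator knows and the pipeline must recover."""

    cell: UnitCell
    point_group: PointGroup
    orientations: np.ndarray            # (n_crystals, 3, 3) lab <- crystal rotations
    true_intensities: dict              # asu hkl -> nonnegative intensity (counts)
    centers: np.ndarray                 # (n_crystals * n_frames, 2) beam centers, px
    n_frames: int
    ellipticity: tuple[float, float] = (1.0, 0.0)
    background: tuple[float, float, float] = (100.0, 80.0, 2.0)  # B0, r0 (px), B1
    beam_amplitude: float = 1e4         # zero-order beam peak counts
    beam_gamma: float = 3.0             # zero-order beam Lorentzian HWHM, px
    dead_pixel_map: np.ndarray | None = None
    dose_k: float = 0.0                 # A^2; decay exp(-frame * k * q^2)
    spot_sigma: float = 1.0             # px
    spot_radius_recip: float = 2e-3     # 1/A
    dmin: float = 3.0                   # A
    seed: int = 0

    def __post_init__(self):
        r = self.orientations
        if r.ndim != 3 or r.shape[1:] != (3, 3):
            raise ValueError("orientations must be (n, 3, 3)")
        err = np.abs(np.einsum("nij,nkj->nik", r, r) - np.eye(3)).max()
        if err > 1e-10 or np.any(np.abs(np.linalg.det(r) - 1) > 1e-10):
            raise ValueError("orientations must be proper rotations (tol 1e-10)")
        if self.ellipticity[0] < 1:
            raise ValueError("ellipticity axis ratio must be >= 1")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")
        if any(v < 0 for v in self.true_intensities.values()):
            raise ValueError("true intensities must be non-negative")

    @property
    def n_crystals(self) -> int:
        return len(self.orientations)

    @property
    def n_shots(self) -> int:
        return self.n_crystals * self.n_frames

    def lab_basis(self, crystal_id: int) -> np.ndarray:
        """Reciprocal basis (rows a*, b*, c*, 1/A) in the lab frame."""
        bc = self.cell.reciprocal_basis()
        return bc @ self.orientations[crystal_id].T

    def intensity_of(self, hkl) -> float:
        rep = tuple(int(v) for v in map_to_asu(hkl, self.point_group)[0])
        return float(self.true_intensities.get(rep, 0.0))

    def dose_decay(self, frame: int, q) -> np.ndarray:
        return np.exp(-frame * self.dose_k * np.asarray(q, dtype=float) ** 2)

    def background_profile(self, r) -> np.ndarray:
        """Radial background incl. the zero-order beam (narrow Lorentzian)."""
        b0, r0, b1 = self.background
        r = np.asarray(r, dtype=float)
        g2 = self.beam_gamma**2
        return (self.beam_amplitude * g2 / (g2 + r**2)
                + b0 / (1.0 + (r / r0) ** 2) + b1)


def make_ground_truth(cell: UnitCell | None = None, n_crystals: int = 50,
                      n_frames: int = 1, geometry: Geometry | None = None,
                      point_group: str = "422", intensity_scale: float = 5e3,
                      wilson_b: float = 20.0, center_jitter: float = 2.0,
                      ellipticity: tuple[float, float] = (1.0, 0.0),
                      background: tuple[float, float, float] = (100.0, 80.0, 2.0),
                      beam_amplitude: float = 1e4, beam_gamma: float = 3.0,
                      dead_fraction: float = 0.002, dose_k: float = 0.0,
                      spot_sigma: float = 1.0, spot_radius_recip: float = 2e-3,
                      dmin: float = 3.0, seed: int = 0,
                      orientation_cap_deg: float | None = None) -> GroundTruth:
    """Draw a random ground truth for a synthetic SerialED experiment.

    Defaults emulate the tetragonal lysozyme-like study system: cell
    a = b = 78.9 A, c = 37.9 A, point group 422 (Friedel mates merged),
    Wilson-like intensities ``I ~ scale * exp(-B q^2) * Exp(1)``, beam-center
    jitter of 2 px RMS per shot.  ``orientation_cap_deg`` restricts the
    rotation axes to a cone (preferred-orientation scenario); ``None`` draws
    uniform random orientations.
    """
    rng = np.random.default_rng(seed)
    if cell is None:
        cell = UnitCell("tP", a=78.9, c=37.9)
    if geometry is None:
        geometry = Geometry()
    pg = PointGroup(point_group, friedel=True)
    if orientation_cap_deg is None:
        rots = Rotation.random(n_crystals, random_state=rng).as_matrix()
    else:
        # rotations clustered near identity: axis uniform, angle < cap
        axes = rng.normal(size=(n_crystals, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = np.deg2rad(orientation_cap_deg) * rng.random(n_crystals)
        rots = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()

    hkl, q = enumerate_lattice(cell, dmin)
    asu = np.unique(map_to_asu(hkl, pg), axis=0)
    q_asu = cell.one_over_d(asu)
    inten = intensity_scale * np.exp(-wilson_b * q_asu**2) * rng.exponential(1.0, len(asu))
    true_intensities = {tuple(int(v) for v in t): float(i) for t, i in zip(asu, inten)}

    n_shots = n_crystals * n_frames
    centers = np.asarray(geometry.detector_center) + rng.normal(
        scale=center_jitter, size=(n_shots, 2))
    ny, nx = geometry.detector_shape
    dead = rng.random((ny, nx)) < dead_fraction

    return GroundTruth(cell=cell, point_group=pg, orientations=rots,
                       true_intensities=true_intensities, centers=centers,
                       n_frames=n_frames, ellipticity=ellipticity,
                       background=background, beam_amplitude=beam_amplitude,
                       beam_gamma=beam_gamma, dead_pixel_map=dead, dose_k=dose_k,
                       spot_sigma=spot_sigma, spot_radius_recip=spot_radius_recip,
                       dmin=dmin, seed=seed)


# ----------------------------------------------------------------------


def _render_gaussian(image, x0, y0, sigma, integral):
    """Add a truncated (4 sigma) 2-D Gaussian of given integral in place."""
    ny, nx = image.shape
    r = 4.0 * sigma
    x_lo, x_hi = int(np.floor(x0 - r)), int(np.ceil(x0 + r)) + 1
    y_lo, y_hi = int(np.floor(y0 - r)), int(np.ceil(y0 + r)) + 1
    x_lo, y_lo = max(x_lo, 0), max(y_lo, 0)
    x_hi, y_hi = min(x_hi, nx), min(y_hi, ny)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    d2 = (xx - x0) ** 2 + (yy - y0) ** 2
    g = np.exp(-d2 / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    g[d2 > r**2] = 0.0
    image[y_lo:y_hi, x_lo:x_hi] += integral * g


def simulate_pattern(truth: GroundTruth, crystal_id: int, frame: int,
                     geometry: Geometry, noise: bool = True,
                     detector_model=None) -> tuple[np.ndarray, PeakList]:
    """Render one still diffraction pattern and its true peak list.

    The image is radial background plus one truncated Gaussian spot (width
    ``spot_sigma``) per reflection whose excitation error is below the
    reciprocal spot radius, intensity scaled by the dose-decay factor of the
    frame, elliptically distorted about the per-shot center, Poisson-sampled
    (optionally after the paralyzable dead-time forward model of
    ``detector_model``), with dead pixels zeroed.  ``true_peaks`` holds the
    *undistorted* truth positions and effective intensities.
    """
    if frame >= truth.n_frames:
        raise ValueError(f"frame {frame} out of range (n_frames={truth.n_frames})")
    ny, nx = geometry.detector_shape
    if truth.dead_pixel_map is not None and truth.dead_pixel_map.shape != (ny, nx):
        raise ValueError("geometry detector shape inconsistent with truth dead map")
    shot = crystal_id * truth.n_frames + frame
    center = tuple(truth.centers[shot])

    preds = predict_spots(truth.lab_basis(crystal_id), geometry, center=center,
                          spot_radius_recip=truth.spot_radius_recip,
                          dmin=truth.dmin, apply_ellipticity=False)
    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(xx - center[0], yy - center[1])
    image = truth.background_profile(rr)

    eta, theta = truth.ellipticity
    xs, ys, inten = [], [], []
    for p in preds:
        i_eff = truth.intensity_of(p.hkl) * float(truth.dose_decay(frame, p.q))
        if i_eff <= 0:
            continue
        xs.append(p.fs)
        ys.append(p.ss)
        inten.append(i_eff)
        xd, yd = (p.fs, p.ss) if eta == 1.0 else distort_ellipticity(
            p.fs, p.ss, center, eta, theta)
        _render_gaussian(image, float(xd), float(yd), truth.spot_sigma, i_eff)
    true_peaks = PeakList(x=np.array(xs), y=np.array(ys), intensity=np.array(inten),
                          snr=np.full(len(xs), np.inf))

    if detector_model is not None and detector_model.dead_time > 0:
        t_exp = detector_model.exposure
        n_rate = image / t_exp
        image = n_rate * np.exp(-n_rate * detector_model.dead_time) * t_exp
    if noise:
        rng = np.random.default_rng((truth.seed, crystal_id, frame))
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if truth.dead_pixel_map is not None:
        image[truth.dead_pixel_map] = 0.0
    return image, true_peaks


def simulate_dataset(truth: GroundTruth, geometry: Geometry, out_path=None,
                     n_crystals: int | None = None, n_frames: int | None = None,
                     noise: bool = True, detector_model=None,
                     overwrite: bool = False) -> Dataset:
    """Simulate a full dataset, one shot per (crystal, frame).

    Returns the in-memory Dataset; with ``out_path`` it is also written to
    HDF5 (refusing to overwrite unless asked), including a ``/entry/truth``
    side-group with orientations, centers and true intensities that the
    pipeline loader ignores.  Deterministic for a fixed truth seed.
    """
    if n_crystals is None:
        n_crystals = truth.n_crystals
    if n_crystals < 1:
        raise ValueError("need at least one crystal")
    if n_frames is None:
        n_frames = truth.n_frames
    images, rows, true_lists = [], [], []
    for c in range(n_crystals):
        for fr in range(n_frames):
            img, pk = simulate_pattern(truth, c, fr, geometry, noise=noise,
                                       detector_model=detector_model)
            shot = c * truth.n_frames + fr
            images.append(img.astype(np.float32))
            true_lists.append(pk)
            rows.append({"file": "", "entry_index": shot, "sample": "synthetic",
                         "region_id": 0, "crystal_id": c, "frame": fr,
                         "selected": True,
                         "center_true_x": truth.centers[shot][0],
                         "center_true_y": truth.centers[shot][1]})
    shots = pd.DataFrame(rows)
    features = pd.DataFrame({
        "region_id": np.zeros(n_crystals, dtype=int),
        "crystal_id": np.arange(n_crystals),
        "map_x": np.linspace(10, 100, n_crystals),
        "map_y": np.linspace(10, 100, n_crystals),
    })
    meta = {"instrument/detector/camera_length_mm": geometry.camera_length,
            "instrument/detector/pixel_size_mm": geometry.pixel_size,
            "instrument/detector/shape": np.array(geometry.detector_shape),
            "instrument/beam/wavelength_A": geometry.wavelength,
            "sample/name": "synthetic"}
    ds = Dataset(shots=shots, features=features,
                 stacks={"data": np.stack(images)},
                 global_meta={"<memory>": meta})
    x, y, inten, npk = peaklists_to_cxi(true_lists)
    ds.add_stack("truePeakXPos", x)
    ds.add_stack("truePeakYPos", y)
    ds.add_stack("truePeakIntensity", inten)
    ds.add_stack("nTruePeaks", npk)
    if out_path is not None:
        ds.write(out_path, overwrite=overwrite)
        _append_truth(out_path, truth)
    return ds


def _append_truth(path, truth: GroundTruth):
    with h5py.File(path, "a") as f:
        g = f["entry"].create_group("truth")
        g.create_dataset("orientations", data=truth.orientations)
        g.create_dataset("centers", data=truth.centers)
        hkl = np.array(list(truth.true_intensities.keys()), dtype=int)
        g.create_dataset("hkl", data=hkl)
        g.create_dataset("intensity",
                         data=np.array(list(truth.true_intensities.values())))
        g.create_dataset("cell", data=np.array([truth.cell.a, truth.cell.b, truth.cell.c,
                                                truth.cell.alpha, truth.cell.beta,
                                                truth.cell.gamma]))
        g.attrs["bravais"] = truth.cell.bravais
        g.attrs["seed"] = truth.seed


def simulate_peak_lists(cell: UnitCell, n_patterns: int, geometry: Geometry,
                        spot_radius_recip: float = 2e-3, dmin: float = 10.0,
                        noise_px: float = 0.3, center_jitter: float = 0.0,
                        seed: int = 0):
    """Fast peak-list-only simulation (no images) for cell-refinement studies.

    Random uniform orientations; each pattern's peak positions are the spot
    predictions of its crystal plus isotropic Gaussian positional noise of
    ``noise_px`` px.  Returns ``(peak_lists, centers)``.
    """
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_patterns, random_state=rng).as_matrix()
    bc = cell.reciprocal_basis()
    det_center = np.asarray(geometry.detector_center)
    peak_lists, centers = [], []
    for i in range(n_patterns):
        ctr = det_center + rng.normal(scale=center_jitter, size=2) \
            if center_jitter > 0 else det_center.copy()
        preds = predict_spots(bc @ rots[i].T, geometry, center=tuple(ctr),
                              spot_radius_recip=spot_radius_recip, dmin=dmin,
                              apply_ellipticity=False)
        x = np.array([p.fs for p in preds]) + rng.normal(scale=noise_px, size=len(preds))
        y = np.array([p.ss for p in preds]) + rng.normal(scale=noise_px, size=len(preds))
        peak_lists.append(PeakList(x=x, y=y, intensity=np.ones(len(preds)),
                                   snr=np.full(len(preds), 10.0)))
        centers.append(ctr)
    return peak_lists, np.array(centers)
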