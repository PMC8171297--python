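"""Canonical end-to-end experiments on synthetic data.

These routines define the reference study conditions under which the
pipeline is validated: the histogram-based cell refinement on peak lists
from the tetragonal reference cell (a = 78.9 A, c = 37.9 A), and the full
predict -> integrate -> merge recovery run.  They are used both by the
reproduction script and by the test suite, so the numbers the package
reports always come from the same computation.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .background import correct_background
from .cell import UnitCell, pairwise_histogram, powder_histogram, refine_cell
from .geometry import Geometry, electron_wavelength
from .integrate import integrate_spots, observations_to_table, predict_spots
from .merge import cc_half, cc_star, completeness_redundancy, merge_mc
from .synthdata import make_ground_truth, simulate_pattern, simulate_peak_lists

#: reference still-camera geometry for full-image runs: 512 x 512 px,
#: 55 um pitch, 1.5 m camera length, 200 kV electrons — covers ~2.7 A at
#: the edge while keeping neighbouring reflections of the reference cell
#: well separated (~8.7 px)
IMAGE_GEOMETRY = Geometry(camera_length=1500.0, pixel_size=0.055,
                          wavelength=0.0251, detector_shape=(512, 512))

#: wide-camera geometry used for peak-list statistics (virtual powder)
POWDER_GEOMETRY = Geometry(camera_length=2000.0, pixel_size=0.055,
                           wavelength=0.0251, detector_shape=(1024, 1024))

REFERENCE_CELL = UnitCell("tP", a=78.9, c=37.9)


def invert_cc_star(cc_star_value: float = 0.5) -> float:
    """CC1/2 at which CC* equals the given value, by numerical inversion."""
    return float(optimize.brentq(lambda c: cc_star(c) - cc_star_value, 0.0, 1.0,
                                 xtol=1e-12))


def wavelength_at_200kv() -> float:
    """Relativistic electron wavelength at 200 kV, in Angstrom."""
    return electron_wavelength(200.0)


def cell_refinement_experiment(seed: int = 42, n_patterns: int = 500,
                               noise_px: float = 0.3, bin_width: float = 2e-4,
                               start_factors: tuple[float, float] = (1.02, 0.975),
                               dmin: float = 10.0):
    """Recover the reference tetragonal cell from synthetic peak histograms.

    Peak lists for ``n_patterns`` still patterns are simulated from the
    reference cell at random orientations with ``noise_px`` positional
    noise; virtual-powder and pairwise-distance histograms are built at
    ``bin_width`` (1/A) and the cell refined starting from
    ``(a * f_a, c * f_c)``.  Returns ``(refined_cell, report)``.
    """
    geom = POWDER_GEOMETRY
    peak_lists, centers = simulate_peak_lists(
        REFERENCE_CELL, n_patterns, geom, dmin=dmin, noise_px=noise_px, seed=seed)
    powder = powder_histogram(peak_lists, centers, geom, bin_width=bin_width)
    pairs = pairwise_histogram(peak_lists, geom, bin_width=bin_width)
    start = UnitCell("tP", a=REFERENCE_CELL.a * start_factors[0],
                     c=REFERENCE_CELL.c * start_factors[1])
    return refine_cell(start, powder, pairs, dmin=dmin)


def merge_recovery_experiment(n_crystals: int = 200, seed: int = 0,
                              noise: bool = False,
                              orientation_cap_deg: float | None = None,
                              dmin: float = 3.0, split_seed: int = 0) -> dict:
    """Full predict -> background-subtract -> integrate -> merge run.

    Simulates ``n_crystals`` still patterns of the reference system on the
    image geometry, integrates at the truth indexing solutions on
    background-subtracted images, merges under 4/mmm and compares merged
    intensities with the injected truth.  Returns a dict with ``pearson_r``,
    ``completeness`` (%), ``redundancy``, ``cc_half`` and ``n_unique``.
    """
    geom = IMAGE_GEOMETRY
    truth = make_ground_truth(geometry=geom, n_crystals=n_crystals, seed=seed,
                              dmin=dmin, dead_fraction=0.0,
                              orientation_cap_deg=orientation_cap_deg)
    all_obs = []
    for c in range(n_crystals):
        img, pk = simulate_pattern(truth, c, 0, geom, noise=noise)
        ctr = tuple(truth.centers[c])
        sub = correct_background(img, ctr, peaks=pk)
        preds = predict_spots(truth.lab_basis(c), geom, center=ctr,
                              spot_radius_recip=truth.spot_radius_recip, dmin=dmin)
        obs, _ = integrate_spots(sub, preds, r_int=4.0, shot_key=c, crystal_key=c)
        all_obs.extend(obs)
    table = observations_to_table(all_obs)
    pg = truth.point_group
    merged = merge_mc(table, pg)
    truth_i = np.array([truth.intensity_of((r.h, r.k, r.l))
                        for r in merged.itertuples()])
    pearson = float(np.corrcoef(merged["intensity"], truth_i)[0, 1])
    comp = completeness_redundancy(merged, truth.cell, pg, dmin=dmin)
    out = {
        "pearson_r": pearson,
        "completeness": float(comp.attrs["overall_completeness"]),
        "redundancy": float(comp.attrs["overall_redundancy"]),
        "n_unique": int(len(merged)),
        "n_obs": int(len(table)),
    }
    if n_crystals >= 4:
        cc = cc_half(table, pg, truth.cell, shells=5, split_seed=split_seed)
        out["cc_half"] = float(cc.attrs["overall_cc_half"])
    return out
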