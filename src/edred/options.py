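"""Flat, YAML-backed processing options (the single source of tunables).

All pipeline tunables live in one flat mapping with dotted section keys
(``peaks.snr_min``, ``cell.bin_width_invA``, ...), serialized to a
human-readable YAML file.  Unknown keys are rejected on load, and every CLI
run writes the fully resolved options next to its outputs, so a finished
run documents the exact parameters used.
"""

from __future__ import annotations

import numpy as np
import yaml

from .detector import DetectorModel
from .geometry import Geometry

DEFAULTS: dict[str, object] = {
    "seed": 0,
    # geometry
    "geometry.camera_length_mm": 2000.0,
    "geometry.pixel_size_mm": 0.055,
    "geometry.wavelength_A": 0.0251,
    "geometry.detector_nx": 1024,
    "geometry.detector_ny": 1024,
    "geometry.ellipticity_ratio": 1.0,
    "geometry.ellipticity_angle_rad": 0.0,
    # detector corrections
    "detector.dead_time_s": 0.0,          # no physical default; set per detector
    "detector.exposure_s": 1.0,
    "detector.saturation_mode": "none",
    "detector.cutoff_level": 0.0,
    "detector.dead_pixel_mode": "interpolate",
    # centering / peak finding
    "peaks.com_quantile": 0.999,
    "peaks.lorentz_radius_px": 30.0,
    "peaks.snr_min": 5.0,
    "peaks.intensity_min": 0.0,
    "peaks.min_pix": 2,
    "peaks.max_pix": 200,
    "peaks.friedel_sigma_px": 2.0,
    "peaks.refind_after_friedel": True,
    # background
    "background.exclusion_radius_px": 5.0,
    "background.median_window_bins": 9,
    # cell refinement
    "cell.bravais": "tP",
    "cell.a_A": 78.9,
    "cell.b_A": 78.9,
    "cell.c_A": 37.9,
    "cell.alpha_deg": 90.0,
    "cell.beta_deg": 90.0,
    "cell.gamma_deg": 90.0,
    "cell.dmin_A": 10.0,
    "cell.bin_width_invA": 2.0e-4,
    "cell.tol_bins": 1.5,
    "cell.prominence_frac": 0.02,
    # prediction / integration
    "integrate.spot_radius_invA": 2.0e-3,
    "integrate.dmin_A": 3.0,
    "integrate.r_int_px": 4.0,
    # merging / validation
    "merge.point_group": "422",
    "merge.friedel": True,
    "merge.scaling": "none",
    "merge.n_cycles": 3,
    "merge.n_shells": 10,
    "merge.split_seed": 0,
}


class Options:
    """Resolved option set; behaves like a read/write mapping over DEFAULTS."""

    def __init__(self, overrides: dict | None = None):
        self._values = dict(DEFAULTS)
        if overrides:
            self.update(overrides)

    def update(self, overrides: dict):
        unknown = sorted(set(overrides) - set(DEFAULTS))
        if unknown:
            raise KeyError(f"unknown option key(s): {unknown}")
        self._values.update(overrides)

    def __getitem__(self, key: str):
        return self._values[key]

    def __setitem__(self, key: str, value):
        if key not in DEFAULTS:
            raise KeyError(f"unknown option key: {key}")
        self._values[key] = value

    def as_dict(self) -> dict:
        return dict(self._values)

    # -- YAML ----------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "Options":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: options file must be a flat mapping")
        return cls(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self._values, sort_keys=True, default_flow_style=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    # -- object builders ----------------------------------------------

    def geometry(self) -> Geometry:
        v = self._values
        return Geometry(
            camera_length=v["geometry.camera_length_mm"],
            pixel_size=v["geometry.pixel_size_mm"],
            wavelength=v["geometry.wavelength_A"],
            detector_shape=(int(v["geometry.detector_ny"]), int(v["geometry.detector_nx"])),
            ellipticity=(v["geometry.ellipticity_ratio"], v["geometry.ellipticity_angle_rad"]),
        )

    def detector_model(self, dead_map=None, flatfield=None) -> DetectorModel:
        v = self._values
        cutoff = v["detector.cutoff_level"]
        return DetectorModel(
            dead_map=dead_map, flatfield=flatfield,
            dead_time=v["detector.dead_time_s"], exposure=v["detector.exposure_s"],
            saturation_mode=v["detector.saturation_mode"],
            cutoff_level=cutoff if cutoff else np.inf,
        )

    def unit_cell(self):
        from .cell import UnitCell
        v = self._values
        return UnitCell(v["cell.bravais"], a=v["cell.a_A"], b=v["cell.b_A"],
                        c=v["cell.c_A"], alpha=v["cell.alpha_deg"],
                        beta=v["cell.beta_deg"], gamma=v["cell.gamma_deg"])
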