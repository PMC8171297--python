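# edred — serial electron diffraction data reduction

`edred` is a data-reduction library and command-line tool for **serial
electron diffraction (SerialED)**: nanocrystallography in a transmission
electron microscope where each of thousands of crystals contributes a single
still diffraction pattern (optionally as a short dose-fractionation movie),
with no goniometer rotation.  It takes raw, dose-fractionated still-image
stacks to merged, validated Bragg intensities ready for phasing and
refinement, and ships a synthetic-data simulator with full ground truth so
the entire pipeline is testable without microscope data.

It is aimed at electron crystallographers and methods developers who need
the SerialED-specific steps that generic serial-crystallography pipelines do
not provide: per-shot beam centers, elliptical distortion from the imaging
optics, heavy inelastic background, and still-shot (partiality-free)
Monte-Carlo merging.

## The pipeline

1. **Sorting / aggregation** — shot, crystal and region metadata are managed
   in tables row-aligned with the (lazily loaded, larger-than-memory) image
   stacks; dose-fraction frames are summed over any range.
2. **Detector corrections** — dead pixels (8-neighbour interpolation or
   flagging), flat-field normalisation, and count-rate saturation via the
   paralyzable dead-time model: a measured rate m relates to the true rate n
   by m = n·exp(−nτ), inverted by Newton iteration on the branch nτ < 1.
3. **Centering and peak finding** — the zero-order beam wanders shot to
   shot; it is found per pattern by thresholded center of mass, a 2-D
   Lorentzian fit, and refined with Friedel mates: on the near-flat electron
   Ewald sphere the pairs (h,k,l)/(−h,−k,−l) appear together and are
   symmetric about the true center, so the score

   F(x₀, y₀) = (1/2N_pk) Σᵢⱼ exp[−((xᵢ+xⱼ−2x₀)² + (yᵢ+yⱼ−2y₀)²)/2σ²]

   peaks at the center; 1/F is minimized to sub-pixel accuracy.  Bragg peaks
   are found with a peakfinder8-style algorithm (per-radius robust
   background, SNR threshold, connected components).
4. **Ellipticity** — pooled peak positions are histogrammed in polar
   coordinates; a cos 2φ modulation of ring radii betrays the (few percent)
   elliptical distortion, removed iteratively as an area-preserving
   (axis ratio η, angle θ) model applied to coordinates.
5. **Background rejection** — azimuthal averaging around the center with
   exclusion zones at found peaks, median filtering, re-expansion to a 2-D
   background image, subtraction (negatives preserved).
6. **Unit-cell refinement** — the virtual powder pattern (histogram of peak
   radii as 1/d) and the pairwise peak-distance histogram both peak at
   inverse layer spacings; predicted spacings of the Bravais cell are
   matched to observed maxima and the free cell parameters fitted by
   weighted least squares.
7. **Spot prediction and integration** — from per-crystal reciprocal bases
   (read from `.sol` files or simulator truth), all reflections with
   excitation error |ζ| below the reciprocal spot radius are predicted and
   integrated by simple summation in a disk.
8. **Merging and validation** — observations are mapped to the asymmetric
   unit, averaged without weighting (Monte-Carlo), optionally with iterative
   per-crystal global or resolution-dependent (k, B) scaling; quality is
   reported as half-set correlation CC₁/₂, CC* = √(2CC₁/₂/(1+CC₁/₂)),
   completeness, redundancy, R_split and ⟨I/σ⟩ per resolution shell.

Interop with the serial-crystallography ecosystem: CrystFEL-style `.geom`,
`.cell`, `.sol`, `.hkl`, list files, a minimal `.stream` parser, CXI peak
arrays inside NeXus-style HDF5, and image-free *virtual* files for indexing
with peaks re-centered per shot.

## Worked example

```python
import edred
from edred.experiments import IMAGE_GEOMETRY, POWDER_GEOMETRY

# a synthetic SerialED experiment with known ground truth
geom = IMAGE_GEOMETRY                       # 512x512 px, 55 um, 1.5 m, 200 kV
truth = edred.make_ground_truth(geometry=geom, n_crystals=20, seed=1)
img, true_peaks = edred.simulate_pattern(truth, 0, 0, geom)

com = edred.center_of_mass(img)             # bright central beam
ctr = edred.lorentz_fit(img, com)           # sub-pixel center
peaks = edred.find_peaks(img, ctr)          # peakfinder8-style
ref = edred.friedel_refine(peaks, ctr)      # Friedel-mate refinement

# cell refinement from pooled peak statistics of 500 patterns
cell = edred.UnitCell("tP", a=78.9, c=37.9)
pls, ctrs = edred.simulate_peak_lists(cell, 500, POWDER_GEOMETRY,
                                      dmin=10.0, noise_px=0.3, seed=42)
powder = edred.powder_histogram(pls, ctrs, POWDER_GEOMETRY, bin_width=2e-4)
pairs = edred.pairwise_histogram(pls, POWDER_GEOMETRY, bin_width=2e-4)
refined, report = edred.refine_cell(edred.UnitCell("tP", a=80.5, c=37.0),
                                    powder, pairs, dmin=10.0)
```

This prints (via the obvious `print` statements):

```
COM center      : (257.18, 255.44) px
Lorentzian fit  : (257.118, 255.142) px
Friedel refined : (257.121, 255.134) px  (F = 0.33)
true center     : (257.119, 255.124) px
found peaks     : 267  (rendered: 326)
refined cell    : a = 78.88 A, c = 37.92 A (5 iterations, 16 spacings matched)
```

The Friedel-refined center lands within 0.01 px of the injected truth even
on a Poisson-noised pattern, and the cell refinement recovers the true
tetragonal cell (a = 78.9 Å, c = 37.9 Å) from a start 2% off.

The same stages are available from the shell:

```sh
edred simulate --out run0.h5 --crystals 20 --seed 1
edred preprocess run0.h5 --out-dir proc/
edred cell proc/run0_proc.h5 --out refined.cell
edred integrate proc/run0_proc.h5 truth.sol --out obs.csv
edred merge obs.csv --out merged.hkl
```

Every run writes its fully resolved YAML options next to the outputs, so a
finished run documents the exact parameters used.

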