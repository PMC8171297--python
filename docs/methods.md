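# Methods

This note records the models, conventions, parameter choices and known
limitations behind `edred`'s SerialED reduction pipeline.

## Conventions

Pixel indices are 0-based and refer to pixel centers; `x` is the fast axis
(last array dimension), images are indexed `image[y, x]`; the nominal center
of an `(ny, nx)` detector is `(nx/2, ny/2)`.  Scattering-vector lengths are
`1/d` in Å⁻¹ without a 2π factor; the beam travels along +z.  The paraxial
mapping `1/d = r·p/(L·λ)` (radius r px, pixel pitch p, camera length L,
wavelength λ) is used throughout; the exact `2 sin θ_B/λ` form is available
and differs by < 0.1% inside a 2° scattering angle, far beyond the detector
edge at 200 kV.

## Synthetic data: what it emulates, and what it does not

The simulator is the reference experiment for every test.  Per crystal it
draws a uniform random orientation; per shot a beam center jittered about
the detector center (2 px RMS by default — the beam-shift pivot error of
serial acquisition); the image is a radially symmetric background
`b(r) = A·γ²/(γ²+r²) + B₀/(1+(r/r₀)²) + B₁` (zero-order beam of peak
amplitude A = 10⁴ counts and HWHM γ = 3 px, plus a heavy-tailed inelastic
term with B₀ = 100, r₀ = 80 px, B₁ = 2), plus one isotropic 2-D Gaussian
spot (σ = 1 px, truncated at 4σ, analytically normalised so the pixel sum
equals the reflection intensity) for every reflection whose excitation
error is below the reciprocal spot radius (default 0.002 Å⁻¹, inside the
< 0.005 Å⁻¹ range realistic for 3-D electron diffraction).  Intensities are
Wilson-like, `I ~ scale·exp(−B q²)·Exp(1)` with B = 20 Å², symmetrized over
the point group (422 plus Friedel by default, matching the tetragonal
reference cell a = b = 78.9 Å, c = 37.9 Å).  Optional ingredients:
elliptical distortion of spot positions about the per-shot center,
per-frame dose fading `exp(−frame·k·q²)`, a paralyzable dead-time forward
model, Poisson sampling, and random dead pixels (0.2%).

Not emulated: dynamical (multiple elastic) scattering, mosaicity and
partiality structure (every rendered reflection carries its full intensity),
detector module gaps, and energy filtering.  Consequently, passing tests
demonstrate the correctness of the reduction machinery — centering,
background treatment, geometry, bookkeeping, merging statistics — not
robustness to partiality or dynamical effects in real data.

Reference problem sizes: full-image runs use a 512×512 px camera at
L = 1.5 m (neighbouring reflections of the reference cell are ~8.7 px
apart; the detector edge reaches ~2.7 Å) with 3–200 crystals depending on
the check; peak-list statistics (virtual powder, ellipticity) use the
1024×1024 px, L = 2 m camera with 150–500 patterns.

## Detector corrections

Order fixed as dead pixels → flat-field → saturation (the dead-time
inversion needs true per-pixel gains).  Dead pixels are filled with the
mean of non-dead 8-neighbours, iterated so interior holes converge; flag
mode emits an exclusion mask instead.  The paralyzable dead-time inversion
solves `m = n·exp(−nτ)` by Newton iteration from n₀ = m with 1e-12
tolerance on the physical branch nτ < 1; rates above the model maximum
1/(eτ) are flagged saturated and left uncorrected.  τ has no physical
default — it is a per-detector calibration supplied in the options file.

## Centering and peak finding

The chain is center-of-mass (upper-quantile threshold, default 0.999, so
essentially only the central beam contributes) → 2-D Lorentzian
least-squares fit (disk radius 30 px) → peakfinder8-style peak finding →
Friedel refinement → optional second peak-finding pass with the refined
center (the radial background depends on it).

The radial background estimate is two-pass: pass one computes per-radius
median and MAD-based σ (robust to Bragg pixels sharing a bin), pixels more
than `snr_min`·σ above the median are rejected, pass two takes plain
mean/σ of the survivors.  Candidates need `I > bg + snr_min·σ` (default 5)
and form 8-connected components of 2–200 px; positions are
background-corrected centroids, intensities background-corrected sums.

The Friedel score is summed over all ordered peak pairs *including* i = j;
the diagonal only matters for a peak at the center and keeps reported F
values reproducible.  Two safeguards proved necessary.  First, for a
periodic peak lattice F has **aliased maxima** at half-lattice shifts of
the center which can outscore the true one (every peak pairs with a
neighbour instead of its mate); the optimizer is therefore strictly local —
simplex restarts on a 3×3 px grid around the Lorentzian center, with moves
beyond `max_shift` barred (adaptive default: 0.35× the median
nearest-neighbour peak distance, capped at 5 px, since aliases sit at half
that distance).  Second, a significance floor: the result is accepted only
if `F·N_pk ≥ min(2.5, N_pk/4)` — clearly more than one coincidentally
aligned pair — otherwise the initial center is returned, flagged.  On
paired synthetic data the refinement recovers centers to < 0.05 px
(noiseless) and < 0.2 px (Poisson-noised).

## Ellipticity

A two-parameter, area-preserving model: coordinates relative to the center
are scaled by 1/√η along the major axis (angle θ) and √η along the minor
axis.  A general affine would be over-parametrized for the few-percent
artifact; the model is exactly inverted by η → 1/η at the same θ.  The fit
iterates: locate the strongest virtual-powder ring (global maximum of the
azimuth-integrated radial profile, optionally windowed), fit
`r(φ) = r̄(1 + ε·cos 2(φ−θ))` by linear least squares, compose the step
into a cumulative symmetric tensor, and stop when ε < 1e-4 (max 10
iterations); η and θ are read off the eigen-decomposition of the cumulative
tensor.  At least half-circle azimuthal coverage is required.  Only peak
and prediction *coordinates* are corrected — images are never resampled —
and the model is folded into exported geometry files via the fs/ss axis
vectors.

## Background rejection

Azimuthal averaging about the per-shot center with a 5 px exclusion disk
around each found peak (the radius is configurable; the value is
deliberately generous relative to the 1 px spot σ), running median of
window 9 bins (edges shrink), linear interpolation at each pixel's
sub-pixel radius using the per-bin *mean* radius as abscissa (using the bin
index instead biases steep profiles), then subtraction.  Negative residuals
are preserved so downstream summation integration stays unbiased.  Empty
bins are filled by interpolation and flagged.

## Unit-cell refinement

Both spacing histograms are binned at 2·10⁻⁴ Å⁻¹ (configurable; fine
enough that the 0.3 px positional noise ≈ 1.5 bins at the reference
camera).  Observed maxima are local maxima above a prominence threshold
(2% of the histogram maximum) with sub-bin position by parabolic
interpolation.  Refinement iterates assignment (nearest observed maximum)
and weighted least squares over the free parameters of the Bravais class,
with three robustness measures that the plain iteration needs in practice:

* **Tolerance annealing** — the assignment tolerance starts at 8 bins and
  shrinks by 0.6× per iteration to the final 1.5 bins: a start estimate a
  few percent off displaces predicted spacings by several bins, and a tight
  tolerance from the outset locks onto a wrong self-consistent assignment.
* **Scale pre-scan** — a 1-D scan of an overall length-scale factor
  (±6%), then coordinate-wise scans per length parameter (±3%), scoring
  each candidate by the smoothed histogram counts under its predicted
  spacings; this removes the correlated and anti-correlated start errors
  that gradient refinement cannot escape.
* **Resolvability filter** — predicted spacings closer than 6 bins to
  another prediction are excluded from the fit: the histograms cannot
  resolve them and their blended maxima sit off either constituent.

The pairwise histogram enters the least-squares stage down-weighted
(weight ratio 0.3, configurable): pair distances measure only the
transverse component of the difference vector, and the excitation-error
band smears them asymmetrically toward low 1/d, biasing pairwise maxima by
up to ~1 bin at the primitive-basis spacings, whereas powder radii are
unbiased sub-bin measurements.  The pairwise maxima still anchor the
primitive basis lengths that centering absences remove from the powder
pattern.  A residual +0.05 Å systematic on the long axis of the reference
cell remains across seeds (from the same transverse-projection effect on
the powder radii); it is an order of magnitude below the one-decimal
reporting precision.

Recovery under the reference conditions (500 patterns, 0.3 px noise,
±2–3% perturbed starts): a and c to better than ±0.1 Å; over random
tetragonal cells (a ∈ [40,120] Å, c ∈ [20,60] Å) the median |Δa| is
< 0.1 Å.

## Prediction, integration, merging

Spot prediction enumerates reciprocal-lattice points to the resolution
limit and keeps |ζ| < spot radius, with ζ > 0 outside the Ewald sphere and
the flat-sphere (paraxial) form ζ ≈ g_z + λ|g_xy|²/2 by default.
Integration is simple summation in a disk of r_int = 4 px (≈ 4 spot σ);
an annulus-median background term is available for non-subtracted images,
but the supported pathway integrates background-subtracted images, which
on noiseless synthetic data recovers injected intensities essentially
exactly (Pearson r > 0.9999 over 200 crystals).  σ(I) = √Σ|pixels|,
floored at 1.  Partiality is deliberately not modeled: every retained
prediction is one unweighted observation — the Monte-Carlo pathway —
and overlapping prediction disks are both integrated.

Merging maps Miller indices to a deterministic asymmetric-unit
representative (lexicographically maximal orbit image; point groups built
by closure from hand-coded generators, with Friedel pairs merged by
default).  Optional per-crystal scaling iterates against the current
merged reference: global `k_c = Σ I_ref·I_obs / Σ I_obs²`, or
resolution-dependent `(k_c, B_c)` from the log-linear model
`log(I_ref/I_obs) = log k_c + B_c q²/2` (3 cycles by default).  Merged σ
is the standard error for n ≥ 2 and the integration σ for n = 1.

Validation: crystals (never single observations) are split into seeded
random halves; CC₁/₂ is the Pearson correlation of the independently
merged halves over common uniques, per shell and overall;
CC* = √(2CC₁/₂/(1+CC₁/₂)), extended with sign for −1/3 < CC₁/₂ < 0 and
undefined below.  Resolution shells hold approximately equal numbers of
unique reflections (default 10).  Completeness counts observed uniques
against brute-force enumeration of the expected asymmetric unit (centering
absences removed); with uniform orientations 200 crystals reach ≥ 99% at
3 Å, while orientations confined to a 30° cone plateau near 50% — the
preferred-orientation signature.  Half-sets are merged unscaled by default
(a flag enables scaling before the split).

## Degenerate inputs and tie-breaks

Fully dead images fail per shot (recorded in a status column) without
aborting a batch; flat images return the initial center flagged; empty
peak lists are valid everywhere; histograms with no counts refuse
refinement (< 3 assigned spacings is under-determined); shells with < 3
common uniques report NaN; R_split with a zero denominator is NaN; merged
intensities may be negative (never clipped).  Degenerate assignment of two
predicted spacings to one observed maximum is allowed — they may be
genuinely unresolved — subject to the resolvability filter above.

## Limitations

The `.sol` and `.stream` dialects cover the subset needed for solutions,
integration and validation, not full stream fidelity.  Orientation
determination (indexing) itself is out of scope: orientations are consumed
from `.sol` files or simulator truth.  Single-panel detector geometry only;
no higher-order (barrel/pincushion) distortion; background models are
radially symmetric by construction.
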