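# Methods

## Signal model and assumptions

Each pixel of an SLI measurement carries an azimuthal intensity profile
I(φ) sampled on a uniform grid that tiles the full circle (≥ 6 samples;
the standard measurement uses 15° steps starting at twelve o'clock,
clockwise). The analysis assumes only that fiber signals appear as smooth,
roughly symmetric peaks on a slowly varying background:

- one in-plane bundle → two peaks ≈ 180° apart at φ_f ± 90°;
- two/three crossing in-plane bundles → superimposed pairs (4/6 peaks);
- inclination moves a bundle's peak pair together, broadens it, and lowers
  its prominence until it merges into one peak at φ_f.

No peak-shape model is fitted; all quantities are defined directly on the
sampled profile.

## Per-profile chain

**Normalization** divides by the profile mean (mean of the output is
exactly 1). Profiles with amplitude below 1e-9 of their mean (or
non-positive mean) are classified *flat*: no peaks, no directions; this
threshold only guards against numerically-constant profiles.

**Peak detection** enumerates circular local maxima by run-decomposition
of the profile: a maximal run of equal values flanked by strictly smaller
neighbors on both (circular) sides is one peak at the run's center sample,
rounding to the lower index for even runs. This plateau rule is
deterministic and symmetric in expectation; wrap-around maxima are found
like any other. An exhaustive brute-force scan over all small discrete
profiles (lengths 6–8, values 0–3) doubles as an independent oracle in the
test suite.

**Prominence** follows the conventional signal-processing definition
extended to the circle: walk from the peak in each direction to the next
strictly higher sample (or the full circle if none), take the minimum
value encountered on each side, and subtract the higher of the two minima
from the peak value. Relative prominence divides by the profile amplitude
I_max − I_min; the default 8 % threshold separating signal from noise
peaks, and the 6 % tip cut below, are taken as given operating points and
exposed as parameters.

**Width** is the full width at the height (peak − prominence/2), with the
two crossings located by linear interpolation on the flanks; degrees.

**Position correction** places a cut `tip_fraction` (default 6 %) of the
amplitude below the peak top, interpolates the two flank crossings, and
reports their circular midpoint. "Geometric center of the peak tip" is
implemented as this crossing midpoint rather than an intensity-weighted
centroid of the tip samples; both suppress the discretization error, the
midpoint is exactly invariant under affine intensity changes and has a
closed-form hand check. If a flank starts rising again before reaching the
cut (tips of adjacent peaks merging), the correction falls back to the raw
sample position rather than interpolating through a neighboring peak.

Simulated two-peak profiles at 15° sampling (the acceptance script) put
the corrected-position error spread at ≈ 1° std, versus a uniform ±7.5°
bound for the raw argmax.

## Directions and maps

Corrected positions of the *prominent* peaks map to axial directions in
[0, 180) by the 1/2/4/6-peak rules (README). For 4 or 6 peaks, peaks are
paired by sorted order (i with i + n/2); a best-assignment search was
considered and rejected because sorted-order pairing is unambiguous,
order-preserving, and already correct whenever the pairing is physically
interpretable. Pairing is all-or-nothing: if any pair misses the
180° ± 35° window, no direction is emitted for the pixel — partially
valid pairings are not interpreted. Counts of 0, 3, 5 or > 6 prominent
peaks yield no direction. Emitted directions are sorted ascending into
`dir_1..dir_3`; no meaning attaches to the slot order.

`peak_distance` reports the circular separation of exactly two prominent
peaks (∈ (0, 180]), 0 for a single peak (merged pair of a steep bundle),
NaN otherwise.

Whole-image assembly caches results per unique profile byte-pattern
(uniform regions are common in phantoms and tissue backgrounds). Direction
maps use sentinel −1 (impossible in [0, 180) and exactly representable in
float32); all other maps use NaN. Flat pixels report zero peak counts and
sentinels everywhere except the average-intensity map.

The **axial median filter** replaces each pixel by the defined window
value minimizing the summed axial distance d(a,b) = min(|a−b|, 180−|a−b|)
(ties → smaller angle), computed brute-force over the ≤ 9 candidates.
This coincides with the ordinary median when the window's values span
< 90° and, unlike averaging, never blends the distinct directions of
crossing bundles; all-undefined windows stay undefined.

Directions are reported in the illumination-azimuth frame (mod 180). Any
fixed rotation or mirror needed to match a particular mounting is applied
explicitly via `--angle-offset` / `--mirror`.

## Synthetic generator

Profiles are `baseline + Σ_k w_k [G(φ − (φ_k − s_k)) + G(φ − (φ_k + s_k))]`
with G a wrapped Gaussian (three image terms; truncation error < 1e-12
for σ ≤ 60°), optionally times multiplicative noise (1 + ε),
ε ~ N(0, noise_sd), fully determined by the seed. Defaults: baseline 1,
weight 1, peak σ = 20° (the width scale of measured profiles), noiseless.
Half-separation s parameterizes inclination *only through its observable
signature* (s = 90° in-plane, s → 0 merged); no quantitative s↔α
calibration is claimed, since that relationship is not established.

Phantom presets `cross2(angle)` / `cross3(angle)` place straight bands
through the image center whose overlap carries the union of the bands'
bundles; overlap profiles are exactly the superposition of the single-band
profiles minus the shared baseline, mirroring stacked tissue layers.
Defaults: 40×40 pixels, band half-width one fifth of the image size.

What the generator does **not** emulate: speckle correlations, background
gradients, partial-volume mixtures at band edges, asymmetric or
non-Gaussian peak shapes, detector saturation, and inclined *crossing*
configurations. Tests passing on these phantoms therefore demonstrate
correctness of the evaluation chain, not robustness to every property of
measured tissue.

## Comparison utilities

Scatterometry comparison normalizes both profiles by min-subtraction then
division by the mean of the min-subtracted profile ("average signal
intensity" is read as the post-subtraction mean; the choice is localized
in `normalize_minmean`). Peak sets (SLI at 8 %, finely sampled references
at 3 % prominence) are matched by optimal one-to-one assignment on
circular distance with a 30° gate — the gate and assignment rule are this
package's choices; any gate well below the ~90° ambiguity scale gives the
same matches in practice. Profile difference is the sum of absolute
differences on the SLI grid after circular linear interpolation of the
reference.

Scattering patterns are blurred with a Gaussian whose FWHM equals the 8°
angular diameter of the illumination aperture (a `2σ = 8°` reading is
available behind a flag), azimuth treated circularly and the polar axis
clamped, then sampled on the θ = 48° ring (the SLI illumination polar
angle) with linear interpolation between rings.

Axial direction differences are wrapped to (−90°, 90°], with exactly
±90° reported as +90 by convention; retardation-binned spread uses
population standard deviation in bins of width 0.1 over [0, 1].

## Numerical choices and edge cases

- All angle arithmetic wraps explicitly (`% 360`, axial `% 180`); no
  trigonometric averaging is used anywhere in the direction rules, so the
  hand-computable rational examples are reproduced exactly.
- Interpolations are linear; evaluation heights are exact data arithmetic
  (value − prominence/2, value − 0.06·amplitude), so exactly tied flank
  values resolve deterministically for a given input.
- Width falls back to the full circle if a crossing is missing (possible
  only for zero prominence, which detection excludes).
- Problem sizes in the tests and acceptance script (40×40 phantoms,
  10,000 simulated profiles, 0.1° sweeps, exhaustive scans to length 8)
  were chosen as the smallest sizes at which the statistics are stable to
  well below their tolerances; the full suite runs in seconds.

## Known limitations

- No out-of-plane inclination estimate is produced; peak distance is
  reported as-is and its mapping to inclination is left uncalibrated.
- Inclined crossing bundles (4 peaks with pair separations far from 180°)
  are deliberately left directionless rather than guessed.
- The per-pixel chain is independent across pixels; no spatial
  regularization beyond the optional median filter.
- The pure-Python per-pixel loop handles desk-scale stacks comfortably;
  very large stacks (10⁷+ pixels) would warrant a vectorized driver.
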