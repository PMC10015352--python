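# Methods

`bilicam` is a desk-scale re-creation of a smartphone-based transcutaneous
bilirubin screening pipeline.  No clinical images exist for it by design:
every stage is exercised on synthetic calibration-card scenes whose ground
truth is known exactly, so the pipeline's claims (color calibration undoes
illuminant and camera differences; quality control catches specific capture
failures; calibrated skin color inverts to bilirubin) become measurable
statements about code.

## Skin optics forward model

Newborn skin is modelled as two plane-parallel layers: a finite epidermis
(default thickness 0.1 mm) carrying melanin, over a semi-infinite dermis
carrying whole blood (oxy/deoxy hemoglobin at saturation S = 0.7) and
bilirubin.  Diffuse reflectance uses the Kubelka–Munk two-flux closed form:
the semi-infinite dermis solution

    R_inf = a − sqrt(a² − 1),   a = 1 + K/S_km

backs the finite epidermis slab

    R = (1 − R_g (a − b·coth(b·S_km·d))) / (a + b·coth(b·S_km·d) − R_g)

with K = 2 µa and S_km = µs′ (the standard diffuse-illumination
identification).  The form is closed, fast, continuous, and monotone
decreasing in any absorber — the properties a lookup-table inversion needs.
It is not photon transport: no spatially resolved reflectance, no
anisotropy, no layer inter-reflection beyond the two-flux composition.

Chromophore spectra are analytic band approximations embedded as code
constants (no downloads): bilirubin as a Gaussian band at 460 nm
(σ 35 nm, 8·10⁻³ mm⁻¹ per µmol/L at peak — the amplitude folds the
tissue partition into a single effective coefficient); melanin as a
power-law `30·(λ/550)^(−3.3)` mm⁻¹ at unit volume fraction; hemoglobin as
Soret (415/430 nm) plus Q (542/577, 555 nm) bands at whole-blood
magnitude.  They reproduce the qualitative features that drive the method
— a blue-absorbing bilirubin band vanishing in the red, monotone melanin,
strong green blood absorption — not any specific published dataset.
Reduced scattering is `2.5·(λ/500)^(−1.3)` mm⁻¹; baseline absorption
0.015 mm⁻¹.  The wavelength grid is 400–700 nm at 5 nm (61 points).

The constants were fixed by a design sweep for a usable dynamic range:
Kubelka–Munk reflectance saturates as absorption grows, so the blue-channel
response flattens above ~300 µmol/L; the chosen amplitudes keep the
smallest local slope near 7·10⁻⁵ RGB units per µmol/L, which bounds how
hard high-bilirubin estimates lean on color accuracy.

## Rendering and the lookup database

Linear RGB is the inner product reflectance × SPD × channel sensitivity,
normalized per channel against the flat unit illuminant, so a perfect white
under the flat illuminant maps to (1,1,1) and tinted illuminants genuinely
tint the image (which is what calibration must undo).  Cameras are Gaussian
channel models: the canonical camera peaks at 600/540/465 nm (σ 35/35/28)
and an alternate at 603/543/465.5 nm with slightly broader channels.
Illuminants are flat, blackbody 4000 K ("warm") and 6500 K ("cool"),
scaled so a white reflector stays inside gamut.  These stand-ins were
chosen inside the regime where a linear 3×3 correction does correct
camera/illuminant differences to a few 8-bit counts — consistent with the
bench behavior the pipeline emulates (worst-case metameric residual
~2/255 over the cohort's skin states); markedly more divergent sensor
sets would need the root-polynomial correction instead.

The lookup database renders the chromophore grid under the canonical
condition: bilirubin 0–400 µmol/L step 10, melanin fraction 0.01–0.15 in
36 levels, blood fraction 0.005–0.05 in 24 levels, saturation fixed 0.7
(~35 000 entries, built in a few seconds, serialized as CSV + JSON
provenance).  The melanin/blood density matters: with coarse slices
(≤10 levels) the nearest neighbors of an off-grid skin color sit in the
wrong melanin/blood slice and the mismatch aliases into bilirubin,
inflating round-trip error several-fold.  Step sizes were set so grid
quantization contributes less error than sensor noise.

## Synthetic scenes

The card is 100 × 76 mm: 24 color patches — 16 from a fixed seeded
palette of smooth abstract spectra plus 8 skin-tone patches painted with
skin-model spectra at representative chromophore states (anchoring the
calibration fit for the skin spectral family roughly halves the metameric
residual on skin colors) — 8 gray patches, a 6-tone gray strip, a central
14 mm hole exposing skin, 4 corner fiducials (black squares with a white
center dot), and a 14-cell stripe barcode (dark/light sentinels + 12 data
bits).
Rendering is fronto-parallel with a similarity transform (pinhole scale
`f_px/d`, f_px = 1250, nominal distance 25 cm ⇒ 5 px/mm), painted in
linear RGB and sRGB-encoded to 8 bits at the end.  Corruptions apply in
order shadow → occlusion → lens blob → noise:

- shadow: multiplicative linear ramp, depth relative to the card extent
  (default 0.3);
- occlusion: card-frame rectangle of constant color (fabric-like default);
- lens blob: soft Gaussian darkening (σ 6 mm, depth 0.5), compact so it
  reads as localized darkening rather than a gradient;
- sensor noise: additive Gaussian in linear RGB, sd 0.005 (default).

A cohort draws bilirubin from a truncated normal (mean 178.2, sd 76.5,
range 13–367 µmol/L — the distribution of the reference population the
statistics mirror), melanin ~ U(0.02, 0.13), blood ~ U(0.008, 0.045), and
sets reference TSB = bilirubin + N(0, 5 µmol/L) lab noise.  Image sets
default to 3 flash + 3 no-flash frames; flash is ambient SPD plus a
flat-spectrum boost (weight 0.7), renormalized.

What the generator deliberately does not emulate: skin texture and
curvature, body geometry, lens distortion, demosaicing/tone-mapping ISPs,
real QR symbology, specular highlights.  Passing tests therefore show the
pipeline's logic is correct under its stated image formation model — not
that the thresholds transfer unchanged to clinical photographs.

## Card processing

Fiducials are found by thresholding dark pixels (luminance < 0.10 linear)
and keeping connected components with one hole (Euler number 0),
square-ish bounding box, plausible area, and no border contact; exactly
four must survive or the image fails "card not detected".  Canonical order
is by angle around the centroid starting nearest the image top-left.  A
projective transform fitted to the four marker correspondences maps card-mm
into pixels; each patch region is its rectangle shrunk 20 % per side, the
hole a circle shrunk 25 %.  Samples are trimmed means (central 60 % by
luminance rank) of sRGB-decoded linear pixels; the full-region channel SD
above 0.06 flags a patch missing (occluders, specks).  Distance comes from
marker pixel pitch via the pinhole relation.  Barcode cells are read at
their centers; sentinel contrast below 0.15 means "absent".

## Calibration

A linear 3×3 matrix (no offset) is least-squares fitted from observed
patch colors to the reference colors (patch spectra rendered under the
canonical condition), so calibrated colors live in the lookup database's
space.  No offset keeps the map exposure-scale invariant; a degree-2
root-polynomial (6 features, still scale-invariant) is available for
harder sensor mismatches.  Grays are not up-weighted.  Leave-one-out
refits give per-patch prediction residuals; the damage signal is the
residual after intensity normalization (chromaticity), because any
channel-uniform spatial gain — shadow, vignetting — cancels under a linear
no-offset transform, while a recolored patch cannot.  Cross-validation is
two-pass: first-pass outliers (chromaticity residual > 0.03) are excluded
from every other patch's second-pass fit, so one damaged patch does not
bleed into its neighbours' residuals.

## Quality control

Eight checks per image, geometric before colorimetric; when the card is
not detected the rest are "not evaluated"; the first failing check names
the exclusion code, so codes partition excluded images.  The two
illumination checks share the gray-patch gain field (observed/reference
luminance per gray patch): its planar component (shadow) is separated from
localized residuals (lens blob) by a least-median-of-squares plane fit over
all point triples with an inlier refit — ordinary or trimmed least squares
has bad local minima here, where a tilted plane keeps its own outliers.
The same plane flat-fields patch samples before the damage check.

Thresholds (no clinical values exist; all in config): distance 25 ± 5 cm;
planar gain range > 0.15 fails shadow; plane residual < −0.15 fails
lens_clear; max LOO chromaticity residual > 0.03 fails card_undamaged; the
calibrated hole color must sit inside the convex hull of database colors
dilated by 0.02 (skin plausibility — rejects non-skin objects in the
hole).  They were tuned jointly with the renderer's default corruption
severities so that each corruption trips exactly its designated check
(verified over 100 seeded fixtures per corruption).  Set inclusion is
m-of-n: 3-of-4 for the four-frame protocol, 4-of-6 for the
3-flash/3-no-flash protocol.

## Inversion

Per image: detect → sample → calibrate → QC → estimate.  The estimate is
the inverse-distance-weighted mean bilirubin of the k = 5 nearest database
entries in linear-RGB distance (ε = 10⁻⁹ guard; an exact color match
returns its entry's value; queries farther than 0.02 from every entry are
flagged extrapolated).  Local averaging marginalizes small melanin/blood
mismatch between subject and grid.  The set estimate is the median over
QC-passing frames (robust to one aberrant frame), flash and no-flash
pooled after calibration; a set failing the inclusion rule carries no
estimate, only failure codes.

## Statistics

Conversion: 1 mg/dL = 17.1 µmol/L, rounding only at presentation.
Agreement: Pearson r (two-sided t transform) and Bland–Altman bias with
limits of agreement bias ± 1.96·sd(differences) (sample sd, n−1); the
limits are reported as the interval expected to contain ~95 % of
differences.  Screening: empirical ROC with the strict predicate
score > cutoff over all distinct cutoffs, trapezoid AUC (equal to the
tie-aware pair-counting identity), Youden cutoff = argmax(sens + spec − 1)
with the smallest cutoff on ties; severe hyperbilirubinemia is
TSB > 250 µmol/L.  Group comparison: tie-corrected Kruskal–Wallis H with
Dunn pairwise z tests on mean ranks, Bonferroni-adjusted.  Recruitment
accounting supports both 1-decimal and integer percentage styles.

## Problem sizes and reproducibility

The shipped verification runs use: a 100-subject cohort (6 frames each)
for round-trip recovery, 20 skin states × 3 illuminants × 2 cameras for
calibration invariance, 100 fixtures per corruption for the QC matrix,
200 random instances for the AUC identity and 10 000 draws for the
limits-of-agreement coverage.  All randomness flows from explicit seeds;
rebuilding a database or re-rendering a scene with the same inputs is
byte-identical.

## Known limitations

- The optical model and chromophore curves are self-contained stand-ins;
  absolute bilirubin accuracy against real skin is out of scope by
  construction.
- The skin-plausibility hull test stands in for a rash/texture check; it
  only sees color.
- Fiducials are synthetic donut squares, not real QR codes; the barcode is
  a 12-bit stripe, enough for an id channel.
- The estimator's blue-channel signal compresses above ~300 µmol/L
  (reflectance saturation), so errors grow toward the top of the range.
  A consequence: although calibrated skin *colors* agree across
  illuminants/cameras to ~2/255 per channel, the inversion amplifies
  those sub-count metameric residuals into bilirubin spreads of tens of
  µmol/L at high concentrations, so per-subject estimates are not
  illuminant-stable to better than roughly the method's limits of
  agreement.  Screening-level agreement (correlation, AUC) is unaffected.
- QC thresholds are calibrated to the renderer's corruption severities and
  would need re-tuning on real capture data.
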