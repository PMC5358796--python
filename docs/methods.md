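# Methods

This package quantifies subchondral bone changes in osteoarthritis (OA) on
2D histological sections: it thins a hand-drawn band around the
bone–cartilage interface (BCI) to a ~3-px mask, derives a local orientation
for every interface pixel from its local binary pattern (LBP), reduces the
orientation field to two scalars — the Shannon entropy of the angle
distribution and the homogeneity of an angle-level co-occurrence matrix
(ALCM) — measures layer thicknesses at five evenly distributed random
points, and runs the grading statistics (ICC, one-way ANOVA with Tukey HSD,
Welch t-tests, OLS regression) that relate a four-stage subchondral bone
grade to the OARSI cartilage grade. Because the underlying study images are
not redistributable, a synthetic-data module generates osteochondral
phantoms and study tables with the statistical structure the analysis
expects; every stage is tested against those phantoms and against
brute-force oracles.

## The synthetic osteochondral section

A section is a stack of horizontal layers — background, uncalcified
cartilage, calcified cartilage, subchondral plate, then a trabecular
bone/marrow compartment — with one thickness per layer drawn from the
grade's normal distribution (truncated at zero) and layer boundaries
displaced by a random-phase sum of three sinusoids. The per-grade thickness
and OARSI parameters are the published group means ± SD for human tibial
plateau samples (plate 58±28, 176±87, 473±229, 1245±448 µm for grades 0–3;
calcified cartilage 84±69, 104±62, 128±50, 36±46 µm; cartilage 2374±506,
1753±615, 1826±1268, 82±142 µm; mean OARSI 1.46, 3.45, 3.99, 5.19).

Parameters that the source material describes only qualitatively were fixed
once, as follows:

* **Roughness.** Wavelengths (400, 100, 25) µm, geometrically spaced;
  component amplitudes ∝ √wavelength, normalized so their root-sum-square
  equals the profile's `roughness_amplitude`, making the column-wise
  displacement SD equal amplitude/√2. The long component undulates the
  boundary; the 25 µm component supplies the pixel-scale jaggedness of a
  fibrillated plate. Amplitudes per grade: 6, 25, 60, 5 µm — rising to
  grade 2 (fibrillation) and dropping at grade 3 (smooth, worn plate),
  which is the qualitative ordering the interface descriptors must
  reproduce.
* **Fenestrae.** Open plate gaps at Poisson rates 2.0 and 0.8 per mm of
  width for grades 0 and 1 (none above), each 20–60 µm wide, replacing
  calcified cartilage and plate with marrow so cartilage contacts the
  marrow space.
* **Optics.** Per-label stain-channel intensities (bone 210, calcified
  cartilage 130, cartilage 90, marrow 55, background 15 on an 8-bit scale;
  invertible for stains with opposite polarity), a Gaussian point-spread
  blur of 1 px, and additive Gaussian noise of SD 6. The blur matters:
  without it, flat tissue plateaus are exact intensity ties, and the
  tie-counting LBP operator degenerates under any noise.
* **Pixel size.** No magnification-to-µm calibration is available for a ×5
  objective in general, so pixel size is an explicit parameter everywhere;
  8 µm/px is the package's working value for phantoms (a 384-px view then
  spans ~3 mm, one microscope field).
* **Study table.** Each patient contributes three samples cycling through
  the harvest-site categories; bone grades are drawn from per-site mixtures
  chosen to reproduce the reported site-level mean OARSI (≈2.1/4.4/5.3).
  Under any mixture anchored at the published per-grade OARSI means, this
  makes the overall OARSI SD ≈1.65, larger than the reported 1.31 — the two
  published summaries are not simultaneously matchable, and the site means
  were prioritized. Replicate rater scores are the true grade plus rounded
  Gaussian noise clipped to 0–3; the default rater SD of 0.28 was derived
  so that the simulated inter-rater ICC is ≈0.97, the reported reliability
  (clipping at the scale ends absorbs about half the nominal flips, which
  is why the value exceeds the naive 0.17 a continuous-scale calculation
  suggests). Interface descriptors are linear in OARSI (entropy
  +0.16 bits/grade from 1.4; homogeneity −0.032/grade from 0.86) with
  Gaussian residuals (SD 0.18 bits and 0.0385) sized so the population R²
  over the analyzable range (OARSI < 5) is ≈0.6 with the reported signs.
  Samples at OARSI ≥ 5 carry no descriptors (no remaining cartilage to
  segment).

What the phantoms do **not** emulate: real Safranin-O chromatics and stain
variability, tidemark duplication, osteophytes, vascular invasion, section
artefacts (tears, folds, debris), and 3D context. Passing tests therefore
demonstrate that the measurement chain recovers known geometry and known
statistical structure — not that it is robust to every histological
artefact; on real slides the manual band remains the artefact filter.

## Interface segmentation

The thick band (7 px nominal) either comes from a mask file or is derived
from a phantom's layer map: the boundary is each column's top subchondral
plate pixel with calcified cartilage directly above, dilated to Chebyshev
radius 3. Columns without a boundary — open fenestrae — and a half-width
margin around them carry no band, the way a manual tracing stops short of a
gap instead of wrapping around its corner. Band pixels are classified
bone/cartilage by Otsu's threshold computed from band intensities only (or
a fixed threshold), and the classification is thinned by the opposite-class
test: a pixel stays iff its 8-neighbourhood within the band contains the
other class. On smooth boundaries this yields the two one-pixel boundary
layers plus corner-touching pixels (~3 px); on an exact 45° edge, diagonal
adjacency keeps a fourth layer.

## LBP orientations

Each interior interface pixel's eight radius-1 neighbours are thresholded
at the centre value, ties counting as set — which makes the operator
invariant to adding a constant to the image and, together with the pure
ordering comparisons, to any monotone intensity rescaling. The 8-bit
pattern maps to an axial angle in [0°, 180°):

* Patterns whose set flags form one contiguous compass arc (the "uniform"
  patterns) are edge patterns: the plain vector mean of the set flags
  points at the locally bright side, and the reported angle is the
  perpendicular axis. A pixel whose brighter neighbours are SW, S, SE lies
  on a horizontal interface → 0°.
* All other patterns have bright flags on multiple sides (ridges,
  saddles); their plain mean can cancel (E+W), so their flags are averaged
  as axial directions with the angle-doubling trick and the angle is half
  the resultant direction: E+W → 0°, N+S → 90°, NE+SW → 45°.
* A pattern is undefined when it has no orientation content: zero or eight
  flags, or a balanced multi-sided pattern (e.g. all four cardinals) whose
  doubled and plain resultants both vanish.

Pure doubling alone is not usable here: the eight compass directions
collapse onto four doubled axes, so every contiguous 4-arc — the generic
pattern of a pixel sitting dead on a straight edge — cancels exactly, and
near half the pixels of a sloped interface would be undefined. The full
256-pattern table is exported (`pattern_angle_table`) so the mapping is
auditable, and the test suite checks it against an independent
enumeration.

Angles are binned into 8 uniform bins of 22.5° over [0°, 180°) by default
(configurable); border mask pixels are dropped with a count.

## Interface descriptors

* **Entropy** H = −Σ pᵢ log₂ pᵢ of the angle histogram (0·log 0 = 0),
  0 bits for a single occupied bin up to log₂ B for uniform; natural-log
  base available.
* **ALCM and homogeneity.** Every unordered 8-adjacent pair of
  defined-angle interface pixels increments both (i,j) and (j,i) of a B×B
  matrix, pooled over all directions (rotation of the section permutes
  directions but not the matrix) and normalized to sum 1. Homogeneity is
  Σ P(i,j)/(1+d(i,j)) with d the **circular** bin distance
  min(|i−j|, B−|i−j|) by default: orientations are periodic, and a
  near-horizontal interface scatters angles on both sides of the 0°/180°
  seam — with a linear distance those near-identical orientations would
  count as maximally dissimilar and the grade ordering of real interest
  inverts. The linear distance remains available (`circular=False`).

On default phantoms the two descriptors order the grades the way the
disease does: mean entropy ≈1.6 → 2.4 → 3.0 bits and mean homogeneity
≈0.72 → 0.67 → 0.61 across grades 0–2, with grade 3 (smooth worn plate)
reverting toward grade-0 values; 20 seeds per grade reproduce this
ordering reliably.

## Morphometry

Thickness is the vertical chord: the count of pixels carrying the layer's
label in a column times the pixel size, measured at five columns — one
uniform draw inside each fifth of the view, so the points are random *and*
evenly distributed. The same five columns serve all three layers. A column
through a fenestra contributes 0 µm and is flagged rather than resampled,
so exclusion is the caller's choice. Group summaries report n, mean, SD
and SE = SD/√n per bone grade; fold changes are ratios against the grade-0
mean with a rounded integer fold (176/58 → 3.03 → "3-fold"; 1245/58 →
21.5 → ">21-fold").

## Statistics

ICC for grading repeatability is the two-way mixed-model, single-rating,
consistency form — ICC(3,1) = (MS_rows − MS_error)/(MS_rows +
(k−1)·MS_error) — because the same fixed raters score every sample; it is
undefined (NaN with a warning) without between-sample variance, and the
report labels it inter-rater consistency since the rating columns are
raters. ANOVA, Tukey HSD, the independent t-test (Welch by default, as the
printed per-grade SDs are plainly unequal) and OLS regression delegate to
scipy; every statistic is pinned to a brute-force oracle (explicit sums of
squares, studentized-range tail, normal equations) at 1e-10 in the tests.
The study report excludes grade-3 samples from descriptor group
comparisons (worn smooth surfaces) and samples without descriptors
(OARSI ≥ 5), counts every exclusion, annotates p-values in the figure
convention (* p<0.05, *** p<0.001), and computes the cohort OARSI both
ways (per-sample and per-patient means) where applicable — the packaged
patient table reproduces a mean of per-patient means of 4.07.

## Numerical choices and degenerate inputs

Angles live in the half-open interval [0°, 180°); values within 1e-9 of
180° are folded to 0°. The resultant-vanishing threshold is 1e-9. Otsu
classification refuses constant bands; interface extraction returns an
empty mask with a warning when the band holds one class; the angle field
refuses empty masks and reports border-dropped and undefined counts; ALCM
refuses fields without adjacent defined pairs. Sections whose drawn
thickness cannot fit the raster raise an error naming the offending layer;
the pipeline redraws such sections (and ones whose calcified cartilage
pinched away) with fresh seeds and reports the count. All randomness
descends from one root seed through a master generator, so a run is
reproducible from (config, seed) alone.

## Problem sizes

Phantom-based tests use 256–384 px sections at 8 µm/px with 12–20 seeds
per condition; recovery tests use simulated studies of 1500 patients
(≈500+ samples per grade); the acceptance script uses 20 phantom seeds per
grade and the same study sizes. These sizes give the descriptor orderings
and 2-SE recoveries comfortable margins while keeping any single test run
in seconds.

## Known limitations

The pattern→angle mapping and bin count of the original method are not
published; the package's choices are documented above and shipped as an
auditable table, but absolute entropy/homogeneity values are therefore not
comparable to the original study's — only signs, orderings and correlation
structure are. Thickness is a vertical chord, not a boundary-normal
distance, so it overestimates on steeply sloped layers. The ICC is
computed from rater columns as inter-rater consistency; the original
study's repeat structure (labelled intra-observer) is unknown. Grade-3
phantom sections at the default raster occasionally cannot host the drawn
plate and are redrawn, which slightly trims the upper tail of rendered
grade-3 plate thickness (table-based statistics are unaffected).
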