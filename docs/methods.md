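# Methods

This note documents the models and procedures implemented in `underice`,
the parameter choices where the design was genuinely open, and what the
synthetic data do and do not establish about field data.

## Synthetic campaigns

The generator emulates a winter IFCB deployment on a moored profiler:
syringe draws of 5 mL recurring every sampling period per depth (default
25 min at 2/4/10 m and 125 min at 15 m, i.e. ~5× higher shallow
frequency), each draw yielding a Poisson number of particle images per
taxon with mean `abundance_trajectory(t) × exp(−depth/depth_scale)`.
Samples start at the campaign start and recur every period; the last
partial interval is dropped, so a 1-day campaign at 25 min holds 57
samples.

Six taxon models follow the canonical morphologies of common winter
diatoms: rods fanned from a common origin (star colonies,
*Asterionella*-like), single long thin rods (needles, cf. *Synedra*),
cells stacked side by side (ribbons, *Fragilaria*-like), rods chained end
to end at alternating ±40° (zigzags, *Tabellaria*-like), circular disks
(round centric diatoms), and a wide cylinder whose silica shell is so thin
that, with probability `frustule_loss_prob`, only 2–4 small chloroplast
blobs are rendered (*Urosolenia*-like). Ground-truth biovolume is always
the analytic volume of the generating solid — π(w/2)²·L per cylindrical
cell, summed over colony cells, or (4/3)πr³ for disks — including for
fragment renders, whose *estimated* biovolume is then necessarily far
smaller. Whole organisms are clamped to ≥ 10 µm rendered extent (the
instrument's trigger threshold); fragments may be smaller. A configurable
flash-lamp step multiplies the fragment rate after a given date, emulating
a mid-season change in illumination intensity.

Default seasonal trajectories vary by a factor of ~4–8 within the season
(peaks, declines to ~15–25% of peak), matching the order-of-magnitude
seasonal contrast winter series show in the field; sizes are lognormal
with ~10% spread. Rendering uses Gaussian background noise (mean 30, σ 6
on 8-bit counts) with object intensities near 170; the default pixel scale
is 1.0 µm px⁻¹ and is configurable, as the real optical pitch and imaged
volume fraction are instrument calibration constants.

Three environmental scenarios exercise both outcomes of the mixing
diagnostic. `stable_winter`: inverse stratification (0.8 °C at surface to
3.5 °C at depth, all < 4 °C) with a strong near-surface gradient and weak,
snow-attenuated light — stable layers are detected, convection never.
`clear_ice_heating`: a thin cold stable layer over a nearly isothermal
~2 °C interior with strong midday light — convection is diagnosed at
midday. `isothermal_autumn`: a uniform 6 °C column — no stable layer at
all. Irradiance is spectrally flat across ten channels spanning
398.76–700.04 nm, attenuated as exp(−k_d·z), with a diel half-sine (zero
at night) and a seasonal envelope.

What passing tests on these data show: that the estimators, the selection
grid, the filter, the gridding rules and the convection logic are
implemented correctly and recover known inputs. What they do not show:
performance on real IFCB imagery (optical blur, debris, attached
epibionts, 100+ category richness), real winch noise, or the real lake's
abundances — those require field data.

## Biovolume from a 2-D silhouette

Each connected component of the mask is rotated so its second-moment major
axis is horizontal; every pixel column then crosses the silhouette in
runs, and each run pixel contributes π·d, where d = min(i, n−1−i) + 0.5 is
its 1-D distance to the run end. A run of n pixels therefore contributes
exactly π(n/2)² — the area of the disk swept by revolving the local
half-width about the run midline. Summing columns recovers πr²L for
rasterised rectangles exactly and (4/3)πr³ for disks to within the
rasterisation error (≲ 2% at r = 20 px); random ellipses agree with
brute-force voxelisations of their generating ellipsoids within 10%.
Biovolume scales exactly as pixel_scale³. For branched or overlapping
colonies the revolved-silhouette reading overestimates (a ribbon of n
touching cells reads as one thick cylinder, ≈ n× the summed per-cell
volume); this is intrinsic to single-silhouette biovolumetry, is shared by
the field's standard estimators, and cancels in within-class *relative*
series, which is what the time-series stage interprets. Colony biovolume
is reported per image; cells within colonies are never counted.

Segmentation thresholds at max(Otsu, floor) with floor 80 counts: the
floor keeps Otsu from splitting pure-background frames. Masks are closed
with a radius-1 disk and specks under 4 px dropped. Features are computed
over the union mask (a colony is one particle) in a fixed, versioned
order; axis lengths come from the mask's normalised second moments, and
`number_of_blobs` exposes fragment structure to the classifier.

## Classifier selection

Training sets are balanced per category: below `min_n` images a category
is excluded (reported), above `max_n` it is subsampled reproducibly by
seed; the catch-all 'Other' is never trained on. The selection grid takes
the full Cartesian product of minima {200..500 step 100} × maxima
{300..900 step 100} × trees {25, 50} — 28 ranges, 56 candidates; pairs
with max < min are enumerated but recorded as failed candidates rather
than trained. Each viable candidate is scored on a stratified 80/20
hold-out with a fixed seed (the original evaluation protocol being
unrecorded, a held-out split is the conservative default). Two metrics are
kept: error rate over *accepted* classifications and the unclassified
fraction over all images. The winner minimises the error rate, with ties
broken by lower unclassified fraction, fewer training images, then fewer
trees — exactly the two reported quantities, in that order of priority.

Voting is per-tree plurality (not averaged probabilities): an image gets
the class most trees chose, provided the winning fraction clears
`vote_threshold` (default 0.5, configurable — the rejection rate is
reported in the field but the threshold itself is not); otherwise it is
'unclassified'. Ties break to the lexicographically first class name.
Bagging, bootstrap resampling and seeded determinism come from
scikit-learn's `RandomForestClassifier`.

Verification scheduling draws 3 samples without replacement per 14-day
window (fewer where a window is short), reproducibly by seed; comparison
against a manual assessor returns the confusion matrix, per-class counts
and agreement rate. In tests the "manual" labels are the generator's
ground truth.

## Water-column physics

Volumetric salinity sums the mass concentrations of the eight major ions,
the carbonate species partitioned from a single DIC value by pH using a
two-pK equilibrium (pK1 = 6.35, pK2 = 10.33), and the H⁺/OH⁻ masses
implied by pH itself. Density follows a Chen–Millero-type limnological
polynomial (coefficients in `data/eos_chen_millero.json`): a sixth-degree
freshwater curve with single interior maximum at 3.98 °C, a linear dilute
salinity correction, and a secant bulk-modulus pressure term. α is a
centred finite difference of that polynomial (step 0.01 °C), so it is
consistent with the density operation by construction; c_p is the standard
freshwater polynomial (4.2 kJ kg⁻¹ °C⁻¹ ± 5% over 0–10 °C) with a small
salinity term. Valid ranges are enforced (−1–40 °C, 0–10 g L⁻¹,
0–500 dbar); g = 9.81 m s⁻².

Scalar radiation at depth trapezoid-integrates the spectral planar
irradiance over 398.76–700.04 nm (µW cm⁻² nm⁻¹ → W m⁻², ×0.01) and
divides by 0.75 to approximate scalar from planar irradiance.

Stability is evaluated on **potential** density (EOS at a common reference
pressure, surface by default): in-situ density would add an adiabatic
compression gradient of ~0.005 kg m⁻⁴ even to a perfectly mixed column
and corrupt both the layer criterion and N². Density is resampled to
0.5-m intervals from the first valid depth (typically 1 m); an interval is
stable iff ∂ρ/∂z > 0.01 kg m⁻⁴ (threshold configurable), and the layer
thickness h is the maximal contiguous stable run from the first valid
depth — if the very first interval fails, no layer is diagnosed at all.

The convection test evaluates, at the layer base (the convective test
depth): buoyancy flux b = −g·α·Q/(ρ·c_p), positive when cold (α < 0) water
is heated — the convection-driving sign; convective velocity
w\* = (b·h)^{1/3} for b > 0, else 0; and buoyancy frequency
N² = (g/ρ)·∂ρ/∂z taken from the density gradient in the first interval
**below** the layer base — the stratification a forming convective layer
must overcome, per the picture of convective cells growing *under* the
stable surface layer. (A `n2_mode="layer"` switch uses the within-layer
mean gradient instead; note that with that reading the joint condition is
unreachable wherever a layer exists, since any gradient above the 0.01
threshold forces Ri into the tens at under-ice irradiances.) Then
Ri = N²·h²/w\*² (∞ when w\* = 0) and convection is diagnosed iff Ri ≤ 1
and b > 0. Q in b is the flux at the test depth; a layer-absorbed
difference is a documented alternative left to the caller via the Q
profile. Degenerate inputs: no layer → the season driver records a
diagnosis with h = None and convective = False; fewer than two valid
depths → warning and no layer.

## Gridding rules

QC rejects empty casts, non-monotone depth records and physically
impossible values, always returning a per-cast log. Irradiance gaps are
filled per channel by regressing ln E_d on depth over the observed
positive values and exponentiating the fit at missing depths only
(< 2 positive values → unfilled, with a warning); on a two-point bracket
the fill is exactly the geometric interpolant. Sections interpolate depth
first (linearly, onto 0–18.5 m × 0.1 m — 186 rows — masked outside each
cast's observed range), then time: each cast snaps to its nearest 20-min
grid time, and grid times strictly between two consecutive casts ≤ 6 h
apart are linearly interpolated. Longer gaps and section edges are
masked — the 6-h cap is read strictly, as *between consecutive casts
only*, to avoid bridging winch outages; the grid-time origin is midnight
of the campaign start.

## Aggregation

Per sample and class, biovolume per mL is the sum of image biovolumes
divided by the analysed volume (syringe volume × a configurable imaged
fraction, default 1). Requested classes absent from a sample report 0;
'Other' and 'unclassified' remain explicit series, and an explicit 'Total'
row sums everything. The ±12 h moving average is a centred mean over all
samples of the same depth and class inside the window. The small-image
filter (strictly < 61 µm³, default class *Urosolenia*) is applied after
classification to the named class only and is idempotent.

## Problem sizes used in the test suite

The shared end-to-end season runs 6 taxa × 3 depths × 56 samples at a
12-h cadence over 28 days (~3,500 campaign images) with a 230-image-per-
category training database and a reduced 8-candidate selection grid; the
trajectory-recovery check pools depths per class and applies the ±12 h
smoothing before computing Spearman rank correlations. These sizes give
the statistical checks comfortable power while keeping a full run to tens
of seconds; the full 56-candidate grid is exercised separately at the
enumeration level and through degenerate-pair handling.

## Known limitations

No optical/PSF simulation of the flow cell; a documented ~15-feature
subset instead of the upstream code's several hundred features;
single-silhouette colony biovolume biases (above); no heat-budget or
ice-growth modelling; trajectories and scenarios are smooth parametric
forms, not resampled field series.
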