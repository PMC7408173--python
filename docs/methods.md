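# Methods

## Scope and design

The package quantifies three families of nuclear-reassembly readouts —
fixed-image morphology/intensity, live-imaging event timing, and protein
sequence conservation — and pairs them with a synthetic generator that
produces the same data shapes with exact ground truth. The guiding design
rule is that every measurement operation must be checkable against an
independent oracle: painted region means for intensity metrics, generative
hole indicators for detectors, continuous durations for quantized dwell
times, and closed-form distribution medians for summaries.

## Synthetic image model

Nuclei are smoothed star-convex blobs: the boundary radius is perturbed by
angular harmonics 2–6 with total relative amplitude bounded by
`shape_irregularity` (default 0.08), which exercises irregular-outline
handling without leaving the star-convex regime that the single-threshold
segmentation recipe assumes. Nuclei are placed by rejection sampling with a
border margin and a pairwise gap, so fields are non-touching by construction
(declumping is explicitly out of scope). Defaults: 50 ± 5 px nucleus radius
(chosen so the 20-px periphery band is a realistic minority of nuclear
area; no pixel calibration is implied — all px values here are simulation
fixtures), chromatin level 180 over a cytoplasmic background of 20, and
16-bit output.

Chromatin voids model both nucleoli and the larger cell-free-assay "holes";
they share one mechanism and differ only in radius distribution and
prevalence. Voids are circular, strictly interior (≥ 4 px clearance from
the boundary) and mutually separated by ≥ 6 px, so that a ~1.5-px detection
blur can neither merge neighbouring voids nor push them onto the boundary.

Marker channels are painted region-by-region from a `MarkerSpec`: nuclear
and cytoplasmic means, a multiplicative periphery-band enrichment, a
nuclear-envelope toroid enrichment and a nucleolar factor (0 = excluded
from nucleoli). The noise model is additive Gaussian "camera" noise
(default sd 8) on piecewise-constant means; no shot noise, no PSF. This is
deliberate: the quantities under test are threshold and region-mean
statistics, which Gaussian noise stresses adequately, and with noise sd 0
the painted means are recovered *exactly*, which the test suite exploits.
Ground truth records the label map, void label map, per-void geometry and
the brute-force pre-noise mean of every channel over every region. All
randomness flows from `seed`; identical config + seed is bit-identical.

What the generator does **not** emulate: optical blur at object boundaries,
intensity gradients, shading, touching nuclei, mitotic figures, 3D
structure, photobleaching. Passing tests therefore demonstrate correctness
of the measurement definitions and robustness at realistic SNR, not
performance on degraded real micrographs.

## Segmentation and ROIs

Segmentation recipe: Gaussian smoothing (σ = 2 px) → global Otsu → fill
holes → 4-connected components → minimum area 500 px² → border objects
dropped (band and ring ROIs are undefined off-field). Otsu on the smoothed
histogram makes the label map invariant to intensity scaling. Hole-filling
runs before ROI derivation so nucleolar voids do not perforate the nuclear
outline. On noiseless piecewise-constant images the smoothing step itself
moves the boundary by a fraction of a pixel on curved outlines; exactness
tests therefore disable smoothing, while default-noise tests require
IoU ≥ 0.9 against ground truth.

The "periphery" ROI is read as the 20-px-wide **annulus** between the
outline and its 20-px shrink — not the shrunken core — because the
radial/peripheral ratio divides the periphery mean by the whole-nucleus
mean to measure peripheral enrichment; the core reading would make the
ratio insensitive to the band. Shrink/expand use Euclidean
distance-transform thresholding rather than iterative pixel erosion:
pixel distances are metric, and the diagonal bias of iterative erosion
would distort band areas by several percent. A nucleus too small for the
20-px shrink keeps its whole mask as the band and is flagged degenerate;
degenerate nuclei are excluded from ratio summaries by callers.

The cytoplasm background ring (5–20-px expansion) excludes pixels within
20 px of any *other* nucleus. Two plausible exclusion radii exist (the
other nuclei's 5-px expansions, or their full 20-px background distance);
the stricter 20-px rule is used since it prevents neighbour bleed-through
into background estimates and subsumes the weaker rule.

## Intensity metrics

Background subtraction applies to the two intensity metrics
(nuclear, NE) only; the radial/peripheral ratios are computed on raw means
by definition. "Radial distribution" and "peripheral distribution" are two
names for the same periphery/nucleus mean ratio and are emitted as two
equal columns rather than inventing a distinction. H2A.Z intensity is the
background-subtracted nuclear mean — the same convention as every other
marker. Empty-ring nuclei keep raw means, get NaN subtracted intensities
and a flag. Consequences that the property tests pin down: adding a
constant to a channel leaves subtracted intensities unchanged and drives
the raw ratio monotonically to 1; scaling a channel scales subtracted
intensities and leaves ratios unchanged.

## Nucleolus ("chromatin hole") detection

Per nucleus: min–max rescale of the intra-nuclear chromatin signal to
8-bit (per-object, mirroring how display conversion behaves on a cropped
object, and making per-object Otsu meaningful), Gaussian blur σ = 1.5 px,
Otsu, inversion (particles = dark side), 4-connected particles, size
filter. Three numerical guards replace the judgment a human applies in the
manual workflow:

- **Contrast gate** — if the Otsu classes separate by < 2 within-nucleus
  SDs of the blurred signal, the histogram is treated as unimodal (camera
  noise alone separates by ~1.6 SD; a true void by far more) and the
  nucleus reports zero nucleoli with a `weak_contrast` flag.
- **Blur-corrected minimum size** — the blur dilates dark particles by
  roughly σ, so the ≥ 20 px² rule is applied to the equivalent disk eroded
  by σ; otherwise sub-threshold specks inflated by the blur would pass.
- **Boundary rule** — particles touching the nuclear boundary are
  background leakage (the blur drags exterior darkness inward) and are
  discarded.

Detected void areas run ~10–15% above painted areas at σ = 1.5 (tests use
a 15% tolerance). The nucleolus-vs-nucleus signal ratio is a sum ratio,
bounded in [0, 1] for nonnegative channels and scale-invariant.

## Cell-free assay scoring

Hole and dextran-penetration calls were made visually in the original
workflow; here both are formalized as relative-intensity rules with
declared, tunable constants. A substrate has a hole iff some interior
connected region of the blurred chromatin falls below 0.35 × the nuclear
median with area ≥ 100 px²; a structure is dextran-positive iff its mean
interior dextran reaches 0.5 × the mean of the 5–20-px surrounding
annulus. Both calls are invariant to global intensity scaling, and the
dextran call is monotone in its threshold. Prevalences follow the
replicate convention: with experiment labels, the mean of per-experiment
percentages and their SD; otherwise the pooled percentage.

## Track timing

Anaphase onset is the first `ana`-labelled frame; the end of mitosis is the
first `inter` frame after the last `telo` frame (tracks that skip `telo`
fall back to the last `ana`). Tracks never reaching interphase are
censored: excluded from medians, counted separately, and visible as a
sub-100% plateau in the cumulative curve, which is exactly the ECDF of the
duration multiset scaled to percent of all tracks. Medians use the
standard midpoint convention. An optional width-1 majority filter smooths
single-frame annotation flickers (off by default). Measured durations obey
the quantization identity `measured = Δt · ceil(d/Δt)` per track.

### Condition fixtures

Continuous exit durations are lognormal with σ = 0.25 (≈ 25% CV, a
realistic cell-to-cell spread for mitotic timing). Because reported
medians are frame-quantized observations, each fixture's continuous median
sits at the midpoint of the reported value's 3-minute quantization bin:
control 19.5 min (→ 21 min at 3-min frames, 20 min at 1-min frames),
H2A.Z-oligo-C 29.5 min (→ control + 10 min offset), and pontin/reptin/
double-depletion fixtures at 28.5/37.5/34.5 min. The mapping of the three
depletion medians to conditions follows their reporting order; the
fixtures' N/C import series use an exponential approach to a plateau,
`ratio(t) = 1 + (plateau − 1)(1 − e^{−t/τ})`, purely as a smoke-testable
kinetic shape.

## Statistics

The gate: every group is tested with the D'Agostino–Pearson omnibus test;
the parametric path (one-way ANOVA, then Dunnett many-to-one) runs only
when **all** groups pass at p > 0.05 — the conservative combination, since
one non-normal group invalidates ANOVA's assumptions for the whole family.
Groups with n < 8 cannot be tested for normality and force the
nonparametric path with a flag. The nonparametric path is Kruskal–Wallis
followed by Dunn's rank z-tests against the control with tie correction,
Bonferroni-adjusted over the control comparisons only (the design compares
each group to control, not all pairs; Dunn's test is implemented in-package
on the standard rank-statistic formula). Two-group tests default to Welch's
unequal-variance t (the safer choice when variance homogeneity is
unverified) with a pooled-variance toggle.

## Conservation scoring

Identity counts aligned residue pairs that match; similarity additionally
counts pairs in the same physicochemical class, default grouping
{AVLIM} {FYW} {ST} {KRH} {DE} {NQ} {C} {GP} — a partition of the 20 amino
acids, so identity ≤ similarity always holds. The default denominator is
the ungapped length of the shorter sequence over the scored window (the
SIAS service default); alignment-window and mean-length denominators are
selectable, and with gaps present the window denominator can only lower
the score. Domain windows are specified as 1-based inclusive residue spans
per sequence (NCBI convention) and mapped to the minimal covering column
window. Scores depend on the alignment actually supplied: different
aligner choices move integer percentages by a point or two, which is why
the denominator and grouping are recorded in every score object.

## Problem sizes and numerical choices

Test-suite simulation sizes are chosen to keep the whole suite fast on one
CPU while leaving estimator noise well below the asserted tolerances:
300–5,000 tracks for timing recoveries (10,000 for the Monte-Carlo median
check), 200 single-nucleus fields for intensity-RMS and count-recovery
properties, 20 seeds × 200 substrates (128-px fields) for the
hole-detector bias bound, and 2,000 simulated datasets for the 5% ± 2 pp
type-I calibration of the gated nonparametric path. Degenerate inputs are
handled explicitly rather than numerically: constant images yield empty
label maps with a warning, empty rings and zero-signal nuclei yield
flagged NaNs, all-censored conditions yield a warned-about empty summary.

## Known limitations

- The generator's idealizations (no PSF, no gradients, non-touching
  nuclei) mean detector thresholds validated here are starting points, not
  calibrated constants, for real micrographs.
- Phase annotations are consumed, not produced; no morphology classifier
  is included.
- The hole/dextran rules formalize visual judgments; their defaults are
  declared stand-ins and should be re-calibrated against expert scoring
  for any new assay setup.
- Conservation integers are alignment-dependent; reproducing published
  values requires the same ortholog records and a comparable global
  aligner.
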