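# Methods

`magmap` implements a model-based analysis of how cortical responses
to visual stimulus *duration* and *numerosity* change when the two
magnitudes vary separately or together, and a synthetic-data generator
that makes every stage testable against known ground truth.

## Stimulus design

Each run presents 130 moving-dot trials in 13 cycles of 10.  Within a
cycle the varying magnitude sweeps its five levels ascending then
descending.  Durations are 0.3–0.9 s in four geometric steps
(0.3·3^(k/4): 0.3, 0.395, 0.52, 0.684, 0.9 s); numerosities are the
literal set {1, 2, 7, 19, 50} dots, which follows no simple spacing
rule and is therefore stored as data, not generated.  The duration
baseline (T) fixes numerosity at 100 dots; the numerosity baseline (N)
fixes duration at 0.2 s; the congruent condition (C) pairs the two
sweeps level-by-level; the incongruent condition (I) anti-pairs them
(0.9 s with 1 dot … 0.3 s with 50 dots).  A red-dot target appears on
exactly one trial per cycle (10% of trials), its position
counterbalanced as a shuffled pass through all ten within-cycle
positions topped up with distinct extra draws.

Timing: TR 1.25 s, inter-trial interval 1.5 s, inter-cycle interval
5 s, cycle onsets snapped *up* to the TR grid.  The inter-trial
interval is treated as onset-to-onset (trials may not outlast it);
with the default values each cycle occupies exactly 16 TRs.
Both magnitudes are mapped to a common arbitrary-unit axis,
`u = 100·log(x/x_min)/log(x_max/x_min)`, so 0.3 s and 1 dot sit at 0
and 0.9 s and 50 dots at 100; the baselines' fixed values fall
deliberately outside this range (100 dots → 117.7 units, 0.2 s →
−36.9 units).

## Forward model

A vertex's neural response is an unnormalised bivariate Gaussian over
the (duration, numerosity) unit plane with preferred magnitudes
(μ_d, μ_n), principal-axis widths (σ_d, σ_n) and axial orientation θ ∈
[0°, 180°): θ near 0°/90°/180° means sensitivity to one magnitude,
45°/135° joint sensitivity.  The peak response is exactly 1 —
amplitude belongs to the GLM stage, keeping the shape parameters
identifiable.  One impulse per trial is placed at stimulus *offset*
(the moment duration is fully determined; onset locking is available
as a flag), convolved with a canonical two-gamma HRF (peak 6 s,
undershoot 16 s, ratio 1/6, 0.05 s kernel grid) and sampled at the TR.
Duration enters as a feature value, not as integration time, so
response amplitude is not trivially confounded with stimulus length.

Preprocessing mirrors the measurement pipeline: the first six
non-constant discrete-cosine components are projected out (the
constant is preserved so the run mean survives) and the series is
converted to percent signal change about the pre-filter run mean.
Because the data are filtered, the model's design matrix is passed
through the *same* DCT projection, and when several runs are fitted
jointly each run's design block is zero-centred to match the per-run
centring that percent signal change imposes — without both steps a
noiseless simulation cannot reach R² = 1.

## Fitting

The grid stage exploits the fact that a run contains at most a
handful of distinct (duration, numerosity) pairs: predictions for all
grid candidates reduce to `design @ nr(unique stimuli)`, and the best
candidate per vertex is an argmax over data–prediction correlations —
evaluating ~2.3·10⁵ candidates against hundreds of vertices costs two
matrix products.  Default grid: μ every 5 units in [0, 100], 8
log-spaced widths in [2, 80] units, θ every 22.5°.  Correlation ties
(within float jitter) resolve to the smaller σ_d·σ_n, then the lower
grid index, making the stage fully deterministic.

Iterative refinement runs bounded nonlinear least squares over
(μ_d, μ_n, log σ_d, log σ_n, θ) with the GLM amplitude and baseline
profiled out.  Because the sparse stimulus sets leave shallow
secondary basins (a narrow Gaussian between two widely spaced levels
can mimic a broader one centred elsewhere), refinement restarts from
the top three grid candidates (four for the reduced model) and keeps
the best converged fit; R² never decreases relative to the grid
start.  Baseline runs are fitted with the reduced 1-D Gaussian along
the varied magnitude — the published modelling choice of making the
response invariant to the unvaried magnitude — while the full
5-parameter model remains available for any condition.

Inclusion requires R² ≥ 0.25 (inclusive), preferred magnitudes inside
[0, 100] units, widths inside [2, 80] units and positive response
amplitude.  The width bounds operationalise "parameters within the
stimulus range" for σ, which also bounds the aspect ratio at 40.

Identifiability caveats, measured on synthetic data: (i) the two
interaction runs alone under-determine the bivariate Gaussian exactly
(its restriction to two crossing lines fixes five of six degrees of
freedom), so joint-model recovery studies probe with all four runs;
(ii) near the low end of either axis, narrow tuning between widely
spaced levels is weakly identified, producing edge bias of a few
units at realistic noise — fits that fail the 25% threshold account
for almost all large errors; (iii) θ is unidentifiable as the aspect
ratio approaches 1, and the (σ_d, σ_n, θ) labels are only defined up
to the swap (σ_n, σ_d, θ+90°), so orientation accuracy is assessed on
the label-free major-axis angle among fields with aspect ≥ 2.

## Surface topography

Above-threshold masks are reduced to connected components under
shared-triangle-edge adjacency.  The cluster permutation relocates
the observed number of suprathreshold vertices uniformly over the
patch 1000 times, records each relocation's maximum cluster size, and
keeps an observed cluster iff its size has empirical null probability
≤ 0.01 (equivalently, exceeds the empirical 99% null quantile).  The
null is exchangeable with spatially unstructured masks, and on
pure-noise masks the measured retention is at or below the nominal 1%
(discreteness of cluster sizes makes the test conservative).  The
procedure is informative only when the map occupies part of the
patch; a map covering (almost) the whole patch is indistinguishable
from its own null, which is why the synthetic end-to-end study embeds
the tuned ROI in noise-only cortex.

Normalized distance follows the flat-map secant construction: a
vertex V is projected to its nearest points A\* and B\* on the
low/short and high/long edge polylines (straight-segment Euclidean
geometry; ties to the earlier segment), then orthogonally onto the
secant A\*B\* (clamped into the segment, so vertices projecting
outside still land in [0, 1]); the value is |A\*V\*|/|A\*B\*|.
Distances are grouped into twenty 0.05 bins, half-open with the last
closed.  Before group modelling, any map whose preference decreases
with distance is flipped (d → 1−d) and flagged, so edge mislabelling
cannot inflate interaction terms.

## Map statistics

Overlap between condition maps is the Jaccard fraction
|A∩B|/|A∪B| — the symmetric reading of "fraction of vertices shared",
reported once per pair.  Aspect ratio is max(σ)/min(σ).  Orientation
densities use a Gaussian kernel of 15° bandwidth wrapped on the
180°-periodic axial circle, normalised to integrate to 1.  Weber-law
checks compute tie-corrected Kendall τ (τ-b; grid-quantised
parameters tie heavily) between every μ and every σ within the five
orientation groups 0–30°, 30–60°, 60–120°, 120–150°, 150–180°
(half-open, last closed); groups below 10 vertices are flagged
unreliable.

## Group inference

Bin-level datasets hold one row per subject × condition (or ROI) ×
distance bin with the bin's mean preference.  Three random-intercept
models are fitted by REML: preference ~ Condition×Distance,
preference ~ ROI×Distance (per condition) and
AspectRatio ~ ROI×Condition, all with `(1 | subject)`.

The REML engine profiles the single variance ratio of the
random-intercept model and works entirely from per-subject sufficient
statistics, so a refit with new responses or resampled subjects costs
microseconds — this is what makes 999-draw bootstraps inside
calibration studies affordable.  Fixed effects use sum-to-zero coding;
Type III F-tests and all contrasts carry Satterthwaite denominator
degrees of freedom computed from the REML information (multi-df
tests via the eigen-decomposition construction).  The engine
reproduces `lmerTest`/`emmeans` F statistics, denominator df and
marginal-mean differences on shared fixtures (a cross-check in the
test suite), and reduces exactly to ordinary ANOVA when the
random-effect variance hits zero, in which case inference downgrades
to the fixed-effects model with a logged flag.  Kenward–Roger df are
not implemented; every result table carries a note flagging the
Satterthwaite substitution.  Marginal means are evaluated at the mean
of the distance covariate; pairwise p-values are Bonferroni-adjusted
(min(1, m·p)) within their contrast family; marginal and conditional
R² follow the variance-partition (Nakagawa) definitions.

Confidence intervals for marginal-mean and slope differences come
from a 999-iteration percentile bootstrap.  The default flavour is
*parametric* (simulate subject intercepts from N(0, τ̂²) and noise
from N(0, σ̂²) about the fitted fixed effects, refit, take 2.5/97.5
percentiles) — the behaviour of `confint(method="boot")` in the lme4
ecosystem this analysis descends from.  Resampling whole subjects
with replacement is available (`boot_method="subjects"`) but measured
coverage at six subjects is ~87% against a nominal 95% — a known
small-n property of subject-resampling percentile intervals — while
the parametric flavour covers at ~95%; hence the default.

## Synthetic ground truth

The generator encodes the study conditions the analysis assumes:

- **Geometry**: a regular triangulated grid patch (default 20×20
  vertices) with flat coordinates; edge A is the left column, edge B
  the right, so normalized distance is exact and known.
- **Topography**: preferred magnitudes linear in normalized distance,
  20 units at edge A to 80 at edge B — inside the stimulus range with
  margin, spanning most of it.
- **Weber scaling**: σ = 0.3·μ + 5 units plus N(0, 2) jitter, clipped
  to [2, 75] — tuning width grows with preference, the scalar
  property the correlation analysis looks for.
- **Orientation structure**: baselines are *invariant* to the
  unvaried magnitude — θ exactly 90°, irrelevant-axis width at the
  75-unit cap, irrelevant preference parked mid-range — matching the
  published modelling of the baseline conditions and giving baseline
  fields high aspect ratios.  C draws θ from modes {45°, 135°}, I
  from {30°, 90°, 150°}, each with 10° jitter, mirroring the
  reported unimodal/bimodal/trimodal orientation distributions.
- **Subjects**: per-subject preference offsets N(0, 5 units) on both
  μ — the random-intercept structure the group model assumes.
- **Noise**: white Gaussian BOLD noise, default 0.3% signal against a
  1% response amplitude, chosen once to put the median variance
  explained of passing fits near 0.5, in line with what
  high-field pRF mapping typically retains.  An optional shuffle
  degradation permutes preferences across vertices, flattening the
  topography while preserving marginals.

All randomness descends from one integer seed through named
SeedSequence spawns; regenerating from the stored provenance is
bitwise reproducible.  What the generator does **not** emulate:
spatially correlated noise, physiological confounds, draining veins,
HRF variability, irregular cortical geometry, and spatially smooth
signal-quality variations.  Passing tests therefore demonstrate the
pipeline's correctness and calibration under its own assumptions, not
robustness to the full messiness of real fMRI.

## Evaluation studies and problem sizes

The acceptance studies run at: 400 vertices for noiseless recovery
(baseline map construction; both preferences within 1 unit for ≥95%
of vertices), 200 vertices × 4 noise levels (2.4 → 0.3% in halvings,
common random numbers) for the SNR ladder, 500 pure-noise masks
(5% density, 30×30 patch, 1000 permutations each) for cluster
calibration, 500 vertices for the Weber correlation and its
permutation null, 6 subjects × 2 ROIs × 4 conditions × 40 vertices
for the tuning-shape contrast, 500 null simulations for the Type III
type-I rate, and 200 replicates × 999 bootstrap draws for CI
coverage.  The end-to-end smoke study uses a 16×16 patch whose left
7 columns form the tuned map, 4 subjects, both baselines, at a
moderate-noise operating point; it checks that the stages compose
(significant positive progression, positive μ–σ correlation,
edge recovery within 5 units, and conservation — every vertex
entering inference passed both threshold and pruning).

## Known limitations

- Only a random intercept per subject is supported in the LME engine
  (the published models need nothing more); no random slopes.
- Kenward–Roger df are approximated by Satterthwaite throughout.
- Edge bias of preference estimates near the ends of the sampled
  range is inherent to the five-level design; reported progressions
  slightly steepen as a result.
- The cluster-permutation null assumes exchangeable (spatially
  unstructured) suprathreshold noise; smooth noise would need a
  smoothness-preserving null that is not implemented.
- Dot-array rendering (positions, sizes, motion) is abstracted away;
  only (duration, numerosity, onset) enter the model.
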