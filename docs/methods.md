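# Methods

This note documents the models, defaults, and numerical choices behind
`tractofluency`, and what the synthetic cohort does and does not emulate.

## The analysis model

The pipeline treats a white-matter tract as a bundle of streamlines in a
common millimetre space and summarizes its microstructure as a
**tract profile**: scalar values (FA, MD) at 30 equidistant nodes along
the bundle core, plus the mean across nodes. Brain–behavior analysis then
asks two questions per tract, metric, and behavioral measure:

1. *Mean-tract:* is the tract-average value rank-correlated with the
   behavior? Tested with two-tailed Spearman correlations and
   Benjamini–Hochberg FDR at q = 0.05 across the family of 8 tracts,
   with separate families per behavioral measure and per metric.
2. *Along-tract:* is there a localized run of nodes whose values
   correlate with the behavior? Node-wise Spearman tests at uncorrected
   α = 0.05 define candidate clusters (maximal runs of adjacent
   suprathreshold nodes); familywise error across the 30 nodes is
   controlled by a cluster-size permutation test.

Significant associations are followed up with first-order partial
Spearman correlations (e.g., holding articulation rate constant when the
finding concerns speaking rate) and, where two correlations sharing a
variable are compared, the Meng–Rosenthal–Rubin Z test on
Fisher-transformed coefficients.

### The cluster-size permutation null

Each of `n_permutations` (default 1000) iterations permutes the
behavioral vector across subjects **once** and reuses it at all 30
nodes. Profile rows are never permuted, so the spatial autocorrelation
of the profiles — the very thing that makes long chance runs likely — is
preserved in the null. The null statistic is the maximum suprathreshold
run length per permutation (a maxT-style construction); the critical
cluster size is the ⌈(1−α)·n_permutations⌉-th order statistic of that
null, and observed clusters must be **strictly longer** to be declared
significant. Because run length is integer-valued the test is slightly
conservative (measured familywise error ≈ 0.03–0.05 at the 0.05 level).
No further correction is applied across tracts, behavioral measures, or
metrics; the run-length statistic is the default (cluster mass is a
possible alternative the package does not currently implement).

### Spearman machinery

Correlations use mid-ranks (average ranks for ties) and the
t-approximation p = 2·P(T₍n−2₎ > |ρ|·√((n−2)/(1−ρ²))). At the n = 45
scale of the design this approximation is accurate (measured null
rejection 0.0497 at α = 0.05 over 2×10⁵ draws); exact permutation
p-values would only matter below n ≈ 10. The vectorized implementation
inside the permutation test is cross-checked against
`scipy.stats.spearmanr` in the test suite. A constant node column
(zero variance) yields ρ = 0, p = 1 with a warning rather than a run
failure. The dependent-correlation comparison defaults to a one-sided
test; the partial and simple correlations default to two-sided.

## Segmentation and profiling choices

* **Point-in-ROI tests** use closed intervals on axis-aligned boxes (or
  nearest-voxel lookup for mask ROIs). Streamlines and ROIs must already
  be co-registered; no warping is performed. The shipped template-space
  boxes for the cerebellar peduncles are approximate, landmark-based
  stand-ins (superior SCP waypoint around the red nucleus at z = −10,
  superior MCP waypoint at the cerebral peduncle at z = −16, inferior
  ICP waypoint below the pons) and real analyses should supply their own
  ROI file.
* **Outlier cleaning** is iterative (default max 5 passes) with the core
  and all statistics recomputed each pass, because a gross outlier
  distorts the first core estimate. The spatial-deviation statistic is
  the mean node-wise Euclidean distance to the core over 100 resampled
  nodes — chosen for robustness over the maximum. SDs use the unbiased
  (n−1) denominator (bundles can be small), and thresholds are strict
  inequalities, so a bundle of identical streamlines (SD = 0) is left
  untouched. The ICP uses a 1-SD length criterion (it is short and
  easily contaminated by long pontine fibers) while keeping the 4-SD
  distance criterion; both are per-tract configurable.
* **Core clipping** truncates each streamline between its ROI crossing
  points after reorienting it to run first-ROI → second-ROI. The
  crossing is the first point inside the ROI walking from the far end;
  for multiple crossings this selects the one nearest the other ROI,
  keeping the retained segment enclosed between the waypoints.
  Streamlines missing a crossing are dropped and counted.
* **Profiling** resamples each streamline to 30 nodes by linear
  interpolation at equal arc length (computed directly at 30 nodes, not
  subsampled from a 100-node profile) and averages streamline scalars
  per node with Gaussian weights exp(−d²/2) on the Mahalanobis distance
  to the core (node-wise covariance, ridge-regularized with a relative
  1e-6 term for near-singular geometry); uniform weighting is available
  and is used in tests where exact averages matter. Node numbering is
  1-based in every interface and output. FA of the all-zero tensor is
  defined as 0 (isotropic limit of the 0/0 case).

## The synthetic cohort

The generator provides the statistical structure the analysis assumes,
at the scale of the study design (45 subjects, 8 tracts, 30 nodes):

* **Geometry.** Streamlines follow cubic-spline centerlines through
  anatomically flavored control points (SCP/MCP crossing the midline,
  ICP ipsilateral, FAT rising from inferior frontal gyrus to SMA). Each
  streamline is displaced by a smooth random degree-3 Legendre
  polynomial per axis with coefficients scaled so the mean-square
  displacement equals `streamline_jitter_sd` (default 1.5 mm) — real
  streamlines are spatially coherent curves, not point clouds.
* **Scalar profiles.** Baseline FA is an arch (0.40 + 0.12·sin πt) with
  a Gaussian mid-tract dip (depth 0.12, width 0.08) for the decussating
  SCP/MCP, where MD is correspondingly elevated; these amplitudes are
  calibration constants of the generator, not empirical claims. Subject
  profiles add a subject-level offset (FA SD 0.03) and node-wise noise
  (FA SD 0.04) smoothed along nodes with a Gaussian kernel (σ = 1.5
  nodes), giving realistic inter-node autocorrelation — the property
  that makes cluster-size null calibration non-trivial.
* **Behavior.** The four measures come from a Gaussian copula whose
  latent correlations are 2·sin(π·ρ_s/6) of the target Spearman matrix
  (exact for the bivariate normal): rates 0.599, fluency scores 0.548,
  cross-block 0.05, with marginals 5.04 ± 0.68 and 6.42 ± 1.05
  syllables/s and 43.78 ± 9.83 and 66.96 ± 12.22 words. Articulation
  rate is floored at speaking rate per subject by reflecting the ~5% of
  violating draws about the speaking rate; this inflates the realized
  rate–rate Spearman by about +0.02, an accepted cost of the hard
  ordering constraint.
* **Effects.** `embed_effect` replaces each window node column by
  mean + sd·(√(1−r²)·z(values) + r·z(behavior)) with r = 2·sin(π·ρ/6)
  and z the standardized normal-score transform, so the population
  Spearman at those nodes approaches the target; nodes outside the
  window are bit-for-bit untouched and ρ = 0 is an exact no-op. The
  default cohort embeds one effect, ρ = −0.45 between right-MCP MD at
  nodes 17–22 and speaking rate.
* **Transcripts.** 50 utterances per subject; syllable counts
  1 + Poisson(10); fluent durations from a lognormal rate around the
  subject's articulation rate; each disfluency type (interjections and
  revisions dominant) occurs independently per utterance and adds pause
  time, so disfluent utterances are locally slower and speaking rate
  falls below articulation rate. A subject's disfluency propensity
  decreases with their speaking rate (multiplier exp(−0.8·z(SR) + ε)),
  reproducing the negative association between disfluency percentage
  and speaking rate qualitatively.
* **Seeding.** One master seed expands into named sub-streams via
  CRC-32-hashed `SeedSequence` spawn keys, so any subject, tract, or
  stage is reproducible independently and the whole pipeline is
  bit-reproducible from its serialized config.

**What the generator does not emulate:** raw diffusion signals, fiber
orientation distributions, tracking errors, partial-volume effects,
registration error, or any audio. Passing tests therefore demonstrate
the correctness and calibration of the *analysis* under its assumed
data-generating process, not the fidelity of upstream MRI processing on
real data.

## Simulation sizes

The calibration suite uses 500 global-null replicates × 500 permutations
for the familywise-error and node-level checks, 1000 replicates for the
FDR check, and 100 seeds for planted-effect recovery — sizes chosen so
Monte-Carlo standard errors are a fraction of the tolerances being
checked while the whole suite runs in seconds to minutes on one CPU.
The pooled node-level rejection rate has an effective sample of ~500
(not 500 × 30) because nodes within a replicate are correlated; its
seed-to-seed scatter of ±0.01 around the nominal 0.05 reflects that.

## Known limitations

* The dependent-correlation Z test is one specific variant of a family
  (Steiger-type alternatives exist); it is isolated behind a single
  function so the choice can be swapped.
* Mask-ROI membership uses nearest-voxel lookup, not sub-voxel
  interpolation.
* Cleaning convergence is capped at 5 iterations; pathological bundles
  may not reach a fixed point (in practice one or two passes suffice).
* The 50–200 mm physiological length window is not applied by default in
  the synthetic pipeline (generated bundles are within range by
  construction); real tractograms should be pre-filtered at tracking
  time.
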