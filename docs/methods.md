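# Methods

## Problem and pipeline

Children with cerebral palsy (CP) show heterogeneous gait deviations, and
ankle–foot orthoses (AFOs) are prescribed with considerable variability.
`somgait` implements an unsupervised classification of lower-limb gait
patterns from three-dimensional gait analysis kinematics, and evaluates
orthosis outcomes within the recovered patterns:

1. time-normalized joint-angle curves → directional gait variable scores
   (GVS);
2. a 10×10 batch self-organizing map (SOM) over the 13-dimensional score
   space;
3. k-means partitioning of the SOM codebook with a sensitivity analysis for
   the number of clusters;
4. per-cluster statistics (Levene, Shapiro–Wilk, one-way ANOVA, Bonferroni
   pairwise Welch tests);
5. orthosis outcome evaluation through gait profile score (GPS)
   differences.

Each limb is treated as an independent observation (no within-child
correlation is modeled), and the analysis uses barefoot kinematics as the
model input; orthosis trials enter only the outcome stage.

## Scores

For a kinematic variable v with time-normalized curve x_v(t) (51 samples,
0–100% of the gait cycle at 2% steps) and a typically developing (TD)
reference mean m_v(t), the deviation is d_v(t) = x_v(t) − m_v(t).

* Unsplit variables (pelvic tilt/obliquity/rotation, hip ab/adduction, hip
  rotation): GVS_v = RMS_t d_v(t).
* Split variables (sagittal hip, knee, ankle; foot progression): two
  one-sided scores, RMS_t max(d_v, 0) and RMS_t max(−d_v, 0), computed over
  all 51 samples with the opposite side contributing zeros.  This makes the
  split exact: pos² + neg² equals the full-cycle RMS², and scores remain
  comparable between limbs with different phase durations.

This yields 13 directional scores from 9 variables.  The GPS is the RMS
average of all 13 scores; GPS² is exactly the mean of the squared scores.
Sign convention: flexion, dorsiflexion, adduction, internal rotation,
anterior tilt and inward foot progression are positive.  All scores are
translation-covariant (adding a constant to both curve and reference leaves
them unchanged) and homogeneous of degree one in the deviation.

An alternative convention — RMS over only the samples on the deviating side
— would break the Pythagorean decomposition and make scores depend on phase
durations; it is noted as a possible variant but not implemented.

## Self-organizing map

Features are z-scored per score across the cohort (zero-variance features
are flagged and zeroed); the normalization parameters are stored on the
model so BMU lookups and codebook clustering share one space.

Training is the deterministic batch algorithm on a 10×10 rectangular grid:
each epoch assigns samples to best matching units (BMU; Euclidean distance,
ties to the lowest unit index) and replaces every prototype by the
Gaussian-neighborhood-weighted mean of all samples.  Grid distance is
Euclidean in (row, col); the neighborhood σ shrinks linearly from grid/6
(≈1.67 units) to 1.0 over 50 rough epochs and holds at 1.0 for 50 fine-tune
epochs.  Holding σ fixed during fine-tuning makes the quantization error
empirically non-increasing in that phase, which the suite asserts on fixed
data.  The codebook is initialized on the plane of the first two principal
components (deterministic SVD sign convention), so identical data, config
and seed give bit-identical models.  Map quality is reported as
quantization error (mean sample-to-BMU distance) and topographic error
(fraction of samples whose two best units are not 8-neighbors).

## Cluster number and assignment

k-means (Lloyd with k-means++ seeding, 10 restarts, 300-iteration cap,
per-iteration inertia monotonicity asserted, empty clusters re-seeded at
the point farthest from its centroid) partitions the 100 codebook vectors
unweighted; limbs inherit the label of their BMU.  The number of clusters
is chosen over k = 2…10 by maximizing the mean silhouette of the codebook
vectors, with the inertia elbow curve reported alongside; ties go to the
smaller k.  Labels are defined up to permutation — comparisons use the
adjusted Rand index (ARI) — and are canonicalized for reporting so that
group 0 is the cluster richest in TD limbs.

Clustering the codebook rather than the limbs directly smooths the
partition through the map topology; a hit-count-weighted variant is a
possible extension and not implemented.

## Statistics

Per directional score, clusters are compared with the Brown–Forsythe
(median-centered) Levene test, per-group Shapiro–Wilk normality tests
(n = 3…5000; skipped for degenerate constant groups), one-way
fixed-effects ANOVA, and two-sided Welch pairwise t-tests.  The pairwise
significance threshold is α = 0.05 divided by the number of clusters
(0.008 at three decimals for six clusters) — deliberately the cluster
count, not the number of pairs.  Box summaries use linear-interpolation
percentiles with whiskers at the 10th/90th percentiles and outliers beyond
them.

## Orthosis outcomes

ΔGPS = GPS_barefoot − GPS_orthosis, so positive differences are
improvements.  Improvement is strict (ΔGPS > 0; a zero difference is not an
improvement); a separate inclusive flag marks ΔGPS ≥ 1.6 points, the
minimal clinically important difference (MCID) reported for the GPS (the
threshold is configurable; it annotates, never filters).  Per
(cluster, orthosis design) cell the table reports limb counts, the share
improved, mean ΔGPS, and mean ΔGPS over improved limbs only; cells with no
improved limb report the latter as missing, never zero.  Limbs without a
measured orthosis condition are excluded from all outcome denominators but
appear in the prescription crosstab under "No Orthosis"; supra-malleolar
and sport dynamic orthoses collapse into "Others" for the crosstab while
full types stay on the records.

## Synthetic cohort generator

The generator emulates a pediatric gait laboratory cohort at the modeled
study's scale: 25 TD children contributing both limbs (50 limbs) plus five
pathological archetypes × 40 limbs (250 barefoot limbs), with ~70% of CP
limbs carrying an orthosis prescription.

* **TD template.** Nine low-order Fourier curves with physiologic
  magnitudes (e.g. hip flexion ≈ +35° at foot strike to −11° in terminal
  stance; double-bump pelvic tilt around 12° anterior); integer harmonics
  make every curve exactly periodic, and the curvature bound
  |Δ²| < 1°/sample² is asserted.
* **Archetypes.** Each archetype plants one-sided deviations (amplitude ×
  unit-RMS waveform: constant, early-stance bump, swing bump or ramp) on a
  small set of variables: mild (swing knee flexion, pelvic obliquity,
  early-stance dorsiflexion), external foot progression (out-toeing with
  pelvic retraction), crouch (hip/knee flexion, dorsiflexion, anterior
  tilt), rotational (hip rotation and ab/adduction), and jump/equinus
  (plantarflexion, reduced swing knee flexion, anterior tilt, in-toeing).
  Because waveforms are unit-RMS, the amplitude *is* the planted one-sided
  score at zero noise.
* **Noise.** Per limb and variable: a constant offset (SD 1.0°,
  marker-placement-like) plus a smooth random low-order Fourier curve
  (RMS 1.7°), combined per-variable RMS ≈ 2.0°.  Defining amplitudes are
  4° (2× noise) and secondary 3° (1.5×), chosen so archetypes are
  recoverable but not trivially separated; at these defaults the pipeline
  selects k = 6 across seeds and recovers planted labels with ARI ≈ 0.8
  (0.73–0.87 over seeds 0–5; 0.80 at the default seed).  The noise budget leans toward the smooth component because pure
  offset noise mimics constant-shape pathology deviations.
* **Orthosis effect.** Paired orthosis trials shrink a limb's whole
  deviation multiplicatively; the per-limb factor is solved against the
  noiseless template so the expected ΔGPS equals a per-archetype target
  drawn as N(μ_a, 1.5°), with μ_a ∈ [−0.8, 0.15] chosen so that roughly
  30–55% of limbs improve per pattern and improved limbs gain ≈1 GPS point
  — the efficacy profile reported for clinical AFO caseloads.  Negative
  targets (worsening) amplify the deviation.

What the generator does **not** emulate: real inter-variable correlation
structure, stride-to-stride variability (one pre-averaged cycle per
limb-condition), kinetics, asymmetric within-child limb pairing, mixed or
intermediate gait patterns, and orthosis effects that reshape rather than
uniformly scale the deviation.  Passing recovery tests therefore shows the
pipeline can find cluster structure of this geometry at clinical
signal-to-noise ratios; it does not validate the clinical taxonomy itself.

## Numerical choices and degenerate inputs

* BMU and k-means ties break to the lowest index; SVD component signs are
  fixed by the largest-magnitude element, so all stages are deterministic
  given (data, config, seed); one seeded generator per run.
* Resampling is strictly interpolating (inputs must cover 0–100%); curves
  need not close (0% may differ from 100%).
* Reference SD is the population SD and is informational only.
* A codebook collapsed to one point makes silhouettes undefined;
  `select_k` raises a degenerate-map error rather than guessing.
* Zero-variance features are excluded from normalization (zeroed and
  flagged) instead of dividing by zero.
* Problem sizes in the test suite and acceptance script are the generator
  defaults (250 limbs); SOM training, model selection and the statistics
  battery complete in seconds at that scale.

## Known limitations

The GPS weighting treats all 13 directional scores equally, which differs
from the classic 9-score formulation; clustering operates on barefoot data
only; limbs are independent observations; and the statistical battery
reports no effect sizes beyond mean differences.  Stance/swing-restricted
scores and hit-weighted codebook clustering are left as extensions.
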