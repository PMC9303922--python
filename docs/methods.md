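# Methods

`nbsfc` implements network-level inference for task-conditioned
functional connectivity: condition-specific weighted ROI-to-ROI
correlation matrices, edge-wise group contrasts, and network-based
statistics (NBS) — connected-component detection on the suprathreshold
graph with permutation-based family-wise-error (FWE) control — together
with a synthetic cohort generator whose ground truth is controlled
analytically. This note records the models, the defaults and why they
were chosen, the numerical decisions, and the limits of what the
synthetic validation can show.

## First-level model: condition-specific weighted correlation

For each subject and condition c, connectivity between nodes i and j is
the weighted Pearson correlation

r_ij(c) = Σ_t w_c(t)(x_i(t) − m_i)(x_j(t) − m_j) /
          √(Σ_t w_c(t)(x_i(t) − m_i)² · Σ_t w_c(t)(x_j(t) − m_j)²),

with m the w_c-weighted means, Fisher-transformed to z = arctanh(r).
The temporal weights w_c are the condition's stimulus boxcar (per-frame
fractional occupancy of its events) convolved, within each run, with a
canonical double-gamma haemodynamic response function (peak 6 s,
undershoot 16 s, unit dispersions, peak:undershoot 6, 32 s support,
peak-normalized). Three decisions here were genuinely open:

- **Rectification.** The HRF undershoot makes the convolved regressor
  dip negative; a weighted correlation needs nonnegative weights, so
  negative values are rectified to zero.
- **No renormalization.** The weighted correlation is invariant to a
  positive rescaling of the weight vector, so weights are left on the
  convolution's natural scale.
- **Degenerate pairs raise.** |r| = 1 (identical or anti-identical
  series) raises an error naming the nodes rather than clipping:
  silent clipping would leak an arbitrary huge arctanh into component
  masses downstream.

With 30 nodes there are 435 unordered node pairs; all edge enumeration
in the package is undirected, upper-triangle, row-major.

## Denoising

Per run: (1) high-pass by regression on a discrete-cosine basis with
cutoff 1/128 Hz — the standard 128-s task high-pass — chosen over an IIR
filter because it is exactly linear and idempotent; (2) regression of
the supplied confound traces plus, optionally, per-run intercepts and
HRF-convolved per-condition regressors (session and mean task-evoked
effects as nuisance); (3) framewise-displacement censoring with the
conventional 0.40 mm threshold, strict inequality (a frame at exactly
0.40 mm is kept). Censored frames are *not* deleted: they are carried
with zero weight into the weighted correlation, so the weight algebra
stays aligned with the task design. The QC-FC diagnostic (across-subject
correlation between each edge's connectivity and mean framewise
displacement, summarized by the median absolute value) is provided to
confirm motion-connectivity decoupling.

## Second-level model and permutation inference

Contrasts over condition z-maps are linear (e.g. self − stranger, or the
compound (self − stranger) − (sad − neutral)). The group model is the
one-sample t-test on per-subject contrast values (for a paired
difference this is exactly the paired t-test), df = n − 1. Default
sidedness is two-sided so components may mix positive and negative
edges; one-sided mode exists for directional hypotheses, and the choice
is recorded in output metadata.

The t-map is thresholded at a user-set uncorrected height p (default
.001), connected components are found among suprathreshold edges, and
each component is summarized three ways: **size** (edge count),
**mass_t2** (Σt²) and **intensity_abs** (Σ|t|). Both mass conventions
are first-class because both are in common use; the configuration
selects which statistic drives the null (default `intensity_abs`), and
all three maxima are recorded per permutation so each component carries
an FWE p per statistic.

Permutations honour the within-subject constraint. For a paired
difference, exchanging one subject's two condition labels is exactly an
independent ±1 sign on that subject's whole difference vector; the same
sign applies to every edge, preserving inter-edge dependence. For
compound contrasts, each subject's condition vectors are rearranged by
an independent random permutation of the involved conditions, again
identical across edges. Edge t-statistics are recomputed in full inside
every permutation (no residual shortcuts — with 435 edges, correctness
is cheap). The FWE p of a component is the proportion of permutations
whose *maximal* component statistic is as large or larger (ties count);
the default estimator adds one to numerator and denominator
((1 + #{≥})/(1 + n_perms)), which keeps p ≥ 1/(n_perms + 1) and avoids
p = 0 artefacts; the plain proportion estimator is available.

The threshold sweep re-runs the chain over a descending grid of height
thresholds (default 0.05 · 0.9^k down to 10⁻⁴, i.e. 10% steps) and
classifies the effect: significant only at conservative thresholds
(height p ≤ .01) → "focal" (strong, topologically concentrated), only
at liberal thresholds → "extended" (subtle but spatially distributed),
at both → "combined". The 0.01 split of the grid is a package choice.

Component effect size follows the mass-based convention
d = mean(t over component edges)/√n. No standard interval accompanies
that estimator, so the 90% CI is a percentile bootstrap over subjects
(default 2,000 resamples, seeded), recomputing edge t and d per
resample; the method is labelled in output.

## Synthetic cohorts with analytic ground truth

Real task fMRI cannot provide ground truth, so validation uses a
generator in which the estimand of the first-level model is known
exactly. Each frame t is an independent Gaussian draw with correlation
matrix

Σ(t) = (1 − ρ₀)I + ρ₀J + e(t)·B,

where ρ₀ is the baseline inter-node correlation (default 0.1), B marks
the ground-truth edge set, and e(t) = Σ_c δ_c α_c(t) is the
condition-gated excess correlation. The gate α_c is the bounded
per-frame function with the smallest possible peak — found by a small
linear program — satisfying ⟨w_c′, α_c⟩/Σw_c′ = 1{c′ = c} against every
condition weight train. The optimum in practice has peak exactly 1 (the
gate sits at 1 across the target condition's weight support and swings
within ±1 elsewhere to cancel the other conditions' integrals), so the
largest excess correlation ever injected is |δ| itself, keeping the
per-frame covariance comfortably positive definite for star topologies
at realistic effect sizes. Every per-frame covariance is Cholesky-
checked; infeasible parameter combinations raise an error naming the
edge set.

Because the frame draws are i.i.d. given Σ(t) and the analysis weights
are the same w_c, the condition-c weighted correlation converges to
ρ₀ + δ_c on ground-truth edges and to ρ₀ elsewhere, giving closed-form
targets such as z(self) − z(stranger) → arctanh(ρ₀ + δ) − arctanh(ρ₀).
Nuisance structure is layered on top so the denoising stages have real
work to do, each exactly removable by a linear projection: slow cosine
drift per node (0.002–0.006 Hz, below the high-pass cutoff), six
smooth AR(1) confound traces with random node loadings, and a
framewise-displacement trace (|AR(1)| plus sparse spikes above 0.40 mm)
driving censoring. `noise_sd` scales the stochastic frame draw itself;
an *additive* white term instead would shrink every correlation by
1/(1 + σ²) and destroy the calibration.

Cohorts draw an independent design realization per subject
(trial = 200 ms fixation + 100 ms stimulus + 1000 ms blank, ISI jittered
uniformly on 2–6 s; defaults TR 2 s, 2 runs, 40 trials/condition, all
config-flagged stand-ins). Each subject's nonzero deltas are perturbed
by a truncated (±2 sd) normal with scale `between_subject_sd`
(default 0.05): truncation is symmetric, so the population mean equals
the nominal delta, while keeping every subject inside the
positive-definiteness region. Zero deltas are never perturbed, so a
delta-0 cohort is an exact null.

**What the generator does not emulate:** spatial structure (no volumes,
no smoothing-induced spillage), temporal autocorrelation of the BOLD
noise (frames are independent given the gate), physiological noise
beyond generic confound columns, task-evoked mean activation, and
heterogeneous per-edge baselines. Passing tests therefore show that the
inference machinery is calibrated and sensitive under its own
assumptions — not that those assumptions hold in scanner data.

## Validation experiments and problem sizes

The experiment layer runs the full pipeline at desk scale (two
conditions, one run; 12 trials/condition for null batches, 24 for
effect batches — sizes chosen so that a planted z ≈ 0.3 star effect at
n = 20 sits well above the p < .001 height threshold while whole
batches stay cheap):

- **FWE calibration:** 200 null cohorts of 20 subjects, 500
  permutations, intensity statistic; the fraction with any component at
  p_fwe ≤ .05 must sit in the exact binomial 95% band around 0.05
  ([0.024, 0.089]).
- **Recovery:** 50 cohorts with the 4-edge medial-prefrontal star at
  z ≈ 0.3 (between-subject sd 0.05); top-component edge Jaccard ≥ 0.75
  in ≥ 90% of runs, spurious disjoint significant components in ≤ 10%.
- **Exact oracles:** component partition and statistics against a
  brute-force transitive closure on 1,000 random graphs; weighted
  correlation against the definitional sums at 10⁻¹².
- **Structure:** suprathreshold nesting across the 10%-step threshold
  grid; byte-identical reruns under a fixed seed.

## Numerical choices and degenerate inputs

- Zero-variance edges at the group level are flagged and excluded with a
  warning, never silently zeroed; inside permutations the variance floor
  is 10⁻³⁰⁰ (sign flips leave each edge's sum of squares invariant, so
  only means vary and a single matrix product yields all permuted
  t-maps).
- Component ordering: descending driving statistic, ties broken by the
  smallest canonical edge index, making the partition independent of
  edge enumeration order.
- All TSV output uses a fixed float format (%.10g data, %.6g reports) so
  identical runs are byte-identical.
- Seeds: a single mandatory config seed is fanned out through
  `numpy.random.SeedSequence`; derived seeds stay below 2³¹.

## Known limitations

- The per-component FWE comes from the maximal-component null; no
  across-contrast correction and no FDR variant over components is
  provided.
- The label-permutation scheme for compound contrasts assumes full
  exchangeability of the involved conditions under the null.
- The i.i.d.-frames assumption makes effective temporal sample sizes
  larger than in autocorrelated scanner data; empirical power figures
  from the generator are therefore optimistic.
- Cerebellar coverage is excluded from the default 30-node atlas.
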