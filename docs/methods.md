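# Methods

## The problem

During randomized reaching practice a subject reaches toward targets in six
movement directions in shuffled order, under a nonlinear visuomotor
distortion (the cursor displays joint angles, not hand position) and, for
most subjects, error-augmented visual feedback.  Each trial is reduced to a
single scalar observation: the signed maximum L2 deviation of the first
submovement from the ideal straight (minimum-jerk) line.  The question the
package answers is *which trial-to-trial update rule best explains how that
error evolves*: does each direction keep its own memory, does learning
generalize from the practiced direction to its neighbours, and is the
learning rate constant or error-dependent?

## The model family

All 28 candidate structures share the state-space form

    e[n+1, d] = e[n, d] + f_d(ê[n, d])                     direction-specific (ds)
    e[n+1, d] = e[n, d] + f_d(ĝ[n, d])                     generalizing (g)
    e[n+1, d] = e[n, d] + f_d(ê[n, d]) + Z_d · ĝ[n, d]     mixed (m)

with latent error `e` (cm) per direction `d`, perceived error
`ê = gain·e + offset·e0` under the trial's error-augmentation (EA)
condition (zero on no-vision trials), and generalized error
`ĝ[n, d] = W(θ_{d,p}) · ê[n, p]` from the practiced direction `p` through an
angular kernel over the separations {0, ±60, ±120, 180}°, `W(0) ≡ 1`,
`|W| ≤ 1`.  The inter-trial change `f_d` is linear (`1L`), affine (`1`),
quadratic (`2`), cubic (`3`), or Gaussian-weighted
(`1G`: `A + B·exp(-(ê/H)²)·ê`); orders k = 2..8 add lagged linear terms
`B_k · ê[n-k+1]`.  Model ids follow the `scheme.order.nonlinearity`
convention (`m.1.1` = mixed, first-order, affine).

Free-parameter counts are per-direction structure parameters × 6, plus one
`Z_d` per direction for the mixed scheme, plus 5 free weights for the
generalizing/mixed schemes: e.g. `ds.1.1L` = 6, `ds.1.1` = 12, `g.1.1` = 17,
`m.1.1` = 23, `ds.8.1` = 54.

### Momentum rule and state initialisation

Every direction updates on every trial.  The practiced direction perceives
its error through the trial's EA condition; each unpracticed direction
evolves under a *momentum* rule whose default reading (`normal_feedback`)
recomputes `f` as if normal feedback EA{gain 1, offset 0} applied to the
latent state.  A second reading (`repeat_delta`), in which an unpracticed
direction verbatim repeats its previous inter-trial change, is kept behind
the `momentum_mode` switch.  On no-vision trials the perceived error is
zeroed for the practiced direction only (ĝ is then also zero, since it is
sourced from the practiced direction); internal momentum updates proceed.

The latent state starts at the per-direction initial-exposure errors `e0`;
history entries required before the first trial are zero.  Higher-order lags
index the global trial sequence of each direction's internal perceived-error
series (well-defined because the momentum rule updates every direction every
trial), not practiced-trial occurrences only.

### Simulation engines

`simulate_learning_curves` has two engines that agree bit-for-bit (tested):
a readable Python iteration of `step`, and a numba-jitted kernel used by the
fitting stage, which needs on the order of 10^5 forward simulations per
subject × task fit.  One 250-trial simulation costs ~40 µs jitted.

## Geometry and trial observables

The two-link arm uses the standard planar forward/inverse kinematics with
quadrant-aware two-argument arctangents (the single-argument form fails for
x ≤ 0 inside the workspace) and the positive square-root (elbow-up) branch,
consistent with the centre pose (θ_S = 2°, θ_E = 111°) pinned to display
(0, 47) cm.  The eight distortion tasks enumerate {2 axis assignments} × {2
x-signs} × {2 y-signs} at 5/11 cm per degree; which combination carries
which published task number is not machine-readable from the source figure,
so task identity is configuration (lexicographic order), not science.
Targets sit on a 15 cm equilateral triangle centred at (0, 47) cm, oriented
75.243° (both constants taken as given); the six ordered vertex pairs are
sorted by movement angle so direction ids step by 60°.

Error augmentation acts pointwise on paths resampled to a common arc-length
grid (default 100 stations) because the ideal path has no time samples:
`augmented = ideal + gain·(cursor − ideal) + offset·(ie − ideal)`.

Speed humps are local maxima above 14 cm/s whose prominence exceeds 2 cm/s
(the "drops more than 2 cm/s on either side" rule); the first submovement is
bounded by the lowest-speed samples below 5 cm/s flanking the first hump,
falling back to the trajectory ends, ties resolved to the first occurrence.
Speed is estimated by central differences followed by a 5-sample moving
average; the appropriate smoothing is not uniquely determined, so tests use
analytically generated speed profiles that are filter-insensitive.  The
signed max error takes the maximum pointwise distance between cursor and
ideal on the common arc-length grid, signed by the side of the start→goal
line (cross-product test) at the argmax relative to the initial-exposure
launch side.

## Synthetic cohorts

No raw data accompany the study the analysis reimplements, so the generator
emulates the experiment's structure: 15 subjects × 8 tasks × 250 trials, six
near-balanced randomized directions, one-in-four no-vision trials never
adjacent (uniformly sampled non-adjacent sets via the gap construction),
five subjects on normal feedback and ten drawing per-task EA coordinates
without replacement from the 11 non-normal coordinates with the same order
repeated per subject pair.  Initial-exposure errors are |N(20.19, 3.0²)| cm
with a direction/task-alternating sign pattern; the 20.19 cm magnitude is the
reported initial-exposure mean, the 3 cm spread is a package choice (only the
across-subject summary is published).  Observations are the latent practiced
error plus i.i.d. N(0, noise_sd²); noise_sd defaults to 2 cm (unpublished;
chosen to reproduce the low signal-to-noise regime the original fits report)
and Student-t noise is available for robustness experiments.  Seeding fans
out from one integer through `numpy.random.SeedSequence` spawn keys per
(subject, task), so each subject's data are independent of cohort size.

The default generating model is `m.1.1` with A = 0.5 cm, B = +0.02,
Z = −0.40, W = (0.15 at ±60°, 0.06 at ±120°, 0.03 at 180°): the reported
sign structure (positive offset, small positive direction-specific rate =
forgetting, negative generalization gain with net learning Z + B < 0 at the
practiced direction, local generalization).  Magnitudes are constrained by
stability: the coupled dynamics under sign-alternating e0 diverge for
steeper W at ±60° or larger B, whereas this set decays from ~20 cm toward a
~9 cm steady state.  What the generator does *not* emulate: within-trial
feedback corrections, inter-subject parameter variability (off by default;
`truth_jitter_rel` enables it), EA-gain-driven heteroscedasticity, and any
learning during the correction phase — so passing tests demonstrate that the
estimation machinery is sound, not that real behaviour follows m.1.1.

## Fitting

Sparse direction repetition rules out trial-to-next-trial regression, so
parameters are estimated by simulation-based least squares: simulate the
full phase from the slice's own e0 and schedule, and minimise the squared
difference from the observed errors at each trial's practiced direction
(vision and no-vision trials alike), jointly over all six directions —
required because W and Z are shared across directions.  Slices with EA-gain
zero are excluded (perceived error carries no information about performance
there).

The optimizer is a staged multi-start bounded trust-region search: Latin
hypercube trial points over the bound box (plus one neutral mid-box start),
local `scipy.optimize.least_squares` (trf) runs from the most promising ~30%
of trial points capped at 60 function evaluations, then a full-tolerance
(1e-12) polish of the incumbent — the filtering mirrors how global-search
multistart methods allocate local solves.  Bounds: A ∈ [−10, 10] cm,
B/Z ∈ [−2, 2], C ∈ [−1, 1] cm⁻¹, D ∈ [−0.1, 0.1] cm⁻², H ∈ (0.1, 100] cm,
W ∈ [−1, 1]; only the W bounds are part of the model definition.  Fits are
deterministic given (seed, n_starts); n_starts defaults to a desk-scale 50
(the original analysis used a 1000-fold global search).  On noiseless
synthetic data the m.1.1 round trip recovers all 23 parameters to machine
precision (acceptance requires ≤ 1e-3 relative).

R² is computed about the observed mean; adjusted R² penalises by the free
parameter count.

## Cross-validated selection

Fits are computed once per (model, subject, task) and reused across
partitions.  Exhaustive partitions: all C(15, 3) = 455 leave-3-subjects-out
splits, or all C(8, 2) = 28 leave-2-tasks-out splits per subject (the only
integer test sizes consistent with 4/5:1/5 splits and the printed partition
counts).  Per partition and model, the element-wise median (default; mean
available) of the training-set fit parameters forms a consensus model, which
predicts each held-out subject × task curve from that slice's own
e0/schedule/EA; prediction quality is the RMSE over the first 50 trials,
where the learning transient dominates the noise floor.  The partition is
summarised by the mode of a Gaussian KDE over its per-curve RMSEs (Silverman
bandwidth, 512-point grid spanning the sample ± 3 bandwidths; degenerate
samples return their value).

Models are compared pairwise with left-tailed Wilcoxon signed-rank tests
across partition MLEs, multiplied by the Bonferroni factor for the number of
ordered pairs (clipped at 1; all-zero difference vectors yield p = 1), at
α = 0.01.  The model score is wins minus losses.  Because the score is
integer-valued and saturates at small partition counts (with 6 partitions
the one-sided Wilcoxon can never clear the correction), the report ranks
models by score with ties broken by mean partition MLE and then by parameter
count; `best_model` is the head of that ranking.

Parameter-level inference on the selected model: per-parameter sign tests
for non-zero medians (α = 0.05), Kruskal–Wallis tests with learning task and
movement direction as factors, and the effective rates `B + Z` (practiced
direction) and `Z·W(θ)` per separation.

## Problem sizes and numerical choices

The test suite and examples run at desk scale: structure recovery uses 6
subjects × 2 tasks × 250 trials, 6 candidate structures, 25 starts, 10
cohort seeds (the generating m.1.1 wins the ranking in 10/10 at these
sizes); the noiseless round trip uses one subject × task at 50 starts.
Degenerate inputs are handled explicitly: zero-length paths and coincident
start/goal raise; trajectories with no qualifying hump raise a dedicated
error; argmax and boundary ties take the first occurrence; simulation
divergence in the generator raises a warning and flags the dataset; diverged
residuals are clipped at 1e8 cm so the optimizer can retreat.

## Known limitations

* The exact published task-number ↔ distortion assignment and the original
  speed-profile smoothing are unrecoverable from the source; both are
  configuration here.
* The generalizing-scheme higher orders lag ĝ at each target direction;
  the alternative (lagging at the practiced direction) has identical
  parameter counts and is not implemented.
* Published headline numbers that depend on the human subjects' data
  (baseline error, R² modes, fitted magnitudes) are not reproduction
  targets; only the analysis's analytic bookkeeping and its behaviour on
  synthetic data are.
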