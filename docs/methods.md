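# Methods

This note documents the models and numerical choices behind `navscape`:
what the synthetic navigators emulate, how each metric and statistic is
defined, and where a genuinely open design decision was resolved.

## The study design being emulated

The package targets a virtual spatial-navigation battery with a 2×2
between-subject design — sex (F/M) × treatment (placebo PBO vs estradiol
valerate E2V), reference cell F.PBO — over three environments:

1. **Arena** — an open circular arena of radius *R* = 5000 Unreal units
   (U.u.; ≈16 virtual meters, so 1 virtual meter = 312.5 U.u.).
   Participants repeatedly return eight everyday objects to their eight
   fixed locations, in randomized complete cycles, over six blocks of at
   least 10 min; a drop-off in progress at a block boundary completes.
   Each drop-off earns one of five feedback grades (best: within
   700 U.u.; worst: beyond 4500 U.u.), after which the object reappears
   at its true location and is re-collected (the *retrieval* phase). The
   session starts 879 U.u. from the center.
2. **Y-maze** — three arms at 120°. Training from a fixed arm until five
   consecutive correct entries into the target arm, then a probe from the
   third arm. Repeating the trained body turn (which cannot reach the
   target from the new start) is *egocentric*; reaching the cue-defined
   target arm is *allocentric*; egocentric movers who report noticing the
   cue change (*ego+*) are excluded.
3. **Town** — a fixed route over 16 intersections with 6 landmarks.
   After two passive learning runs, probe runs stop at every intersection;
   learning cycles repeat until an error-free probe, so an error-free
   navigator still scores the task minimum of 2 rounds. A surprise
   pointing phase then tests all C(6,2) landmark pairs twice (30 trials).

No raw participant data accompany this design, so every analysis is
exercised on synthetic cohorts whose generative knobs map one-to-one onto
the measured constructs.

## Synthetic navigators

### Arena agent

A waypoint-steering agent at fixed speed *v* (default 650 U.u./s ≈ 2
virtual m/s) and sampling rate 10 Hz (the logging rate is not part of the
task design; both are free parameters). Per trial the agent recalls the
cued location with fresh isotropic Gaussian error (SD
`memory_noise_sd`, default 600 U.u.), walks toward it, and places the
object exactly at the remembered point once within 120 U.u. of it — so
with zero memory noise the drop error is exactly zero, and mean drop
error is monotone in the noise SD. A leg that exceeds 150 s is abandoned
and the object dropped in place (thigmotactic agents therefore complete
fewer drop-offs with larger errors, as heavy wall-huggers should).

**Thigmotaxis** is a one-sided radial attraction toward the ring of
radius `bias · R`: the steering direction blends the goal unit vector
(weight 1 − bias) with a ring term (weight bias) composed of an outward
push, saturating within 1/12 of *R* of the ring, plus a tangential
wall-following component active only while the ring constraint is
engaged. The attraction never pulls an agent inward off the periphery —
thigmotaxis is center *avoidance* — and it relaxes within 0.3 *R* of the
goal so the agent darts in, drops, and returns to the wall. Consequences
worth knowing: the periphery-preference proportion is flat (not
increasing) for biases below ~0.5, because sub-boundary rings only
re-route inner-half travel; once the ring enters the outer half
(bias > 0.5) the preference rises steeply. Monotonicity therefore holds
across well-separated bias levels (0, 0.65, 0.95 in the tests), not
between arbitrary nearby low biases.

Heading jitter is Gaussian per step (default SD 6°); idle pauses start
with per-sample probability 0.004 and last Exp(1.5 s). Positions are
geometrically confined to the disc by truncating any step at the bank, so
inter-sample speed never exceeds *v*.

### Y-maze agent

Turn convention: from arm *a*, left → (a+1) mod 3, right → (a+2) mod 3;
with this convention, replaying the trained turn from the probe arm
always leads to the old start arm, and the other turn to the target arm,
which is what makes the probe diagnostic. The per-trial wrong-turn
probability is `memory_noise_sd / 5000` capped at 0.49, tying maze
performance to the same memory-noise axis as the arena. Egocentric agents
report noticing the cue change with probability `notice_change_prob`
(default 0.1), generating ego+ exclusions independently of movement.

### Town agent

Probe runs are Bernoulli error vectors (per-intersection error
probability `turn_error_prob`), repeated until clean; pointing responses
are the true inter-landmark bearing plus wrapped Gaussian noise, with
log-normal response times. With 16 intersections an error rate of ~0.13
reproduces the regime where roughly one navigator in ten is error-free —
the regime in which hurdle models of cumulative errors are interesting.

### What the generator does *not* emulate

Learning (memory noise is stationary within a session), fatigue,
speed–accuracy strategy shifts, landmark visibility, 3-D rendering, or
body-based cues. Passing tests therefore show that the *analysis layer*
recovers planted generative contrasts; they are not evidence about any
real population.

## Metrics

- **Drop error**: Euclidean distance drop→target (bounded by 2*R* =
  10,000 U.u.).
- **Periphery preference**: fraction of samples with *r* > *R*/2
  (radial-midpoint rule; the equal-area alternative *r* > *R*/√2 is a
  config option). A retrieval-only variant conditions on the phase label.
- **Path metrics** per cue→drop leg, keyed by the unordered pair of known
  locations (8 targets + start ⇒ C(9,2) = 36 path ids): traveled
  distance; crow distance between the actual segment endpoints (so
  sinuosity = traveled/crow ≥ 1, undefined — NaN, never coerced — when
  the endpoints coincide); maximum absolute deviation from the straight
  chord; x-/y-flips counted as velocity-component sign changes after
  merging legs below a 50 U.u. displacement debounce (the flip definition
  needs *some* debounce; 50 U.u. suppresses 10 Hz sampling jitter at
  default speeds); idle time as the summed duration of intervals slower
  than 1% of the navigator speed.
- **LISAS** (linear integrated speed–accuracy score):
  `RT_i + (SD_RT / SD_DE) · DE_i` with SDs over all of the participant's
  trials (ddof = 1). All-zero drop errors give LISAS = RT (zero penalty);
  constant *nonzero* errors are a degenerate-variance error. The score is
  invariant to rescaling the drop-error units.
- **AUC**: trapezoidal area of drop error over cumulative navigation
  duration, with the curve extended left-constant to time zero; computed
  over the full session by default (per-block AUC is possible by slicing
  events).

## Density maps and Gi*

Heat maps: per-bin sample counts over the arena bounding box (default
101×101), Gaussian-smoothed with kernel SD 5 bins, peak-normalized, then
log1p-transformed (normalization and transform variants are config
options). Group difference maps subtract transformed intensities on the
same grid and are antisymmetric and shift-linear by construction.

Because rectangular binning introduces artefacts, inference runs on a
flat-top hexagonal lattice clipped to centroids inside the disc
(neighbor spacing √3·cell_size; default cell size 700 U.u. gives 61
tiles over the default arena). Neighborhoods are each tile's own
centroid plus its k nearest centroids (k = 6, the hexagonal coordination
number), i.e. self-inclusive binary weights; row-standardized weights
are available. The local Getis-Ord statistic per tile is

    z_i = (Σ_j w_ij x_j − X̄ W_i) / (S √[(n S1_i − W_i²)/(n−1)])

with X̄ and S the global mean and population SD, W_i = Σ_j w_ij and
S1_i = Σ_j w_ij². Positive z marks clustering of high values. A constant
field is 0/0 everywhere and raises a dedicated error. Tiles are flagged
at two-sided normal p < 0.10 — a *descriptive* threshold, deliberately
uncorrected for multiple comparisons; the map is an exploration device,
not a test. Group comparisons compute Gi* on the difference of per-tile
crossing fractions (cohort-size-normalized); a per-group mode is a one
liner via `hex_crossings`.

On iid Gaussian null fields the flag rate is 0.099 over 1000 simulated
61-tile maps (the acceptance suite recomputes this), confirming the
normal approximation is adequate at this n and k.

## Group statistics

Estimation is delegated to statsmodels; this module owns the model
assembly and reporting. All fitters are deterministic given the data.

- **Beta regression** (`BetaModel`): probit link by default (logit and
  cauchit available), single log-link precision parameter Φ. Boundary
  proportions must be squeezed first via (y(n−1)+0.5)/n. BFGS with
  gradient tolerance 1e-8; a fit is accepted when the optimizer converges
  or the final score norm is below 1e-4 (BFGS occasionally flags
  precision loss on a solved problem), else a Nelder-Mead restart, else a
  hard error — never a silent bad fit. The reported pseudo-R² is the
  standard beta-regression one (squared correlation of the
  link-transformed response with the linear predictor); Cragg-Uhler is
  reserved for the discrete-likelihood count models, where it is well
  defined.
- **Hurdle negative binomial**: logistic model of P(y > 0) plus
  zero-truncated NB2 on the positive counts
  (`TruncatedLFNegativeBinomialP`); the joint log-likelihood is exactly
  the sum of the two parts (verified in tests against a hand-coded hurdle
  density). All-zero or all-positive responses fail with an explicit
  message naming the degenerate component. Wald CIs are normal-theory;
  at n ≈ 500 their empirical coverage runs one to two points below the
  nominal 95% (a known property of Wald intervals in these models), which
  the acceptance suite's coverage bands account for.
- **Dispersion check**: Pearson χ² / residual df of a Poisson GLM — the
  standard overdispersion diagnostic that motivates NB/hurdle modeling.
- **Model comparison**: LRT (caller declares nesting) plus ΔAIC/ΔBIC
  reported as reduced − full, so positive deltas favor the fuller model.

## Pipeline and problem sizes

`run_study` funnels all randomness through one master `SeedSequence`, so
deterministic stages are bit-identical on rerun. The analysis drivers and
the acceptance script run studies of 6–8 navigators per cell with
single-block 2-minute arena sessions: tens of drop-offs per navigator are
enough for every direction-recovery and calibration check while keeping a
full 20-replicate ensemble under a minute. The generator *defaults*
remain the full task design (six 10-minute blocks); passing
`ArenaConfig()` unchanged reproduces hour-long sessions.

Small cohorts can separate the hurdle's logistic component (too few
zero-error navigators in a cell); the pipeline then backs off to a
sex-only design and, failing that, records the degeneracy in the report
instead of aborting the study.

## Known limitations

- The steering model is phenomenological; its parameters are chosen for
  qualitative realism (speeds, trial durations, and error magnitudes in
  the right ranges), not fitted to any participant data.
- Periphery preference is a *proportion of samples*, so behaviors that
  lengthen inner-half travel (central ring attractors, central targets)
  move it even when wall-hugging is unchanged.
- Gi* p-values are per-tile normal approximations without multiplicity
  correction, by design.
- Mixed-effects models with temporal autocorrelation, Conway-Maxwell-
  Poisson and zero-inflated Poisson fits, and post-hoc contrast machinery
  are out of scope; the tidy per-trial tables are the extension point.
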