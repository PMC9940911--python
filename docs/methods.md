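# Methods

## Model

Choice behaviour in the two-armed reversal task is modelled as a hybrid
of delta-rule value learning and a drift-diffusion choice rule (an
RLDDM).  Each option carries an expected value `Q` in [0, 1], updated
after feedback by `Q <- Q + α (R − Q)` with `R ∈ {0, 1}`.  The dual-rate
variant uses `α⁺` for positive and `α⁻` for negative prediction errors;
the single-rate variant ties them.  Learning rates are parameterised on
an unbounded scale and mapped through the logistic function at use time;
this keeps hierarchical normal population distributions well-defined and
is the only convention consistent with reporting group-level rates below
zero alongside rates in (0, 1).

The decision is a Wiener diffusion with unit diffusion coefficient on
`(0, a)`, started at `z·a`, with trial-wise drift `v_t = m (Q_A − Q_B)`
computed from the *pre-feedback* values (the decision precedes the
outcome).  Hitting the upper boundary selects option A.  Observed
decision time is first-passage time plus the non-decision time `t`.  The
drift-rate scaling `m` plays the role of a softmax inverse temperature:
at `m = 0` the diffusion is value-blind and chooses at chance; large `m`
makes choices deterministic in the value difference.  A choice of the
strictly lower-valued option is exploratory; ties count as not
exploratory (relevant only on the first trials, before values separate).

Assumptions: no inter-trial variability parameters (the four-parameter
model), independent Bernoulli reward arms, values initialised at the
outcome-range midpoint `Q₀ = 0.5` (the natural uninformative choice; the
initialisation convention shifts early-trial classifications slightly),
and no value update on omitted trials since no feedback is shown.

## Parameters

| parameter | meaning | units | default group mean (ON / OFF / HC) |
|---|---|---|---|
| `a` | boundary separation | evidence | 1.78 / 1.96 / 1.96 |
| `t` | non-decision time | s | 0.57 / 0.57 / 0.42 |
| `z` | relative start point | – | 0.5 |
| `m` | drift-rate scaling | evidence per unit ΔQ | 3.40 / 4.51 / 2.80 |
| `α⁺` (raw) | positive-PE learning rate | unbounded | 0.22 / −0.85 / −0.85 |
| `α⁻` (raw) | negative-PE learning rate | unbounded | −2.65 / −2.97 / −1.65 |

The ON/OFF locations are fitted whole-task group means for the patient
conditions; the control column applies the reported group contrasts
(lower `m`, higher `α⁻`, faster `t`) to the OFF baseline.  Between-
subject SDs (0.25, 0.10, 0.05, 1.30, 1.0, 1.0 in table order) are chosen
once to give individual-estimate scatter comparable to subject-level
fits; they are deliberately wide enough that parameter recovery has
signal to detect.

## Synthetic data generator

`rlddm.task` emulates the study conditions: 18 subjects per group, three
40-trial sessions, 80%:20% arms reversing after trial 60 (the swap takes
effect from trial 61, so pre-reversal is trials 1–60), a 3 s response
window, and omissions at a 1.5% Bernoulli lapse rate per trial (matching
reported omission counts of 0–8 in 120 trials).  Behaviour is generated
by the closed loop: drift from the current value difference → simulated
diffusion (choice, decision time) → outcome drawn from the schedule →
delta-rule update of the chosen option.  A diffusion that has not
terminated within the response window is recorded as an omission — a
second, mechanistic omission source that mirrors how slow decisions are
lost in the task; agents with very low drift can therefore exceed the
lapse-only omission count.

The voxel-map generator plants a chosen across-subject correlation
between a behaviour vector and every voxel inside an effect region;
outside the region the maps are i.i.d. Gaussian noise.  Real
connectivity maps are spatially smooth and share a strong common profile
across subjects; unstructured noise is the harder case for the R-map
pipeline's null (see below) but does not emulate spatial autocorrelation,
so passing tests demonstrate the correctness and calibration of the
procedure, not the effect sizes to expect on real maps.  The same
applies to behaviour: the generator produces stationary agents with no
fatigue, attention lapses beyond the Bernoulli mechanism, session-break
effects, condition-order effects, or disease-specific biases.

## Likelihood and numerics

The WFPT density is evaluated with the standard pair of series
expansions — the small-time image sum and the large-time eigenvalue
(sine) series — choosing per evaluation whichever needs fewer terms for
a truncation error of 1e−7.  Decision times at or below the non-decision
time return `−inf` log density (an impossible observation, distinct from
numeric failure).  The diffusion coefficient is fixed at 1; estimates are
only comparable under a fixed scale convention.

Trial simulation uses Euler–Maruyama with step 1e−4 s, a 10 s cap
(non-terminating walks are flagged censored), and the
Broadie–Glasserman–Kou continuity correction — boundaries pulled in by
`0.5826·√step` — which removes the leading-order discretisation bias in
first-passage times.  At these settings the simulator matches the
analytic density to a Kolmogorov–Smirnov distance of ≈ 0.003–0.004 at
10⁵ draws, dominated by sampling noise.

## Hierarchical inference

Every subject contributes one dataset per condition.  `a`, `m`, `α⁺`,
`α⁻` are condition dependent (separate group normals per condition); `t`
and `z` are subject traits assumed unaffected by condition ( `z` is
estimated, shared across conditions).  Priors are weakly informative in
the hierarchical-DDM style: group means ~ broad normals (e.g.
`a: N(1.5, 1)`, `m: N(0, 5)`, raw rates `N(0, 2)`, `t: N(0.4, 0.5)`,
`z: N(0.5, 0.2)`), group SDs ~ half-normal.  Subject-level proposals are
bounded to the simulable support (`a ∈ (0.05, 10)`, `t > 0`,
`z ∈ (0.02, 0.98)`); `t` is additionally capped by each subject's
minimum decision time through the likelihood.

The sampler is an adaptive Metropolis-within-Gibbs written for this
likelihood: random-walk Metropolis on each subject-level parameter
(proposal scales adapted in blocks of 50 burn-in sweeps toward 0.44
acceptance), conjugate normal draws for group means, and log-scale
random-walk Metropolis for group SDs.  Per-dataset log likelihoods are
cached so a subject-parameter update re-scores only the affected
condition.  The model log likelihood at any point equals the sum of
trial-wise WFPT terms exactly (tested).  Convergence is summarised by
the Gelman–Rubin statistic of the group-level nodes (arviz); a fit with
any R-hat ≥ 1.1 warns rather than fails.

Budgets: the reference budget is 4 chains × (7,000 burn-in + 15,000
draws).  The analysis drivers, tests and the acceptance script run 2
chains × (1,000 + 1,000), which this sampler's R-hat and recovery
results show is sufficient at the 18-subject, 120-trial problem size;
the full budget remains available via arguments.

Model comparison uses DIC = D̄ + p_D with p_D = D̄ − D(θ̂), θ̂ the
posterior mean of the subject-level parameters; non-finite deviance
draws are excluded with a logged count.  Contrasts are draw-wise
differences of group means with 85% and 95% highest-density intervals;
a difference is called significant when the 95% HDI excludes zero.

## Validation

Posterior-predictive checks simulate 50 full replications from the
posterior-mean subject parameters (full-posterior simulation is
available behind a flag) and compare learning curves — the per-trial
probability of choosing the objectively better arm — decision-time
distributions and exploration statistics; the observed curve should sit
inside the 95% replication band at ≥ 90% of trials when the model
generated the data.  Parameter recovery simulates five cohorts at the
study scale from known parameters, refits each at the reduced budget,
and correlates generating with recovered subject-level values; all four
condition-dependent parameters recover with r ≈ 0.75–0.95.  The
exploration map simulates 20 datasets per grid cell (the mapping
convention) over `α⁺`, `m`, `a` centred on the OFF-state means;
P(Explore) is ≈ 0.5 at `m = 0` (slightly below, because first-trial ties
are not exploratory) and decreases monotonically in `m`.

## Connectivity R-map pipeline

The R-map is the voxelwise Pearson correlation, across subjects, between
connectivity maps and the behavioural regressor (the max-session
increase in P(Explore); a whole-task variant is provided).  Each
subject's spatial correlation with the R-map is then regressed against
the behaviour.  This pipeline is circular — the map is built from the
subjects it is tested on — so on maps with many independent voxels the
in-sample prediction R² is strongly optimistic (approaching 1 as the
voxel count grows; with V ≫ S the similarity vector converges to the
regressor itself).  The permutation test is therefore the meaningful
inferential output: the *entire* pipeline is recomputed for each of
1,000 shuffles of the behaviour vector, which reproduces the circular
inflation under the null.  P-values use add-one smoothing and are
reported both two-sided (|R|) and directional.  Under a null generator
the permutation p is uniform (tested over 200 replicates); the power to
detect a planted effect is limited by the inflated null and grows with
the spatial extent of the effect region relative to the grid — the
strong-effect check accordingly plants an extended region on a compact
grid.

Heat maps: the n-map counts, per voxel, how many subjects' binary
stimulation volumes cover it; a region's weighted overlap is the sum of
n-map values inside its mask (probabilistic masks binarised at 50% by
default).  Grids must match exactly; there is no silent resampling.

## Known limitations

* The sampler explores the hierarchical posterior by random-walk moves;
  it is well-calibrated at this model's size but would need longer
  chains for much larger cohorts or models with strong posterior
  correlations.
* Exact priors and transforms of any particular published fit are
  unknowable from summary tables; posterior means on real data may
  differ modestly under other conventions, and the fitted-value defaults
  of the generator inherit that uncertainty.
* The R-map stage treats voxels as exchangeable; spatial autocorrelation
  in real maps changes effective dimensionality and hence in-sample R²,
  though not the validity of the permutation test.
* Repeated-measures ANOVA-style group hypothesis testing is out of
  scope; the behavioural module exports tidy tables for any stats
  package.
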