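# Methods

This note documents the models, parameter choices, numerical conventions and
known limits of the `alloreach` pipeline. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scene design

The table top is an 80 x 80 cm square with the origin at its centre,
x positive to the participant's right, y positive away from the participant;
all lengths are cm. The catalog holds six objects, three per semantic
cluster (natural: apple, banana, pear; man-made: pencil case, puncher,
stapler), with planar footprints of length (x) by width (y); heights are
metadata only — collision tests are planar.

Arrangements are rejection-sampled: object centres are drawn uniformly in a
central placement zone (default half-extent 25 cm), and a draw is accepted
only if (a) no footprint leaves the table, (b) no footprint intersects the
central fixation disc (default radius 10 cm; the disc size is a design
choice, configurable), and (c) all 15 object pairs keep at least 1 cm of
clearance (each rectangle inflated by half the padding). The 25 cm zone was
chosen so that realized target-cluster distances are of order 25 cm, the
scale typical of a reachable tabletop scene. Each of the six objects serves
as target in `n_per_target` (default 4) arrangements.

Two additional constraints operate at the set level:

* **Shift feasibility.** An arrangement is accepted only if every candidate
  landmark shift — both directions, the congruent pair and all three
  incongruent pair options — can be realized for *any* magnitude in the
  configured range without leaving the table or touching a stationary
  object. Stationary clearance uses the swept footprint over the whole
  magnitude range (conservative); the two co-shifted objects, which move
  nearly together, are tested with their maximal relative displacement.
  This guarantees the later expansion never has to discard an arrangement.
* **Cluster-distance balance.** The whole set is regenerated until the
  dataset means of dTownC (target to its two own-cluster members) and
  dTotherC (target to the three other-cluster members) agree within 3 cm,
  so congruent landmarks hold no systematic spatial advantage.

`expand_design` emits, per arrangement, one baseline scene plus four shift
scenes (left/right x congruent/incongruent): 24 x 5 = 120 scenes. Congruent
shifts displace the two remaining own-cluster objects; incongruent shifts
displace two of the three other-cluster objects, the pair choice
counterbalanced over each target's arrangements. Displacement magnitudes are
drawn per object from Uniform(4, 6) cm — 5 cm on average, and able to
represent the {4, 5} worked example — with a fixed-magnitude option. The
MERE of a scene is the mean signed displacement of its shifted objects
(baseline: 0); rightward is positive.

The spatial-advantage diagnostic pairs each participant's weight for a
target cluster with that cluster's mean advantage (dTotherC - dTownC),
separately per congruence, and reports Pearson r with a two-sided p. The
unit of pairing is a repo choice; the advantage has only two distinct values
(one per cluster), so the correlation is effectively a two-group contrast.

## Reaching generator

The generator inverts the measurement model the analysis estimates. Each
participant draws one latent weight per congruence condition from
Normal(w_condition, sigma_w), shared across the two clusters (a
`cluster_offset` parameter exists for power studies of cluster effects).
Endpoints land at

```
x = target_x + w * MERE + bias_x + N(0, sigma_x)
y = target_y + N(0, sigma_y)
```

The shift term is additive in x only because landmark shifts are horizontal
and the weight statistic uses horizontal error; y error is pure noise.
Defaults: w_congruent = 0.28, w_incongruent = 0.13, sigma_x = 4.73 cm,
sigma_y = 6.51 cm — the cell means and endpoint dispersions of the study
conditions this pipeline models — and bias_x = 1 cm for the rightward hand
bias. sigma_w = 0.10 is the package's own choice: the between-participant
SD implied by cell SEMs of 0.02-0.04 at n = 21 is 0.09-0.18 in total, part
of which is trial-sampling noise rather than true heterogeneity.

The trial timeline is encoding (modeled at a fixed 2.0 s; self-paced in the
task being emulated), mask 0.2 s, delay 1.8 s, test 1.0 s, then an auditory
go signal at t = 5.0 s. Reaction times are Normal(0.30, 0.05) s (floor
0.15 s) and movement durations Normal(0.8, 0.1) s (floor 0.3 s). Fingertip
trajectories are minimum-jerk profiles `s(tau) = 10 tau^3 - 15 tau^4 +
6 tau^5` from the start cube at (0, -30) cm to the endpoint, sampled at
250 Hz from 0.6 s before the go signal until 0.1 s after touch, with a
smooth vertical lift (peak 10 cm) vanishing at both ends and 0.002 cm
Gaussian marker jitter (sub-resolution jitter keeps the 10%-of-peak onset
detector noise-free even for short reaches). The recorded endpoint is by
definition the final trajectory sample's table-plane coordinates. Gaze is
modeled directly as table-surface intersection points around the fixation
cross (SD 0.3 cm), sampled at 120 Hz over the fixation-required phases
(mask through end of reach); the pipeline never needs angular gaze.

Contamination processes, each independent per trial with its own rate and
recorded as hidden ground truth:

* marker dropout (rate 0.06): half the affected trials truncate to < 20
  samples, half dive below the table surface mid-flight;
* premature starts (rate 0.03): onset shifted 200-500 ms before the go;
* fixation violations (rate 0.12): a 5-8 cm gaze excursion lasting 0.2-0.5 s,
  large and long enough to survive the median filter.

All randomness descends from one root seed; `simulate_cohort` spawns one
`SeedSequence` child per participant, so cohorts are bit-reproducible and
participants independent.

## Trial reduction

Five filters, evaluated in order; each produces a boolean flag and a trial
survives only if all are false:

1. fewer than 20 trajectory samples;
2. any sample outside the table's x/y extent or more than 0.5 cm below its
   surface;
3. movement onset — the first sample whose speed (central finite
   differences, one-sided at the ends; no smoothing by default, a 5-sample
   moving average behind a flag) exceeds 10% of peak speed — earlier than
   the go signal. Peak speeds below 1 mm/s signal "no movement". The flag is
   evaluated only on trials that passed the marker filters, since onset is
   meaningless on a broken trajectory;
4. endpoint error (endpoint minus target position) deviating more than 2 SD
   horizontally or vertically from its stratum's mean, with stratum
   statistics computed — and the flag evaluated — on trials surviving
   filters 1-3. The stratum is the shift-direction x congruence cell across
   participants (a pooled-stratum option exists); target-relative errors are
   used because raw endpoints vary with the arrangement's target position;
5. after a 15-sample running median (truncated windows at the edges), a
   gaze excursion range exceeding 4 cm on either axis during the
   fixation-required phases.

For speed, the gaze filter exploits the fact that a running median never
leaves the raw signal's range: trials whose raw range is already below the
threshold are on the same side of the decision and skip the exact filter.
With Gaussian endpoint noise the 2-SD rule alone removes ~9% of trials
(1 - (1 - 0.0455)^2), and the default contamination rates put overall
retention near 73%.

## Weights and inference

Reaching errors are baseline-relative, with a three-level reference
hierarchy per participant: the baseline endpoint of the same arrangement;
else the mean baseline error for the same target object; else the
participant's grand baseline error (all as target-relative horizontal
errors). Weights are formed from cell-mean errors and cell-mean MEREs, not
averaged trial-wise ratios, because trial-wise ratios are far noisier; the
across-direction form `(err_R - err_L) / (MERE_R - MERE_L)` additionally
cancels direction-independent bias. Cells missing a whole direction are
flagged incomplete and propagate as missing, never imputed.

The 2x2 within-subject ANOVA tests each effect against its own
effect-by-subject interaction; with 2-level factors sphericity holds
automatically, so no correction is exposed, and each main-effect F equals
the squared paired-t statistic on the marginal means (used as a test
oracle, alongside a cross-check against an independent implementation).
Partial eta squared is SS_effect / (SS_effect + SS_error). Participants with
any missing cell are excluded listwise. The four tests against zero form one
Holm family; pairwise EMM contrasts form their own family. Holm adjustment
is the standard step-down procedure; note it is *not* idempotent
(re-adjusting adjusted values inflates them), so tests assert dominance,
order-invariance and rank monotonicity instead.

## Power analysis

Power is the fraction of simulated datasets rejecting the congruence effect
at alpha. The summary mode draws n paired differences from Normal(dz, 1)
and applies the paired t-test — exact for this effect since F = t^2 in a
2-level within design — at 10,000 replicates by default (2,000 behind the
CLI `--fast` flag). The default dz = sqrt(11.447 / 21) ~= 0.738
back-computes a paired effect size from a reported F(1, 20) = 11.447 at
n = 21; it is a reconstruction from a published test statistic, not a
pilot-data estimate, so the historically chosen minimum sample size is not
claimed to be exactly reproducible. The pipeline mode replaces the normal
draw with a full simulate / preprocess / weights / ANOVA cycle per
replicate. A closed-form noncentral-t power serves as the analytic oracle.

## Multi-arrangement RSA

Latent semantic spaces place 7 cluster centres on a circle (radius 5) with
isotropic item scatter (SD 0.8) in 2 dimensions; 49 items by default. A
session's first trial contains all items; later trials are random subsets
(>= 3 items) or subsets chosen by a simplified lift-the-weakest heuristic.
Screen positions are a trial-specific random rotation and scaling
(Uniform(0.5, 2)) of the latent coordinates plus Gaussian placement noise
(default SD 0.5), so each trial measures the latent geometry up to scale.

The RDM estimator initializes from the (complete) first trial scaled to
unit RMS and iterates to convergence (cap 100 sweeps, tolerance 1e-6 on the
max entry change): per-trial least-squares scale factors against the
current estimate over shared pairs, then per-pair evidence-weighted means of
the scaled distances, with evidence proportional to the squared scaled
distance — pairs dragged close together carry little metric evidence. The
final matrix is normalized to unit maximum (so pooled dissimilarities live
in [0, 1]; unit-RMS available), and pooling across participants is the
entrywise mean of unit-max matrices. Unobserved pairs stay missing with a
warning. The subset selector starts from the least-evidenced pair and
greedily adds the item with the largest still-needed evidence per unit of
added trial cost (cost ~ size^1.5), stopping when the marginal gain-per-cost
drops below the best running ratio; it is a documented simplification of
the adaptive selector used by multi-arrangement software, and sessions can
always be generated with random subsets so estimation is testable
independently of it. The 12-minute session budget is modeled as a 24-trial
budget.

MDS uses SMACOF metric-stress majorization with a classical-scaling
initialisation (exact on Euclidean-embeddable inputs; seeded random
restarts optional) and reports normalized stress-1. The random-triad test
draws distinct random triads uniformly without replacement (excluding the
candidate), so setting n_random at or above the population size reproduces
exhaustive enumeration; the t statistic is a one-sample t of the
triad-minus-random-mean differences.

## What the synthetic data do and do not show

The generator reproduces exactly the structure the analysis assumes:
additive horizontal shift transfer, Gaussian endpoint noise, independent
contamination, minimum-jerk kinematics. Passing tests therefore demonstrate
that the pipeline is a consistent, approximately unbiased estimator *under
its own measurement model* — they cannot certify robustness to real-data
departures such as non-Gaussian endpoint errors, target-dependent movement
strategies, serial dependence across trials, or oculomotor dynamics (gaze
is a noise process around fixation, not a saccade model). One quantitative
consequence is worth stating: with trial-level sigma_x = 4.73 cm and 12
trials per cell and direction, weight-estimation noise alone is ~0.19 per
participant-cell, so the per-cohort between-participant SEM of recovered
weights is ~0.05 — noticeably above the 0.02-0.04 cell SEMs typical of
empirical weight tables, which implies that within-cell trial noise in real
data is smaller than the group-level dispersion that sigma_x encodes.

## Problem sizes

Defaults throughout are full study scale (120 scenes, 21 participants, 2520
trials, 10,000 power replicates). Repeated-cohort experiments in the test
suite and acceptance script use 200 cohorts, enough to pin grand means to
~0.003 (3 Monte Carlo SEs ~ 0.01); pipeline-mode power checks use reduced
replicate counts with correspondingly wide Monte Carlo tolerances.
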