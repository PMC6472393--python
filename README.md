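# alloreach

Analysis pipeline for quantifying how **object semantics modulate
allocentric spatial coding** in memory-guided reaching.

When people reach to a remembered target on a table, they encode its
location partly relative to themselves (egocentrically) and partly relative
to surrounding landmark objects (allocentrically). If two landmarks are
covertly shifted sideways between encoding and reach, a purely allocentric
observer's endpoint moves with them; a purely egocentric observer's endpoint
does not. The *allocentric weight*

```
w = reaching error relative to baseline / MERE,
MERE = mean horizontal displacement of the shifted landmarks
```

is the fraction of the landmark shift transferred to the endpoint
(w = 2 / 4.5 = 0.44 means a 44% allocentric influence). One weight per
condition cell is computed across shift directions,
`w = (err_R - err_L) / (MERE_R - MERE_L)`, which cancels any
direction-independent bias such as a rightward hand bias. The scientific
question is whether w is larger when the shifted landmarks belong to the
same semantic cluster as the target (congruent: e.g. fruit landmarks for a
fruit target) than when they belong to the other cluster (incongruent).

The package covers the complete chain, end to end, on synthetic data whose
generator mirrors the measurement model:

| module | what it does |
| --- | --- |
| `scene_design` | six-object catalog (3 natural, 3 man-made), constrained random table arrangements, 120-scene shifted design, MERE and target-cluster distance diagnostics |
| `synthetic_data` | minimum-jerk reach trajectories (250 Hz), gaze-on-table traces (120 Hz), endpoint model `target + w x MERE + bias + noise`, contamination processes; latent clustered semantic spaces and multi-arrangement sessions |
| `preprocessing` | trial reduction: sample-count, bounds, premature-start (10%-of-peak-velocity onset), 2-SD endpoint, and gaze-fixation filters |
| `allocentric_weights` | baseline-relative errors, MERE-normalized weights per participant x congruence x cluster |
| `inferential_stats` | Shapiro-Wilk screen, 2x2 repeated-measures ANOVA with partial eta squared, tests vs zero, Holm correction, EMM contrasts |
| `power_sim` | Monte Carlo a-priori power for the congruence effect (paired-t shortcut and full-pipeline modes) |
| `semantic_rsa` | RDM estimation from partial multi-arrangement trials, pooling, metric MDS, random-triad tests, triad selection |

## Worked example

```python
import alloreach as ar

arrangements = ar.generate_arrangements(seed=7)        # 24 layouts
design = ar.expand_design(arrangements, seed=7)        # 120 scenes
cohort = ar.simulate_cohort(design, arrangements, n_participants=21, seed=7)
clean, report = ar.apply_exclusions(cohort)
print(report.summary())
weights = ar.aggregate_weights(clean)
print(ar.stats_report(weights))
```

prints (abridged):

```
trials inspected: 2520
  low_samples: 2.5% affected
  out_of_bounds: 3.5% affected
  premature: 2.5% affected
  endpoint_outlier: 8.2% affected
  gaze_violation: 12.8% affected
retained: 72.6%

cell descriptives:
  congruent/natural: M = 0.254, SEM = 0.058 (n = 21)
  congruent/man-made: M = 0.216, SEM = 0.042 (n = 21)
  incongruent/natural: M = 0.086, SEM = 0.044 (n = 21)
  incongruent/man-made: M = 0.196, SEM = 0.045 (n = 21)

repeated-measures ANOVA (2 x 2 within):
  congruence: F(1, 20) = 3.466, p = 0.077, pes = 0.15
  ...
```

The 2520 raw trials are the 120 scenes reached once by each of 21 simulated
participants; ~27% are removed by the five filters. The cell means recover
the generating weights (0.28 congruent, 0.13 incongruent) up to one cohort's
sampling noise; the congruence F statistic for a single cohort fluctuates
around the ~0.74-dz effect the defaults encode.

The same pipeline is scriptable from the shell:

```bash
alloreach design --seed 7 --outdir design
alloreach simulate --design-dir design --n-participants 21 --outdir trials
alloreach preprocess --trials-dir trials --outdir clean
alloreach weights --clean-trials clean/clean_trials.tsv --out weights.tsv
alloreach stats --weights weights.tsv
alloreach power --fast
alloreach rsa --n-participants 15
```

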