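"""Monte Carlo a-priori power analysis for the congruence main effect.

Power at a candidate sample size is the fraction of simulated datasets in
which the congruence effect is rejected at the chosen alpha. Two effect
specifications are supported:

* summary mode -- a paired standardized effect size dz: each replicate draws
  n paired differences from Normal(dz, 1) and applies the two-sided paired
  t-test. This is exact for the congruence effect because in a 2-level
  within design F equals the squared paired-t statistic.
* pipeline mode -- full GeneratorParams: each replicate simulates a cohort,
  runs trial reduction and weight aggregation, and tests the congruence
  effect of the repeated-measures ANOVA.

The default effect size dz = sqrt(F / n) = sqrt(11.447 / 21) ~= 0.738
back-computes a paired effect size from a reported repeated-measures
F(1, 20) = 11.447 at n = 21; it is a reconstruction from the published test
statistic, not a pilot-data estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allocentric_weights import aggregate_weights
from .inferential_stats import rm_anova_2x2
from .preprocessing import apply_exclusions
from .synthetic_data import GeneratorParams, simulate_cohort

#: dz reconstructed from F(1, 20) = 11.447 at n = 21
DEFAULT_DZ = float(np.sqrt(11.447 / 21))


@dataclass(frozen=True)
class PowerEstimate:
    n_participants: int
    n_sims: int
    power: float
    mc_se: float
    alpha: float


def analytic_paired_t_power(dz: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form two-sided paired t-test power via the noncentral t."""
    df = n - 1
    ncp = dz * np.sqrt(n)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))


def simulate_power(
    n: int,
    effect: float | GeneratorParams = DEFAULT_DZ,
    n_sims: int = 10_000,
    alpha: float = 0.05,
    seed=0,
    mode: str = "summary",
    design=None,
    arrangements=None,
) -> PowerEstimate:
    """Monte Carlo power of the congruence effect at sample size ``n``.

    In pipeline mode ``effect`` must be a :class:`GeneratorParams`; the
    design defaults to the standard 120-scene design. In summary mode
    ``effect`` is the paired effect size dz.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)

    if mode == "summary":
        dz = float(effect)
        draws = rng.normal(dz, 1.0, size=(n_sims, n))
        sd = draws.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise ValueError("degenerate effect specification (zero variance)")
        t = draws.mean(axis=1) / (sd / np.sqrt(n))
        crit = stats.t.ppf(1 - alpha / 2, n - 1)
        reject = np.abs(t) > crit
    elif mode == "pipeline":
        if not isinstance(effect, GeneratorParams):
            raise TypeError("pipeline mode requires GeneratorParams as the effect spec")
        if design is None or arrangements is None:
            from .scene_design import expand_design, generate_arrangements
            arrangements = generate_arrangements(seed=int(rng.integers(2**31)))
            design = expand_design(arrangements, seed=int(rng.integers(2**31)))
        reject = np.empty(n_sims, dtype=bool)
        for k in range(n_sims):
            cohort = simulate_cohort(design, arrangements, effect, n,
                                     seed=rng.integers(2**31))
            clean, _ = apply_exclusions(cohort)
            res = rm_anova_2x2(aggregate_weights(clean))
            reject[k] = res.effects["congruence"].p < alpha
    else:
        raise ValueError(f"unknown mode {mode!r}")

    power = float(reject.mean())
    se = float(np.sqrt(power * (1 - power) / n_sims))
    return PowerEstimate(n, n_sims, power, se, alpha)


def min_n_for_power(
    effect: float | GeneratorParams = DEFAULT_DZ,
    target_power: float = 0.80,
    n_range=range(5, 41),
    n_sims: int = 10_000,
    alpha: float = 0.05,
    seed=0,
    mode: str = "summary",
) -> tuple[int | None, pd.DataFrame]:
    """Smallest n in ``n_range`` whose estimated power reaches the target.

    Returns (minimal n or None if the target is unreachable in the range,
    full power curve). The curve is always returned.
    """
    if not 0 < target_power < 1:
        raise ValueError("target power must lie in (0, 1)")
    ss = np.random.SeedSequence(seed)
    rows = []
    found = None
    for n, child in zip(sorted(n_range), ss.spawn(len(list(n_range)))):
        est = simulate_power(n, effect, n_sims, alpha, seed=child, mode=mode)
        rows.append((est.n_participants, est.n_sims, est.power, est.mc_se, est.alpha))
        if found is None and est.power >= target_power:
            found = n
    curve = pd.DataFrame(rows, columns=["n_participants", "n_sims", "power",
                                        "mc_se", "alpha"])
    return found, curve
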