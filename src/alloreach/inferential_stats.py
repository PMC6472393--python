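"""Within-subject inference on the weight table.

The design is fully within-subject with two 2-level factors (semantic
congruence x semantic cluster of the target). The repeated-measures ANOVA
uses the classical subject-by-treatment decomposition: each effect is tested
against its own effect-by-subject interaction, F = MS_effect / MS_(effect x
subject), with partial eta squared = SS_effect / (SS_effect + SS_error).
With 2-level factors sphericity holds automatically, so no correction is
applied. Participants with any missing cell are excluded listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CELLS = [("congruent", "natural"), ("congruent", "man-made"),
         ("incongruent", "natural"), ("incongruent", "man-made")]


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    effects: dict[str, EffectResult]
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, e.F, e.df_effect, e.df_error, e.p, e.partial_eta_sq)
             for k, e in self.effects.items()],
            columns=["effect", "F", "df_effect", "df_error", "p", "partial_eta_sq"])


def _cell_matrix(weights: pd.DataFrame, dv: str = "weight") -> np.ndarray:
    """(n, 2, 2) array of cell values, listwise-complete participants only."""
    wide = weights.pivot_table(index="participant_id", columns=["congruence", "cluster"],
                               values=dv, aggfunc="mean")
    try:
        wide = wide[[c for c in CELLS]]
    except KeyError as err:
        raise ValueError("weight table must contain all four congruence x cluster cells") from err
    wide = wide.dropna()
    return wide.to_numpy(float).reshape(-1, 2, 2)


def rm_anova_2x2(weights: pd.DataFrame | np.ndarray, dv: str = "weight") -> AnovaResult:
    """2 x 2 repeated-measures ANOVA (congruence x cluster) on the weights.

    Accepts a weight table or a pre-built (n, 2, 2) cell array with axes
    (participant, congruence, cluster).
    """
    y = weights if isinstance(weights, np.ndarray) else _cell_matrix(weights, dv)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValueError("expected an (n, 2, 2) cell array")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete participants")

    grand = y.mean()
    subj = y.mean(axis=(1, 2))          # (n,)
    a_m = y.mean(axis=(0, 2))           # congruence means (2,)
    b_m = y.mean(axis=(0, 1))           # cluster means (2,)
    sa = y.mean(axis=2)                 # (n, 2) subject x congruence
    sb = y.mean(axis=1)                 # (n, 2) subject x cluster
    ab = y.mean(axis=0)                 # (2, 2)

    ss_a = 2 * n * ((a_m - grand) ** 2).sum()
    ss_b = 2 * n * ((b_m - grand) ** 2).sum()
    ss_ab = n * ((ab - a_m[:, None] - b_m[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((sa - subj[:, None] - a_m[None, :] + grand) ** 2).sum()
    ss_bs = 2 * ((sb - subj[:, None] - b_m[None, :] + grand) ** 2).sum()
    resid = (y - sa[:, :, None] - sb[:, None, :] - ab[None, :, :]
             + subj[:, None, None] + a_m[None, :, None] + b_m[None, None, :] - grand)
    ss_abs = (resid ** 2).sum()

    df_err = n - 1
    effects = {}
    for name, ss_eff, ss_err in (("congruence", ss_a, ss_as),
                                 ("cluster", ss_b, ss_bs),
                                 ("interaction", ss_ab, ss_abs)):
        if ss_err > 0:
            F = (ss_eff / 1) / (ss_err / df_err)
        else:
            F = 0.0 if ss_eff == 0 else np.inf
        p = float(stats.f.sf(F, 1, df_err))
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects[name] = EffectResult(float(F), 1, df_err, p, float(pes))
    return AnovaResult(effects, n)


def normality_screen(weights: pd.DataFrame, dv: str = "weight") -> pd.DataFrame:
    """Shapiro-Wilk W and p per congruence x cluster cell (advisory only)."""
    rows = []
    for (congruence, cluster) in CELLS:
        vals = weights[(weights["congruence"] == congruence)
                       & (weights["cluster"] == cluster)][dv].dropna().to_numpy()
        if len(vals) < 3:
            raise ValueError(f"cell {congruence}/{cluster}: need >= 3 values")
        if np.ptp(vals) == 0:
            raise ValueError(f"cell {congruence}/{cluster}: constant input, W undefined")
        w, p = stats.shapiro(vals)
        rows.append((congruence, cluster, len(vals), float(w), float(p)))
    return pd.DataFrame(rows, columns=["congruence", "cluster", "n", "W", "p"])


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjustment, returned in the original order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def tests_vs_zero(weights: pd.DataFrame, dv: str = "weight") -> pd.DataFrame:
    """Two-sided one-sample t per cell against zero, Holm-adjusted as a family."""
    rows = []
    for (congruence, cluster) in CELLS:
        vals = weights[(weights["congruence"] == congruence)
                       & (weights["cluster"] == cluster)][dv].dropna().to_numpy()
        if len(vals) < 2:
            raise ValueError(f"cell {congruence}/{cluster}: need >= 2 values")
        if np.ptp(vals) == 0 and vals[0] == 0:
            t, p = 0.0, 1.0
        elif np.ptp(vals) == 0:
            raise ValueError(f"cell {congruence}/{cluster}: zero variance")
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows.append((congruence, cluster, len(vals), float(np.mean(vals)),
                     float(stats.sem(vals)) if np.ptp(vals) else 0.0, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["congruence", "cluster", "n", "mean", "sem", "t", "p"])
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def emm_pairwise(weights: pd.DataFrame, effect: str = "cells", dv: str = "weight") -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means with Holm adjustment.

    ``effect`` is ``"congruence"`` or ``"cluster"`` (the two marginal means,
    one paired contrast) or ``"cells"`` (all six pairwise contrasts among the
    four cell means). In this balanced within design the contrasts reduce to
    paired t-tests on per-participant (marginal) cell means.
    """
    y = _cell_matrix(weights, dv)
    if effect == "congruence":
        levels = {"congruent": y.mean(axis=2)[:, 0], "incongruent": y.mean(axis=2)[:, 1]}
    elif effect == "cluster":
        levels = {"natural": y.mean(axis=1)[:, 0], "man-made": y.mean(axis=1)[:, 1]}
    elif effect == "cells":
        levels = {f"{c}/{cl}": y[:, i // 2, i % 2]
                  for i, (c, cl) in enumerate(CELLS)}
    else:
        raise ValueError(f"unknown effect {effect!r}")

    names = list(levels)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = levels[names[i]], levels[names[j]]
            diff = a - b
            if np.ptp(diff) == 0:
                t, p = (0.0, 1.0) if diff[0] == 0 else (np.inf, 0.0)
            else:
                t, p = stats.ttest_rel(a, b)
            rows.append((names[i], names[j], float(np.mean(a)), float(np.mean(b)),
                         float(np.mean(diff)), float(t), float(p)))
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "emm_a", "emm_b",
                                      "contrast", "t", "p"])
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def stats_report(weights: pd.DataFrame, dv: str = "weight") -> str:
    """Structured text report: descriptives, ANOVA, normality, tests vs zero."""
    anova = rm_anova_2x2(weights, dv)
    zero = tests_vs_zero(weights, dv)
    lines = [f"n complete participants: {anova.n_participants}", "", "cell descriptives:"]
    for _, r in zero.iterrows():
        lines.append(f"  {r['congruence']}/{r['cluster']}: M = {r['mean']:.3f}, "
                     f"SEM = {r['sem']:.3f} (n = {int(r['n'])})")
    lines.append("")
    lines.append("repeated-measures ANOVA (2 x 2 within):")
    for name, e in anova.effects.items():
        lines.append(f"  {name}: F({e.df_effect}, {e.df_error}) = {e.F:.3f}, "
                     f"p = {e.p:.3f}, pes = {e.partial_eta_sq:.2f}")
    lines.append("")
    lines.append("one-sample t vs zero (Holm-adjusted):")
    for _, r in zero.iterrows():
        lines.append(f"  {r['congruence']}/{r['cluster']}: t = {r['t']:.2f}, "
                     f"p_holm = {r['p_holm']:.4g}")
    try:
        shap = normality_screen(weights, dv)
        lines.append("")
        lines.append("Shapiro-Wilk normality screen:")
        for _, r in shap.iterrows():
            lines.append(f"  {r['congruence']}/{r['cluster']}: W = {r['W']:.3f}, "
                         f"p = {r['p']:.3f}")
    except ValueError:
        pass
    return "\n".join(lines)
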