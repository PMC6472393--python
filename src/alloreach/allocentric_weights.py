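"""Baseline-relative reaching errors and MERE-normalized allocentric weights.

The allocentric weight is the fraction of a landmark shift that transfers to
the reach endpoint: the horizontal reaching error relative to baseline (the
unshifted presentation of the same arrangement) divided by the MERE, the
mean horizontal displacement of the shifted objects. One weight per
participant and congruence x target-cluster cell is computed across shift
directions,

    w = (mean err_right - mean err_left) / (mean MERE_right - mean MERE_left),

which cancels any direction-independent endpoint bias. Weights are formed
from cell-mean errors and cell-mean MEREs rather than averaged trial-wise
ratios, mirroring how the aggregate quantities are defined.

Baseline reference hierarchy: the participant's baseline endpoint for the
same arrangement; if that trial was excluded, the participant's mean
baseline error for the same target object; failing that, the participant's
grand mean baseline error. All references are expressed as target-relative
horizontal errors so they remain comparable across arrangements.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic_data import ReachDataset

WEIGHT_COLUMNS = ["participant_id", "congruence", "cluster",
                  "err_left_cm", "err_right_cm", "mere_left_cm", "mere_right_cm",
                  "n_left", "n_right", "weight", "complete"]


def reaching_error(endpoint_x_cm: float, baseline_x_cm: float) -> float:
    """Signed horizontal error relative to the baseline reference (rightward +)."""
    return float(endpoint_x_cm) - float(baseline_x_cm)


def allocentric_weight(error_cm: float, mere_cm: float) -> float:
    """error / MERE, signs respected; undefined for a zero MERE."""
    if mere_cm == 0:
        raise ZeroDivisionError("allocentric weight undefined for MERE = 0")
    return float(error_cm) / float(mere_cm)


def weight_across_directions(
    mean_error_left_cm: float,
    mean_error_right_cm: float,
    mean_mere_left_cm: float,
    mean_mere_right_cm: float,
) -> float:
    """One weight across directions; cancels direction-independent bias."""
    denom = float(mean_mere_right_cm) - float(mean_mere_left_cm)
    if denom == 0:
        raise ZeroDivisionError("degenerate MERE difference across directions")
    return (float(mean_error_right_cm) - float(mean_error_left_cm)) / denom


def _baseline_references(trials: pd.DataFrame) -> tuple[dict, dict, dict]:
    base = trials[trials["congruence"] == "baseline"].copy()
    base["berr"] = base["endpoint_x_cm"] - base["target_x_cm"]
    by_arr = base.set_index(["participant_id", "arrangement_id"])["berr"].to_dict()
    by_tgt = base.groupby(["participant_id", "target_id"])["berr"].mean().to_dict()
    by_p = base.groupby("participant_id")["berr"].mean().to_dict()
    return by_arr, by_tgt, by_p


def aggregate_weights(data: ReachDataset | pd.DataFrame) -> pd.DataFrame:
    """Build the weight table from a preprocessed trial set.

    Returns one row per participant x congruence {congruent, incongruent} x
    target cluster {natural, man-made} with direction-wise mean errors and
    MEREs and the across-direction weight. Cells missing an entire shift
    direction get ``complete = False`` and a NaN weight; participants whose
    baseline trials were all excluded are dropped with a warning.
    """
    trials = data.trials if isinstance(data, ReachDataset) else data
    by_arr, by_tgt, by_p = _baseline_references(trials)

    shifted = trials[trials["congruence"] != "baseline"].copy()
    missing_base = [p for p in shifted["participant_id"].unique() if p not in by_p]
    if missing_base:
        warnings.warn(f"no usable baseline for participants {missing_base}; dropped")
        shifted = shifted[~shifted["participant_id"].isin(missing_base)]

    def ref(row):
        key = (row["participant_id"], row["arrangement_id"])
        if key in by_arr:
            return by_arr[key]
        key = (row["participant_id"], row["target_id"])
        if key in by_tgt:
            return by_tgt[key]
        return by_p[row["participant_id"]]

    if shifted.empty:
        return pd.DataFrame(columns=WEIGHT_COLUMNS)
    raw_err = shifted["endpoint_x_cm"] - shifted["target_x_cm"]
    shifted["err_cm"] = raw_err - shifted.apply(ref, axis=1)

    g = (shifted
         .groupby(["participant_id", "congruence", "target_cluster", "shift_direction"])
         .agg(err=("err_cm", "mean"), mere=("mere_cm", "mean"), n=("err_cm", "size"))
         .unstack("shift_direction"))

    rows = []
    for (pid, congruence, cluster), r in g.iterrows():
        err_l, err_r = r.get(("err", "left"), np.nan), r.get(("err", "right"), np.nan)
        mere_l, mere_r = r.get(("mere", "left"), np.nan), r.get(("mere", "right"), np.nan)
        n_l = r.get(("n", "left"), np.nan)
        n_r = r.get(("n", "right"), np.nan)
        n_l = 0 if pd.isna(n_l) else int(n_l)
        n_r = 0 if pd.isna(n_r) else int(n_r)
        complete = n_l > 0 and n_r > 0
        weight = (weight_across_directions(err_l, err_r, mere_l, mere_r)
                  if complete else np.nan)
        rows.append((pid, congruence, cluster, err_l, err_r, mere_l, mere_r,
                     n_l, n_r, weight, complete))
    out = pd.DataFrame(rows, columns=WEIGHT_COLUMNS)
    incomplete = out[~out["complete"]]
    if len(incomplete):
        warnings.warn(
            f"{len(incomplete)} weight cell(s) missing a shift direction; "
            "flagged incomplete and excluded from inference")
    return out


def load_weight_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a weight table from delimited text.

    ``column_map`` renames external columns onto the canonical schema
    (``participant_id``, ``congruence``, ``cluster``, ``weight`` at minimum),
    which is how externally deposited participant x condition weight tables
    are ingested after a documented manual mapping.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        table = table.rename(columns=column_map)
    required = {"participant_id", "congruence", "cluster", "weight"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"weight table missing columns {sorted(missing)}")
    return table


def write_weight_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
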