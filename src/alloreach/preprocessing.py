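"""Trial reduction: kinematic, endpoint and gaze-fixation filters.

Five exclusion criteria are evaluated in sequence, each producing an
independent boolean flag (flags are not mutually exclusive):

1. ``low_samples`` -- fewer than 20 trajectory samples (marker dropout);
2. ``out_of_bounds`` -- any trajectory sample outside the table's planar
   extent or below its surface;
3. ``premature`` -- movement onset (first sample whose speed exceeds 10% of
   peak speed) earlier than the go signal, evaluated on trials that passed
   the marker filters (onset is meaningless on a broken trajectory);
4. ``endpoint_outlier`` -- target-relative endpoint error deviating more than
   ``sd_mult`` standard deviations (horizontal or vertical) from its stratum
   mean, with stratum statistics computed -- and the flag evaluated -- on
   trials that survived filters 1-3;
5. ``gaze_violation`` -- after median filtering, the gaze excursion range
   during the fixation-required phases exceeds ``gaze_range_cm`` on either
   axis.

A trial survives if every flag is false.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import ReachDataset

FLAG_COLUMNS = ("low_samples", "out_of_bounds", "premature",
                "endpoint_outlier", "gaze_violation")

#: peak speeds below this floor (cm/s) count as "no movement"
SPEED_FLOOR_CM_S = 0.1


class NoMovementError(ValueError):
    """Raised when a trajectory never exceeds the minimal-speed floor."""


@dataclass(frozen=True)
class ExclusionCriteria:
    """Thresholds of the trial-reduction procedure."""

    min_samples: int = 20
    sd_mult: float = 2.0
    gaze_range_cm: float = 4.0
    median_window: int = 15
    table_half_cm: float = 40.0
    #: z below this (cm) counts as "underneath the table"
    z_floor_cm: float = -0.5
    #: "condition" strata (shift-direction x congruence) or one "pooled" stratum
    stratum: str = "condition"
    #: optional 5-sample moving average on speed before onset detection
    smooth_velocity: bool = False


@dataclass
class ExclusionReport:
    """Per-trial flags plus the per-criterion and overall proportions."""

    flags: pd.DataFrame
    proportions: dict[str, float] = field(default_factory=dict)
    retained_proportion: float = float("nan")

    @property
    def n_trials(self) -> int:
        return len(self.flags)

    def summary(self) -> str:
        lines = [f"trials inspected: {self.n_trials}"]
        for k in FLAG_COLUMNS:
            lines.append(f"  {k}: {self.proportions[k]:.1%} affected")
        lines.append(f"retained: {self.retained_proportion:.1%}")
        return "\n".join(lines)


def detect_movement_onset(trajectory: np.ndarray, smooth: bool = False) -> float:
    """Movement onset: time of the first sample whose speed exceeds 10% of peak.

    ``trajectory`` is an (n, 4) array of (t_s, x, y, z) samples. Speed is the
    norm of the position derivative, computed by central finite differences
    (one-sided at the ends). Raises :class:`NoMovementError` if the peak
    speed stays below 1 mm/s.
    """
    traj = np.asarray(trajectory, float)
    if traj.ndim != 2 or traj.shape[0] < 2 or traj.shape[1] < 4:
        raise ValueError("trajectory must be an (n >= 2, 4) array of t,x,y,z")
    t = traj[:, 0]
    vel = np.gradient(traj[:, 1:4], t, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    if smooth:
        speed = np.convolve(speed, np.ones(5) / 5, mode="same")
    peak = speed.max()
    if peak < SPEED_FLOOR_CM_S:
        raise NoMovementError("peak speed below the 1 mm/s floor")
    return float(t[np.argmax(speed > 0.1 * peak)])


def median_filter_gaze(samples: np.ndarray, window: int = 15) -> np.ndarray:
    """Running median with truncated windows at the edges.

    ``samples`` may be 1-D or (n, k); each column is filtered independently
    and the output has the same shape as the input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd count >= 1")
    arr = np.asarray(samples, float)
    if arr.size == 0:
        raise ValueError("empty gaze input")
    squeeze = arr.ndim == 1
    frame = pd.DataFrame(arr if not squeeze else arr[:, None])
    out = frame.rolling(window, center=True, min_periods=1).median().to_numpy()
    return out[:, 0] if squeeze else out


def _onset_times(data: ReachDataset, smooth: bool) -> np.ndarray:
    """Vectorised onset detection over the padded trajectory array.

    Returns +inf for trials whose peak speed stays below the floor.
    """
    traj = data.traj
    n, T, _ = traj.shape
    dt = 1.0 / data.traj_rate_hz
    vel = np.gradient(traj, dt, axis=1)
    speed = np.linalg.norm(vel, axis=2)
    # one-sided differences at each trial's own last valid sample
    last = data.traj_len - 1
    rows = np.arange(n)
    with np.errstate(invalid="ignore"):
        prev = np.clip(last - 1, 0, None)
        speed[rows, last] = np.linalg.norm(
            (traj[rows, last] - traj[rows, prev]) / dt, axis=1)
    speed = np.nan_to_num(speed, nan=0.0)
    if smooth:
        kern = np.ones(5) / 5
        speed = np.apply_along_axis(lambda s: np.convolve(s, kern, "same"), 1, speed)
    peak = speed.max(axis=1)
    crossed = speed > 0.1 * peak[:, None]
    idx = crossed.argmax(axis=1)
    onset = data.traj_t0_s + idx * dt
    onset[peak < SPEED_FLOOR_CM_S] = np.inf
    return onset


def _gaze_ranges(data: ReachDataset, window: int, threshold: float | None = None) -> np.ndarray:
    """(n_trials, 2) max-min filtered gaze excursion per axis.

    A running median never leaves the raw signal's range, so the raw range
    bounds the filtered range from above. When a decision ``threshold`` is
    given, trials whose raw range already sits below it keep their raw range
    (same side of the threshold, cheaper); only candidates get the exact
    truncated-window median filter.
    """
    out = np.empty((data.n_trials, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for axis in range(2):
            sig = data.gaze[:, :, axis]
            raw = np.nanmax(sig, axis=1) - np.nanmin(sig, axis=1)
            out[:, axis] = raw
            cand = np.arange(data.n_trials) if threshold is None else \
                np.flatnonzero(raw > threshold)
            if len(cand):
                frame = pd.DataFrame(sig[cand].T)
                filt = frame.rolling(window, center=True, min_periods=1).median()
                out[cand, axis] = (filt.max(axis=0) - filt.min(axis=0)).to_numpy()
    return out


def apply_exclusions(
    data: ReachDataset,
    criteria: ExclusionCriteria | None = None,
) -> tuple[ReachDataset, ExclusionReport]:
    """Apply the five trial-reduction filters; return (clean data, report)."""
    criteria = criteria or ExclusionCriteria()
    trials = data.trials
    n = data.n_trials

    low_samples = data.traj_len < criteria.min_samples

    h = criteria.table_half_cm
    with np.errstate(invalid="ignore"):
        out_of_bounds = (
            (np.abs(data.traj[:, :, 0]) > h)
            | (np.abs(data.traj[:, :, 1]) > h)
            | (data.traj[:, :, 2] < criteria.z_floor_cm)
        )
    out_of_bounds = np.nansum(out_of_bounds, axis=1) > 0

    # onset is meaningless on broken trajectories, so the premature filter is
    # evaluated on trials that survived the marker filters (sequential order)
    onset = _onset_times(data, criteria.smooth_velocity)
    premature = (onset < trials["go_time_s"].to_numpy()) & ~(low_samples | out_of_bounds)

    # endpoint outliers: target-relative errors vs stratum statistics, with
    # the statistics computed on trials that survived filters 1-3
    err = pd.DataFrame({
        "ex": trials["endpoint_x_cm"] - trials["target_x_cm"],
        "ey": trials["endpoint_y_cm"] - trials["target_y_cm"],
    })
    if criteria.stratum == "condition":
        strata = trials["shift_direction"].astype(str) + "/" + trials["congruence"].astype(str)
    elif criteria.stratum == "pooled":
        strata = pd.Series("all", index=trials.index)
    else:
        raise ValueError(f"unknown stratum rule {criteria.stratum!r}")
    usable = ~(low_samples | out_of_bounds | premature)
    endpoint_outlier = np.zeros(n, dtype=bool)
    for name, idx in err.groupby(strata).groups.items():
        pos = trials.index.get_indexer(idx)
        ok = usable[pos]
        ref = err.loc[idx][ok]
        if len(ref) < 2:
            warnings.warn(f"stratum {name!r} has fewer than 2 usable trials; "
                          "2-SD rule skipped there")
            continue
        mean, sd = ref.mean(), ref.std(ddof=1)
        dev = ((err.loc[idx] - mean).abs() > criteria.sd_mult * sd).any(axis=1).to_numpy()
        endpoint_outlier[pos] = dev & ok

    ranges = _gaze_ranges(data, criteria.median_window,
                          threshold=criteria.gaze_range_cm)
    gaze_violation = (ranges > criteria.gaze_range_cm).any(axis=1)

    flags = pd.DataFrame({
        "low_samples": low_samples,
        "out_of_bounds": out_of_bounds,
        "premature": premature,
        "endpoint_outlier": endpoint_outlier,
        "gaze_violation": gaze_violation,
    })
    flags.insert(0, "participant_id", trials["participant_id"].to_numpy())
    flags.insert(1, "condition_id", trials["condition_id"].to_numpy())
    flags["onset_s"] = onset

    keep = ~flags[list(FLAG_COLUMNS)].any(axis=1).to_numpy()
    report = ExclusionReport(
        flags=flags,
        proportions={k: float(flags[k].mean()) for k in FLAG_COLUMNS},
        retained_proportion=float(keep.mean()),
    )
    return data.subset(keep), report
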