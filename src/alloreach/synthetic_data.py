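"""Simulated reaching cohorts and multi-arrangement sessions.

The reaching generator inverts the measurement model the analysis estimates:
a participant carries one latent allocentric weight per congruence condition
(drawn once from a normal population distribution), and every reach endpoint
lands at the remembered target position plus weight x MERE along the shift
axis, plus a constant rightward bias and independent Gaussian endpoint noise.
Fingertip trajectories are minimum-jerk reaches sampled at 250 Hz; gaze on
the table surface is sampled at 120 Hz around the central fixation cross
during the phases that require fixation (mask, delay, test, reach).

Three contamination processes emulate the failure modes the trial-reduction
filters target: marker dropout (truncated or out-of-bounds trajectories),
premature movement starts (onset 200-500 ms before the go signal), and
fixation violations (gaze excursions beyond the tolerated range). Ground
truth for every contaminated trial is recorded so filter sensitivity and
specificity can be measured.

All randomness descends from a single root seed: ``simulate_cohort`` spawns
one independent child seed per participant via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene_design import (MAN_MADE, SceneArrangement, TrialCondition,
                           compute_mere)

# trial timeline (s): encoding is self-paced, modeled as a fixed duration
ENCODING_S = 2.0
MASK_S = 0.2
DELAY_S = 1.8
TEST_S = 1.0
#: auditory go signal, measured from trial start
GO_TIME_S = ENCODING_S + MASK_S + DELAY_S + TEST_S
#: fixation is required from mask onset to the end of the reach
FIXATION_START_S = GO_TIME_S - (MASK_S + DELAY_S + TEST_S)
#: trajectory recording begins this long before the go signal
PRE_GO_RECORD_S = 0.6
POST_TOUCH_RECORD_S = 0.1

#: start-position cube centre in table coordinates (cm): body midline,
#: 10 cm behind the placement zone's front edge
START_POSITION_CM = (0.0, -30.0, 0.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Population and nuisance parameters of the reaching generator.

    Weights are unitless fractions of the landmark shift transferred to the
    endpoint; noise terms are cm; rates are per-trial probabilities.
    """

    w_congruent: float = 0.28
    w_incongruent: float = 0.13
    sigma_w: float = 0.10
    sigma_x_cm: float = 4.73
    sigma_y_cm: float = 6.51
    bias_x_cm: float = 1.0
    movement_duration_mean_s: float = 0.8
    movement_duration_sd_s: float = 0.1
    movement_duration_min_s: float = 0.3
    reaction_mean_s: float = 0.30
    reaction_sd_s: float = 0.05
    reaction_min_s: float = 0.15
    lift_height_cm: float = 10.0
    marker_jitter_cm: float = 0.002
    gaze_noise_cm: float = 0.3
    rate_marker_fail: float = 0.06
    rate_premature: float = 0.03
    rate_gaze_violation: float = 0.12
    #: additive weight offset for man-made-target trials (0 = no cluster effect)
    cluster_offset: float = 0.0
    traj_rate_hz: float = 250.0
    gaze_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        for name in ("sigma_w", "sigma_x_cm", "sigma_y_cm", "marker_jitter_cm",
                     "gaze_noise_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rate_marker_fail", "rate_premature", "rate_gaze_violation"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TrialRecord:
    """One reaching trial as a self-contained record."""

    participant_id: str
    condition: TrialCondition
    trajectory: np.ndarray  # (n, 4): t_s, x_cm, y_cm, z_cm
    gaze: np.ndarray  # (m, 3): t_s, gx_cm, gy_cm
    go_time_s: float
    endpoint: tuple[float, float]


@dataclass
class ReachDataset:
    """Column-major cohort container.

    ``trials`` holds one row of metadata per trial; trajectories and gaze are
    NaN-padded arrays of shape (n_trials, T, 3) and (n_trials, G, 2) with
    per-trial valid lengths. ``trial_record(i)`` materialises the i-th trial
    as a :class:`TrialRecord`.
    """

    trials: pd.DataFrame
    traj: np.ndarray
    traj_len: np.ndarray
    traj_t0_s: np.ndarray
    gaze: np.ndarray
    gaze_len: np.ndarray
    gaze_t0_s: np.ndarray
    traj_rate_hz: float = 250.0
    gaze_rate_hz: float = 120.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def subset(self, mask: np.ndarray) -> "ReachDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ReachDataset(
            trials=self.trials.iloc[idx].reset_index(drop=True),
            traj=self.traj[idx], traj_len=self.traj_len[idx],
            traj_t0_s=self.traj_t0_s[idx],
            gaze=self.gaze[idx], gaze_len=self.gaze_len[idx],
            gaze_t0_s=self.gaze_t0_s[idx],
            traj_rate_hz=self.traj_rate_hz, gaze_rate_hz=self.gaze_rate_hz,
        )

    def trial_record(self, i: int, design_by_id: dict[int, TrialCondition] | None = None) -> TrialRecord:
        row = self.trials.iloc[i]
        nt = int(self.traj_len[i])
        ng = int(self.gaze_len[i])
        t = self.traj_t0_s[i] + np.arange(nt) / self.traj_rate_hz
        g = self.gaze_t0_s[i] + np.arange(ng) / self.gaze_rate_hz
        cond = design_by_id[row["condition_id"]] if design_by_id else None
        return TrialRecord(
            participant_id=row["participant_id"],
            condition=cond,
            trajectory=np.column_stack([t, self.traj[i, :nt]]),
            gaze=np.column_stack([g, self.gaze[i, :ng]]),
            go_time_s=float(row["go_time_s"]),
            endpoint=(float(row["endpoint_x_cm"]), float(row["endpoint_y_cm"])),
        )


def _concat_datasets(parts: list[ReachDataset]) -> ReachDataset:
    T = max(p.traj.shape[1] for p in parts)
    G = max(p.gaze.shape[1] for p in parts)

    def pad(a, n):
        if a.shape[1] == n:
            return a
        out = np.full((a.shape[0], n) + a.shape[2:], np.nan)
        out[:, :a.shape[1]] = a
        return out

    return ReachDataset(
        trials=pd.concat([p.trials for p in parts], ignore_index=True),
        traj=np.concatenate([pad(p.traj, T) for p in parts]),
        traj_len=np.concatenate([p.traj_len for p in parts]),
        traj_t0_s=np.concatenate([p.traj_t0_s for p in parts]),
        gaze=np.concatenate([pad(p.gaze, G) for p in parts]),
        gaze_len=np.concatenate([p.gaze_len for p in parts]),
        gaze_t0_s=np.concatenate([p.gaze_t0_s for p in parts]),
        traj_rate_hz=parts[0].traj_rate_hz, gaze_rate_hz=parts[0].gaze_rate_hz,
    )


# ---------------------------------------------------------------------------
# minimum-jerk kinematics

def _minjerk_pos(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile; zero velocity at both ends."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _minjerk_speed(tau: np.ndarray) -> np.ndarray:
    """d/dtau of the profile; peaks at tau = 0.5 with value 30/16 = 1.875."""
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def simulate_trajectory(
    start,
    endpoint,
    duration_s: float,
    rate_hz: float = 250.0,
    noise_cm: float = 0.0,
    lift_cm: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Minimum-jerk point-to-point reach sampled at ``rate_hz``.

    Returns an (n, 4) array of (t_s, x, y, z) samples from t = 0 to
    t = duration_s inclusive, with optional additive Gaussian marker jitter
    and a smooth vertical lift that vanishes at both endpoints. With zero
    noise the final sample lands exactly on ``endpoint``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    start = np.asarray(start, float)
    end = np.asarray(endpoint, float)
    n = int(round(duration_s * rate_hz)) + 1
    t = np.linspace(0.0, duration_s, n)
    tau = t / duration_s
    s = _minjerk_pos(tau)
    pos = start[None, :] + (end - start)[None, :] * s[:, None]
    pos[:, 2] += lift_cm * 16 * tau**2 * (1 - tau)**2
    if noise_cm > 0:
        pos += np.random.default_rng(seed).normal(0.0, noise_cm, pos.shape)
    return np.column_stack([t, pos])


# ---------------------------------------------------------------------------
# reaching cohort generator

def simulate_participant(
    design: list[TrialCondition],
    arrangements: list[SceneArrangement],
    params: GeneratorParams | None = None,
    participant_id: str = "P01",
    seed=0,
) -> ReachDataset:
    """Simulate every scene of the design once for a single participant."""
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    arr_by_id = {a.arrangement_id: a for a in arrangements}
    n = len(design)

    w_cong = rng.normal(params.w_congruent, params.sigma_w)
    w_incong = rng.normal(params.w_incongruent, params.sigma_w)

    target_x = np.empty(n)
    target_y = np.empty(n)
    mere = np.empty(n)
    w_eff = np.empty(n)
    meta = []
    for i, cond in enumerate(design):
        arr = arr_by_id[cond.arrangement_id]
        target_x[i], target_y[i] = arr.target_position
        mere[i] = compute_mere(cond)
        if cond.congruence == "baseline":
            w_eff[i] = 0.0
        else:
            w = w_cong if cond.congruence == "congruent" else w_incong
            if arr.target_cluster == MAN_MADE:
                w += params.cluster_offset
            w_eff[i] = w
        meta.append((cond.condition_id, cond.arrangement_id, arr.target_id,
                     arr.target_cluster, cond.shift_direction, cond.congruence))

    endpoint_x = target_x + w_eff * mere + params.bias_x_cm + rng.normal(0, params.sigma_x_cm, n)
    endpoint_y = target_y + rng.normal(0, params.sigma_y_cm, n)

    duration = np.maximum(rng.normal(params.movement_duration_mean_s,
                                     params.movement_duration_sd_s, n),
                          params.movement_duration_min_s)
    reaction = np.maximum(rng.normal(params.reaction_mean_s, params.reaction_sd_s, n),
                          params.reaction_min_s)

    premature = rng.random(n) < params.rate_premature
    marker_fail = rng.random(n) < params.rate_marker_fail
    gaze_violation = rng.random(n) < params.rate_gaze_violation

    onset = GO_TIME_S + reaction
    onset[premature] = GO_TIME_S - rng.uniform(0.2, 0.5, int(premature.sum()))

    # --- trajectories (vectorised over trials, NaN-padded)
    fs = params.traj_rate_hz
    t0 = np.full(n, GO_TIME_S - PRE_GO_RECORD_S)
    total = (onset - t0) + duration + POST_TOUCH_RECORD_S
    traj_len = np.floor(total * fs).astype(int) + 1
    T = int(traj_len.max())
    tgrid = np.arange(T) / fs  # relative to t0
    tau = (tgrid[None, :] - (onset - t0)[:, None]) / duration[:, None]
    np.clip(tau, 0.0, 1.0, out=tau)
    s = _minjerk_pos(tau)
    sx, sy, sz = START_POSITION_CM
    traj = np.empty((n, T, 3))
    traj[:, :, 0] = sx + (endpoint_x - sx)[:, None] * s
    traj[:, :, 1] = sy + (endpoint_y - sy)[:, None] * s
    traj[:, :, 2] = sz + params.lift_height_cm * 16 * tau**2 * (1 - tau)**2
    if params.marker_jitter_cm > 0:
        traj += rng.normal(0.0, params.marker_jitter_cm, traj.shape)

    # marker dropout: half the affected trials truncate to < 20 samples,
    # the other half dive below the table surface mid-flight
    for i in np.flatnonzero(marker_fail):
        if rng.random() < 0.5:
            traj_len[i] = int(rng.integers(5, 20))
        else:
            k = int(rng.integers(int(0.2 * traj_len[i]), int(0.7 * traj_len[i])))
            traj[i, k:k + 10, 2] = -3.0

    pad = tgrid[None, :] > (traj_len - 1)[:, None] / fs + 1e-12
    traj[pad] = np.nan

    # the recorded endpoint is the final valid trajectory sample
    last = traj_len - 1
    endpoint_x = traj[np.arange(n), last, 0]
    endpoint_y = traj[np.arange(n), last, 1]

    # --- gaze on the table surface during fixation-required phases
    gs = params.gaze_rate_hz
    g_t0 = np.full(n, FIXATION_START_S)
    g_total = onset + duration - g_t0
    gaze_len = np.floor(g_total * gs).astype(int) + 1
    G = int(gaze_len.max())
    gaze = rng.normal(0.0, params.gaze_noise_cm, (n, G, 2))
    for i in np.flatnonzero(gaze_violation):
        axis = int(rng.integers(0, 2))
        amp = rng.uniform(5.0, 8.0) * (1 if rng.random() < 0.5 else -1)
        span = int(rng.integers(24, 61))
        start_idx = int(rng.integers(0, max(1, gaze_len[i] - span)))
        gaze[i, start_idx:start_idx + span, axis] += amp
    ggrid = np.arange(G) / gs
    gpad = ggrid[None, :] > (gaze_len - 1)[:, None] / gs + 1e-12
    gaze[gpad] = np.nan

    trials = pd.DataFrame(meta, columns=["condition_id", "arrangement_id", "target_id",
                                         "target_cluster", "shift_direction", "congruence"])
    trials.insert(0, "participant_id", participant_id)
    trials["mere_cm"] = mere
    trials["target_x_cm"] = target_x
    trials["target_y_cm"] = target_y
    trials["go_time_s"] = GO_TIME_S
    trials["onset_true_s"] = onset
    trials["duration_s"] = duration
    trials["endpoint_x_cm"] = endpoint_x
    trials["endpoint_y_cm"] = endpoint_y
    trials["true_w"] = w_eff
    trials["true_marker_fail"] = marker_fail
    trials["true_premature"] = premature
    trials["true_gaze_violation"] = gaze_violation

    return ReachDataset(trials=trials, traj=traj, traj_len=traj_len, traj_t0_s=t0,
                        gaze=gaze, gaze_len=gaze_len, gaze_t0_s=g_t0,
                        traj_rate_hz=fs, gaze_rate_hz=gs)


def simulate_cohort(
    design: list[TrialCondition],
    arrangements: list[SceneArrangement],
    params: GeneratorParams | None = None,
    n_participants: int = 21,
    seed=0,
) -> ReachDataset:
    """Simulate ``n_participants`` independent participants over the design.

    Each participant receives a child seed spawned from the root
    ``SeedSequence(seed)``, so cohorts are reproducible and participants are
    statistically independent.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    params = params or GeneratorParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(n_participants)
    parts = [
        simulate_participant(design, arrangements, params,
                             participant_id=f"P{i + 1:02d}", seed=seeds[i])
        for i in range(n_participants)
    ]
    return _concat_datasets(parts)


# ---------------------------------------------------------------------------
# multi-arrangement sessions from a latent clustered semantic space

@dataclass(frozen=True)
class LatentSemanticSpace:
    """Ground-truth item coordinates with cluster structure."""

    items: tuple[str, ...]
    coordinates: np.ndarray  # (n_items, dim)
    clusters: tuple[int, ...]

    def distances(self) -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform
        return squareform(pdist(self.coordinates))


def make_semantic_space(
    n_items: int = 49,
    n_clusters: int = 7,
    dim: int = 2,
    cluster_spread: float = 5.0,
    within_scatter: float = 0.8,
    seed=0,
) -> LatentSemanticSpace:
    """Clustered latent space emulating items drawn from semantic categories.

    Cluster centres sit on a circle (first two dimensions) of radius
    ``cluster_spread``; items scatter isotropically around their centre. By
    construction the mean within-cluster distance is below the mean
    between-cluster distance for the default spread/scatter ratio.
    """
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, dim))
    ang = 2 * np.pi * np.arange(n_clusters) / n_clusters
    centers[:, 0] = cluster_spread * np.cos(ang)
    centers[:, 1] = cluster_spread * np.sin(ang)
    assign = np.arange(n_items) % n_clusters
    coords = centers[assign] + rng.normal(0, within_scatter, (n_items, dim))
    items = tuple(f"item{i:02d}" for i in range(n_items))
    return LatentSemanticSpace(items, coords, tuple(int(a) for a in assign))


def simulate_arrangement_session(
    space: LatentSemanticSpace,
    n_trials: int = 24,
    placement_noise: float = 0.5,
    seed=0,
    selector: str = "random",
    subset_size_bounds: tuple[int, int] = (3, 12),
):
    """Simulate one multi-arrangement session.

    Trial 1 contains every item; later trials contain subsets chosen either
    uniformly at random (``selector="random"``) or by the adaptive
    lift-the-weakest heuristic (``selector="lift_weakest"``). Each trial's
    screen positions are a trial-specific random rotation and scaling of the
    latent coordinates (projected to 2D) plus Gaussian placement noise, so
    on-screen distances reflect latent dissimilarities up to a per-trial
    scale factor.
    """
    from .semantic_rsa import ArrangementTrial, estimate_rdm, select_next_subset

    if subset_size_bounds[0] < 3:
        raise ValueError("subsets must contain at least 3 items")
    rng = np.random.default_rng(seed)
    items = list(space.items)
    n_items = len(items)

    def place(subset_idx: np.ndarray) -> ArrangementTrial:
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        scale = rng.uniform(0.5, 2.0)
        xy = space.coordinates[subset_idx][:, :2] @ rot.T * scale
        if placement_noise > 0:
            xy = xy + rng.normal(0, placement_noise, xy.shape)
        return ArrangementTrial(tuple(items[i] for i in subset_idx), xy)

    trials = [place(np.arange(n_items))]
    lo, hi = subset_size_bounds
    for _ in range(1, n_trials):
        if selector == "random":
            size = int(rng.integers(lo, hi + 1))
            subset = rng.choice(n_items, size=size, replace=False)
        elif selector == "lift_weakest":
            rdm = estimate_rdm(trials)
            chosen = select_next_subset(rdm, rdm.evidence, subset_size_bounds,
                                        seed=rng.integers(2**31))
            subset = np.array([items.index(c) for c in chosen])
        else:
            raise ValueError(f"unknown selector {selector!r}")
        trials.append(place(np.asarray(subset)))
    return trials
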