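"""Delimited-text readers and writers for designs, trials and RDMs.

Everything is tab-separated plain text so outputs diff cleanly and can be
inspected with standard tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scene_design import SceneArrangement, TrialCondition, compute_mere
from .semantic_rsa import RDM, ArrangementTrial
from .synthetic_data import ReachDataset


def write_arrangements(arrangements: list[SceneArrangement], path) -> None:
    rows = []
    for a in arrangements:
        for oid, (x, y) in a.positions.items():
            rows.append((a.arrangement_id, oid, a.clusters[oid], x, y,
                         int(oid == a.target_id)))
    pd.DataFrame(rows, columns=["arrangement_id", "object_id", "cluster",
                                "x_cm", "y_cm", "is_target"]).to_csv(
        path, sep="\t", index=False)


def read_arrangements(path, fixation_zone_radius_cm: float = 10.0) -> list[SceneArrangement]:
    table = pd.read_csv(path, sep="\t")
    out = []
    for aid, g in table.groupby("arrangement_id", sort=True):
        target = g.loc[g["is_target"] == 1, "object_id"].iloc[0]
        out.append(SceneArrangement(
            arrangement_id=int(aid), target_id=target,
            positions={r.object_id: (float(r.x_cm), float(r.y_cm)) for r in g.itertuples()},
            clusters={r.object_id: r.cluster for r in g.itertuples()},
            fixation_zone_radius_cm=fixation_zone_radius_cm))
    return out


def write_conditions(conditions: list[TrialCondition], path) -> None:
    rows = []
    for c in conditions:
        ids = list(c.shifted_ids)
        d = [c.displacements_cm.get(i, np.nan) for i in ids]
        rows.append((c.arrangement_id, c.condition_id, c.shift_direction, c.congruence,
                     ";".join(ids), d[0] if d else np.nan, d[1] if len(d) > 1 else np.nan,
                     compute_mere(c)))
    pd.DataFrame(rows, columns=["arrangement_id", "condition_id", "shift_direction",
                                "congruence", "shifted_ids", "displacement_1",
                                "displacement_2", "mere_cm"]).to_csv(
        path, sep="\t", index=False)


def read_conditions(path) -> list[TrialCondition]:
    table = pd.read_csv(path, sep="\t")
    out = []
    for r in table.itertuples():
        ids = tuple(str(r.shifted_ids).split(";")) if isinstance(r.shifted_ids, str) and r.shifted_ids else ()
        disp = {}
        if ids:
            disp = {ids[0]: float(r.displacement_1), ids[1]: float(r.displacement_2)}
        out.append(TrialCondition(int(r.condition_id), int(r.arrangement_id),
                                  r.shift_direction, r.congruence, ids, disp))
    return out


def write_trials(data: ReachDataset, outdir, samples: bool = True) -> None:
    """Write the trials table plus long-format trajectory and gaze samples."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.trials.to_csv(outdir / "trials.tsv", sep="\t", index=False)
    if not samples:
        return
    for name, arr, lens, t0, rate, cols in (
            ("trajectory_samples.tsv", data.traj, data.traj_len, data.traj_t0_s,
             data.traj_rate_hz, ["x_cm", "y_cm", "z_cm"]),
            ("gaze_samples.tsv", data.gaze, data.gaze_len, data.gaze_t0_s,
             data.gaze_rate_hz, ["gx_cm", "gy_cm"])):
        frames = []
        for i in range(data.n_trials):
            m = int(lens[i])
            frame = pd.DataFrame(arr[i, :m], columns=cols)
            frame.insert(0, "t_s", t0[i] + np.arange(m) / rate)
            frame.insert(0, "trial", i)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(outdir / name, sep="\t",
                                                    index=False, float_format="%.5f")


def read_trials(indir) -> ReachDataset:
    indir = Path(indir)
    trials = pd.read_csv(indir / "trials.tsv", sep="\t")
    n = len(trials)

    def load(name, ncol, rate):
        table = pd.read_csv(indir / name, sep="\t")
        groups = [g for _, g in table.groupby("trial", sort=True)]
        lens = np.array([len(g) for g in groups])
        T = int(lens.max())
        arr = np.full((n, T, ncol), np.nan)
        t0 = np.zeros(n)
        for i, g in enumerate(groups):
            arr[i, :len(g)] = g.iloc[:, 2:2 + ncol].to_numpy()
            t0[i] = g["t_s"].iloc[0]
        return arr, lens, t0

    traj, tlen, tt0 = load("trajectory_samples.tsv", 3, 250.0)
    gaze, glen, gt0 = load("gaze_samples.tsv", 2, 120.0)
    return ReachDataset(trials=trials, traj=traj, traj_len=tlen, traj_t0_s=tt0,
                        gaze=gaze, gaze_len=glen, gaze_t0_s=gt0)


def write_session(trials: list[ArrangementTrial], path, session_id: str = "S01") -> None:
    rows = []
    for tid, trial in enumerate(trials):
        for item, (x, y) in zip(trial.items, np.asarray(trial.positions)):
            rows.append((session_id, tid, item, x, y))
    pd.DataFrame(rows, columns=["session_id", "trial_id", "item",
                                "screen_x", "screen_y"]).to_csv(
        path, sep="\t", index=False, float_format="%.5f")


def read_session(path) -> list[ArrangementTrial]:
    table = pd.read_csv(path, sep="\t")
    out = []
    for _, g in table.groupby("trial_id", sort=True):
        out.append(ArrangementTrial(tuple(g["item"]),
                                    g[["screen_x", "screen_y"]].to_numpy(float)))
    return out


def write_rdm(rdm: RDM, path) -> None:
    pd.DataFrame(rdm.matrix, index=rdm.items, columns=rdm.items).to_csv(path, sep="\t")


def read_rdm(path, normalization: str = "unit-max") -> RDM:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return RDM(tuple(table.columns), table.to_numpy(float), normalization=normalization)
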