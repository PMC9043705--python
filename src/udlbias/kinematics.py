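"""Reduce raw 200 Hz trajectories to validated heading observations.

Per trial the reduction is:

1. movement onset = first sample at which tangential speed (central
   differences on the 200 Hz grid, no smoothing) exceeds 3 cm/s; this
   time is the trial's reaction time,
2. heading = direction of the displacement from onset to 40 ms after
   onset (~2.4 cm of travel, before online corrections could act),
3. validity flags: reaction time under 70 ms is ``too_fast``
   (anticipation), movement time over 400 ms is ``too_slow``,
4. angular deviation from the presented target, corrected by the
   participant's idiosyncratic per-target baseline (mean deviation in
   the no-feedback baseline block), and
5. recoding into bias coordinates: the frequent target is reset to 0,
   probe distances collapse to {0, 30, 60, 90} degrees, and the sign is
   flipped so positive biases point toward the frequent target.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ._angles import ang_diff
from .generate import DT, TARGET_AMPLITUDE_CM, SimulatedDataset, Trajectory

V_THRESH_CM_S = 3.0
HEADING_DT_S = 0.040
RT_FLOOR_S = 0.070
MT_CAP_S = 0.400

REASON_OK = "ok"
REASON_TOO_FAST = "too_fast"
REASON_TOO_SLOW = "too_slow"
REASON_NO_ONSET = "no_onset"

OBSERVATION_COLUMNS = ["participant", "block", "trial", "phase", "target_deg",
                       "is_probe", "feedback", "group", "probe_distance",
                       "bias_deg", "rt_s", "mt_s", "valid", "reason"]


class NoOnsetError(ValueError):
    """Raised when the speed threshold is never crossed."""


def _speed(x: np.ndarray, y: np.ndarray, dt: float) -> np.ndarray:
    """Tangential speed by central differences (one-sided at the ends)."""
    vx = np.gradient(x, dt, axis=-1)
    vy = np.gradient(y, dt, axis=-1)
    return np.hypot(vx, vy)


def detect_onset(traj: Trajectory, v_thresh: float = V_THRESH_CM_S) -> float:
    """Movement-onset time: first sample with speed above ``v_thresh``.

    Raises
    ------
    NoOnsetError
        If the threshold is never crossed.
    """
    if traj.t.size < 2:
        raise ValueError("need at least 2 samples")
    sp = _speed(traj.x, traj.y, float(traj.t[1] - traj.t[0]))
    above = np.flatnonzero(sp > v_thresh)
    if above.size == 0:
        raise NoOnsetError("speed never exceeds threshold")
    return float(traj.t[above[0]])


def heading_at(traj: Trajectory, onset: float,
               dt: float = HEADING_DT_S) -> float:
    """Screen-frame heading (deg, in (-180, 180]) of the displacement
    from ``onset`` to ``onset + dt``; positions are linearly
    interpolated between samples."""
    t_end = onset + dt
    if t_end > traj.t[-1] + 1e-12:
        raise ValueError("trajectory too short for the heading window")
    x0 = np.interp(onset, traj.t, traj.x)
    y0 = np.interp(onset, traj.t, traj.y)
    x1 = np.interp(t_end, traj.t, traj.x)
    y1 = np.interp(t_end, traj.t, traj.y)
    return float(np.degrees(np.arctan2(y1 - y0, x1 - x0)))


def flag_validity(rt: float, movement_time: float) -> str:
    """Reason code for a trial's timing: anticipatory reactions
    (rt < 70 ms) and capped movements (mt > 400 ms) are invalid."""
    if rt < 0 or movement_time < 0:
        raise ValueError("times must be nonnegative")
    if rt < RT_FLOOR_S:
        return REASON_TOO_FAST
    if movement_time > MT_CAP_S:
        return REASON_TOO_SLOW
    return REASON_OK


def recode_bias(heading: float, target: float, frequent_loc: float,
                baseline: float = 0.0):
    """Recode one heading into (probe_distance, bias).

    ``baseline`` is the participant's mean angular deviation at this
    target in the no-feedback baseline block and is subtracted from the
    raw deviation before the sign flip. Positive bias points toward the
    frequent target; probe distance is the absolute angular separation,
    one of {0, 30, 60, 90} degrees.
    """
    rel = ang_diff(frequent_loc, target)
    d = float(np.round(np.abs(rel)))
    if d not in (0.0, 30.0, 60.0, 90.0):
        raise ValueError(f"target {target} is not in the session set for "
                         f"frequent location {frequent_loc}")
    dev = ang_diff(heading, target) - baseline
    sign = 1.0 if rel >= 0 else -1.0
    return d, float(sign * dev)


def build_baseline(baseline_obs: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-target mean angular deviation in the
    no-feedback baseline block.

    ``baseline_obs`` needs columns ``participant, target_deg,
    deviation_deg`` (valid trials only). Every participant must have at
    least one trial at each of their session's seven targets.
    """
    tbl = (baseline_obs.groupby(["participant", "target_deg"])["deviation_deg"]
           .mean().rename("baseline_deg").reset_index())
    counts = tbl.groupby("participant").size()
    short = counts[counts < 7]
    if len(short):
        raise ValueError(
            "missing baseline cells for participants "
            f"{short.index.tolist()} (need 7 target locations each)")
    return tbl


def reduce_dataset(ds: SimulatedDataset,
                   v_thresh: float = V_THRESH_CM_S,
                   heading_dt: float = HEADING_DT_S,
                   chunk: int = 4000) -> pd.DataFrame:
    """Run the full kinematic reduction on a rendered dataset.

    Returns the observations table (one row per trial) with recoded,
    baseline-corrected biases. Trials whose onset cannot be determined
    or whose timing violates the validity rules are flagged and carry
    NaN bias where undefined; downstream analyses use ``valid`` rows.
    """
    if not ds.has_trajectories:
        raise ValueError("dataset has no trajectories; use "
                         "generate_observations for the headings-only path")
    trials = ds.trials
    n = len(trials)
    onset = np.full(n, np.nan)
    heading = np.full(n, np.nan)
    mt = np.full(n, np.nan)

    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        x = ds.traj_x[lo:hi]
        y = ds.traj_y[lo:hi]
        lengths = ds.traj_len[lo:hi]
        sp = _speed(np.nan_to_num(x), np.nan_to_num(y), DT)
        cols = np.arange(x.shape[1])[None, :]
        in_range = cols < (lengths[:, None] - 1)
        above = (sp > v_thresh) & in_range
        has = above.any(axis=1)
        idx = np.argmax(above, axis=1)

        t_on = idx * DT
        t_end = t_on + heading_dt
        # heading window: linear interpolation on the uniform grid
        f_end = t_end / DT
        i2 = np.floor(f_end).astype(int)
        frac = f_end - i2
        ok = has & (i2 + 1 < lengths)
        rows = np.arange(hi - lo)
        i2c = np.clip(i2, 0, x.shape[1] - 2)
        x0 = x[rows, idx]
        y0 = y[rows, idx]
        x1 = x[rows, i2c] * (1 - frac) + x[rows, i2c + 1] * frac
        y1 = y[rows, i2c] * (1 - frac) + y[rows, i2c + 1] * frac
        hd = np.degrees(np.arctan2(y1 - y0, x1 - x0))

        r = np.hypot(np.nan_to_num(x), np.nan_to_num(y))
        reached = (r >= TARGET_AMPLITUDE_CM - 1e-3) & (cols < lengths[:, None])
        t_reach = np.where(reached.any(axis=1), np.argmax(reached, axis=1) * DT,
                           (lengths - 1) * DT)

        onset[lo:hi] = np.where(has, t_on, np.nan)
        heading[lo:hi] = np.where(ok, hd, np.nan)
        mt[lo:hi] = np.where(has, t_reach - t_on, np.nan)

    reason = np.where(np.isnan(onset) | np.isnan(heading), REASON_NO_ONSET,
                      np.where(onset < RT_FLOOR_S, REASON_TOO_FAST,
                               np.where(mt > MT_CAP_S, REASON_TOO_SLOW,
                                        REASON_OK)))
    valid = reason == REASON_OK

    target = trials["target_deg"].to_numpy(float)
    frequent = trials["frequent_deg"].to_numpy(float)
    deviation = ang_diff(heading, target)

    base_mask = (trials["phase"].to_numpy() == "baseline_nofeedback") & valid
    base_obs = pd.DataFrame({
        "participant": trials["participant"].to_numpy()[base_mask],
        "target_deg": target[base_mask],
        "deviation_deg": deviation[base_mask],
    })
    base_tbl = build_baseline(base_obs)
    lookup = base_tbl.set_index(["participant", "target_deg"])["baseline_deg"]
    key = pd.MultiIndex.from_arrays([trials["participant"], trials["target_deg"]])
    baseline = lookup.reindex(key).to_numpy()
    baseline = np.where(np.isnan(baseline), 0.0, baseline)

    rel = ang_diff(frequent, target)
    sign = np.where(rel >= 0, 1.0, -1.0)
    d = np.round(np.abs(rel)).astype(int)
    bad = ~np.isin(d, (0, 30, 60, 90))
    if bad.any():
        raise ValueError(f"targets outside the session set: "
                         f"{sorted(set(target[bad]))[:5]}")
    bias = sign * (deviation - baseline)

    return pd.DataFrame({
        "participant": trials["participant"],
        "block": trials["block"],
        "trial": trials["trial"],
        "phase": trials["phase"],
        "target_deg": target,
        "is_probe": trials["is_probe"],
        "feedback": trials["feedback"],
        "group": trials["group"],
        "probe_distance": d,
        "bias_deg": bias,
        "rt_s": onset,
        "mt_s": mt,
        "valid": valid,
        "reason": reason,
    })[OBSERVATION_COLUMNS]
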