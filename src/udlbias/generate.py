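"""Two-process synthetic reach generator.

Latent model
------------
Every test-phase reach to a target ``d`` degrees from the frequent
location is planned in *bias coordinates* (probe target at 0, positive
toward the frequent target). With preparation time ``P`` (reaction time
plus any imperative delay) the planned bias is

    b(P) = max(d - omega * max(0, P - t0), eps_exec) + N(0, sigma_motor)

for ``d > 0`` and pure motor noise for ``d = 0``. Reaches therefore fall
into three regimes: *default* (P <= t0; the frequent-target plan is
executed unchanged, b ~ d), *intermediate* (the plan is partway through
re-aiming), and *re_aimed* (planning finished; only the execution shift
``eps_exec`` remains). With a small probability ``p_lapse`` a reach is a
lapse, drawn Uniform(-d-30, d+30). Baseline-phase reaches precede any
use-dependent learning and carry motor noise only.

Rendering
---------
Trajectories are sampled at 200 Hz in a frame with the start circle at
the origin. The hand holds the start position (plus digitizer jitter)
until the latent reaction time, then travels along a straight ray at the
planned heading with a minimum-jerk radial speed profile that reaches
the 10 cm target ring at ``rt + move_time``.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._angles import ang_diff
from .params import GenerativeParams
from .schedule import PHASE_TEST, make_schedule

HZ = 200.0
DT = 1.0 / HZ
TARGET_AMPLITUDE_CM = 10.0

REGIME_DEFAULT = "default"
REGIME_INTERMEDIATE = "intermediate"
REGIME_REAIMED = "re_aimed"
REGIME_BASELINE = "baseline"

ALLOWED_DISTANCES = (0.0, 30.0, 60.0, 90.0)

TRIALS_COLUMNS = ["participant", "block", "trial", "phase", "target_deg",
                  "is_probe", "feedback", "group", "frequent_deg",
                  "rt_latent_s", "regime"]


@dataclass
class Trajectory:
    """A single 200 Hz stylus trajectory (times in s, positions in cm)."""
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray


def _planned_bias(d, prep, params: GenerativeParams, rng) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized latent bias draw; returns (bias, regime, lapse)."""
    d = np.asarray(d, dtype=float)
    prep = np.asarray(prep, dtype=float)
    progress = params.omega * np.maximum(0.0, prep - params.t0)
    core = np.where(d > 0,
                    np.maximum(d - progress, params.eps_exec),
                    0.0)
    bias = core + rng.normal(0.0, params.sigma_motor, size=core.shape)

    regime = np.where(prep <= params.t0, REGIME_DEFAULT, REGIME_INTERMEDIATE)
    done_at = np.maximum(d - params.eps_exec, 0.0) / params.omega
    regime = np.where(prep >= params.t0 + done_at, REGIME_REAIMED, regime)
    regime = np.where(d > 0, regime, REGIME_REAIMED)

    lapse = rng.random(size=core.shape) < params.p_lapse
    if lapse.any():
        lo, hi = -d - 30.0, d + 30.0
        bias = np.where(lapse, rng.uniform(0, 1, size=core.shape) * (hi - lo) + lo, bias)
    return bias, regime, lapse


def sample_heading(probe_distance: float, rt: float,
                   params: GenerativeParams, rng) -> float:
    """Draw one planned heading in bias coordinates.

    Parameters
    ----------
    probe_distance : float
        Absolute recoded distance from the frequent target; one of
        {0, 30, 60, 90} degrees.
    rt : float
        Reaction time in seconds (>= 0). Preparation time is
        ``rt + params.delay``.
    params : GenerativeParams
    rng : numpy.random.Generator

    Returns
    -------
    float
        Planned bias in degrees, positive toward the frequent target.
    """
    if rt < 0:
        raise ValueError("rt must be >= 0")
    if float(probe_distance) not in ALLOWED_DISTANCES:
        raise ValueError(f"probe_distance must be one of {ALLOWED_DISTANCES}")
    bias, _, _ = _planned_bias(np.array([probe_distance]),
                               np.array([rt + params.delay]), params, rng)
    return float(bias[0])


def _min_jerk_radius(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return TARGET_AMPLITUDE_CM * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)


def min_jerk_speed(t, rt: float, move_time: float) -> np.ndarray:
    """Analytic radial speed (cm/s) of the rendered profile; 0 outside
    the movement window. Exposed for use as an independent oracle."""
    tau = (np.asarray(t, dtype=float) - rt) / move_time
    v = TARGET_AMPLITUDE_CM / move_time * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return np.where((tau >= 0) & (tau <= 1), v, 0.0)


def _render_batch(headings, rts, move_times, params: GenerativeParams, rng):
    """Render many trials at once into NaN-padded (n, N) position arrays."""
    headings = np.asarray(headings, float)
    rts = np.asarray(rts, float)
    move_times = np.asarray(move_times, float)
    if np.any(move_times <= 0):
        raise ValueError("move_time must be > 0")
    if np.any(rts < 0):
        raise ValueError("rt must be >= 0")

    lengths = np.floor((rts + move_times) / DT).astype(int) + 2
    n, N = len(headings), int(lengths.max())
    tgrid = np.arange(N) * DT

    tau = (tgrid[None, :] - rts[:, None]) / move_times[:, None]
    r = _min_jerk_radius(tau)
    theta = np.deg2rad(headings)[:, None]
    x = r * np.cos(theta)
    y = r * np.sin(theta)

    pre = tgrid[None, :] < rts[:, None]
    if params.start_jitter_sd > 0:
        x += np.where(pre, rng.normal(0, params.start_jitter_sd, (n, N)), 0.0)
        y += np.where(pre, rng.normal(0, params.start_jitter_sd, (n, N)), 0.0)

    pad = tgrid[None, :] >= lengths[:, None] * DT
    x[pad] = np.nan
    y[pad] = np.nan
    return x, y, lengths


def render_trajectory(planned_heading: float, rt: float, move_time: float,
                      params: GenerativeParams, rng) -> Trajectory:
    """Render one trial's 200 Hz trajectory.

    The hand holds the start position (digitizer jitter only) for
    ``rt`` seconds, then moves along a straight ray at
    ``planned_heading`` (screen frame, degrees) with a minimum-jerk
    radial profile reaching 10 cm at ``rt + move_time``.
    """
    x, y, lengths = _render_batch([planned_heading], [rt], [move_time], params, rng)
    m = lengths[0]
    t = np.arange(m) * DT
    return Trajectory(t=t, x=x[0, :m].copy(), y=y[0, :m].copy())


@dataclass
class SimulatedDataset:
    """A simulated cohort: trial table, padded trajectories, latent truth.

    ``traj_x``/``traj_y`` are (n_trials, N) arrays padded with NaN; row
    order matches ``trials``. ``latent`` records, per trial, the
    realized planned bias (bias coordinates), the screen-frame heading,
    the latent RT/preparation time, the movement time and the regime —
    the ground truth against which recovery is tested.
    """
    trials: pd.DataFrame
    traj_x: Optional[np.ndarray]
    traj_y: Optional[np.ndarray]
    traj_len: Optional[np.ndarray]
    latent: pd.DataFrame

    @property
    def has_trajectories(self) -> bool:
        return self.traj_x is not None

    def trajectory(self, i: int) -> Trajectory:
        m = int(self.traj_len[i])
        return Trajectory(t=np.arange(m) * DT,
                          x=self.traj_x[i, :m].copy(),
                          y=self.traj_y[i, :m].copy())

    def trajectories_frame(self) -> pd.DataFrame:
        """Long-format trajectory table (one row per 5 ms sample)."""
        idx = np.repeat(np.arange(len(self.trials)), self.traj_len)
        within = np.concatenate([np.arange(m) for m in self.traj_len])
        meta = self.trials.iloc[idx]
        return pd.DataFrame({
            "participant": meta["participant"].to_numpy(),
            "block": meta["block"].to_numpy(),
            "trial": meta["trial"].to_numpy(),
            "t_s": within * DT,
            "x_cm": self.traj_x[idx, within],
            "y_cm": self.traj_y[idx, within],
        })

    def to_dir(self, path: str) -> None:
        """Write the canonical CSV triple (trials/trajectories/latent)."""
        os.makedirs(path, exist_ok=True)
        self.trials.to_csv(os.path.join(path, "trials.csv"), index=False)
        self.latent.to_csv(os.path.join(path, "latent.csv"), index=False)
        if self.has_trajectories:
            self.trajectories_frame().to_csv(
                os.path.join(path, "trajectories.csv"), index=False,
                float_format="%.6g")

    @classmethod
    def from_dir(cls, path: str) -> "SimulatedDataset":
        trials = pd.read_csv(os.path.join(path, "trials.csv"))
        latent_path = os.path.join(path, "latent.csv")
        latent = pd.read_csv(latent_path) if os.path.exists(latent_path) else pd.DataFrame()
        traj_path = os.path.join(path, "trajectories.csv")
        traj_x = traj_y = traj_len = None
        if os.path.exists(traj_path):
            long = pd.read_csv(traj_path)
            key = ["participant", "block", "trial"]
            sizes = long.groupby(key, sort=False).size()
            order = trials.set_index(key).index
            traj_len = sizes.reindex(order).to_numpy()
            if np.any(pd.isna(traj_len)):
                missing = order[pd.isna(traj_len)][:3].tolist()
                raise ValueError(f"trials without trajectories, e.g. {missing}")
            traj_len = traj_len.astype(int)
            N = int(traj_len.max())
            n = len(trials)
            traj_x = np.full((n, N), np.nan)
            traj_y = np.full((n, N), np.nan)
            row = np.repeat(np.arange(n), traj_len)
            col = np.concatenate([np.arange(m) for m in traj_len])
            # trajectories.csv rows are grouped by trial in trial order
            long = long.set_index(key).loc[order].reset_index()
            traj_x[row, col] = long["x_cm"].to_numpy()
            traj_y[row, col] = long["y_cm"].to_numpy()
        return cls(trials=trials, traj_x=traj_x, traj_y=traj_y,
                   traj_len=traj_len, latent=latent)


def _latent_draws(schedule: pd.DataFrame, params: GenerativeParams, rng):
    n = len(schedule)
    rt = np.minimum(params.rt_shift + rng.lognormal(params.rt_mu, params.rt_sigma, n),
                    params.rt_cap)
    move_time = rng.uniform(*params.move_time_range, n)

    target = schedule["target_deg"].to_numpy(float)
    frequent = schedule["frequent_deg"].to_numpy(float)
    if params.freq_loc_sd > 0:
        freq_trial = (schedule["phase"].to_numpy() == PHASE_TEST) & \
                     (~schedule["is_probe"].to_numpy()) & \
                     (np.abs(ang_diff(target, frequent)) < 1e-9)
        target = target + np.where(freq_trial,
                                   rng.normal(0, params.freq_loc_sd, n), 0.0)

    rel = ang_diff(frequent, target)
    sign = np.where(rel >= 0, 1.0, -1.0)
    d = np.abs(rel)
    is_test = schedule["phase"].to_numpy() == PHASE_TEST
    d_eff = np.where(is_test, d, 0.0)  # baseline reaches precede learning

    prep = rt + params.delay
    bias, regime, lapse = _planned_bias(d_eff, prep, params, rng)
    regime = np.where(is_test, regime, REGIME_BASELINE)
    heading = target + sign * bias

    latent = pd.DataFrame({
        "participant": schedule["participant"].to_numpy(),
        "block": schedule["block"].to_numpy(),
        "trial": schedule["trial"].to_numpy(),
        "target_deg": target,
        "probe_distance": d_eff,
        "toward_sign": sign,
        "rt_latent_s": rt,
        "prep_s": prep,
        "move_time_s": move_time,
        "bias_planned_deg": bias,
        "heading_deg": heading,
        "regime": regime,
        "lapse": lapse,
    })
    return latent


def generate_dataset(design: str, params: GenerativeParams,
                     n_participants: int, seed: int,
                     frequent_loc: Optional[float] = None,
                     groups: Optional[Sequence[str]] = None,
                     render: bool = True,
                     chunk: int = 4000) -> SimulatedDataset:
    """Simulate a full cohort: schedule, latent headings, trajectories.

    Deterministic given ``seed``. With ``render=False`` only the trial
    table and latent truth table are produced (no trajectories), which
    is sufficient for analyses that start from heading observations.
    """
    schedule = make_schedule(design, n_participants, frequent_loc=frequent_loc,
                             seed=seed, groups=groups)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    latent = _latent_draws(schedule, params, rng)

    trials = schedule.copy()
    trials["rt_latent_s"] = latent["rt_latent_s"].to_numpy()
    trials["regime"] = latent["regime"].to_numpy()
    trials = trials[TRIALS_COLUMNS]

    traj_x = traj_y = traj_len = None
    if render:
        n = len(trials)
        rts = latent["rt_latent_s"].to_numpy()
        mts = latent["move_time_s"].to_numpy()
        lengths = np.floor((rts + mts) / DT).astype(int) + 2
        N = int(lengths.max())
        traj_x = np.full((n, N), np.nan)
        traj_y = np.full((n, N), np.nan)
        heads = latent["heading_deg"].to_numpy()
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            x, y, ln = _render_batch(heads[lo:hi], rts[lo:hi], mts[lo:hi],
                                     params, rng)
            traj_x[lo:hi, :x.shape[1]] = x
            traj_y[lo:hi, :y.shape[1]] = y
        traj_len = lengths

    return SimulatedDataset(trials=trials, traj_x=traj_x, traj_y=traj_y,
                            traj_len=traj_len, latent=latent)


def generate_observations(design: str, params: GenerativeParams,
                          n_participants: int, seed: int,
                          frequent_loc: Optional[float] = None,
                          groups: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Fast path: heading observations without trajectory rendering.

    Produces the same table as running the kinematics reduction on a
    rendered dataset, except that RT is the latent movement-start time
    (the rendered pipeline's 3 cm/s threshold crossing sits a constant
    ~15-25 ms later) and bias is the realized planned bias corrected by
    the baseline estimated from the simulated no-feedback baseline
    block, exactly as the reduction would do.
    """
    ds = generate_dataset(design, params, n_participants, seed,
                          frequent_loc=frequent_loc, groups=groups,
                          render=False)
    trials, latent = ds.trials, ds.latent

    base = trials["phase"] == "baseline_nofeedback"
    base_tbl = (latent[base.to_numpy()]
                .groupby(["participant", "target_deg"])["bias_planned_deg"]
                .mean())
    key = pd.MultiIndex.from_arrays(
        [latent["participant"], latent["target_deg"]])
    correction = base_tbl.reindex(key).to_numpy()
    correction = np.where(np.isnan(correction), 0.0, correction)

    rt = latent["rt_latent_s"].to_numpy()
    mt = latent["move_time_s"].to_numpy()
    reason = np.where(rt < 0.070, "too_fast",
                      np.where(mt > 0.400, "too_slow", "ok"))

    rel = ang_diff(trials["frequent_deg"].to_numpy(float),
                   trials["target_deg"].to_numpy(float))
    obs = pd.DataFrame({
        "participant": trials["participant"],
        "block": trials["block"],
        "trial": trials["trial"],
        "phase": trials["phase"],
        "target_deg": trials["target_deg"],
        "is_probe": trials["is_probe"],
        "feedback": trials["feedback"],
        "group": trials["group"],
        "probe_distance": np.abs(rel).round().astype(int),
        "bias_deg": latent["bias_planned_deg"].to_numpy() - correction,
        "rt_s": rt,
        "mt_s": mt,
        "reason": reason,
    })
    obs["valid"] = obs["reason"] == "ok"
    return obs
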