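"""End-to-end orchestration: simulate -> reduce -> distributions -> stats.

A single ``RunConfig`` drives both simulation and analysis so a whole
run is reproducible from one file. Every run writes its tables, a
``summary.json`` with the headline numbers, and a ``manifest.json``
recording the config hash, seed and library versions.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .generate import SimulatedDataset, generate_dataset, generate_observations
from .kinematics import reduce_dataset
from .mixtures import modality_test, peak_ci
from .params import GenerativeParams
from .stats import (distance_contrasts, quintile_summary, reward_compare,
                    select_probes, slope_table)

log = logging.getLogger("udlbias")

DISTANCES = (0, 30, 60, 90)


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulate+analyze run."""
    design: str = "exp1"
    n_participants: int = 10
    seed: int = 1
    #: generator parameters; None resolves to the design's defaults
    #: (in particular the 500 ms imperative delay for "exp2")
    params: Optional[GenerativeParams] = None
    frequent_loc: Optional[float] = None
    groups: Optional[Sequence[str]] = None
    render: bool = True
    input_dir: Optional[str] = None      # analyze existing data instead of simulating
    n_boot_modality: int = 999
    n_boot_peak: int = 10000
    k_mode: str = "auto"                 # "auto" | "1" | "2"
    slope_method: str = "two_stage"
    n_quintiles: int = 5
    make_figures: bool = False

    @property
    def resolved_params(self) -> GenerativeParams:
        if self.params is not None:
            return self.params
        return GenerativeParams(delay=0.5 if self.design == "exp2" else 0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = None if self.params is None else self.params.to_dict()
        if d["groups"] is not None:
            d["groups"] = list(d["groups"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("params"), dict):
            d["params"] = GenerativeParams.from_dict(d["params"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config: RunConfig
    observations: pd.DataFrame
    mixtures: pd.DataFrame
    slopes: pd.DataFrame
    quintiles: "pd.DataFrame"
    contrasts: pd.DataFrame
    reward: Optional[dict]
    summary: dict


def _stage(name):
    log.info("stage: %s", name)


def _analyze_distances(probes: pd.DataFrame, cfg: RunConfig):
    rows = []
    for d in DISTANCES:
        x = probes.loc[probes["probe_distance"] == d, "bias_deg"].to_numpy()
        if x.size < 10:
            log.warning("distance %d: only %d probe trials, skipped", d, x.size)
            continue
        mt = modality_test(x, n_boot=cfg.n_boot_modality, seed=cfg.seed + d)
        k = mt.k_selected if cfg.k_mode == "auto" else int(cfg.k_mode)
        pk = peak_ci(x, n_boot=cfg.n_boot_peak, seed=cfg.seed + d, k=k)
        fit = mt.fit2 if k == 2 else mt.fit1
        rows.append({
            "probe_distance": d,
            "n": int(x.size),
            "k_selected": k,
            "means": ";".join(f"{m:.3f}" for m in fit.means),
            "sds": ";".join(f"{s:.3f}" for s in fit.sds),
            "weights": ";".join(f"{w:.3f}" for w in fit.weights),
            "lrt": mt.lrt_stat,
            "p_bimodal": mt.p_value,
            "peak": pk.peak,
            "ci_low": pk.ci_low,
            "ci_high": pk.ci_high,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> RunReport:
    """Execute the full pipeline and (optionally) write all artifacts.

    Deterministic given an identical config: the same ``summary.json``
    is produced byte-for-byte on every run.
    """
    cfg = config
    try:
        if cfg.input_dir is not None:
            _stage("load")
            ds = SimulatedDataset.from_dir(cfg.input_dir)
            _stage("kinematics")
            obs = reduce_dataset(ds)
        elif cfg.render:
            _stage("simulate")
            ds = generate_dataset(cfg.design, cfg.resolved_params,
                                  cfg.n_participants, cfg.seed,
                                  frequent_loc=cfg.frequent_loc,
                                  groups=cfg.groups)
            _stage("kinematics")
            obs = reduce_dataset(ds)
        else:
            _stage("simulate (headings only)")
            obs = generate_observations(cfg.design, cfg.resolved_params,
                                        cfg.n_participants, cfg.seed,
                                        frequent_loc=cfg.frequent_loc,
                                        groups=cfg.groups)
    except Exception as e:
        raise RuntimeError(f"stage 'data' failed: {e}") from e

    n_invalid = int((~obs["valid"]).sum())
    log.info("%d trials reduced, %d invalid (%s)", len(obs), n_invalid,
             obs.loc[~obs["valid"], "reason"].value_counts().to_dict())
    probes = select_probes(obs)

    _stage("distribution")
    mixtures = _analyze_distances(probes, cfg)

    _stage("bias-rt statistics")
    slopes = slope_table(obs, method=cfg.slope_method)
    quint = quintile_summary(obs, n_bins=cfg.n_quintiles)
    contr = distance_contrasts(obs)

    reward = None
    if {"reward", "no_reward"} <= set(obs["group"].unique()):
        rc = reward_compare(obs)
        reward = {
            "accuracy_t": rc.accuracy_t, "accuracy_p": rc.accuracy_p,
            "accuracy_d": rc.accuracy_d,
            "reward_main_p": rc.reward_main_p,
            "interaction_p": rc.interaction_p,
            "interaction_F": rc.interaction_F,
        }

    summary = {
        "config_hash": cfg.config_hash,
        "design": cfg.design,
        "n_participants": cfg.n_participants,
        "n_trials": int(len(obs)),
        "n_invalid": n_invalid,
        "mixtures": mixtures.round(6).to_dict(orient="records"),
        "slopes": slopes.round(6).to_dict(orient="records"),
        "per_distance_bias": contr.per_distance.round(6).to_dict(orient="records"),
        "contrasts": contr.contrasts.round(6).to_dict(orient="records"),
        "reward": {k: round(v, 6) for k, v in reward.items()} if reward else None,
    }

    report = RunReport(cfg, obs, mixtures, slopes, quint, contr.contrasts,
                       reward, summary)
    if out_dir is not None:
        _write_outputs(report, out_dir)
    return report


def _write_outputs(rep: RunReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    rep.observations.to_csv(os.path.join(out_dir, "observations.csv"), index=False)
    rep.mixtures.to_csv(os.path.join(out_dir, "mixture_results.csv"), index=False)
    rep.slopes.to_csv(os.path.join(out_dir, "slopes.csv"), index=False)
    rep.quintiles.group.to_csv(os.path.join(out_dir, "quintiles.csv"), index=False)
    rep.contrasts.to_csv(os.path.join(out_dir, "contrasts.csv"), index=False)
    if rep.reward is not None:
        pd.DataFrame([rep.reward]).to_csv(os.path.join(out_dir, "reward.csv"),
                                          index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(rep.summary, fh, indent=2, sort_keys=True)
    import udlbias
    manifest = {
        "config": rep.config.to_dict(),
        "config_hash": rep.config.config_hash,
        "seed": rep.config.seed,
        "versions": {
            "udlbias": udlbias.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if rep.config.make_figures:
        _write_figures(rep, out_dir)


def _write_figures(rep: RunReport, out_dir: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    probes = select_probes(rep.observations)
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    for ax, d in zip(axes, (30, 60, 90)):
        x = probes.loc[probes["probe_distance"] == d, "bias_deg"]
        ax.hist(x, bins=40, density=True, color="steelblue", alpha=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.axvline(d, color="crimson", ls="--", lw=0.8)
        ax.set_title(f"probe distance {d}\N{DEGREE SIGN}")
        ax.set_xlabel("bias toward frequent target (deg)")
    axes[0].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "heading_distributions.png"), dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for d, sub in rep.quintiles.group.groupby("probe_distance"):
        if d == 0:
            continue
        ax.errorbar(sub["mean_rt_s"], sub["mean_bias_deg"],
                    yerr=sub["sem_bias_deg"], marker="o", label=f"{d}\N{DEGREE SIGN}")
    ax.set_xlabel("reaction time (s)")
    ax.set_ylabel("bias (deg)")
    ax.legend(title="probe distance")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "bias_vs_rt_quintiles.png"), dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# dataset validation

@dataclass
class ValidationReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(path: str) -> ValidationReport:
    """Schema, unit, sampling-rate and referential-integrity checks on a
    canonical dataset directory (trials.csv + trajectories.csv)."""
    v = []
    tpath = os.path.join(path, "trials.csv")
    if not os.path.exists(tpath):
        return ValidationReport([f"missing file: {tpath}"])
    trials = pd.read_csv(tpath)
    required = {"participant", "block", "trial", "phase", "target_deg",
                "is_probe", "feedback", "group"}
    missing = required - set(trials.columns)
    if missing:
        v.append(f"trials.csv missing columns: {sorted(missing)}")
        return ValidationReport(v)

    phases = {"baseline_feedback", "baseline_nofeedback", "test"}
    bad = set(trials["phase"].unique()) - phases
    if bad:
        v.append(f"unknown phase labels: {sorted(bad)}")
    if trials.duplicated(["participant", "block", "trial"]).any():
        v.append("duplicate (participant, block, trial) keys in trials.csv")

    jpath = os.path.join(path, "trajectories.csv")
    if os.path.exists(jpath):
        traj = pd.read_csv(jpath)
        need = {"participant", "block", "trial", "t_s", "x_cm", "y_cm"}
        missing = need - set(traj.columns)
        if missing:
            v.append(f"trajectories.csv missing columns: {sorted(missing)}")
        else:
            key = ["participant", "block", "trial"]
            dt = traj.groupby(key)["t_s"].diff().dropna()
            off = np.abs(dt - 0.005) > 1e-6
            if off.any():
                v.append(f"{int(off.sum())} samples deviate from 200 Hz spacing")
            tk = set(map(tuple, trials[key].itertuples(index=False)))
            jk = set(map(tuple, traj[key].drop_duplicates().itertuples(index=False)))
            if jk - tk:
                v.append(f"{len(jk - tk)} trajectories reference unknown trials")
            if tk - jk:
                v.append(f"{len(tk - jk)} trials lack a trajectory")
            r = np.hypot(traj["x_cm"], traj["y_cm"])
            rmax = pd.Series(r.to_numpy()).groupby(
                traj[key].apply(tuple, axis=1).to_numpy()).max()
            short = (rmax < 10.0 - 1e-3).sum()  # 1 mm slack for CSV precision
            if short:
                v.append(f"{int(short)} trajectories never reach the 10 cm ring")
    return ValidationReport(v)
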