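"""Bias-versus-RT statistics and group comparisons.

Covers the RT-conditioned side of the analysis: per-participant RT
quintile curves, bias-on-RT slopes (two-stage summary statistics by
default, a random-intercept mixed model as the pooled alternative),
per-distance contrasts with Bonferroni correction, and the reward-group
comparison of the delayed-response design.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

PROBE_DISTANCES = (30, 60, 90)


def select_probes(obs: pd.DataFrame, distances: Optional[Iterable[int]] = None,
                  valid_only: bool = True) -> pd.DataFrame:
    """Valid probe-trial observations, optionally at given distances."""
    m = obs["is_probe"].astype(bool)
    if valid_only:
        m &= obs["valid"].astype(bool)
    if distances is not None:
        m &= obs["probe_distance"].isin(list(distances))
    return obs.loc[m]


# ---------------------------------------------------------------------------
# quintiles

@dataclass
class QuintileTable:
    """Per-cell and group-averaged RT-quintile summaries.

    ``cells``: participant x probe_distance x quintile rows with mean
    RT, mean bias and trial count. ``group``: unweighted across-
    participant means with SEM (SD across participants / sqrt(n)).
    ``skipped`` records cells with too few trials.
    """
    cells: pd.DataFrame
    group: pd.DataFrame
    skipped: list = field(default_factory=list)


def quintile_summary(obs: pd.DataFrame, n_bins: int = 5,
                     min_trials: int = 5) -> QuintileTable:
    """Bin each participant's probe RTs into quintiles and average bias.

    Trials are sorted by RT ascending and split into ``n_bins`` bins of
    near-equal size (any remainder goes to the earliest, i.e. fastest,
    bins), so bin 1 holds the fastest ~20% of reaches. Cells with fewer
    than ``min_trials`` valid trials are skipped and logged.
    """
    data = select_probes(obs)
    rows, skipped = [], []
    for (pid, d), cell in data.groupby(["participant", "probe_distance"]):
        if len(cell) < min_trials:
            skipped.append((pid, int(d), len(cell)))
            continue
        cell = cell.sort_values("rt_s", kind="mergesort")
        for q, part in enumerate(np.array_split(np.arange(len(cell)), n_bins)):
            sub = cell.iloc[part]
            rows.append((pid, int(d), q + 1, sub["rt_s"].mean(),
                         sub["bias_deg"].mean(), len(sub)))
    cells = pd.DataFrame(rows, columns=["participant", "probe_distance",
                                        "quintile", "mean_rt_s",
                                        "mean_bias_deg", "n"])
    grp = (cells.groupby(["probe_distance", "quintile"])
           .agg(mean_rt_s=("mean_rt_s", "mean"),
                mean_bias_deg=("mean_bias_deg", "mean"),
                sem_bias_deg=("mean_bias_deg", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
                n_participants=("participant", "nunique"))
           .reset_index())
    return QuintileTable(cells=cells, group=grp, skipped=skipped)


# ---------------------------------------------------------------------------
# slopes

@dataclass
class SlopeResult:
    """Bias-on-RT slope at one probe distance (degrees per second)."""
    probe_distance: int
    slope: float
    se: float
    stat: float
    p_value: float
    df: float
    method: str
    per_participant: Optional[pd.Series] = field(repr=False, default=None)
    singular_participants: list = field(default_factory=list)


def _two_stage(data: pd.DataFrame, d: int) -> SlopeResult:
    slopes, singular = {}, []
    for pid, cell in data.groupby("participant"):
        if len(cell) < 3 or cell["rt_s"].nunique() < 2:
            singular.append(pid)
            continue
        b, _ = np.polyfit(cell["rt_s"].to_numpy(), cell["bias_deg"].to_numpy(), 1)
        slopes[pid] = b
    s = pd.Series(slopes, name="slope")
    if len(s) < 2:
        raise ValueError("need >= 2 participants with estimable slopes")
    sd = s.std(ddof=1)
    se = sd / np.sqrt(len(s))
    if sd == 0:
        stat, p = (np.inf if s.mean() != 0 else 0.0), (0.0 if s.mean() != 0 else 1.0)
    else:
        stat, p = sps.ttest_1samp(s, 0.0)
    return SlopeResult(d, float(s.mean()), float(se), float(stat), float(p),
                       float(len(s) - 1), "two_stage", s, singular)


def _pooled_mixed(data: pd.DataFrame, d: int) -> SlopeResult:
    import statsmodels.formula.api as smf
    model = smf.mixedlm("bias_deg ~ rt_s", data, groups=data["participant"])
    res = None
    # boundary fits (random-effect variance ~ 0) can break an optimizer;
    # fall through a few before giving up
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            res = model.fit(reml=True, method=method)
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if res is None:
        raise RuntimeError("mixed-model fit failed for all optimizers")
    slope = float(res.params["rt_s"])
    se = float(res.bse["rt_s"])
    stat = slope / se
    df = float(len(data) - 2)  # residual df; backend has no Satterthwaite
    p = float(2 * sps.t.sf(abs(stat), df))
    return SlopeResult(d, slope, se, stat, p, df, "pooled_mixed")


def slope_fit(obs: pd.DataFrame, probe_distance: int,
              method: str = "two_stage") -> SlopeResult:
    """Bias-on-RT slope at one probe distance.

    ``two_stage`` (default): per-participant OLS of bias on RT followed
    by a one-sample t-test of the slopes against zero. ``pooled_mixed``:
    a random-intercept mixed model on the pooled trials (statsmodels
    backend; residual degrees of freedom reported).
    """
    data = select_probes(obs, distances=[probe_distance])
    if data["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    if method == "two_stage":
        return _two_stage(data, int(probe_distance))
    if method == "pooled_mixed":
        return _pooled_mixed(data, int(probe_distance))
    raise ValueError(f"unknown method {method!r}")


def slope_table(obs: pd.DataFrame, distances: Iterable[int] = PROBE_DISTANCES,
                method: str = "two_stage") -> pd.DataFrame:
    """slope_fit at each distance, as one tidy table."""
    rows = []
    for d in distances:
        r = slope_fit(obs, d, method=method)
        rows.append((r.probe_distance, r.slope, r.se, r.stat, r.p_value,
                     r.df, r.method))
    return pd.DataFrame(rows, columns=["probe_distance", "slope_deg_per_s",
                                       "se", "stat", "p_value", "df", "method"])


# ---------------------------------------------------------------------------
# normalization and contrasts

def normalize_bias(obs: pd.DataFrame) -> pd.DataFrame:
    """Bias as a fraction of its maximal inward value (bias / distance).

    Only probe distances > 0 are kept; a reach fully captured by the
    frequent-target default plan scores 1, an unbiased reach 0.
    """
    out = obs.loc[obs["probe_distance"] > 0].copy()
    out["bias_norm"] = out["bias_deg"] / out["probe_distance"]
    return out


@dataclass
class DistanceContrasts:
    per_distance: pd.DataFrame
    contrasts: pd.DataFrame
    missing_cells: list = field(default_factory=list)


def distance_contrasts(obs: pd.DataFrame,
                       distances: Iterable[int] = PROBE_DISTANCES) -> DistanceContrasts:
    """Per-distance mean biases, one-sample tests, and paired contrasts
    (30v60, 60v90, 30v90) Bonferroni-corrected for three comparisons.
    Effect sizes are within-subject Cohen's d_z."""
    data = select_probes(obs, distances=distances)
    means = (data.groupby(["participant", "probe_distance"])["bias_deg"]
             .mean().unstack())
    missing = [(p, int(d)) for d in means.columns
               for p in means.index[means[d].isna()]]

    per_rows = []
    for d in means.columns:
        v = means[d].dropna()
        t, p = sps.ttest_1samp(v, 0.0)
        dz = v.mean() / v.std(ddof=1)
        per_rows.append((int(d), v.mean(), v.std(ddof=1) / np.sqrt(len(v)),
                         float(t), float(p), float(dz), len(v)))
    per = pd.DataFrame(per_rows, columns=["probe_distance", "mean_bias_deg",
                                          "sem", "t", "p_value", "dz", "n"])

    pairs = [(30, 60), (60, 90), (30, 90)]
    con_rows = []
    for a, b in pairs:
        if a not in means.columns or b not in means.columns:
            continue
        diff = (means[b] - means[a]).dropna()
        t, p = sps.ttest_1samp(diff, 0.0)
        con_rows.append((a, b, diff.mean(), diff.std(ddof=1) / np.sqrt(len(diff)),
                         float(t), float(p), min(1.0, 3.0 * float(p)),
                         float(diff.mean() / diff.std(ddof=1)), len(diff)))
    con = pd.DataFrame(con_rows, columns=["d_low", "d_high", "mean_diff_deg",
                                          "sem", "t", "p_raw", "p_bonf",
                                          "dz", "n"])
    return DistanceContrasts(per, con, missing)


# ---------------------------------------------------------------------------
# reward comparison

@dataclass
class RewardComparison:
    """Reward vs no-reward group comparison in the delayed design.

    ``accuracy``: per-participant mean absolute (baseline-corrected)
    bias at the frequent target, by group, plus the between-group
    t-test. ``anova``: mixed ANOVA (group between, probe distance
    within) on per-participant mean probe biases."""
    accuracy: pd.DataFrame
    accuracy_t: float
    accuracy_p: float
    accuracy_d: float
    reward_main_p: float
    interaction_p: float
    interaction_F: float
    anova: pd.DataFrame = field(repr=False, default=None)


def reward_compare(obs: pd.DataFrame,
                   groups=("reward", "no_reward")) -> RewardComparison:
    """Test whether reward changes accuracy or the bias profile.

    Accuracy at the frequent target (all valid trials at distance 0) is
    compared between groups with an independent-samples t-test
    (between-subjects Cohen's d). Probe biases (30/60/90 deg) enter a
    mixed ANOVA with group as the between factor and probe distance as
    the within factor; the reward main effect and reward x distance
    interaction p-values are reported.
    """
    known = set(obs["group"].unique())
    if not set(groups) <= known:
        raise ValueError(f"groups {groups} not all present in data ({known})")
    data = obs[obs["group"].isin(groups) & obs["valid"].astype(bool)].copy()
    data["subject"] = data["group"].astype(str) + "_" + data["participant"].astype(str)

    acc = (data[data["probe_distance"] == 0]
           .assign(abs_bias=lambda f: f["bias_deg"].abs())
           .groupby(["subject", "group"])["abs_bias"].mean().reset_index())
    a = acc.loc[acc["group"] == groups[0], "abs_bias"]
    b = acc.loc[acc["group"] == groups[1], "abs_bias"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 participants per group")
    t, p = sps.ttest_ind(a, b)
    pooled_sd = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                        / (len(a) + len(b) - 2))
    cohen_d = float((a.mean() - b.mean()) / pooled_sd) if pooled_sd > 0 else 0.0

    probes = select_probes(data, distances=PROBE_DISTANCES)
    cell = (probes.groupby(["subject", "group", "probe_distance"])["bias_deg"]
            .mean().reset_index())
    import pingouin as pg
    aov = pg.mixed_anova(data=cell, dv="bias_deg", within="probe_distance",
                         between="group", subject="subject")
    main = aov.loc[aov["Source"] == "group"].iloc[0]
    inter = aov.loc[aov["Source"] == "Interaction"].iloc[0]

    return RewardComparison(accuracy=acc, accuracy_t=float(t),
                            accuracy_p=float(p), accuracy_d=cohen_d,
                            reward_main_p=float(main["p_unc"]),
                            interaction_p=float(inter["p_unc"]),
                            interaction_F=float(inter["F"]),
                            anova=aov)
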