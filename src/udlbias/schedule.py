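"""Trial schedules for the frequent-target reaching designs.

Two designs are supported:

* ``exp1`` — self-paced reaching. Two 70-trial baseline blocks (10
  reaches to each of 7 targets; the first with online cursor feedback,
  the second without) followed by eight 90-trial test blocks: 10 initial
  reaches to the frequent target, then 80 trials of which 66 go to the
  frequent target with cursor feedback and 14 are feedback-free probes,
  two per target location (including the frequent one). Rare locations
  therefore each receive 2/90 ~ 2.2% of block trials.
* ``exp2`` — delayed-response reaching. The same baselines followed by
  six 134-trial test blocks: 113 reaches to the frequent target
  (reward-eligible in the reward group) and 21 feedback-free probes,
  three per location.

The seven session targets sit at 0, +-30, +-60 and +-90 degrees from
the frequent location (wrapped to [0, 360)); with the frequent target at
60 deg this is the canonical set {0, 30, 60, 90, 120, 150, 330}.
Probe positions are pseudorandomized by splitting each block's eligible
trials into as many near-equal consecutive slots as there are probes and
placing one probe uniformly at random within each slot, so probes stay
evenly interspersed among frequent-target reaches.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

TARGET_OFFSETS = np.array([-90, -60, -30, 0, 30, 60, 90], dtype=float)

PHASE_BASELINE_FB = "baseline_feedback"
PHASE_BASELINE_NOFB = "baseline_nofeedback"
PHASE_TEST = "test"

_DESIGNS = {
    "exp1": dict(n_test_blocks=8, block_len=90, n_initial=10,
                 n_freq_main=66, probes_per_loc=2),
    "exp2": dict(n_test_blocks=6, block_len=134, n_initial=0,
                 n_freq_main=113, probes_per_loc=3),
}

SCHEDULE_COLUMNS = ["participant", "block", "trial", "phase", "target_deg",
                    "is_probe", "feedback", "group", "frequent_deg"]


def session_targets(frequent_loc: float) -> np.ndarray:
    """The seven session target angles for a given frequent location."""
    return np.mod(frequent_loc + TARGET_OFFSETS, 360.0)


def _baseline_block(rng, targets: np.ndarray) -> np.ndarray:
    order = np.repeat(targets, 10)
    rng.shuffle(order)
    return order


def _probe_positions(rng, n_slots: int, n_trials: int) -> np.ndarray:
    """One pseudorandom probe index inside each of n_slots consecutive
    near-equal slots partitioning range(n_trials)."""
    slots = np.array_split(np.arange(n_trials), n_slots)
    return np.array([rng.choice(s) for s in slots])


def _test_block(rng, design: dict, targets: np.ndarray, frequent_loc: float,
                freq_feedback: str):
    n_probes = design["probes_per_loc"] * 7
    n_main = design["n_freq_main"] + n_probes
    pos = _probe_positions(rng, n_probes, n_main)
    probe_targets = np.tile(targets, design["probes_per_loc"])
    rng.shuffle(probe_targets)

    target = np.full(n_main, frequent_loc, dtype=float)
    target[pos] = probe_targets
    is_probe = np.zeros(n_main, dtype=bool)
    is_probe[pos] = True
    feedback = np.where(is_probe, "none", freq_feedback)

    n_init = design["n_initial"]
    if n_init:
        target = np.concatenate([np.full(n_init, frequent_loc), target])
        is_probe = np.concatenate([np.zeros(n_init, dtype=bool), is_probe])
        feedback = np.concatenate([np.full(n_init, freq_feedback), feedback])
    return target, is_probe, feedback


def make_schedule(design: str,
                  n_participants: int,
                  frequent_loc: Optional[float] = None,
                  seed: int = 0,
                  groups: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Build the full trial schedule for a simulated cohort.

    Parameters
    ----------
    design : {"exp1", "exp2"}
        Which session structure to emit.
    n_participants : int
        Cohort size (>= 1).
    frequent_loc : float, optional
        Frequent-target angle in degrees. By default it is
        counterbalanced across participants between 60 and 150.
    seed : int
        Seed for the pseudorandomization; schedules are deterministic
        given (design, n_participants, frequent_loc, seed, groups).
    groups : sequence of str, optional
        Per-participant group labels. Defaults to "exp1" for the
        self-paced design and to alternating "reward"/"no_reward" for
        the delayed-response design.

    Returns
    -------
    pandas.DataFrame
        One row per trial with columns ``participant, block, trial,
        phase, target_deg, is_probe, feedback, group, frequent_deg``.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected 'exp1' or 'exp2'")
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    spec = _DESIGNS[design]
    rng = np.random.default_rng(seed)

    if groups is None:
        if design == "exp1":
            groups = ["exp1"] * n_participants
        else:
            groups = ["reward" if p % 2 == 0 else "no_reward"
                      for p in range(n_participants)]
    elif len(groups) != n_participants:
        raise ValueError("groups must have one label per participant")

    rows = []
    for p in range(n_participants):
        floc = frequent_loc if frequent_loc is not None else (60.0 if p % 2 == 0 else 150.0)
        targets = session_targets(floc)
        group = groups[p]
        if design == "exp1":
            freq_feedback = "online_cursor"
        else:
            freq_feedback = "reward_binary" if group == "reward" else "none"

        blocks = []
        for phase, fb in ((PHASE_BASELINE_FB, "online_cursor"),
                          (PHASE_BASELINE_NOFB, "none")):
            order = _baseline_block(rng, targets)
            blocks.append((phase, order, np.zeros(order.size, bool),
                           np.full(order.size, fb)))
        for _ in range(spec["n_test_blocks"]):
            tgt, is_probe, fb = _test_block(rng, spec, targets, floc, freq_feedback)
            blocks.append((PHASE_TEST, tgt, is_probe, fb))

        for b, (phase, tgt, is_probe, fb) in enumerate(blocks):
            n = tgt.size
            rows.append(pd.DataFrame({
                "participant": p,
                "block": b,
                "trial": np.arange(n),
                "phase": phase,
                "target_deg": tgt,
                "is_probe": is_probe,
                "feedback": fb,
                "group": group,
                "frequent_deg": floc,
            }))
    out = pd.concat(rows, ignore_index=True)
    return out[SCHEDULE_COLUMNS]
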