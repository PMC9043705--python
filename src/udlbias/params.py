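"""Parameters of the two-process reach generator.

The generator expresses use-dependent reaching biases as the sum of two
latent sources:

* a small, preparation-time-invariant *execution* shift of ``eps_exec``
  degrees toward the frequently practiced direction, and
* a *planning* bias that starts at the frequent-target default plan and
  is rotated toward the actual target at ``omega`` deg/s once planning
  has been underway for ``t0`` seconds.

A reach prepared for ``P`` seconds toward a probe ``d`` degrees from the
frequent target is therefore aimed at

    b(P) = max(d - omega * max(0, P - t0), eps_exec) + noise,   d > 0

in "bias coordinates" (probe at 0, positive toward the frequent target).
Short preparation leaves the default plan intact (b = d); long
preparation fully re-aims the reach, leaving only the execution shift.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml


@dataclass
class GenerativeParams:
    """Tunable parameters of the synthetic two-process reach generator.

    Attributes
    ----------
    eps_exec : float
        Stable execution shift toward the frequent target, degrees (>= 0).
    omega : float
        Plan re-aiming rate, degrees per second (> 0).
    t0 : float
        Re-aiming onset latency after target presentation, seconds.
    sigma_motor : float
        Reach execution noise SD, degrees (> 0).
    rt_mu, rt_sigma : float
        Log-scale location and scale of the log-normal reaction-time law.
    rt_shift : float
        Minimum RT offset in seconds; RT = rt_shift + LogNormal(mu, sigma).
    rt_cap : float
        Upper truncation of generated RTs, seconds (keeps trajectories
        bounded; the clipped tail mass is negligible at the defaults).
    delay : float
        Target-to-imperative interval, seconds (0.0 for the self-paced
        design, 0.5 for the delayed-response design).
    freq_loc_sd : float
        SD of trial-by-trial jitter of the frequent location, degrees
        (0 in the main designs; 7.5 or 15 in the variable-location
        variant).
    move_time_range : tuple of float
        Uniform draw bounds for movement time, seconds.
    p_lapse : float
        Probability that a reach is a uniformly misdirected lapse,
        replaced by a Uniform(-d-30, d+30) heading in bias coordinates.
    start_jitter_sd : float
        Positional digitizer noise before movement onset, cm.
    """

    eps_exec: float = 3.0
    omega: float = 300.0
    t0: float = 0.1
    sigma_motor: float = 4.0
    rt_mu: float = -1.386
    rt_sigma: float = 0.6
    rt_shift: float = 0.07
    rt_cap: float = 2.0
    delay: float = 0.0
    freq_loc_sd: float = 0.0
    move_time_range: Tuple[float, float] = (0.25, 0.40)
    p_lapse: float = 0.0
    start_jitter_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.eps_exec < 0:
            raise ValueError("eps_exec must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.sigma_motor <= 0:
            raise ValueError("sigma_motor must be > 0")
        if self.rt_shift < 0:
            raise ValueError("rt_shift must be >= 0")
        if not (0.0 <= self.p_lapse < 0.05):
            raise ValueError("p_lapse must lie in [0, 0.05)")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        lo, hi = self.move_time_range
        if not (0 < lo <= hi):
            raise ValueError("move_time_range must satisfy 0 < lo <= hi")
        if self.freq_loc_sd < 0:
            raise ValueError("freq_loc_sd must be >= 0")

    def replace(self, **kwargs) -> "GenerativeParams":
        d = asdict(self)
        d.update(kwargs)
        d["move_time_range"] = tuple(d["move_time_range"])
        return GenerativeParams(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["move_time_range"] = list(d["move_time_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        if "move_time_range" in d:
            d["move_time_range"] = tuple(d["move_time_range"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GenerativeParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: Defaults for the self-paced design (no imperative delay).
EXP1_DEFAULTS = GenerativeParams(delay=0.0)

#: Defaults for the delayed-response design (500 ms imperative delay).
EXP2_DEFAULTS = GenerativeParams(delay=0.5)
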