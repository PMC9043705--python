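"""Does reward at the frequent target change the bias profile?

Simulates a delayed-response cohort split into a reward group (binary
reward within +-5.7 deg of the frequent target during training) and a
no-reward group. With identical generator parameters the reward x
probe-distance interaction should stay null; giving the reward group
lower motor noise makes the frequent-target accuracy contrast fire.
"""
import pandas as pd

import udlbias as u

# both groups share the same execution shift -> interaction should be null
a = u.generate_observations("exp2", u.EXP2_DEFAULTS, 8, seed=21,
                            groups=["reward"] * 8)
b = u.generate_observations("exp2", u.EXP2_DEFAULTS, 8, seed=22,
                            groups=["no_reward"] * 8)
rc = u.reward_compare(pd.concat([a, b], ignore_index=True))
print("identical groups:")
print(f"  accuracy t = {rc.accuracy_t:.2f} (p = {rc.accuracy_p:.2f}), "
      f"reward x distance interaction p = {rc.interaction_p:.2f}")

# a genuinely more precise reward group is detected by the accuracy test
tight = u.EXP2_DEFAULTS.replace(sigma_motor=3.0)
c = u.generate_observations("exp2", tight, 8, seed=23, groups=["reward"] * 8)
rc2 = u.reward_compare(pd.concat([c, b], ignore_index=True))
print("reward group with lower motor noise (3 vs 4 deg):")
print(f"  accuracy t = {rc2.accuracy_t:.2f} (p = {rc2.accuracy_p:.2g}), "
      f"interaction p = {rc2.interaction_p:.2f}")

print("\nA null interaction with a detectable accuracy difference means "
      "reward sharpens reaches without changing the use-dependent bias "
      "itself.")
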