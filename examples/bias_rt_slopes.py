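"""Bias as a function of reaction time: quintiles and slopes.

In the self-paced design, reaches initiated quickly are captured by the
frequent-target default plan, so the inward bias falls steeply with RT;
after a 500 ms delay the relationship disappears. Prints per-quintile
group means and the two-stage slope estimates (deg/s) per probe
distance for both designs.
"""
import udlbias as u

for design, n, label in [("exp1", 10, "self-paced"), ("exp2", 16, "delayed")]:
    params = u.EXP2_DEFAULTS if design == "exp2" else u.EXP1_DEFAULTS
    obs = u.generate_observations(design, params, n, seed=5)

    print(f"--- {label} ({design}), {n} participants ---")
    q = u.quintile_summary(obs)
    far = q.group[q.group.probe_distance == 90]
    print("90 deg probe, bias per RT quintile (fast -> slow):",
          [round(v, 1) for v in far.mean_bias_deg])

    t = u.slope_table(obs)
    for _, r in t.iterrows():
        print(f"  d={int(r.probe_distance)}: slope = "
              f"{r.slope_deg_per_s:7.1f} deg/s  (p = {r.p_value:.2g})")
    print()

print("Steep negative slopes that grow with probe distance are the "
      "planning component; their absence under the delay shows the "
      "residual bias is not a fast-RT artifact.")
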