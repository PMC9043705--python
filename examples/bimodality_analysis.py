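"""Bimodality of heading distributions: self-paced vs delayed designs.

Fits 1- and 2-component Gaussian mixtures to the pooled heading biases
at the 90 deg probe and runs the parametric-bootstrap likelihood-ratio
test in both designs. Self-paced reaching should be bimodal (a cluster
at the probe plus a cluster near the frequent target); adding a 500 ms
response delay lets planning finish, leaving one narrow peak shifted by
only the small execution bias.
"""
import udlbias as u

for design, n, label in [("exp1", 6, "self-paced"), ("exp2", 8, "delayed")]:
    params = u.EXP2_DEFAULTS if design == "exp2" else u.EXP1_DEFAULTS
    obs = u.generate_observations(design, params, n, seed=3)
    probes = u.select_probes(obs)
    x = probes.loc[probes.probe_distance == 90, "bias_deg"].to_numpy()

    res = u.modality_test(x, n_boot=199, seed=0)
    fit = res.fit2 if res.bimodal else res.fit1
    pk = u.peak_ci(x, n_boot=2000, k=res.k_selected, seed=0)
    print(f"{label} ({design}), 90 deg probe, n={len(x)} trials:")
    print(f"  bootstrap LRT p = {res.p_value:.3f} -> "
          f"{'bimodal' if res.bimodal else 'unimodal'}")
    print(f"  component means (deg): {fit.means.round(1)}")
    print(f"  peak near probe: {pk.peak:.2f} deg, "
          f"95% CI [{pk.ci_low:.2f}, {pk.ci_high:.2f}]\n")

print("The peak CI excluding 0 in the delayed design is the execution "
      "bias: a stable ~3 deg shift toward the practiced direction that "
      "survives even when planning is complete.")
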