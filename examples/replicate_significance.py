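"""Distance uncertainty from replicate structures and the 4-sigma rule.

Simulates three isomorphous replicates of a Schiff-base/water pair with
0.02 A-per-axis coordinate noise, reports the distance as mean +/-
sample SD, and asks whether a 0.10 A difference from a reference value
clears four standard deviations.
"""

import retgeom as rg

base = rg.generate_hbond_cluster(
    [rg.PairSpec(("HOH", 402, "O"), ("LYS", 216, "NZ"), 2.77)])
replicates = rg.perturb_replicates(base, sigma=0.02, n=3, seed=42)

est = rg.replicate_distance(replicates,
                            rg.AtomSpec(res_seq=216, name="NZ"),
                            rg.AtomSpec(res_seq=402, name="O"))
print(f"Schiff base N to water O: {est}")

reference = est.mean + 0.10     # a structure whose distance is 0.10 A longer
report = rg.significant_difference(est, reference, k=4)
print(f"difference from reference: {report.difference:+.3f} A, "
      f"4*sd = {4 * est.sd:.3f} A -> "
      f"{'significant' if report.significant else 'not significant'}")
# With three replicates at this precision a 0.1 A shift is resolvable;
# the strict 4-sigma rule keeps marginal differences out.
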