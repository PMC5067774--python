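"""Precursor-region counts as a processing proxy.

If a perturbation acts post-Dicer on one mature arm (tailing/trimming),
the flanks, loop and opposite arm of the precursor should be untouched;
if it changed Drosha/Dicer processing, all parts would shift together.
Here both enzymatic rates are doubled: mature-arm substrate cpm drops
while the loop/3p/flank fragment counts stay flat within noise.
"""

from isotail import SimScenario, simulate_sample
from isotail.pipeline import quantify_sequences

BG = ["upstream_of_5p", "loop", "mature_3p", "downstream_of_3p"]

for label, factor in [("baseline", 1.0), ("2x tailing/trimming", 2.0)]:
    scn = SimScenario(a_rate=0.2 * factor, t_rate=0.3 * factor)
    sample = simulate_sample(scn, 21, label)
    res = quantify_sequences(sample.sequence_counts, [scn.reference], label)
    reg = res.regions[0]
    r = next(x for x in res.ratios if x.arm_name == "miR-sim-5p")
    sub_cpm = r.substrate_count * 1e6 / res.profile.total_counted
    bg = "  ".join(f"{name}={reg.counts[name]:.0f}" for name in BG)
    print(f"{label:20s} substrate_cpm={sub_cpm:9.0f}  {bg}")

print("\nBackground regions move only by sampling noise (~sqrt(5000)); the "
      "substrate cpm roughly halves.")
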