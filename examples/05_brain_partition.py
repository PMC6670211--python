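"""Blood-to-brain ammonia partitioning by the pH difference.

Uncharged NH3 equilibrates across the blood-brain barrier; the more acidic
brain (pH ~7.0 vs blood 7.4) then traps more of the total ammonia/ammonium
pool. The default partition factor is 10^(7.4-7.0) = 2.51; the exact
Henderson-Hasselbalch ratio at pKa 9.25 is also available.
"""

import hepaflux as hf

grid = hf.run_grid()
by = grid.set_index(["protein_g_per_day", "condition"]).ss_nh3_uM

for (diet, cond) in [
    (71.0, "normal"),
    (122.0, "cirrhosis"),
    (71.0, "cps1_het"),
    (100.0, "cps1_het"),
    (122.0, "cps1_het"),
]:
    blood = by[(diet, cond)]
    brain = hf.brain_concentration(blood)
    print(f"{cond:10s} {diet:5.0f} g/day: blood {blood:6.1f} uM -> brain {brain:6.1f} uM")

hh = hf.BrainPartition(mode="henderson_hasselbalch")
print("\npartition factors: simple ratio %.3f, Henderson-Hasselbalch %.3f"
      % (hf.BrainPartition().factor(), hh.factor()))
# Brain levels above ~90 uM (reached by every disease x diet combination
# printed above except none of the healthy rows) are in the range where
# differentiated neuronal cells begin to lose viability.
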