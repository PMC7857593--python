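"""Per-residue TAG contact occupancy around the ring trap.

The trap preset emits probe residues at the 11 ring sites (residues 1-11)
and mirrored distal probes far from the trap (residues 51-61). Occupancy is
the fraction of sampled frames with a TAG within 0.5 nm; site-adjacent
probes should be occupied far more often than distal ones once the trap
fills.
"""

import numpy as np

from memlens import occupancy_analysis, preset_config, simulate_membrane

cfg = preset_config("trap_1_25", seed=3)
cfg.n_lipid_equivalents = 2400
cfg.n_steps = 10000  # 1 us

trajs = []
for seed in (3, 4):  # two replicates -> mean and SEM
    traj, _ = simulate_membrane(cfg, seed=seed)
    trajs.append(traj)

table = occupancy_analysis(trajs, windows=[(0.0, 500.0), (500.0, 1000.0)])
near = table[table.residue_number <= 11]
far = table[table.residue_number > 50]
for t0 in (0.0, 500.0):
    n = near[near.window_t0_ns == t0]["occupancy_mean"].mean()
    f = far[far.window_t0_ns == t0]["occupancy_mean"].mean()
    print(f"window [{t0:5.0f}, {t0 + 500:5.0f}) ns:  "
          f"site-adjacent occupancy = {n:.2f}   distal = {f:.2f}")

print("\nOccupancy near the trap grows as sites fill and the lumen cluster "
      "forms; distal probes only see the dilute background.")
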