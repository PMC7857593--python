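"""Concentration-dependent TAG clustering, with and without the ring trap.

Runs one short replicate of each study preset and prints the final
clustered fraction (fraction of TAGs with at least two TAG neighbors within
0.5 nm — monomers and dimers count as unclustered). At 2.5 mol% TAG
condenses on its own; at 1.25 mol% it stays dissolved unless the ring trap
concentrates it, in which case the largest cluster sits inside the ring.
"""

import numpy as np

from memlens import clustered_fraction_series, preset_config, simulate_membrane

for preset in ("no_trap_2_5", "no_trap_1_25", "trap_1_25"):
    cfg = preset_config(preset, seed=3)  # full preset: 3 us, ~20 s to run
    traj, truth = simulate_membrane(cfg, seed=3)
    ref = np.asarray(cfg.trap.center) if cfg.trap.enabled else None
    series = clustered_fraction_series(traj, stride=250.0, reference=ref)
    line = (f"{preset:14s} final clustered fraction = "
            f"{series.clustered_fraction[-1]:.2f}  "
            f"largest cluster = {series.largest_cluster_size[-1]} TAGs")
    if ref is not None:
        line += (f"  centroid {series.centroid_dist_to_reference[-1]:.1f} nm "
                 f"from trap center (ring radius {cfg.trap.ring_radius} nm)")
    print(line)

print("\nA high fraction means most TAGs sit in multi-TAG clusters; a "
      "centroid distance below the ring radius means the cluster formed "
      "inside the trap lumen.")
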