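"""TAG-site complex lifetimes from a ring-trap run.

Compares two routes to the complex lifetime: the generator's ground-truth
binding events (exact unbind times, mean dwell = 1/k_off) and the
analysis-side detector, which samples the TAG-site distance at a 1 ns
stride and merges recrossings shorter than the gap tolerance. Because a
2D random walk revisits the site quickly, sub-stride unbind/rebind pairs
merge into one apparent event, so the detected mean exceeds the molecular
truth — the survival curve makes the recrossing tail visible.
"""

import numpy as np

from memlens import preset_config, simulate_membrane, site_lifetimes

cfg = preset_config("trap_1_25", seed=6)
cfg.n_steps = 15000              # 1.5 us
cfg.k_off = 0.01                 # 100 ns mean dwell so many events complete
cfg.attraction.epsilon = 0.0     # pure binding kinetics, no cluster contacts
cfg.trap.lumen_epsilon = 0.0

traj, truth = simulate_membrane(cfg, seed=6)

true_dwells = [e.dwell for e in truth.events if not e.censored]
print(f"ground truth: {len(true_dwells)} completed events, "
      f"mean dwell {np.mean(true_dwells):.1f} ns "
      f"(1/k_off = {1 / cfg.k_off:.0f} ns)")

stats = site_lifetimes(traj, cutoff_bind=cfg.trap.capture_radius)
n_unc = sum(not e.censored for e in stats.events)
print(f"detected at 1 ns stride: {len(stats.events)} events "
      f"({n_unc} uncensored), mean apparent lifetime "
      f"{stats.mean_lifetime:.1f} ns")
half = stats.survival_t[stats.survival <= 0.5]
if half.size:
    print(f"survival curve: S(t) drops below 0.5 at ~{half[0]:.0f} ns")

print("\nThe detected mean exceeds the molecular mean because unbind-rebind "
      "recrossings faster than the sampling stride merge into single "
      "events; dwell definitions must state their recrossing tolerance.")
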