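# memlens

Trajectory analysis of neutral-lipid (triacylglycerol, TAG) behavior in and
around ring-shaped membrane proteins — written for structural biologists
and simulators studying how proteins such as seipin, an 11-subunit
disk-shaped oligomer of the ER membrane, nucleate the TAG clusters that
seed lipid droplets.

Phospholipid bilayers dissolve only a few mol% of TAG before it phase
separates into nanoscale lens-like clusters. A protein that traps TAGs at
specific residues inside its ring can catalyze this clustering at
concentrations that would otherwise stay dissolved. `memlens` provides the
measurements that quantify this picture on particle trajectories, plus a
seeded Brownian-dynamics generator that produces membrane-like trajectories
with exact ground truth so every estimator is testable at desk scale.

## What it computes

| Quantity | Definition |
|---|---|
| Contact occupancy | per residue, fraction of sampled frames with a TAG within 0.5 nm (mean ± SEM over replicates) |
| Clustered fraction | fraction of TAGs with ≥ 2 TAG neighbors within 0.5 nm; monomers and dimers excluded by construction |
| Short-time D | MLE fit of the 2D displacement-magnitude distribution P(Δr) = (Δr/2DΔt)·exp(−Δr²/4DΔt); closed form D̂ = ΣΔr²/(4nΔt), exact gamma CI |
| Bound/free D ratio | D estimated separately inside and outside site-bound intervals |
| Complex lifetimes | dwell-time events between TAGs and binding sites, with censoring flags and survival curves |
| Leaflet topography | per-leaflet height fields from head-group positions and mean-curvature maps H = −½∇²h (or the full divergence form); H > 0 toward the midplane |

The core statistics follow the field's standard conventions: the 0.5 nm
contact cutoff, 1 ns analysis stride, per-TAG (not connected-component)
clustering rule, and the short-time diffusion coefficient from the 1 ns
displacement distribution.

## Worked example

```python
import numpy as np
from memlens import preset_config, simulate_membrane, clustered_fraction_series

for preset in ("no_trap_2_5", "no_trap_1_25", "trap_1_25"):
    cfg = preset_config(preset, seed=3)
    traj, truth = simulate_membrane(cfg, seed=3)
    ref = np.asarray(cfg.trap.center) if cfg.trap.enabled else None
    s = clustered_fraction_series(traj, stride=250.0, reference=ref)
    print(preset, s.clustered_fraction[-1])
```

prints (see `examples/01_clustering_presets.py` for the annotated version):

```
no_trap_2_5    final clustered fraction = 0.48  largest cluster = 20 TAGs
no_trap_1_25   final clustered fraction = 0.20  largest cluster = 12 TAGs
trap_1_25      final clustered fraction = 0.23  largest cluster = 14 TAGs  centroid 0.4 nm from trap center (ring radius 3.0 nm)
```

At 2.5 mol% TAG condenses spontaneously; at 1.25 mol% it largely stays
dissolved — unless the ring trap is present, in which case the largest
cluster forms *inside* the ring (centroid 0.4 nm from the trap center,
well inside the 3 nm ring radius). This is the qualitative signature the
package is built to quantify. The `examples/` directory has one short
narrative script per capability: clustering presets, occupancy probes,
short-time diffusion (bound vs free), binding lifetimes, and curvature
maps.

A thin CLI mirrors the library for shell use:

```bash
memlens simulate --preset trap_1_25 --out run/ --seed 1
memlens clusters --traj run/trajectory.csv --topology run/topology.csv --out clusters.csv
memlens report --config analysis.yaml     # full config-driven pipeline
```

Supported formats: multi-frame GRO, extended XYZ
(`time_ns=… box_nm=…` comment), long-format CSV
(`frame,time_ns,particle_id,x,y,z`), with a topology sidecar CSV
(`particle_id,name,group,molecule_id,residue_number,leaflet`).

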