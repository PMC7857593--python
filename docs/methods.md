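# Methods

This note documents the models, estimators and numerical choices behind
`memlens`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what the
synthetic data do and do not establish about real trajectories.

## Scope and units

`memlens` analyzes particle trajectories of membrane systems in which a
neutral lipid (triacylglycerol, TAG) diffuses, clusters and binds to protein
sites — in particular the geometry of an 11-subunit ring-shaped protein
(seipin-like) whose luminal helices trap TAG. All lengths are nm, all times
ns, all diffusion coefficients nm²/ns. Boxes are orthorhombic and periodic;
triclinic input is rejected so the minimum-image convention stays exact.
Internally particles are 0-based; GRO files are 1-based at the boundary.
The GRO `t=` comment is read as ps (GROMACS convention) and converted.

## Contact occupancy

A residue's TAG occupancy over a window is the fraction of sampled frames in
which the smallest distance between any residue particle and any TAG
particle is ≤ 0.5 nm (the boundary case counts as a contact). Distances are
nearest-particle distances: "distance from the residue surface" is read as
the atom–atom minimum, the only definition available without a molecular
surface. Sampling is at a 1 ns stride (nearest frame on the stride grid;
every frame, with a warning, when frames are coarser). Windows are
half-open [t0, t1) so 0–1 µs and 4–5 µs partition cleanly. Replicate
aggregation reports mean ± SEM with the n−1 denominator, the standard choice
for ~10 replicate bars; SEM is reported absent for a single replicate, and
snapped to exactly 0 when replicates are identical.

## TAG clustering statistic

Two TAG molecules are neighbors when their molecule–molecule minimum
particle distance is ≤ 0.5 nm. A TAG is *clustered* when it has ≥ 2
neighbors, which excludes monomers and dimers by construction; the
clustered fraction is the fraction of TAGs satisfying this per-TAG rule.
Note this is deliberately *not* the connected-component definition: on a
chain A–B–C only the middle TAG counts (fraction 1/3), so chain ends are
excluded. Connected components of the same neighbor graph are computed as
auxiliary geometry — sizes, and the largest component's centroid under a
periodic (circular-mean) convention so boundary-straddling clusters get a
sensible center — together with the centroid's distance to a reference
point such as the trap center.

## Short-time diffusion

For 2D Brownian motion the in-plane displacement magnitude over a lag Δt
follows P(Δr) = (Δr / 2DΔt) exp(−Δr²/4DΔt) (a Rayleigh distribution with
σ² = 2DΔt). Fitting this distribution has the closed-form maximum-likelihood
solution D̂ = ΣΔr²/(4nΔt), which coincides with the short-lag MSD relation
⟨Δr²⟩ = 4DΔt. Because ΣΔr²/(4Δt) is Gamma(n, D)-distributed, the 95%
confidence interval is exact, and a Kolmogorov–Smirnov statistic against the
fitted Rayleigh reports goodness of fit. Displacements are computed on
unwrapped coordinates; frames flagged by the unwrapper are excluded;
intervals are non-overlapping by default so the CI's independence
assumption approximately holds. State-conditioned estimates (bound vs free)
use only displacement intervals lying entirely inside, respectively outside,
the per-particle bound spans; the headline contrast is the ratio
D_free/D_bound.

Caveat: when the bound state is spatially confined (capture radius
comparable to √(4·D_bound·Δt)) the bound-state short-time D is biased low
by the confinement, not by the estimator; validation runs therefore use a
capture radius large against the per-lag displacement.

## Binding kinetics

A TAG–site complex exists while their minimum distance is ≤ the binding
cutoff (default 0.5 nm, the only contact cutoff in play; configurable).
Maximal runs of the bound indicator become events; unbound gaps of at most
`gap_tolerance` frames (default 0 — the literal single-crossing reading) are
merged. Events truncated by either trajectory end are flagged censored and
excluded from the mean lifetime (they would bias it downward); when *every*
event is censored the mean falls back to the biased all-event mean with a
warning, so short fixtures still report a number. The survival curve
S(t) = fraction of events with dwell ≥ t keeps censored events. The
geometric hydrogen-bond criterion (donor–acceptor ≤ 0.35 nm and
donor–H–acceptor angle ≥ 150°) uses standard geometric thresholds for
atomistic-mode input.

## Leaflet topography

Head groups are assigned to leaflets by z relative to their median plane.
The leaflet height field bins head-group positions onto a periodic grid
(default 64×64) and averages z over time and particles; Gaussian smoothing
(default σ = 1 nm — resolves a ~15 nm ring feature while suppressing
per-lipid noise) and empty-cell filling are one normalized convolution
(smoothed z-sums divided by smoothed counts, periodic wrap). The spatial
mean is removed, referencing each leaflet to its own mean plane. More than
50% empty cells raises an error suggesting a coarser grid.

Mean curvature uses periodic central differences, either in the small-slope
form H = −½(h_xx + h_yy) or the full divergence form
H = −div(∇h/√(1+|∇h|²))/2. Sign convention (stated in output metadata):
H > 0 where the leaflet bulges toward the bilayer midplane, implemented by
flipping the sign for the upper leaflet. One numerical subtlety: a uniform
tilt h = ax + by carries no curvature but is not representable on a
periodic patch (the stencils would see a seam jump), so an exactly planar
field is detected and mapped to H ≡ 0; all other fields go through the
periodic stencils unchanged. Reconstruction accuracy is validated against
analytic surfaces (sinusoids, paraboloid caps) rather than against any
particular grid tool's filter settings, which are not reproducible.

## Synthetic membrane generator

The generator is a statistical stand-in for coarse-grained membrane
simulations, not an MD engine: overdamped 2D Langevin dynamics of point
TAGs in a periodic box,

    x(t+dt) = x(t) + β D F dt + √(2 D dt) ξ,

with kT = 1 (forces in kT/nm). Design choices:

* **In-plane dynamics.** The analyses in scope are in-plane; explicit-z
  head-group sheets (static lateral positions, per-frame Gaussian roughness)
  are emitted separately so topography analyses have input.
* **TAG–TAG attraction.** A compact pair force: soft capped repulsion below
  the contact distance a = 0.35 nm, attractive bump A(r−a)(r_c−r)² up to
  r_c = 0.6 nm, zero beyond, with A normalized so the well depth is ε (kT).
  Per-particle net force is capped so a step cannot jump across the well;
  a `dt` for which the free random step exceeds r_c/2 is rejected.
* **Ring trap.** 11 sites equally spaced on a ring (radius 3 nm). A free
  TAG within the capture radius (0.6 nm) of an unoccupied site binds
  (nearest-first when contended, one TAG per site — the sites model the 11
  copies of a single residue); bound TAGs diffuse with D_bound and are
  radially reflected at the capture radius, so the ground-truth invariant
  bound ⇒ within capture radius holds at every saved frame. Unbinding is a
  Poisson process with rate k_off (default 0.002 ns⁻¹, a 0.5 µs lifetime);
  the leaving TAG is placed just outside the capture radius (1.05×) so dwell
  times stay exactly exponential and instant recapture is avoided. The disk
  lumen is additionally a smooth radial basin (depth 8 kT out to the ring
  radius + 3 nm, constant force in the annulus, tapered at rim and core):
  this represents the hydrophobic inner opening being a favorable TAG
  environment and is what lets the trap *seed* clustering at a
  concentration that does not cluster on its own — point capture alone
  sequesters single TAGs without nucleating.
* **Mobilities.** D_free = 0.03 nm²/ns with D_bound = D_free/3, matching
  the observed threefold slow-down of site-bound TAG and the mobility scale
  of coarse-grained membrane lipids.
* **Concentrations.** mol% presets (1.25, 2.5, and the replenished 4.85 =
  2.35 preformed + 2.5 free) define TAG counts relative to
  `n_lipid_equivalents` (default 4,800 in a 40×40 nm box, ~0.33 nm²
  area per lipid per leaflet).
* **Calibration.** The preset well depth ε = 5 kT and run length 3 µs
  (dt = 0.1 ns, 30,000 steps, saved every 1 ns) were frozen with
  `scripts/calibrate_attraction.py` so that within the preset run the
  2.5 mol% system condenses while 1.25 mol% stays essentially monomeric —
  the qualitative contrast the presets exist to exhibit. A preset replicate
  runs in well under a minute on one CPU; a 10-replicate, 3-preset
  comparison takes several minutes.
* **Determinism.** One `numpy` Generator per run with a fixed call pattern:
  identical seeds give bit-identical trajectories, states and events.
  Replicate seeds derive deterministically from the config seed via
  `SeedSequence.spawn`.

What passing tests on generator data show — and what they do not: the
generator reproduces the *statistical structure* the estimators assume
(known per-state diffusivities, exponential dwells, concentration- and
trap-dependent clustering, replicate structure). It has no force-field
realism, no solvent, no lipid chains, no protein excluded volume and no
membrane elasticity, so quantitative agreement with any particular MD
system is out of scope; passing tests establish estimator correctness, not
membrane physics.

## Pipeline

`run_pipeline` executes the selected stages in dependency order on exactly
one input source (trajectory + topology files, or a generator preset),
validates stage requirements against the topology *before* any computation,
writes one CSV per stage with fixed float formatting, and emits a manifest
(inputs, parameters, seed, package version, SHA-256 per output). Reruns
with identical config and seed are byte-identical. When the curvature stage
is selected on a preset run, head-group emission is enabled automatically.

## Known limitations

* The per-TAG clustering rule and the component view disagree on chains by
  construction; both are reported.
* Dwell-time means from short runs are survivorship-biased even with
  censoring handled (events that would outlast the run are excluded);
  survival curves are the safer summary.
* The unwrap step cannot detect aliasing (true steps ≥ L/2 wrap to small
  apparent steps); sampling must be adequate, and the rare exactly-L/2 case
  is flagged.
* Height fields assume a single-valued surface per leaflet; overhangs or
  vesiculation are out of scope.
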