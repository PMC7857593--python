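"""Short-time diffusion coefficients: free vs site-bound TAG.

First fits the 2D displacement-magnitude distribution (Rayleigh) to a
theoretical sample, then runs a ring-trap simulation with a known threefold
mobility contrast and recovers D separately for bound and free intervals
using the generator's ground-truth binding spans.
"""

from memlens import estimate_D, sample_displacements
from memlens.experiments import bound_free_ratio

sample = sample_displacements(D=0.5, lag=1.0, n=50_000, seed=2)
est = estimate_D(sample)
print(f"theoretical sample, true D = 0.5 nm^2/ns:")
print(f"  D-hat = {est.D:.4f} nm^2/ns   95% CI "
      f"[{est.ci95[0]:.4f}, {est.ci95[1]:.4f}]   KS = {est.fit_ks:.4f}")

res = bound_free_ratio(seed=2)
print(f"\nring-trap run, true D_free/D_bound = 3:")
print(f"  D_bound = {res.bound.D:.4f} nm^2/ns  (n = {res.bound.n})")
print(f"  D_free  = {res.free.D:.4f} nm^2/ns  (n = {res.free.n})")
print(f"  ratio   = {res.ratio:.2f}")
print("\nA ratio near 3 mirrors the slow-down of TAG while complexed with "
      "a binding site relative to TAG diffusing freely in the bilayer.")
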