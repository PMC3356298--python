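"""Reactive-configuration statistics of a synthetic reactant ensemble.

Generates a reactive-complex ensemble (mean r(CM…Nζ) 3.0 Å, mean θ 30°),
measures the per-frame SN2 geometry, and Boltzmann-inverts the (r, θ)
histogram into free energies at 283.15 K.
"""

import numpy as np

from methylspec import build_histogram2d, compute_geometry, gen_frames, marginal_free_energy
from methylspec.synthetic import preset_spec

spec = preset_spec("reactive_wt_like", n_frames=20_000, seed=7)
records = compute_geometry(gen_frames(spec))

r = np.array([rec.r_CN for rec in records])
theta = np.array([rec.theta for rec in records])
print(f"ensemble mean r(CM…Nζ) = {r.mean():.3f} Å   (reactive complexes sit near 3.0 Å)")
print(f"ensemble mean θ        = {theta.mean():.2f}°  (small θ = lone pair aligned for SN2)")

hist = build_histogram2d(records)
profile = marginal_free_energy(hist, "theta", temperature=283.15)
f = profile["free_energy"].to_numpy()
# free-energy cost of reaching the near-linear 0–15° attack geometry
cost = np.nanmin(f[:3])
print(f"alignment cost to reach θ < 15° = {cost:.2f} kcal/mol")
print("a small cost means the reactant ensemble already visits TS-like geometry,")
print("which is the hallmark of an efficient methyl transfer")
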