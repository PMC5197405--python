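"""Cross-scene consistency with deconvolution correction.

A neuron with a known true consistency (83% of scenes agree with its
square-test preference) is simulated and analyzed: per-scene effects,
surrogate null ensemble, raw and corrected consistency.
"""

import numpy as np

from borderown import consistency as cons
from borderown import effects as eff
from borderown import simulate as sim

truth = 0.83
params = sim.preset_paper_calibrated(
    sigma_scene=sim.sigma_for_consistency(truth), n_scenes=44
)
rng = np.random.default_rng(5)
cell = sim.simulate_cell(params, rng, cell_id="cell1")
fits = eff.fit_cell(cell)

profile = cons.per_scene_effects(fits)
srt = cons.sorted_profile(profile, "full")
print(f"44 per-scene full-image effects, sorted: "
      f"max {srt[0]:+.2f} ... min {srt[-1]:+.2f}")

res = cons.cell_consistency(fits, n_surrogates=1000, seed=rng, n_cells_tested=65)
print(f"\nraw consistency       : {100 * res.raw:.0f}% of scenes positive")
print(f"corrected (deconvolved): {100 * res.corrected:.0f}%   (truth {100 * truth:.0f}%)")
print(f"binomial test vs 0.5   : p = {res.p_value:.2g} "
      f"(Bonferroni x65: {res.p_bonferroni:.2g})")
print("\nThe raw index is dragged toward 50% by trial noise; deconvolving the "
      "surrogate-null distribution recovers most of the true consistency.")
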