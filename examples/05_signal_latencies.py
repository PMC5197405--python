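"""Two-phase-regression latencies of responses and border-ownership signals.

Cumulative pooled spike counts over a 30-cell calibrated population:
response onset (0-80 ms, both regression legs free) and border-ownership /
context signals (30-150 ms, first leg forced to zero).
"""

from borderown import simulate as sim
from borderown import timecourse as tc

cells = sim.simulate_population(
    30, sim.default_population_sampler(sim.preset_paper_calibrated()), seed=1
)
pref = tc.estimate_pref_signs(cells)

print("kind        latency   bootstrap SD  (B=200)")
for kind in ("onset", "bo_full", "context"):
    est = tc.latency_bootstrap_sd(cells, kind, B=200, seed=0, pref_signs=pref)
    print(f"{kind:10s}  {est.latency_ms:6.1f} ms   +/- {est.sd_ms:.1f} ms")

print("\nThe full-image border-ownership signal lags response onset by only "
      "~15 ms, and its context component by ~30 ms — the ordering the "
      "calibrated generator is built to reproduce.")
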