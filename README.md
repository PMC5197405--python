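# borderown

Analysis toolkit for **border-ownership coding in visual cortex with natural
scenes**: how neurons in early visual areas (V2) signal which side of an
occluding contour belongs to the object, when the contour comes from a
complex photograph rather than a simple geometric figure.

When the edge of a figure crosses a neuron's classical receptive field
(CRF), many V2 neurons fire more when the figure lies on one particular
side, even though the stimulus inside the CRF is unchanged. This package
implements the full measurement chain for that phenomenon:

- **Stimulus construction** — from an annotated contour point in a scene,
  the 2×2×2 factorial of displays: object side (180° rotation about the CRF
  center), edge-contrast polarity (color inversion about the two local
  region means, `T(x) = (x̄₁ + x̄₂) − x`), and extent (full image vs a CRF
  patch faded into the background with `α = erfc[k(d − r)]`, `k = 1.8`);
  plus the counterbalanced square test (3° and 8° squares).
- **Effect estimation** — spike counts in 40–300 ms, Anscombe transform
  `√(x + 3/8)`, fixed-effects factorial models with all interactions
  (side × polarity × size for squares; side × polarity × extent × scene for
  scenes), Type-II sums of squares, and border-ownership effects as
  preferred-minus-nonpreferred marginal-mean differences. The *context*
  effect — the part driven by the image outside the CRF — is the
  side × extent interaction (full-image effect minus patch effect).
- **Population comparison** — per-cell effects normalized by the
  square-model residual SD, compared by through-origin orthogonal (total
  least-squares) regression with cell-bootstrap CIs.
- **Cross-scene consistency** — per-scene effects, surrogate-null ensembles
  (side terms zeroed, Gaussian noise at the residual variance), and a
  deconvolution-corrected consistency index: `N(m, s²)` deconvolved with the
  null `N(0, s₀²)` gives `N(m, s² − s₀²)`, whose mass above zero is the
  corrected fraction of scenes assigned consistently.
- **Latencies** — cumulative pooled spike counts at 1-ms resolution and
  two-phase regression (grid-searched breakpoint, latency at the
  intersection of the two legs; first leg forced to zero for differential
  signals), with presentation-bootstrap SDs.
- **Synthetic data** — annotated textured scenes and inhomogeneous-Poisson
  model neurons with condition-dependent onset latencies, a transient local
  border-ownership component, a ramping context component, and
  Normal(1, σ²) scene-to-scene effect dispersion, so every stage is
  testable end-to-end without recorded data.

## Worked example

```python
import numpy as np
from borderown import simulate as sim, effects as eff

params = sim.preset_paper_calibrated(n_scenes=20)
cell = sim.simulate_cell(params, np.random.default_rng(1), cell_id="demo")
e = eff.cell_effects(cell)
print(f"square {e.square_norm:+.2f}  full {e.full_norm:+.2f} "
      f"context {e.context_norm:+.2f}  (p_context = {e.p_context:.2g})")
```

prints

```
square +2.28  full +1.25 context +1.21  (p_context = 2.1e-11)
```

the cell's border-ownership effects in multiples of its trial-to-trial
response SD: a strong square-test preference, a full-scene effect of the
same sign about half as large, and a context effect accounting for nearly
all of it (the patch effect is ≈ 0). The `examples/` directory walks
through each capability — stimulus construction, effect estimation,
population slopes, cross-scene consistency, and latency estimation — as
short narrative scripts that print and explain their numbers.

A thin CLI covers batch use: `borderown simulate | stimuli | analyze |
report` (see `borderown --help`).

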