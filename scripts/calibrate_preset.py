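"""Calibrate the model-neuron preset's component timings.

The preset must be such that the downstream latency pipeline — cumulative
pooled spike counts plus two-phase regression — recovers the target
latencies (onset 44 ms; full-scene border-ownership 60 ms; context 73 ms).
The response-onset time and the context ramp peak are direct generator
parameters; the context onset and the local-component amplitude interact
with the regression estimator, so they are chosen by fitting the estimator
to the *noise-free expected* cumulative curves over a parameter grid.

Run from the repository root:

    python scripts/calibrate_preset.py

and copy the printed values into ``preset_paper_calibrated``.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from borderown import simulate as sim
from borderown import timecourse as tc

TARGETS = {"onset": 44.0, "bo_full": 60.0, "context": 73.0}


def expected_histogram(params: sim.NeuronParams, kind: str) -> np.ndarray:
    """Noise-free expected pooled per-ms counts for a curve kind (per
    presentation-pair, unit scene multiplier)."""
    t = np.arange(300) + 0.5
    if kind == "onset":
        onset = params.onset_ms["scene_full"]
        gains = [params.polarity_gain, 1.0]
        rates = [
            np.where(t < onset, params.baseline_hz, params.evoked_hz * g) for g in gains
        ]
        return sum(rates) / 1000.0 * 2  # both sides, both polarities
    if kind == "bo_full":
        return sim.bo_difference(params, "scene_full", t) / 1000.0
    if kind == "bo_patch":
        return sim.bo_difference(params, "scene_patch", t) / 1000.0
    if kind == "context":
        d = sim.bo_difference(params, "scene_full", t) - sim.bo_difference(
            params, "scene_patch", t
        )
        return d / 1000.0
    raise ValueError(kind)


def expected_latency(params: sim.NeuronParams, kind: str) -> float:
    hist = expected_histogram(params, kind)
    lo, hi = tc.WINDOWS[kind]
    t = np.arange(lo, hi + 1, dtype=float)
    y = np.concatenate([[0.0], np.cumsum(hist[lo:hi])])
    fit = tc.two_phase_fit((t, y), force_zero_first_leg=tc.FORCE_ZERO[kind])
    return fit.latency_ms


def main() -> None:
    base = sim.preset_paper_calibrated()
    print("current preset latencies on expected curves:")
    for kind, target in TARGETS.items():
        print(f"  {kind:8s} target {target:5.1f}  got {expected_latency(base, kind):6.2f}")

    best = None
    tol = {"bo_full": 4.0, "context": 8.0}  # acceptance half-widths, for weighting
    grid = itertools.product(
        np.arange(44.0, 80.1, 0.5),      # ctx_onset_ms (not before response onset)
        np.arange(1.0, 8.1, 0.5),        # local_amp_hz
        (85.0, 90.0, 95.0),              # local_off_ms
        (0.6, 0.8, 1.0),                 # ctx_decay_frac
    )
    for ctx_on, loc_amp, loc_off, decay in grid:
        p = dataclasses.replace(
            base,
            ctx_onset_ms=ctx_on,
            local_amp_hz=loc_amp,
            local_off_ms=loc_off,
            ctx_decay_frac=decay,
        )
        err = sum(
            ((expected_latency(p, k) - TARGETS[k]) / tol[k]) ** 2
            for k in ("bo_full", "context")
        )
        if best is None or err < best[0]:
            best = (err, ctx_on, loc_amp, loc_off, decay)
    err, ctx_on, loc_amp, loc_off, decay = best
    print(
        f"\nbest: ctx_onset_ms={ctx_on} local_amp_hz={loc_amp} "
        f"local_off_ms={loc_off} ctx_decay_frac={decay} (weighted sq err {err:.3f})"
    )
    p = dataclasses.replace(
        base,
        ctx_onset_ms=ctx_on,
        local_amp_hz=loc_amp,
        local_off_ms=loc_off,
        ctx_decay_frac=decay,
    )
    for kind, target in TARGETS.items():
        print(f"  {kind:8s} target {target:5.1f}  got {expected_latency(p, kind):6.2f}")


if __name__ == "__main__":
    main()
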