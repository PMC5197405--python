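"""Synthetic scenes and model V2 neurons for exercising the analysis chain.

Model neurons fire as inhomogeneous Poisson processes whose rate is built
from interpretable pieces:

- a baseline rate before the condition class's onset latency and an evoked
  rate after it (scene-full, scene-patch and square displays each have their
  own onset latency);
- a multiplicative gain for the preferred edge-contrast polarity;
- a *local* border-ownership component — a transient rate difference between
  object-on-preferred-side and object-on-opposite-side displays, present in
  both full and patch conditions (it is carried by the CRF content);
- a *context* border-ownership component — a ramp that rises linearly to a
  peak and then decays partially, present in full-image and square conditions
  only (it is carried by the image outside the CRF).

Scene-to-scene variation multiplies both border-ownership components by an
i.i.d. Normal(1, sigma_scene^2) factor per scene, so the true cross-scene
consistency (fraction of scenes whose effect agrees with the square-test
preference) is the Normal mass above zero, Phi(1/sigma_scene).

Spiking is simulated in 1-ms bins as Bernoulli(rate * 1 ms); at the rates
used here (well below 1000 Hz) the discretization bias of the mean count is
below 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from borderown.stimuli import ScenePoint

TRIAL_MS = 300
CONDITION_CLASSES = ("scene_full", "scene_patch", "square")

_BIN_CENTERS = np.arange(TRIAL_MS) + 0.5


@dataclass
class NeuronParams:
    """Generative parameters of one model neuron.

    Rates in Hz, times in ms from stimulus onset.  ``preferred_side = +1``
    means the neuron prefers the object on the un-rotated ("original") side;
    ``scene_ctx_gain`` scales the context component in natural scenes
    relative to its square-test amplitude.
    """

    baseline_hz: float = 5.0
    evoked_hz: float = 40.0
    onset_ms: dict = field(
        default_factory=lambda: {"scene_full": 44.0, "scene_patch": 47.0, "square": 46.0}
    )
    polarity_gain: float = 1.3
    local_amp_hz: float = 3.5
    local_on_ms: float = 40.0
    local_off_ms: float = 85.0
    ctx_amp_hz: float = 40.0
    scene_ctx_gain: float = 0.5
    ctx_onset_ms: float = 44.0
    ctx_peak_ms: float = 140.0
    ctx_decay_frac: float = 0.6
    sigma_scene: float = 0.6
    preferred_side: int = 1
    omi_value: float = 0.5
    n_reps: int = 4
    n_scenes: int = 43

    def __post_init__(self):
        if self.baseline_hz < 0 or self.evoked_hz < 0:
            raise ValueError("rates must be non-negative")
        if not self.local_on_ms < self.local_off_ms:
            raise ValueError("local component must switch on before it switches off")
        if not self.ctx_onset_ms < self.ctx_peak_ms:
            raise ValueError("context onset must precede its ramp peak")
        if self.sigma_scene < 0:
            raise ValueError("sigma_scene must be non-negative")
        if self.preferred_side not in (-1, 1):
            raise ValueError("preferred_side must be +1 or -1")
        missing = set(CONDITION_CLASSES) - set(self.onset_ms)
        if missing:
            raise ValueError(f"onset_ms missing classes: {sorted(missing)}")


@dataclass(frozen=True)
class TrialCondition:
    """One cell of the factorial, resolved against the neuron's preferences."""

    condition_class: str  # scene_full | scene_patch | square
    object_on_preferred_side: bool
    preferred_polarity: bool

    def __post_init__(self):
        if self.condition_class not in CONDITION_CLASSES:
            raise ValueError(f"unknown condition class {self.condition_class!r}")


def _local_shape(params: NeuronParams, t: np.ndarray) -> np.ndarray:
    return np.where((t >= params.local_on_ms) & (t < params.local_off_ms), 1.0, 0.0)


def _context_shape(params: NeuronParams, t: np.ndarray) -> np.ndarray:
    """Unit-peak ramp: 0 until onset, linear to 1 at the peak, then linear
    decay to ``ctx_decay_frac`` at 300 ms."""
    t0, tp = params.ctx_onset_ms, params.ctx_peak_ms
    rise = np.clip((t - t0) / (tp - t0), 0.0, None)
    decay = 1.0 - (1.0 - params.ctx_decay_frac) * np.clip(
        (t - tp) / (TRIAL_MS - tp), 0.0, 1.0
    )
    return np.where(t < tp, np.clip(rise, 0.0, 1.0), decay)


def bo_difference(params: NeuronParams, condition_class: str, t) -> np.ndarray:
    """Expected preferred-minus-nonpreferred rate difference (Hz) at unit
    scene multiplier: local component (full & patch) plus context component
    (full & square)."""
    t = np.asarray(t, dtype=float)
    delta = np.zeros_like(t)
    if condition_class in ("scene_full", "scene_patch"):
        delta = delta + params.local_amp_hz * _local_shape(params, t)
    if condition_class in ("scene_full", "square"):
        amp = params.ctx_amp_hz * (
            params.scene_ctx_gain if condition_class == "scene_full" else 1.0
        )
        delta = delta + amp * _context_shape(params, t)
    return delta


def rate_function(
    params: NeuronParams,
    condition: TrialCondition,
    scene_multiplier: float,
    t,
) -> np.ndarray:
    """Instantaneous firing rate (Hz) at time ``t`` ms, truncated at zero."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any() or (t >= TRIAL_MS).any():
        raise ValueError(f"t must lie in [0, {TRIAL_MS}) ms")
    onset = params.onset_ms[condition.condition_class]
    gain = params.polarity_gain if condition.preferred_polarity else 1.0
    rate = np.where(t < onset, params.baseline_hz, params.evoked_hz * gain)
    sign = 1.0 if condition.object_on_preferred_side else -1.0
    delta = bo_difference(params, condition.condition_class, t)
    rate = rate + 0.5 * sign * scene_multiplier * delta
    return np.clip(rate, 0.0, None)


def draw_scene_effects(
    params: NeuronParams, n_scenes: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-scene effect multipliers, i.i.d. Normal(1, sigma_scene^2).

    The implied true consistency is ``Phi(1 / sigma_scene)``.
    """
    if params.sigma_scene == 0:
        return np.ones(n_scenes)
    return rng.normal(1.0, params.sigma_scene, size=n_scenes)


def true_consistency(params: NeuronParams) -> float:
    """Normal mass above zero of the scene-multiplier law."""
    from scipy.stats import norm

    if params.sigma_scene == 0:
        return 1.0
    return float(norm.cdf(1.0 / params.sigma_scene))


def sigma_for_consistency(consistency: float) -> float:
    """Scene dispersion whose implied true consistency equals ``consistency``."""
    from scipy.stats import norm

    if not 0.5 < consistency < 1.0:
        raise ValueError("consistency must lie in (0.5, 1)")
    return float(1.0 / norm.ppf(consistency))


def simulate_trial(
    params: NeuronParams,
    condition: TrialCondition,
    multiplier: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One spike train (sorted times in ms) via 1-ms Bernoulli bins."""
    rate = rate_function(params, condition, multiplier, _BIN_CENTERS)
    hits = rng.random(TRIAL_MS) < rate / 1000.0
    return np.flatnonzero(hits) + 0.5


# ---------------------------------------------------------------------------
# cell-level simulation


@dataclass
class CellDataset:
    """All trials of one cell: a trial table plus a (n_trials, 300) boolean
    spike raster at 1-ms resolution.

    Trial-table columns: ``test`` (scene|square), ``scene_id``, ``size_deg``
    (square tests only), ``side`` (original|rotated), ``polarity``
    (original|inverted), ``extent`` (full|patch), ``rep``.
    """

    cell_id: str
    trials: pd.DataFrame
    spikes: np.ndarray
    params: NeuronParams | None = None
    true_multipliers: dict | None = None

    def __post_init__(self):
        if len(self.trials) != self.spikes.shape[0]:
            raise ValueError("trial table and spike raster disagree in length")
        if self.spikes.shape[1] != TRIAL_MS:
            raise ValueError(f"spike raster must have {TRIAL_MS} 1-ms bins")

    def counts(self, t_lo: float = 40.0, t_hi: float = 300.0) -> np.ndarray:
        """Spike counts in the closed-open window [t_lo, t_hi) ms."""
        lo = int(np.ceil(t_lo - 0.5))
        hi = int(np.ceil(t_hi - 0.5))
        return self.spikes[:, lo:hi].sum(axis=1)

    def spike_times(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.spikes[i]) + 0.5

    def iter_trains(self):
        for i in range(len(self.trials)):
            yield self.spike_times(i)

    @property
    def scene_ids(self) -> list[str]:
        mask = self.trials["test"] == "scene"
        return sorted(self.trials.loc[mask, "scene_id"].unique())


def _scene_trial_table(scene_ids, n_reps: int) -> pd.DataFrame:
    rows = []
    for sid in scene_ids:
        for side in ("original", "rotated"):
            for pol in ("original", "inverted"):
                for ext in ("full", "patch"):
                    for rep in range(n_reps):
                        rows.append(("scene", sid, np.nan, side, pol, ext, rep))
    return pd.DataFrame(
        rows, columns=["test", "scene_id", "size_deg", "side", "polarity", "extent", "rep"]
    )


def _square_trial_table(n_reps: int) -> pd.DataFrame:
    rows = []
    for size in (3.0, 8.0):
        for side in ("original", "rotated"):
            for pol in ("original", "inverted"):
                for rep in range(n_reps):
                    rows.append(("square", f"square{size:g}", size, side, pol, "full", rep))
    return pd.DataFrame(
        rows, columns=["test", "scene_id", "size_deg", "side", "polarity", "extent", "rep"]
    )


def _condition_class(test: np.ndarray, extent: np.ndarray) -> np.ndarray:
    cls = np.where(test == "square", "square", "scene_full")
    return np.where((test == "scene") & (extent == "patch"), "scene_patch", cls)


def simulate_cell(
    params: NeuronParams,
    rng: np.random.Generator,
    scene_ids=None,
    cell_id: str = "cell",
    scene_multipliers: np.ndarray | None = None,
) -> CellDataset:
    """Simulate the full factorial for one cell: all 8 scene conditions per
    scene plus the 8-condition square test, ``n_reps`` replicates each."""
    if scene_ids is None:
        scene_ids = [f"s{i:03d}" for i in range(params.n_scenes)]
    scene_ids = list(scene_ids)
    if scene_multipliers is None:
        scene_multipliers = draw_scene_effects(params, len(scene_ids), rng)
    mult = dict(zip(scene_ids, scene_multipliers))

    trials = pd.concat(
        [_scene_trial_table(scene_ids, params.n_reps), _square_trial_table(params.n_reps)],
        ignore_index=True,
    )
    test = trials["test"].to_numpy()
    extent = trials["extent"].to_numpy()
    cls = _condition_class(test, extent)
    onset = np.array([params.onset_ms[c] for c in cls])
    gain = np.where(
        trials["polarity"].to_numpy() == "original", params.polarity_gain, 1.0
    )
    side_is_original = trials["side"].to_numpy() == "original"
    sign = np.where(side_is_original == (params.preferred_side == 1), 1.0, -1.0)
    m = np.array([mult.get(s, 1.0) for s in trials["scene_id"]])
    m = np.where(test == "square", 1.0, m)

    t = _BIN_CENTERS[None, :]
    base = np.where(
        t < onset[:, None],
        params.baseline_hz,
        params.evoked_hz * gain[:, None],
    )
    local = params.local_amp_hz * _local_shape(params, _BIN_CENTERS)
    ctx = _context_shape(params, _BIN_CENTERS)
    has_local = np.isin(cls, ("scene_full", "scene_patch")).astype(float)
    ctx_amp = np.where(
        cls == "square",
        params.ctx_amp_hz,
        np.where(cls == "scene_full", params.ctx_amp_hz * params.scene_ctx_gain, 0.0),
    )
    delta = has_local[:, None] * local[None, :] + ctx_amp[:, None] * ctx[None, :]
    rate = np.clip(base + 0.5 * (sign * m)[:, None] * delta, 0.0, None)
    spikes = rng.random(rate.shape) < rate / 1000.0
    return CellDataset(
        cell_id=cell_id,
        trials=trials,
        spikes=spikes,
        params=params,
        true_multipliers=mult,
    )


def simulate_population(
    n_cells: int,
    param_sampler=None,
    seed: int | np.random.Generator = 0,
    scene_ids=None,
) -> list[CellDataset]:
    """Simulate ``n_cells`` cells with per-cell parameters drawn by
    ``param_sampler(rng)`` (default: :func:`default_population_sampler`).

    One master seed; per-cell streams are spawned deterministically.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if param_sampler is None:
        param_sampler = default_population_sampler()
    cells = []
    for i, child in enumerate(rng.spawn(n_cells)):
        params = param_sampler(child)
        cells.append(
            simulate_cell(params, child, scene_ids=scene_ids, cell_id=f"cell{i:03d}")
        )
    return cells


def default_population_sampler(base: NeuronParams | None = None, amp_sd: float = 0.4):
    """Cell-to-cell heterogeneity: lognormal (unit-mean) scaling of the
    border-ownership amplitudes and random preferred side/polarity."""
    base = base or preset_paper_calibrated()

    def sampler(rng: np.random.Generator) -> NeuronParams:
        h = float(np.exp(rng.normal(-0.5 * amp_sd**2, amp_sd)))
        return replace(
            base,
            ctx_amp_hz=base.ctx_amp_hz * h,
            local_amp_hz=base.local_amp_hz * h,
            preferred_side=int(rng.choice([-1, 1])),
        )

    return sampler


def relative_strength_sampler(
    relative: float = 0.44,
    base: NeuronParams | None = None,
    amp_sd: float = 0.4,
):
    """Sampler whose injected ground truth is a population relative strength:
    each cell's expected full-scene border-ownership effect is ``relative``
    times its square effect.

    The ratio is injected through the context pathway: the scene context
    amplitude is ``relative`` times the square amplitude and the local
    component is switched off, so the expected count-difference ratio equals
    ``relative`` exactly for every cell.
    """
    base = base or preset_paper_calibrated()

    def sampler(rng: np.random.Generator) -> NeuronParams:
        h = float(np.exp(rng.normal(-0.5 * amp_sd**2, amp_sd)))
        return replace(
            base,
            ctx_amp_hz=base.ctx_amp_hz * h,
            local_amp_hz=0.0,
            scene_ctx_gain=relative,
            preferred_side=int(rng.choice([-1, 1])),
        )

    return sampler


def preset_paper_calibrated(**overrides) -> NeuronParams:
    """Model-neuron parameters calibrated so that the downstream latency
    pipeline recovers onset 44 ms, full-scene border-ownership 60 ms and
    context 73 ms on the pooled synthetic population.

    Component timings were tuned with ``scripts/calibrate_preset.py`` (two-
    phase regression on the noise-free expected cumulative curves); all other
    values are the generator defaults.
    """
    params = NeuronParams(
        baseline_hz=5.0,
        evoked_hz=40.0,
        onset_ms={"scene_full": 44.0, "scene_patch": 47.0, "square": 46.0},
        polarity_gain=1.3,
        local_amp_hz=3.5,
        local_on_ms=40.0,
        local_off_ms=85.0,
        ctx_amp_hz=40.0,
        scene_ctx_gain=0.5,
        ctx_onset_ms=44.0,
        ctx_peak_ms=140.0,
        ctx_decay_frac=0.6,
        sigma_scene=0.6,
        n_reps=4,
        n_scenes=43,
    )
    return replace(params, **overrides)


# ---------------------------------------------------------------------------
# scene fixtures


@dataclass
class SceneFixture:
    """A synthetic annotated scene: textured object over a textured
    background with an exact contour-point annotation."""

    scene_id: str
    image: np.ndarray
    point: ScenePoint
    object_mean: np.ndarray
    background_mean: np.ndarray


def generate_scene_fixture(
    seed: int = 0,
    size: int = 65,
    object_shape: str = "disc",
    radius_px: float = 10.0,
    orientation_deg: float | None = None,
    contrast: float = 0.25,
    texture_amp: float = 0.06,
    gradient_amp: float = 0.10,
    scene_id: str | None = None,
) -> SceneFixture:
    """Render a compact textured object over a distinct textured background.

    The occluding contour passes through the image center with the requested
    tangent orientation; region masks are derived exactly from the rendered
    geometry (pixels within half a pixel of the contour are assigned to
    neither mask).  ``object_shape`` is ``"disc"`` (curved contour) or
    ``"half"`` (straight contour).
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    if orientation_deg is None:
        orientation_deg = float(rng.uniform(0.0, 180.0))
    theta = np.deg2rad(orientation_deg)
    center = (size // 2, size // 2)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    # unit normal toward the object, 90° CCW from the tangent direction
    n_vec = np.array([-np.cos(theta), -np.sin(theta)])
    d_n = (rr - center[0]) * n_vec[0] + (cc - center[1]) * n_vec[1]

    if object_shape == "half":
        signed = d_n  # >0 on the object side
    elif object_shape == "disc":
        big_r = 2.5 * radius_px
        oc = (center[0] + big_r * n_vec[0], center[1] + big_r * n_vec[1])
        signed = big_r - np.hypot(rr - oc[0], cc - oc[1])
    else:
        raise ValueError("object_shape must be 'disc' or 'half'")

    obj = signed > 0

    base_bg = np.clip(rng.uniform(0.3, 0.6, size=3), 0.0, 1.0)
    base_obj = np.clip(base_bg + contrast * rng.choice([-1.0, 1.0], size=3), 0.05, 0.95)
    image = np.empty((size, size, 3))
    image[:] = base_bg
    image[obj] = base_obj
    # smooth texture on both regions, plus a luminance gradient on the object
    noise = gaussian_filter(rng.normal(0.0, 1.0, size=(size, size, 3)), (1.5, 1.5, 0))
    image = image + texture_amp * noise
    grad = gradient_amp * np.clip(signed / max(signed.max(), 1.0), 0.0, 1.0)
    image = image + grad[..., None]
    image = np.clip(image, 0.0, 1.0)

    disc = np.hypot(rr - center[0], cc - center[1]) <= radius_px
    mask_obj = disc & (signed > 0.5)
    mask_bgd = disc & (signed < -0.5)
    point = ScenePoint(
        center=center,
        orientation_deg=orientation_deg % 180.0,
        object_side=(float(n_vec[0]), float(n_vec[1])),
        radius_px=radius_px,
        mask1=mask_obj,
        mask2=mask_bgd,
    )
    return SceneFixture(
        scene_id=scene_id or f"synth{seed:04d}",
        image=image,
        point=point,
        object_mean=image[mask_obj].mean(axis=0),
        background_mean=image[mask_bgd].mean(axis=0),
    )
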