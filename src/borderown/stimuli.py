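"""Factorial stimulus construction for border-ownership tests.

A *scene* is an image together with an annotated point on an occluding
contour: the point is centered on the neuron's classical receptive field
(CRF), and two hand-segmented region masks give the image regions on either
side of the contour within the CRF radius ``r``.

From each scene the engine builds the 2x2x2 factorial of display variants:

side
    object on the original side, or on the opposite side after rotating the
    image 180° about the CRF center (the local edge rotates with it);
polarity
    original colors, or colors inverted about the two regions' mean colors,
    which flips the local edge-contrast polarity while preserving the means;
extent
    the full image, or a local patch covering the CRF that fades into a
    uniform background with a complementary-error-function profile.

All images are linear-light RGB arrays of shape ``(H, W, 3)`` with values in
``[0, 1]``.  Gamma encoding/decoding is applied only at import/export.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

GAMMA = 2.2
PATCH_FADE_K = 1.8  # erfc steepness, per-pixel

SIDES = ("original", "rotated")
POLARITIES = ("original", "inverted")
EXTENTS = ("full", "patch")


# ---------------------------------------------------------------------------
# domain types


def _as_color(c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if c.shape != (3,) or not np.all(np.isfinite(c)):
        raise ValueError("color must be 3 finite channel values")
    return c


@dataclass(frozen=True)
class ScenePoint:
    """An annotated contour point: CRF center, orientation and region masks.

    ``center`` is ``(row, col)`` in 0-based pixel coordinates.  ``orientation_deg``
    is the contour tangent in degrees counterclockwise from horizontal, in
    ``[0, 180)``.  ``object_side`` is the unit normal ``(drow, dcol)`` pointing
    from the contour toward the occluding object.  ``mask1``/``mask2`` are
    boolean pixel masks of the two regions on either side of the contour,
    restricted to the disc of ``radius_px`` around the center.
    """

    center: tuple[int, int]
    orientation_deg: float
    object_side: tuple[float, float]
    radius_px: float
    mask1: np.ndarray
    mask2: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.orientation_deg < 180.0):
            raise ValueError("orientation must lie in [0, 180) degrees")
        if self.radius_px <= 0:
            raise ValueError("CRF radius must be positive")
        m1 = np.asarray(self.mask1, dtype=bool)
        m2 = np.asarray(self.mask2, dtype=bool)
        if m1.shape != m2.shape:
            raise ValueError("region masks must share a shape")
        if not m1.any():
            raise ValueError("side-1 region mask is empty")
        if not m2.any():
            raise ValueError("side-2 region mask is empty")
        if (m1 & m2).any():
            raise ValueError("region masks overlap")
        d = _distance_grid(m1.shape, self.center)
        if (d[m1 | m2] > self.radius_px + 0.5).any():
            raise ValueError("region masks extend beyond the CRF disc")
        object.__setattr__(self, "mask1", m1)
        object.__setattr__(self, "mask2", m2)


@dataclass(frozen=True)
class ConditionKey:
    """Label of one cell of the 2x2x2 natural-scene factorial."""

    side: str
    polarity: str
    extent: str
    scene_id: str

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if self.extent not in EXTENTS:
            raise ValueError(f"extent must be one of {EXTENTS}")


@dataclass(frozen=True)
class StimulusVariant:
    """A display image tagged with its factorial condition.

    ``n_clipped`` counts pixels that left the [0, 1] gamut during color
    inversion and were clipped.
    """

    key: ConditionKey
    image: np.ndarray
    background: np.ndarray
    n_clipped: int = 0


@dataclass(frozen=True)
class SquareStimulusSpec:
    """Geometry and colors of the standard square border-ownership test.

    The square's edge passes through the CRF center at ``orientation_deg``;
    ``gray`` and ``preferred`` are the two counterbalanced colors.  ``pitch``
    is degrees of visual angle per pixel; ``shape`` the display size in
    pixels; ``center`` the CRF center (defaults to the display center).
    """

    orientation_deg: float
    gray: np.ndarray = field(default_factory=lambda: np.full(3, 0.5))
    preferred: np.ndarray = field(default_factory=lambda: np.array([0.9, 0.2, 0.2]))
    sizes_deg: tuple[float, float] = (3.0, 8.0)
    pitch: float = 0.1
    shape: tuple[int, int] = (121, 121)
    center: tuple[int, int] | None = None

    def __post_init__(self):
        object.__setattr__(self, "gray", _as_color(self.gray))
        object.__setattr__(self, "preferred", _as_color(self.preferred))
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def center_px(self) -> tuple[int, int]:
        if self.center is not None:
            return self.center
        return (self.shape[0] // 2, self.shape[1] // 2)


# ---------------------------------------------------------------------------
# geometry helpers


def _distance_grid(shape: tuple[int, int], center: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(rr - center[0], cc - center[1])


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must have shape (H, W, 3)")
    return image


# ---------------------------------------------------------------------------
# operations


def region_means(scene: np.ndarray, point: ScenePoint) -> tuple[np.ndarray, np.ndarray]:
    """Channelwise mean colors of the two contour-side regions.

    Means are always taken on the *original* (unrotated) scene; they define
    both the color-inversion map and the background color.
    """
    scene = _check_image(scene)
    means = []
    for name, mask in (("side-1", point.mask1), ("side-2", point.mask2)):
        if not mask.any():
            raise ValueError(f"{name} region mask is empty")
        means.append(scene[mask].mean(axis=0))
    return means[0], means[1]


def invert_colors(
    scene: np.ndarray, point: ScenePoint
) -> tuple[np.ndarray, int]:
    """Invert colors about the two region means: ``x -> (mean1 + mean2) - x``.

    Flips the local edge-contrast polarity (the two region means swap) while
    keeping their midpoint fixed.  Out-of-gamut results are clipped to
    ``[0, 1]``; the number of clipped pixels is returned alongside the image.
    """
    scene = _check_image(scene)
    m1, m2 = region_means(scene, point)
    out = (m1 + m2) - scene
    clipped = int(np.count_nonzero((out < 0.0).any(axis=2) | (out > 1.0).any(axis=2)))
    return np.clip(out, 0.0, 1.0), clipped


def rotate_180(
    scene: np.ndarray, point: ScenePoint, background: np.ndarray | None = None
) -> np.ndarray:
    """Rotate the image 180° about the CRF center.

    The pixel at the center maps to itself; display area not covered by the
    rotated image is filled with ``background`` (the scene's background color
    in the factorial set).  Contour orientation is preserved; the object
    moves to the opposite side.
    """
    scene = _check_image(scene)
    h, w, _ = scene.shape
    r0, c0 = point.center
    if background is None:
        background = 0.5 * np.add(*region_means(scene, point))
    out = np.empty_like(scene)
    out[:] = _as_color(background)
    rows = 2 * r0 - np.arange(h)
    cols = 2 * c0 - np.arange(w)
    rok = (rows >= 0) & (rows < h)
    cok = (cols >= 0) & (cols < w)
    out[np.ix_(rok, cok)] = scene[np.ix_(rows[rok], cols[cok])]
    return out


def patch_alpha(d, r: float, k: float = PATCH_FADE_K):
    """Patch fading weight: 1 inside the CRF radius, ``erfc[k(d - r)]`` outside.

    Continuous at ``d = r`` (``erfc(0) = 1``) and non-increasing in ``d``.
    """
    from scipy.special import erfc

    if r <= 0:
        raise ValueError("CRF radius must be positive")
    if k <= 0:
        raise ValueError("fading steepness k must be positive")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    return np.where(d < r, 1.0, erfc(k * (d - r)))


def background_color(scene: np.ndarray, point: ScenePoint) -> np.ndarray:
    """Midpoint of the two region-mean colors (also the interstimulus color)."""
    m1, m2 = region_means(scene, point)
    return 0.5 * (m1 + m2)


def make_patch(
    scene: np.ndarray,
    point: ScenePoint,
    k: float = PATCH_FADE_K,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Blend the image into the background outside the CRF disc.

    Per pixel: ``alpha * image + (1 - alpha) * background`` with the erfc
    ``alpha`` profile, so the display is identical to the full image inside
    radius ``r``.
    """
    scene = _check_image(scene)
    if background is None:
        background = background_color(scene, point)
    background = _as_color(background)
    d = _distance_grid(scene.shape[:2], point.center)
    a = patch_alpha(d, point.radius_px, k)[..., None]
    return a * scene + (1.0 - a) * background


def build_variant_set(
    scene: np.ndarray, point: ScenePoint, k: float = PATCH_FADE_K, scene_id: str = "scene"
) -> list[StimulusVariant]:
    """Construct the eight factorial variants of one scene.

    The color inversion uses region means from the original scene; rotation
    fills uncovered area with the shared background color; patch fading is
    applied after rotation so the CRF disc content matches the corresponding
    full variant exactly.
    """
    scene = _check_image(scene)
    bg = background_color(scene, point)
    inverted, n_clip = invert_colors(scene, point)
    base = {"original": (scene, 0), "inverted": (inverted, n_clip)}
    variants = []
    for side, polarity, extent in itertools.product(SIDES, POLARITIES, EXTENTS):
        img, nc = base[polarity]
        if side == "rotated":
            img = rotate_180(img, point, background=bg)
        if extent == "patch":
            img = make_patch(img, point, k=k, background=bg)
        variants.append(
            StimulusVariant(
                key=ConditionKey(side, polarity, extent, scene_id),
                image=img,
                background=bg,
                n_clipped=nc,
            )
        )
    return variants


def build_square_test_set(spec: SquareStimulusSpec) -> list[StimulusVariant]:
    """Construct the eight standard square-test displays.

    2 sizes x 2 sides x 2 contrast polarities.  One square edge passes
    through the CRF center at the preferred orientation; square/background
    colors are counterbalanced so that paired (side, polarity) displays are
    pixel-identical within the band swept by the two square placements.
    """
    h, w = spec.shape
    r0, c0 = spec.center_px
    theta = np.deg2rad(spec.orientation_deg)
    # tangent along the edge, normal to the left of the tangent
    t_vec = np.array([-np.sin(theta), np.cos(theta)])  # (drow, dcol), row axis down
    n_vec = np.array([-np.cos(theta), -np.sin(theta)])
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d_n = (rr - r0) * n_vec[0] + (cc - c0) * n_vec[1]
    d_t = (rr - r0) * t_vec[0] + (cc - c0) * t_vec[1]

    variants = []
    for size_deg, side, polarity in itertools.product(
        spec.sizes_deg, SIDES, POLARITIES
    ):
        w_px = size_deg / spec.pitch
        # the two placements partition the edge line (>=0 vs <0) so paired
        # displays are pixel-identical within the swept 2w x w band
        if side == "original":
            strip = (d_n >= 0) & (d_n <= w_px)
        else:
            strip = (d_n < 0) & (d_n >= -w_px)
        inside = strip & (np.abs(d_t) <= w_px / 2.0)
        fig, ground = (
            (spec.preferred, spec.gray)
            if polarity == "original"
            else (spec.gray, spec.preferred)
        )
        img = np.empty((h, w, 3))
        img[:] = ground
        img[inside] = fig
        bg = 0.5 * (spec.gray + spec.preferred)
        variants.append(
            StimulusVariant(
                key=ConditionKey(side, polarity, "full", f"square{size_deg:g}"),
                image=img,
                background=bg,
            )
        )
    return variants


def gamma_encode(image: np.ndarray, gamma: float = GAMMA) -> np.ndarray:
    """Channelwise power law ``v -> v**gamma`` used for the linearized display."""
    return np.power(np.asarray(image, dtype=float), gamma)


def gamma_decode(image: np.ndarray, gamma: float = GAMMA) -> np.ndarray:
    """Inverse of :func:`gamma_encode`: ``v -> v**(1/gamma)``."""
    return np.power(np.asarray(image, dtype=float), 1.0 / gamma)


# ---------------------------------------------------------------------------
# annotation I/O


def load_scene(json_path) -> tuple[np.ndarray, ScenePoint, str]:
    """Load a scene annotation JSON plus its image and region masks.

    Expected keys: ``scene_id, image_path, center, orientation_deg,
    object_side, radius_px, mask1_path, mask2_path``; paths are resolved
    relative to the JSON file.  Images are gamma-decoded to linear RGB.
    """
    import json
    from pathlib import Path

    from PIL import Image

    json_path = Path(json_path)
    meta = json.loads(json_path.read_text())
    root = json_path.parent

    def _img(path):
        return np.asarray(Image.open(root / path).convert("RGB"), dtype=float) / 255.0

    def _mask(path):
        return np.asarray(Image.open(root / path).convert("L")) > 127

    scene = gamma_encode(_img(meta["image_path"]))
    point = ScenePoint(
        center=tuple(meta["center"]),
        orientation_deg=float(meta["orientation_deg"]),
        object_side=tuple(meta["object_side"]),
        radius_px=float(meta["radius_px"]),
        mask1=_mask(meta["mask1_path"]),
        mask2=_mask(meta["mask2_path"]),
    )
    return scene, point, str(meta["scene_id"])


def save_variants(variants: list[StimulusVariant], out_dir) -> list[dict]:
    """Write variants as gamma-encoded PNGs plus a manifest of conditions."""
    import json
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for v in variants:
        name = f"{v.key.scene_id}_{v.key.side}_{v.key.polarity}_{v.key.extent}.png"
        arr = np.clip(gamma_decode(v.image), 0.0, 1.0)
        Image.fromarray(np.round(arr * 255).astype(np.uint8)).save(out_dir / name)
        manifest.append(
            {
                "file": name,
                "scene_id": v.key.scene_id,
                "side": v.key.side,
                "polarity": v.key.polarity,
                "extent": v.key.extent,
                "background": [float(x) for x in v.background],
                "n_clipped": v.n_clipped,
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def rotated_point(point: ScenePoint) -> ScenePoint:
    """The annotation after 180° rotation: masks swap roles, object side flips."""
    h, w = point.mask1.shape
    r0, c0 = point.center

    def _rot(mask):
        out = np.zeros_like(mask)
        rows = 2 * r0 - np.arange(h)
        cols = 2 * c0 - np.arange(w)
        rok = (rows >= 0) & (rows < h)
        cok = (cols >= 0) & (cols < w)
        out[np.ix_(rok, cok)] = mask[np.ix_(rows[rok], cols[cok])]
        return out

    return replace(
        point,
        object_side=(-point.object_side[0], -point.object_side[1]),
        mask1=_rot(point.mask1),
        mask2=_rot(point.mask2),
    )
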