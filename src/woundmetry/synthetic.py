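"""Synthetic clinical-scene generator with exact ground truth.

Renders the kind of photograph the measurement pipeline expects — a
printed QR-style fiducial square of known physical size and an
irregular colored "wound" region of known physical area on a
skin-toned background, with optional clutter patches and sensor noise
— at a chosen resolution (pixels per cm, i.e. simulated camera
distance).  Every scene carries pixel-exact truth masks, so the whole
pipeline is testable without any real photographs.

Geometry is specified in cm with analytic shapes (ellipses and fused
ellipse blobs); rasterization uses the pixel-center rule, and analytic
physical areas are computed by fine supersampling, so truth pixel areas
converge to ``physical_area x px_per_cm^2`` as resolution grows.

The fiducial's module layout is a fixed deterministic pseudo-QR
pattern (dark frame, quiet ring, finder-like corner blocks, fixed
pseudo-random modules); it is never decoded — only its solid square
footprint matters.  A solid-square mode exists for oracle-exact tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidSpecError
from .qr_reference import FiducialSpec

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "render_scene",
    "render_distance_series",
    "render_coin_scene",
    "repeatability_panel",
]

# default palette (sRGB)
SKIN = (224, 172, 150)
WOUND_RED = (186, 59, 56)
FIDUCIAL_DARK = (20, 20, 20)
FIDUCIAL_LIGHT = (250, 250, 250)
CLUTTER_BLUE = (168, 178, 196)
BENCH_GRAY = (228, 228, 228)
COIN_COPPER = (184, 115, 51)

_SUPERSAMPLE_PX_PER_CM = 200


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic scene.

    Positions are (y, x) in cm from the top-left corner.  The wound is
    an ellipse or a fused-ellipse blob scaled so its analytic area
    equals ``wound_area_cm2``.  ``noise_sd`` is the SD of additive
    Gaussian sensor noise in 8-bit intensity units.
    """

    width_cm: float = 8.0
    height_cm: float = 8.0
    px_per_cm: float = 50.0
    seed: int = 0  # geometry seed (blob lobes, clutter jitter)
    noise_seed: int | None = None  # sensor-noise seed; defaults to ``seed``
    noise_sd: float = 4.0
    # fiducial
    fiducial: FiducialSpec = field(default_factory=FiducialSpec)
    fiducial_center: tuple[float, float] = (2.0, 2.0)
    fiducial_style: str = "qr"  # "qr" | "solid"
    sticker_margin_cm: float = 0.15
    # wound
    wound_shape: str = "ellipse"  # "ellipse" | "blob" | "disc" | "none"
    wound_area_cm2: float = 1.5708
    wound_center: tuple[float, float] = (5.0, 4.8)
    wound_aspect: float = 2.0
    wound_angle_deg: float = 30.0
    # colors / clutter
    background_color: tuple[int, int, int] = SKIN
    wound_color: tuple[int, int, int] = WOUND_RED
    fiducial_dark: tuple[int, int, int] = FIDUCIAL_DARK
    fiducial_light: tuple[int, int, int] = FIDUCIAL_LIGHT
    clutter_color: tuple[int, int, int] = CLUTTER_BLUE
    n_clutter: int = 3


@dataclass
class SceneTruth:
    """A rendered scene plus its pixel-exact ground truth."""

    rendered: np.ndarray
    wound_mask_truth: np.ndarray
    fiducial_mask_truth: np.ndarray
    wound_pixel_area_truth: int
    fiducial_pixel_area_truth: int
    wound_physical_area_truth: float  # analytic, cm^2
    px_per_cm: float
    spec: SceneSpec


# ---------------------------------------------------------------- shapes

def _ellipse_indicator(cy, cx, a, b, angle_deg):
    """Indicator of an ellipse with semi-axes a (major) and b, rotated."""
    th = math.radians(angle_deg)
    cos_t, sin_t = math.cos(th), math.sin(th)

    def f(y, x):
        dy, dx = y - cy, x - cx
        u = dx * cos_t + dy * sin_t
        v = -dx * sin_t + dy * cos_t
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    return f


def _blob_indicator(cy, cx, a, b, angle_deg, seed):
    """Fused-ellipse blob: a main ellipse with two overlapping lobes."""
    rng = np.random.default_rng(seed)
    parts = [_ellipse_indicator(cy, cx, a, b, angle_deg)]
    for _ in range(2):
        phi = rng.uniform(0, 2 * math.pi)
        d = rng.uniform(0.5, 0.85) * a
        la = rng.uniform(0.35, 0.55) * a
        lb = rng.uniform(0.6, 1.0) * la
        parts.append(
            _ellipse_indicator(
                cy + d * math.sin(phi), cx + d * math.cos(phi),
                la, lb, math.degrees(rng.uniform(0, math.pi)),
            )
        )

    def f(y, x):
        out = np.zeros(np.broadcast(y, x).shape, dtype=bool)
        for p in parts:
            out |= p(y, x)
        return out

    return f


def _scale_indicator(f, cy, cx, s):
    """Scale a shape about (cy, cx) by factor s (area scales by s^2)."""

    def g(y, x):
        return f(cy + (y - cy) / s, cx + (x - cx) / s)

    return g


def _analytic_area(f, cy, cx, reach_cm) -> float:
    """Supersampled area (cm^2) of an indicator near (cy, cx)."""
    n = int(2 * reach_cm * _SUPERSAMPLE_PX_PER_CM)
    step = 1.0 / _SUPERSAMPLE_PX_PER_CM
    ys = cy - reach_cm + (np.arange(n) + 0.5) * step
    xs = cx - reach_cm + (np.arange(n) + 0.5) * step
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    return float(f(yy, xx).sum()) * step**2


def _wound_indicator(spec: SceneSpec):
    """Wound shape scaled so its analytic area is spec.wound_area_cm2."""
    if spec.wound_area_cm2 <= 0:
        raise InvalidSpecError("wound physical area must be positive")
    cy, cx = spec.wound_center
    a = math.sqrt(spec.wound_area_cm2 * spec.wound_aspect / math.pi)
    b = a / spec.wound_aspect
    if spec.wound_shape == "ellipse":
        return _ellipse_indicator(cy, cx, a, b, spec.wound_angle_deg), spec.wound_area_cm2
    if spec.wound_shape == "disc":
        r = math.sqrt(spec.wound_area_cm2 / math.pi)
        return _ellipse_indicator(cy, cx, r, r, 0.0), spec.wound_area_cm2
    if spec.wound_shape == "blob":
        f = _blob_indicator(cy, cx, a, b, spec.wound_angle_deg, spec.seed)
        reach = 3.0 * a
        # one-dimensional scale so the union's area matches the request
        s = 1.0
        for _ in range(4):
            area = _analytic_area(_scale_indicator(f, cy, cx, s), cy, cx, reach)
            s *= math.sqrt(spec.wound_area_cm2 / area)
        g = _scale_indicator(f, cy, cx, s)
        return g, _analytic_area(g, cy, cx, reach)
    raise InvalidSpecError(f"unknown wound shape {spec.wound_shape!r}")


# ------------------------------------------------------------- fiducial

def _qr_module_grid(n_cells: int = 25) -> np.ndarray:
    """Deterministic pseudo-QR layout: True = dark module.

    Outer 2-cell dark frame, 1-cell white quiet ring, finder-like 5x5
    blocks in three corners of the interior, and fixed pseudo-random
    modules elsewhere (a fixed "payload").
    """
    g = np.zeros((n_cells, n_cells), dtype=bool)
    g[:2, :] = g[-2:, :] = True
    g[:, :2] = g[:, -2:] = True
    rng = np.random.default_rng(20250617)  # fixed payload
    inner = rng.random((n_cells - 6, n_cells - 6)) < 0.45
    finder = np.ones((5, 5), dtype=bool)
    finder[1:4, 1:4] = False
    finder[2, 2] = True
    for r0, c0 in ((0, 0), (0, n_cells - 11), (n_cells - 11, 0)):
        inner[r0:r0 + 5, c0:c0 + 5] = finder
    g[3:-3, 3:-3] = inner
    return g


_QR_GRID = _qr_module_grid()


def _render_fiducial(img, yy, xx, spec: SceneSpec):
    cy, cx = spec.fiducial_center
    half = spec.fiducial.physical_side / 2.0
    footprint = (np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= half)
    if spec.fiducial_style == "solid":
        img[footprint] = spec.fiducial_dark
        return footprint
    if spec.fiducial_style != "qr":
        raise InvalidSpecError(f"unknown fiducial style {spec.fiducial_style!r}")
    sticker_half = half + spec.sticker_margin_cm
    sticker = (np.abs(yy - cy) <= sticker_half) & (np.abs(xx - cx) <= sticker_half)
    img[sticker] = spec.fiducial_light
    n = _QR_GRID.shape[0]
    side = spec.fiducial.physical_side
    cell_r = np.clip(((yy - (cy - half)) / side * n).astype(int), 0, n - 1)
    cell_c = np.clip(((xx - (cx - half)) / side * n).astype(int), 0, n - 1)
    dark = footprint & _QR_GRID[cell_r, cell_c]
    img[dark] = spec.fiducial_dark
    return footprint


def _clutter_spots(spec: SceneSpec):
    """Deterministic clutter patches kept away from wound and fiducial."""
    rng = np.random.default_rng(spec.seed + 104729)
    anchors = [(1.2, 5.8), (6.5, 1.5), (6.8, 6.3), (1.0, 7.0), (7.2, 4.0)]
    spots = []
    for k in range(min(spec.n_clutter, len(anchors))):
        ay, ax = anchors[k]
        cy = ay * spec.height_cm / 8.0 + rng.uniform(-0.15, 0.15)
        cx = ax * spec.width_cm / 8.0 + rng.uniform(-0.15, 0.15)
        spots.append((cy, cx, rng.uniform(0.35, 0.55)))
    return spots


# ------------------------------------------------------------ rendering

def render_scene(spec: SceneSpec) -> SceneTruth:
    """Rasterize a scene and its truth masks; deterministic given seed.

    Raises :class:`InvalidSpecError` if the wound and fiducial
    footprints overlap or touch the image border.
    """
    if spec.px_per_cm <= 0:
        raise InvalidSpecError("px_per_cm must be positive")
    h = int(round(spec.height_cm * spec.px_per_cm))
    w = int(round(spec.width_cm * spec.px_per_cm))
    if h < 4 or w < 4:
        raise InvalidSpecError("scene is too small to rasterize")
    step = 1.0 / spec.px_per_cm
    ys = (np.arange(h) + 0.5) * step
    xs = (np.arange(w) + 0.5) * step
    yy, xx = np.meshgrid(ys, xs, indexing="ij")

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_color

    for cy, cx, r in _clutter_spots(spec):
        img[_ellipse_indicator(cy, cx, r, 0.8 * r, 15.0)(yy, xx)] = spec.clutter_color

    if spec.wound_shape == "none":
        wound_mask = np.zeros((h, w), dtype=np.uint8)
        wound_area_cm2 = 0.0
    else:
        indicator, wound_area_cm2 = _wound_indicator(spec)
        wound_bool = indicator(yy, xx)
        img[wound_bool] = spec.wound_color
        wound_mask = wound_bool.astype(np.uint8)

    fid_bool = _render_fiducial(img, yy, xx, spec)
    fid_mask = fid_bool.astype(np.uint8)

    if (wound_mask & fid_mask).any():
        raise InvalidSpecError("wound and fiducial footprints overlap")
    for name, m in (("wound", wound_mask), ("fiducial", fid_mask)):
        if m.any() and (
            m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()
        ):
            raise InvalidSpecError(f"{name} footprint touches the image border")

    if spec.noise_sd > 0:
        noise_seed = spec.seed if spec.noise_seed is None else spec.noise_seed
        rng = np.random.default_rng(noise_seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    rendered = np.clip(np.round(img), 0, 255).astype(np.uint8)

    return SceneTruth(
        rendered=rendered,
        wound_mask_truth=wound_mask,
        fiducial_mask_truth=fid_mask,
        wound_pixel_area_truth=int(wound_mask.sum()),
        fiducial_pixel_area_truth=int(fid_mask.sum()),
        wound_physical_area_truth=wound_area_cm2,
        px_per_cm=spec.px_per_cm,
        spec=spec,
    )


def _derived_seed(seed: int, i: int) -> int:
    return (seed * 1000003 + 7919 * (i + 1)) % (2**31 - 1)


def render_distance_series(spec: SceneSpec, scales) -> list[SceneTruth]:
    """The same physical scene shot at several simulated distances.

    Each scale s multiplies px_per_cm (s < 1 is farther away); the
    physical ground truth is identical across the series, while truth
    pixel areas scale approximately by s^2.  Noise is redrawn per shot.
    """
    out = []
    for i, s in enumerate(scales):
        if s <= 0:
            raise InvalidSpecError("scales must be positive")
        out.append(
            render_scene(
                replace(
                    spec,
                    px_per_cm=spec.px_per_cm * s,
                    noise_seed=_derived_seed(spec.seed, i),
                )
            )
        )
    return out


def render_coin_scene(coin_diameter_cm: float = 1.905, spec: SceneSpec | None = None) -> SceneTruth:
    """Bench-validation scene: a copper one-cent-style coin and the
    fiducial on a neutral background (the reference-standard setup)."""
    if coin_diameter_cm <= 0:
        raise InvalidSpecError("coin diameter must be positive")
    base = spec or SceneSpec()
    r = coin_diameter_cm / 2.0
    coin = replace(
        base,
        wound_shape="disc",
        wound_area_cm2=math.pi * r**2,
        wound_color=COIN_COPPER,
        background_color=BENCH_GRAY,
        n_clutter=min(base.n_clutter, 2),
    )
    return render_scene(coin)


def repeatability_panel(
    n_wounds: int = 10,
    n_shots: int = 3,
    seed: int = 0,
    base_px_per_cm: float = 50.0,
    scale_range: tuple[float, float] = (0.7, 1.4),
) -> list[list[SceneTruth]]:
    """Panel of distinct wounds, each shot at random simulated heights.

    Emulates the repeated-shots study design: every wound is rendered
    ``n_shots`` times at an independent random scale drawn uniformly
    from ``scale_range`` (shots at random heights), with fresh noise
    per shot.  Returns a list (wounds) of lists (shots) of scenes.
    """
    if n_shots < 2 or n_wounds < 2:
        raise InvalidSpecError("panel needs >= 2 wounds and >= 2 shots")
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_wounds):
        spec = SceneSpec(
            seed=_derived_seed(seed, i),
            wound_shape="blob" if i % 2 else "ellipse",
            wound_area_cm2=float(rng.uniform(1.0, 4.0)),
            wound_aspect=float(rng.uniform(1.3, 2.5)),
            wound_angle_deg=float(rng.uniform(0.0, 180.0)),
            px_per_cm=base_px_per_cm,
        )
        scales = rng.uniform(*scale_range, size=n_shots)
        panel.append(render_distance_series(spec, scales))
    return panel
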