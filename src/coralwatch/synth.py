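"""Synthetic reef scenes, annotations and sensor series with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not the optics of a real reef: a live-coral region carrying an
oriented band-pass texture and a controllable red–green (CIELab a*) tissue
colour on a smoother bluish background; polyps rendered as radially-armed
blobs when extended (feeding) and smooth discs when retracted; hourly imaging
with integer-pixel camera jitter and dropped frames; and environmental sensor
series built from trend + periodic components (tidal 12.4 h, diel 24 h, lunar
~707 h) + AR(1) noise + outage gaps.

Everything is deterministic under a fixed seed, and the injected ground truth
(coral region, per-polyp state, per-frame target a*) is returned alongside the
frames so each processing stage can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage import morphology

from coralwatch.align import IrregularSeries
from coralwatch.imagery import ImageFrame
from coralwatch.wavelets import NoiseModel, ar1_surrogate

__all__ = [
    "SceneTruth",
    "SignalSpec",
    "TextureParams",
    "generate_reef_frame",
    "generate_scene",
    "generate_sequence",
    "generate_sensor_series",
    "generate_annotations",
]

ACTIVE, INACTIVE = "active", "inactive"


@dataclass
class SceneTruth:
    """Ground truth for one rendered frame.

    Attributes
    ----------
    coral_region
        Boolean raster of the live-coral region (before the frame shift).
    polyp_centres
        ``(x, y, state)`` triples with state in ``{"active", "inactive"}``;
        coordinates are in the unshifted scene frame and must lie inside
        ``coral_region``.
    redness_a
        Target CIELab a* of the coral tissue.
    frame_shift
        ``(dx, dy)`` integer pixel translation applied to this frame (camera
        jitter).
    """

    coral_region: np.ndarray
    polyp_centres: list[tuple[int, int, str]]
    redness_a: float
    frame_shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.coral_region = np.asarray(self.coral_region, dtype=bool)
        if not np.isfinite(self.redness_a):
            raise ValueError("redness_a must be finite")
        h, w = self.coral_region.shape
        for x, y, state in self.polyp_centres:
            if state not in (ACTIVE, INACTIVE):
                raise ValueError(f"polyp state must be binary, got {state!r}")
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(f"polyp centre ({x}, {y}) outside the raster")
            if not self.coral_region[int(y), int(x)]:
                raise ValueError(f"polyp centre ({x}, {y}) outside the coral region")

    @property
    def active_fraction(self) -> float:
        if not self.polyp_centres:
            return 0.0
        return float(np.mean([s == ACTIVE for _, _, s in self.polyp_centres]))


@dataclass
class SignalSpec:
    """Recipe for a synthetic environmental sensor series.

    ``components`` are ``(period_hours, amplitude, phase_rad)`` sinusoids;
    ``trend_anchors`` are ``(hour, value)`` knots of a piecewise-linear trend;
    ``noise_sd`` is the *stationary* standard deviation of the AR(1) noise;
    ``gaps`` are ``(start_hour, end_hour)`` outage intervals whose samples are
    removed (not zero-filled).
    """

    components: list[tuple[float, float, float]] = field(default_factory=list)
    trend_anchors: list[tuple[float, float]] = field(default_factory=list)
    ar1_coefficient: float = 0.0
    noise_sd: float = 0.0
    gaps: list[tuple[float, float]] = field(default_factory=list)
    sampling_interval_minutes: float = 60.0

    def __post_init__(self) -> None:
        for period, _, _ in self.components:
            if period <= 0:
                raise ValueError("component periods must be positive")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.sampling_interval_minutes <= 0:
            raise ValueError("sampling interval must be positive")


@dataclass
class TextureParams:
    """Rendering knobs for the two texture classes and tissue colour.

    The coral texture is an oriented carrier wave with noisy amplitude, so a
    Gabor bank responds strongly in one frequency/orientation channel; the
    background is low-pass noise with its energy well below the carrier
    frequency.  Colours are specified in CIELab and converted to sRGB at
    render time.
    """

    coral_frequency: float = 0.12      # carrier, cycles/pixel
    coral_orientation: float = 0.6     # radians
    coral_L: float = 58.0
    coral_L_contrast: float = 9.0
    coral_b: float = 8.0
    background_L: float = 42.0
    background_L_contrast: float = 7.0
    background_a: float = -4.0
    background_b: float = -10.0
    background_smoothing: float = 6.0  # px, low-pass sigma


def _polyp_rng(seed: int, x: int, y: int) -> np.random.Generator:
    # per-polyp morphology must be stable across frames of one scene
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, x, y]))


def _draw_polyp(L: np.ndarray, x: int, y: int, state: str, seed: int) -> None:
    """Stamp one polyp into the luminance channel.

    Active (extended) polyps get 6-10 thin radial arms reaching ~20 px (the
    classifier's 46 px patch scale); inactive (retracted) ones a smooth disc.
    """
    h, w = L.shape
    r_max = 21
    y0, y1 = max(0, y - r_max), min(h, y + r_max + 1)
    x0, x1 = max(0, x - r_max), min(w, x + r_max + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - y, xx - x
    r = np.hypot(dx, dy)
    rng = _polyp_rng(seed, x, y)
    n_arms = rng.integers(6, 11)
    phi0 = rng.uniform(0, 2 * np.pi)
    if state == ACTIVE:
        phi = np.arctan2(dy, dx)
        arms = (np.cos(n_arms * phi + phi0) > 0.55) & (r < 20) & (r >= 2)
        centre = r < 3.5
        L[y0:y1, x0:x1] += 26.0 * (arms | centre) * np.exp(-r / 30.0)
    else:
        L[y0:y1, x0:x1] += 20.0 * np.exp(-(r / 6.0) ** 2)


def _textures(shape: tuple[int, int], params: TextureParams,
              seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Oriented band-pass coral texture and low-pass background texture."""
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    carrier = np.cos(2 * np.pi * params.coral_frequency
                     * (np.cos(params.coral_orientation) * xx
                        + np.sin(params.coral_orientation) * yy))
    amp = ndimage.gaussian_filter(rng.normal(size=shape), 8.0)
    amp = 0.6 + 0.4 * (amp - amp.min()) / max(np.ptp(amp), 1e-9)
    coral = carrier * amp
    bg = ndimage.gaussian_filter(rng.normal(size=shape),
                                 params.background_smoothing)
    bg /= max(np.abs(bg).max(), 1e-9)
    return coral, bg


def generate_reef_frame(truth: SceneTruth, texture_params: TextureParams | None = None,
                        seed: int = 0, timestamp="2015-04-03 00:00:00") -> ImageFrame:
    """Render one frame from its ground truth.

    The same truth and seed always render the identical frame; within a
    sequence the seed is held fixed so the scene (textures, polyp morphology)
    is static and only polyp states, tissue colour and jitter evolve.
    """
    params = texture_params or TextureParams()
    region = truth.coral_region
    h, w = region.shape
    coral_tex, bg_tex = _textures((h, w), params, seed)

    L = np.where(region,
                 params.coral_L + params.coral_L_contrast * coral_tex,
                 params.background_L + params.background_L_contrast * bg_tex)
    a = np.where(region, float(truth.redness_a), params.background_a)
    b = np.where(region, params.coral_b, params.background_b)
    for x, y, state in truth.polyp_centres:
        _draw_polyp(L, int(x), int(y), state, seed)
    L = np.clip(L, 5.0, 95.0)

    lab = np.stack([L, a, b], axis=-1)
    rgb = np.clip(skcolor.lab2rgb(lab), 0.0, 1.0)
    pixels = (rgb * 255.0 + 0.5).astype(np.uint8)

    dx, dy = truth.frame_shift
    if (dx, dy) != (0, 0):
        pixels = np.roll(pixels, (int(dy), int(dx)), axis=(0, 1))
    return ImageFrame(pd.Timestamp(timestamp), pixels)


def generate_scene(shape: tuple[int, int] = (512, 512), n_polyps: int = 40,
                   seed: int = 0, min_separation: float = 26.0,
                   margin: int = 28) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Draw a static scene layout: coral region blob and polyp positions.

    The coral region is a smooth random blob covering roughly a third of the
    frame; polyp centres are sampled inside its interior with a minimum
    separation so the rendered blobs do not merge, and at least ``margin``
    pixels from the frame border so full patches exist around each centre.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), min(h, w) / 8.0)
    region = field_ > np.quantile(field_, 0.62)
    lab, n = ndimage.label(region)
    if n == 0:
        raise ValueError("degenerate scene: no coral region generated")
    sizes = ndimage.sum(region, lab, index=np.arange(1, n + 1))
    region = lab == (1 + int(np.argmax(sizes)))
    region = ndimage.binary_fill_holes(
        morphology.closing(region, morphology.disk(7)))

    interior = morphology.erosion(region, morphology.disk(12))
    interior[:margin, :] = interior[-margin:, :] = False
    interior[:, :margin] = interior[:, -margin:] = False
    ys, xs = np.nonzero(interior)
    if len(xs) == 0:
        raise ValueError("coral region too small to place polyps")
    sep = float(min_separation)
    while True:
        order = rng.permutation(len(xs))
        centres: list[tuple[int, int]] = []
        for i in order:
            x, y = int(xs[i]), int(ys[i])
            if all((x - cx) ** 2 + (y - cy) ** 2 >= sep ** 2
                   for cx, cy in centres):
                centres.append((x, y))
            if len(centres) == n_polyps:
                break
        if len(centres) == n_polyps:
            return region, centres
        # dense scenes: relax the packing before giving up
        sep *= 0.85
        if sep < 14.0:
            raise ValueError(
                f"could only place {len(centres)} of {n_polyps} polyps; "
                "enlarge the frame or reduce n_polyps")


def generate_sequence(n_frames: int, color_trajectory, activity_trajectory,
                      jitter_sd: float = 1.0, missing_fraction: float = 0.0,
                      seed: int = 0, shape: tuple[int, int] = (512, 512),
                      n_polyps: int = 40, start="2015-04-03 00:00:00",
                      texture_params: TextureParams | None = None,
                      ) -> tuple[list[ImageFrame], list[SceneTruth]]:
    """Render an hourly image sequence over a static scene.

    ``color_trajectory`` and ``activity_trajectory`` give the per-frame target
    a* value and expected active-polyp fraction (scalars are broadcast).
    Polyp states are drawn independently per frame as Bernoulli draws of the
    trajectory value; camera jitter is an i.i.d. integer shift with standard
    deviation ``jitter_sd``; a ``missing_fraction`` of frames (never the
    first, which serves as the registration reference) is dropped entirely,
    the way camera malfunctions leave holes in a real record.

    Returns parallel lists of retained frames and their ground truths.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    colors = np.broadcast_to(np.asarray(color_trajectory, dtype=float), (n_frames,))
    activity = np.broadcast_to(np.asarray(activity_trajectory, dtype=float), (n_frames,))
    rng = np.random.default_rng(seed)
    region, centres = generate_scene(shape, n_polyps, seed=seed)

    n_missing = int(round(missing_fraction * n_frames))
    missing = set(rng.choice(np.arange(1, n_frames), size=min(n_missing, n_frames - 1),
                             replace=False).tolist()) if n_missing else set()

    start = pd.Timestamp(start)
    frames: list[ImageFrame] = []
    truths: list[SceneTruth] = []
    for i in range(n_frames):
        states = np.where(rng.random(len(centres)) < activity[i], ACTIVE, INACTIVE)
        if jitter_sd > 0 and i > 0:
            # the first frame is the registration reference and anchors the
            # scene coordinate system, so it carries no jitter
            shift = tuple(int(round(v)) for v in rng.normal(0.0, jitter_sd, 2))
        else:
            shift = (0, 0)
        if i in missing:
            continue
        truth = SceneTruth(region,
                           [(x, y, s) for (x, y), s in zip(centres, states)],
                           redness_a=float(colors[i]), frame_shift=shift)
        frames.append(generate_reef_frame(truth, texture_params, seed=seed,
                                          timestamp=start + pd.Timedelta(hours=i)))
        truths.append(truth)
    return frames, truths


def generate_sensor_series(spec: SignalSpec, n_hours: float, seed: int = 0,
                           start="2015-04-03 00:00:00", name: str = "",
                           unit: str = "") -> IrregularSeries:
    """Simulate one sensor record: trend + sinusoids + AR(1) noise − gaps."""
    step_h = spec.sampling_interval_minutes / 60.0
    t = np.arange(0.0, n_hours + 1e-9, step_h)
    values = np.zeros_like(t)
    if spec.trend_anchors:
        anchors = sorted(spec.trend_anchors)
        values += np.interp(t, [a for a, _ in anchors], [v for _, v in anchors])
    for period, amplitude, phase in spec.components:
        values += amplitude * np.sin(2 * np.pi * t / period + phase)
    if spec.noise_sd > 0:
        noise = ar1_surrogate(len(t), NoiseModel(spec.ar1_coefficient,
                                                 spec.noise_sd ** 2),
                              np.random.default_rng(seed))
        values += noise
    keep = np.ones(len(t), dtype=bool)
    for g0, g1 in spec.gaps:
        if g0 < 0 or g1 > n_hours or g1 < g0:
            raise ValueError(f"gap ({g0}, {g1}) outside the series span")
        keep &= ~((t > g0) & (t < g1))
    start = pd.Timestamp(start)
    ts = start + pd.to_timedelta(t[keep], unit="h")
    return IrregularSeries(pd.DatetimeIndex(ts), values[keep], name=name, unit=unit)


def generate_annotations(truths: list[SceneTruth], annotator_error_rate: float = 0.0,
                         position_sd: float = 0.0, seed: int = 0,
                         annotators: tuple[str, ...] = ("expert1",),
                         image_ids: list[str] | None = None) -> pd.DataFrame:
    """Emulate human point annotations of the polyps in each truth.

    Each annotator marks every polyp once, with the position perturbed by
    Gaussian noise of ``position_sd`` pixels and the active/inactive label
    flipped with probability ``annotator_error_rate``.  Returns a frame with
    columns ``image, x, y, class, annotator``.
    """
    if not 0 <= annotator_error_rate < 0.5:
        raise ValueError("annotator_error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    rows = []
    for i, truth in enumerate(truths):
        image = image_ids[i] if image_ids is not None else str(i)
        h, w = truth.coral_region.shape
        for ann in annotators:
            for x, y, state in truth.polyp_centres:
                px = int(round(x + rng.normal(0, position_sd))) if position_sd else x
                py = int(round(y + rng.normal(0, position_sd))) if position_sd else y
                px, py = int(np.clip(px, 0, w - 1)), int(np.clip(py, 0, h - 1))
                label = state
                if annotator_error_rate and rng.random() < annotator_error_rate:
                    label = INACTIVE if state == ACTIVE else ACTIVE
                rows.append((image, px, py, label, ann))
    return pd.DataFrame(rows, columns=["image", "x", "y", "class", "annotator"])
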