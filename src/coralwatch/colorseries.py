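"""The coral-colour time series xi_t.

Each hourly frame is registered against a fixed reference (translation-only
phase correlation — the camera is fixed and only jitter is expected), colour
corrected with one fixed white balance for the whole sequence, converted to
CIELab (sRGB primaries, D65 white point), and segmented into live coral vs
background by a texture-driven pixel labeller: Gabor filter-bank features fed
to a self-organising map whose nodes carry majority-vote class labels.  The
colour series xi_t is the a-channel (red–green axis) of the mean CIELab colour
over the live-coral mask; L and b are computed and stored as well so the claim
that they carry no variation of interest can be re-checked.

Frames that fail alignment, or whose coral mask comes out empty, are recorded
as gaps rather than interpolated here; gap handling belongs to the alignment
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import fftconvolve
from scipy.spatial.distance import cdist
from skimage import color as skcolor
from skimage import morphology
from skimage.filters import gabor_kernel
from skimage.registration import phase_cross_correlation

from coralwatch.align import IrregularSeries
from coralwatch.imagery import ImageFrame

__all__ = [
    "AlignmentError",
    "EmptyMaskError",
    "LabColor",
    "GaborBank",
    "SOMLabeller",
    "register_frame",
    "estimate_white_balance",
    "white_balance",
    "rgb_to_lab",
    "extract_gabor_features",
    "train_pixel_labeller",
    "segment_coral",
    "mean_color",
    "color_series",
]

logger = logging.getLogger(__name__)

CORAL, BACKGROUND = 1, 0


class AlignmentError(RuntimeError):
    """Raised when a frame cannot be registered against the reference."""


class EmptyMaskError(ValueError):
    """Raised when a mean colour is requested over an empty mask."""


class LabColor(NamedTuple):
    """A CIELab colour: L (lightness), a (green-red), b (blue-yellow)."""

    L: float
    a: float
    b: float


def register_frame(frame: ImageFrame, reference: ImageFrame,
                   fail_threshold: float = 0.2) -> tuple[ImageFrame, tuple[int, int]]:
    """Translation-only registration of a frame against the reference.

    Phase correlation estimates the integer-pixel translation of the frame
    content relative to the reference; the frame is shifted back, and the
    pixels rolled in at the border are flagged invalid.  Blank or unrelated
    frames are detected by the Pearson correlation of the registered overlap
    (the phase-correlation peak statistic itself does not separate noise pairs
    under phase normalisation): below ``fail_threshold`` an
    :class:`AlignmentError` is raised and the caller records a gap.

    Returns ``(aligned frame, (dx, dy))`` with ``(dx, dy)`` the estimated
    translation of the input relative to the reference.
    """
    if frame.pixels.shape != reference.pixels.shape:
        raise ValueError("frames must share dimensions")
    g_ref = reference.gray()
    g_mov = frame.gray()
    if np.ptp(g_mov) == 0 or np.ptp(g_ref) == 0:
        raise AlignmentError("blank frame cannot be aligned")
    shift, _, _ = phase_cross_correlation(g_ref, g_mov, normalization="phase")
    dy_corr, dx_corr = int(round(shift[0])), int(round(shift[1]))
    aligned = np.roll(frame.pixels, (dy_corr, dx_corr), axis=(0, 1))

    h, w = g_ref.shape
    valid = np.ones((h, w), dtype=bool)
    if dy_corr > 0:
        valid[:dy_corr, :] = False
    elif dy_corr < 0:
        valid[dy_corr:, :] = False
    if dx_corr > 0:
        valid[:, :dx_corr] = False
    elif dx_corr < 0:
        valid[:, dx_corr:] = False

    g_aligned = aligned.astype(float) @ np.array([0.299, 0.587, 0.114])
    a, b = g_ref[valid], g_aligned[valid]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise AlignmentError("degenerate overlap after shifting")
    quality = float(np.corrcoef(a, b)[0, 1])
    if quality < fail_threshold:
        raise AlignmentError(
            f"registered overlap correlates at {quality:.3f} "
            f"(< {fail_threshold}); frame excluded")
    return ImageFrame(frame.timestamp, aligned, valid), (-dx_corr, -dy_corr)


def estimate_white_balance(frame: ImageFrame,
                           neutral_patch: tuple[int, int, int, int]) -> tuple[float, float, float]:
    """Per-channel gains that make a configured neutral patch achromatic.

    ``neutral_patch`` is ``(x0, y0, x1, y1)``.  The gains are estimated once
    from the reference frame and then held fixed for the whole sequence.
    """
    x0, y0, x1, y1 = neutral_patch
    patch = frame.pixels[y0:y1, x0:x1].astype(float)
    if patch.size == 0:
        raise ValueError("empty neutral patch")
    means = patch.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("neutral patch has a zero channel mean")
    target = means.mean()
    return tuple(float(target / m) for m in means)


def white_balance(frame: ImageFrame, gains: tuple[float, float, float]) -> ImageFrame:
    """Scale each channel by its (positive, sequence-fixed) gain and clip."""
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (3,) or np.any(gains <= 0):
        raise ValueError("need three positive channel gains")
    scaled = np.clip(frame.pixels.astype(float) * gains, 0, 255)
    return ImageFrame(frame.timestamp, scaled.astype(np.uint8), frame.valid)


def rgb_to_lab(frame: ImageFrame | np.ndarray) -> np.ndarray:
    """Per-pixel CIELab conversion under sRGB primaries and D65 white point."""
    pixels = frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame)
    return skcolor.rgb2lab(pixels / 255.0 if pixels.dtype == np.uint8 else pixels)


@dataclass
class GaborBank:
    """A bank of oriented band-pass (Gabor) filters for texture features.

    Defaults: 4 frequencies x 6 orientations, magnitude responses pooled over
    orientation (rotation-robust, one feature per frequency), lightly smoothed
    so per-pixel labels are spatially coherent.
    """

    frequencies: tuple[float, ...] = (0.04, 0.08, 0.16, 0.32)
    orientations: tuple[float, ...] = tuple(np.pi * k / 6 for k in range(6))
    pool_orientations: bool = True
    smoothing_sigma: float = 4.0

    @property
    def n_features(self) -> int:
        if self.pool_orientations:
            return len(self.frequencies)
        return len(self.frequencies) * len(self.orientations)


def extract_gabor_features(frame: ImageFrame | np.ndarray,
                           bank: GaborBank | None = None) -> np.ndarray:
    """Per-pixel Gabor magnitude features, shape ``(H, W, n_features)``.

    Filtering runs in the Fourier domain (the kernels at low frequencies are
    large), and magnitudes are pooled over orientation when the bank says so.
    """
    bank = bank or GaborBank()
    if not bank.frequencies or not bank.orientations:
        raise ValueError("Gabor bank must list frequencies and orientations")
    gray = frame.gray() if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)
    gray = gray - gray.mean()
    feats = []
    for f in bank.frequencies:
        responses = []
        for theta in bank.orientations:
            k = gabor_kernel(f, theta=theta)
            resp = np.abs(fftconvolve(gray, k, mode="same"))
            responses.append(resp)
        if bank.pool_orientations:
            feats.append(np.mean(responses, axis=0))
        else:
            feats.extend(responses)
    out = np.stack(feats, axis=-1).astype(np.float32)
    if bank.smoothing_sigma > 0:
        for j in range(out.shape[-1]):
            out[..., j] = ndimage.gaussian_filter(out[..., j], bank.smoothing_sigma)
    return out


@dataclass
class SOMLabeller:
    """A flat 2-D self-organising map with majority-vote node labels.

    The SOM quantises the Gabor feature space; each node inherits the majority
    class of the training pixels it wins, and prediction is nearest-prototype
    lookup.  This keeps the class decision of the hierarchical variants used
    for coral segmentation while staying a plain vector quantizer.
    """

    codebook: np.ndarray
    node_labels: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    grid_shape: tuple[int, int]
    #: per-node refinement codebooks {node: (sub_codebook, sub_labels)} for
    #: nodes whose training pixels were class-impure (hierarchical mode)
    refinements: dict = field(default_factory=dict)

    def _standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_mean) / self.feature_sd

    def predict(self, features: np.ndarray, chunk: int = 1 << 16) -> np.ndarray:
        """Class per feature vector; accepts ``(N, D)`` or ``(H, W, D)``."""
        shape = features.shape[:-1]
        flat = self._standardize(features.reshape(-1, features.shape[-1]))
        out = np.empty(len(flat), dtype=np.int8)
        for i in range(0, len(flat), chunk):
            d = cdist(flat[i:i + chunk], self.codebook)
            bmu = np.argmin(d, axis=1)
            labels = self.node_labels[bmu]
            for node, (sub_cb, sub_labels) in self.refinements.items():
                sel = bmu == node
                if sel.any():
                    sub_bmu = np.argmin(cdist(flat[i:i + chunk][sel], sub_cb),
                                        axis=1)
                    labels[sel] = sub_labels[sub_bmu]
            out[i:i + chunk] = labels
        return out.reshape(shape)


def train_pixel_labeller(features: np.ndarray, labels: np.ndarray,
                         som_shape: tuple[int, int] = (8, 8), n_iter: int = 20,
                         seed: int = 0, hierarchical: bool = False,
                         purity_threshold: float = 0.9) -> SOMLabeller:
    """Train the SOM pixel labeller from labelled seed pixels.

    ``features`` is ``(N, D)``; ``labels`` contains class codes (0 background,
    1 coral) and every class must be represented.  Batch SOM training with a
    shrinking Gaussian neighbourhood; deterministic under the seed.  With
    ``hierarchical`` on, nodes whose winning pixels are class-impure (majority
    below ``purity_threshold``) get one level of refinement: a small k-means
    sub-codebook over their pixels with per-prototype majority labels.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need seed pixels for both classes")
    mean = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    x = (features - mean) / sd

    rng = np.random.default_rng(seed)
    gh, gw = som_shape
    n_nodes = gh * gw
    codebook = x[rng.choice(len(x), n_nodes, replace=len(x) < n_nodes)].copy()
    gy, gx = np.divmod(np.arange(n_nodes), gw)
    grid = np.stack([gy, gx], axis=1).astype(float)
    grid_d2 = cdist(grid, grid) ** 2

    sigma0 = max(gh, gw) / 2.0
    for it in range(n_iter):
        sigma = sigma0 * (0.5 / sigma0) ** (it / max(n_iter - 1, 1))
        bmu = np.argmin(cdist(x, codebook), axis=1)
        h = np.exp(-grid_d2[:, bmu] / (2 * sigma ** 2))  # (nodes, N)
        denom = h.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        codebook = (h @ x) / denom

    bmu = np.argmin(cdist(x, codebook), axis=1)
    node_labels = np.full(n_nodes, -1, dtype=np.int8)
    for node in range(n_nodes):
        won = labels[bmu == node]
        if len(won):
            vals, counts = np.unique(won, return_counts=True)
            node_labels[node] = vals[np.argmax(counts)]
    # nodes that won nothing inherit the label of the nearest labelled node
    unlabelled = node_labels < 0
    if unlabelled.any():
        d = cdist(codebook[unlabelled], codebook[~unlabelled])
        node_labels[unlabelled] = node_labels[~unlabelled][np.argmin(d, axis=1)]

    refinements: dict = {}
    if hierarchical:
        from scipy.cluster.vq import kmeans2

        for node in range(n_nodes):
            won_idx = np.nonzero(bmu == node)[0]
            if len(won_idx) < 8:
                continue
            won_labels = labels[won_idx]
            vals, counts = np.unique(won_labels, return_counts=True)
            if counts.max() / counts.sum() >= purity_threshold:
                continue
            sub_cb, sub_assign = kmeans2(x[won_idx], k=min(4, len(won_idx)),
                                         minit="++", seed=seed + node)
            sub_labels = np.empty(len(sub_cb), dtype=np.int8)
            for k in range(len(sub_cb)):
                sub_won = won_labels[sub_assign == k]
                if len(sub_won):
                    v, c = np.unique(sub_won, return_counts=True)
                    sub_labels[k] = v[np.argmax(c)]
                else:
                    sub_labels[k] = node_labels[node]
            refinements[node] = (sub_cb, sub_labels)
    return SOMLabeller(codebook, node_labels, mean, sd, som_shape,
                       refinements=refinements)


def segment_coral(frame: ImageFrame, labeller: SOMLabeller,
                  bank: GaborBank | None = None, clean_radius: int = 2) -> np.ndarray:
    """Binary live-coral mask for one frame.

    Pixel labels from the SOM are cleaned with morphological opening then
    closing (disc of ``clean_radius``) to suppress salt-and-pepper labels; the
    cleaned mask is the published one.
    """
    feats = extract_gabor_features(frame, bank)
    mask = labeller.predict(feats) == CORAL
    if clean_radius > 0:
        selem = morphology.disk(clean_radius)
        mask = morphology.closing(morphology.opening(mask, selem), selem)
    if frame.valid is not None:
        mask &= frame.valid
    return mask


def mean_color(lab: np.ndarray, mask: np.ndarray | None = None) -> LabColor:
    """Arithmetic mean CIELab colour over the selected pixels.

    With ``mask=None`` every pixel contributes (the full-image mean); with a
    mask only pixels inside it do, and an empty mask raises
    :class:`EmptyMaskError` so the time point can be recorded as a gap.
    """
    lab = np.asarray(lab, dtype=float)
    if mask is None:
        sel = lab.reshape(-1, 3)
    else:
        if mask.shape != lab.shape[:2]:
            raise ValueError("mask must match the raster dimensions")
        if not mask.any():
            raise EmptyMaskError("mask selects no pixels")
        sel = lab[mask]
    m = sel.mean(axis=0)
    return LabColor(float(m[0]), float(m[1]), float(m[2]))


def color_series(frames: list[ImageFrame], labeller: SOMLabeller,
                 gains: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 bank: GaborBank | None = None,
                 reference: ImageFrame | None = None,
                 fail_threshold: float = 0.2) -> pd.DataFrame:
    """Compute xi_t over a time-ordered frame sequence.

    Per frame: register -> white balance -> CIELab -> segment -> masked mean;
    ``xi_a`` is the a-component.  Frames that fail any stage are excluded and
    listed with their reason in ``result.attrs['failed']``; all surviving rows
    appear in timestamp order with columns
    ``timestamp, xi_a, L, b, mask_area_px``.
    """
    if not frames:
        raise ValueError("no frames given")
    order = np.argsort([f.timestamp.value for f in frames])
    frames = [frames[i] for i in order]
    ref = reference if reference is not None else frames[0]
    ref = white_balance(ref, gains)
    rows, failed = [], []
    for frame in frames:
        try:
            aligned, _ = register_frame(frame, ref, fail_threshold=fail_threshold)
            balanced = white_balance(aligned, gains)
            lab = rgb_to_lab(balanced)
            mask = segment_coral(balanced, labeller, bank)
            c = mean_color(lab, mask)
        except (AlignmentError, EmptyMaskError) as exc:
            logger.warning("frame %s excluded: %s", frame.timestamp, exc)
            failed.append((frame.timestamp, str(exc)))
            continue
        rows.append((frame.timestamp, c.a, c.L, c.b, int(mask.sum())))
    if not rows:
        raise RuntimeError("every frame failed; no colour series computed")
    df = pd.DataFrame(rows, columns=["timestamp", "xi_a", "L", "b", "mask_area_px"])
    df.attrs["failed"] = failed
    return df


def series_to_irregular(df: pd.DataFrame, column: str = "xi_a",
                        name: str = "xi", unit: str = "CIELab a") -> IrregularSeries:
    """View one column of a series table as an :class:`IrregularSeries`."""
    return IrregularSeries(pd.DatetimeIndex(df["timestamp"]),
                           df[column].to_numpy(dtype=float), name=name, unit=unit)
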