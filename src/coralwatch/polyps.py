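"""The polyp-activity time series gamma_t.

Human experts mark polyp positions as active (extended, feeding) or inactive
(retracted) points on a handful of frames.  From those annotations the module
builds the polyp mask (union of discs around every annotated point), extracts
46x46 patches, augments them 48-fold (flip x2, rotate x12 at 30 degree steps,
Gaussian noise x2), splits them 70/20/10 at the source-annotation level so no
augmented copy of a held-out patch leaks into training, and trains a
LeNet-5-layout classifier.  For each frame, every pixel of the polyp mask is
classified and gamma_t is the fraction of masked pixels classified active:

    gamma_t = |{p(x,y) : C(p(x,y)) = 1}| / |M = 1|

The module also carries the accuracy-assessment protocol: inter-observer
agreement between annotation sets, and a count-based manual activity value to
rank-correlate against gamma_t.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktransform

from coralwatch._lenet import LeNet5
from coralwatch.imagery import ImageFrame

__all__ = [
    "CLASSES",
    "PatchSet",
    "TrainSpec",
    "Classifier",
    "build_polyp_mask",
    "extract_patches",
    "sample_background",
    "augment_patches",
    "split_dataset",
    "train_classifier",
    "classify_pixels",
    "polyp_activity",
    "activity_series",
    "observer_agreement",
    "manual_gamma",
]

logger = logging.getLogger(__name__)

#: Class codes: the classifier's softmax is ordered this way.
CLASSES = ("inactive", "active", "background")
INACTIVE, ACTIVE, BG = 0, 1, 2
PATCH_SIZE = 46


@dataclass
class PatchSet:
    """Labelled 46x46 patches with split assignment and provenance.

    ``patches`` is ``(N, S, S, 3)`` uint8; ``labels`` holds class codes per
    :data:`CLASSES`; ``source_ids`` ties every patch (and each of its
    augmented descendants) to the annotation it came from, which is the unit
    at which train/val/test splits are assigned; ``provenance`` records the
    source image, centre and augmentation op per patch.
    """

    patches: np.ndarray
    labels: np.ndarray
    source_ids: np.ndarray
    split: np.ndarray
    provenance: pd.DataFrame
    skipped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.patches)
        if not (len(self.labels) == len(self.source_ids) == len(self.split)
                == len(self.provenance) == n):
            raise ValueError("inconsistent patch-set field lengths")
        if n and (self.patches.shape[1] != self.patches.shape[2]):
            raise ValueError("patches must be square")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def size(self) -> int:
        return self.patches.shape[1] if len(self) else PATCH_SIZE

    def subset(self, mask: np.ndarray) -> "PatchSet":
        return PatchSet(self.patches[mask], self.labels[mask],
                        self.source_ids[mask], self.split[mask],
                        self.provenance[mask].reset_index(drop=True))

    def for_split(self, name: str) -> "PatchSet":
        return self.subset(self.split == name)

    @staticmethod
    def concat(sets: list["PatchSet"]) -> "PatchSet":
        sets = [s for s in sets if len(s)]
        return PatchSet(
            np.concatenate([s.patches for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.source_ids for s in sets]),
            np.concatenate([s.split for s in sets]),
            pd.concat([s.provenance for s in sets], ignore_index=True),
            skipped=[x for s in sets for x in s.skipped])


def _empty_patchset(size: int = PATCH_SIZE) -> PatchSet:
    return PatchSet(np.empty((0, size, size, 3), np.uint8),
                    np.empty(0, np.int64), np.empty(0, np.int64),
                    np.empty(0, dtype=object),
                    pd.DataFrame(columns=["image", "x", "y", "augmentation"]))


def build_polyp_mask(annotations: pd.DataFrame, roi_shape: tuple[int, int],
                     disc_radius: int = 23) -> np.ndarray:
    """Union of discs around every annotated point (both classes), clipped.

    ``annotations`` needs ``x``/``y`` columns; points from all annotators
    contribute and overlaps are a plain union.  The default radius of half
    the patch size ties the mask extent to the classifier's footprint.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation set")
    mask = np.zeros(roi_shape, dtype=bool)
    h, w = roi_shape
    for x, y in zip(annotations["x"], annotations["y"]):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"annotation ({x}, {y}) outside the ROI")
        rr, cc = skdraw.disk((int(y), int(x)), disc_radius + 0.01, shape=roi_shape)
        mask[rr, cc] = True
    return mask


def extract_patches(frame: ImageFrame, annotations: pd.DataFrame,
                    size: int = PATCH_SIZE, image_id: str | None = None) -> PatchSet:
    """One patch per annotated point, centred on it.

    Points closer than ``size // 2`` to the border cannot carry a full patch;
    they are skipped and logged (and listed in ``result.skipped``) rather than
    padded, so the patch statistics stay honest.
    """
    half = size // 2
    h, w = frame.pixels.shape[:2]
    image_id = image_id if image_id is not None else str(frame.timestamp)
    patches, labels, sources, prov, skipped = [], [], [], [], []
    for idx, row in annotations.iterrows():
        x, y = int(row["x"]), int(row["y"])
        if not (half <= x < w - half + (size % 2) and half <= y < h - half + (size % 2)):
            logger.info("annotation (%d, %d) too close to the border; skipped", x, y)
            skipped.append((image_id, x, y))
            continue
        patches.append(frame.pixels[y - half:y - half + size, x - half:x - half + size])
        labels.append(ACTIVE if row["class"] == "active" else INACTIVE)
        sources.append(idx)
        prov.append((image_id, x, y, "original"))
    if not patches:
        ps = _empty_patchset(size)
        ps.skipped = skipped
        return ps
    return PatchSet(np.stack(patches), np.array(labels), np.array(sources),
                    np.full(len(patches), "", dtype=object),
                    pd.DataFrame(prov, columns=["image", "x", "y", "augmentation"]),
                    skipped=skipped)


def sample_background(frame: ImageFrame, polyp_mask: np.ndarray, n: int = 100,
                      seed: int = 0, size: int = PATCH_SIZE,
                      image_id: str | None = None,
                      source_offset: int = 1_000_000) -> PatchSet:
    """``n`` patches at random locations outside the polyp mask.

    Centres are drawn uniformly (without replacement) from the pixels where
    the mask is 0 and a full patch fits; fewer than ``n`` feasible locations
    is an error naming the shortfall.
    """
    half = size // 2
    h, w = frame.pixels.shape[:2]
    feasible = ~polyp_mask.copy()
    feasible[:half, :] = feasible[h - half:, :] = False
    feasible[:, :half] = feasible[:, w - half:] = False
    ys, xs = np.nonzero(feasible)
    if len(xs) < n:
        raise ValueError(
            f"only {len(xs)} feasible background centres for {n} requested")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(xs), size=n, replace=False)
    image_id = image_id if image_id is not None else str(frame.timestamp)
    patches, prov = [], []
    for i in pick:
        x, y = int(xs[i]), int(ys[i])
        patches.append(frame.pixels[y - half:y - half + size, x - half:x - half + size])
        prov.append((image_id, x, y, "original"))
    return PatchSet(np.stack(patches), np.full(n, BG),
                    source_offset + np.arange(n),
                    np.full(n, "", dtype=object),
                    pd.DataFrame(prov, columns=["image", "x", "y", "augmentation"]))


def augment_patches(patchset: PatchSet, noise_sd: float = 0.02 * 255,
                    seed: int = 0) -> PatchSet:
    """48-fold augmentation: {identity, flip} x {12 rotations} x {clean, noise}.

    Rotations step by 30 degrees with reflective border resampling (angle 0 is
    an exact copy); the Gaussian-noise variant defaults to a standard
    deviation of 2% of the dynamic range.  Labels, source ids and splits are
    inherited, and the augmentation op is recorded in the provenance, so the
    leakage guard in :func:`split_dataset` can be audited.
    """
    if len(patchset) == 0:
        return _empty_patchset(patchset.size)
    rng = np.random.default_rng(seed)
    out_patches, out_rows = [], []
    prov = patchset.provenance
    for i in range(len(patchset)):
        base = patchset.patches[i]
        img, x, y = prov.iloc[i][["image", "x", "y"]]
        for flip in (False, True):
            p = base[:, ::-1] if flip else base
            pf = p.astype(np.float32)
            for k in range(12):
                angle = 30.0 * k
                if k == 0:
                    rot = pf
                else:
                    rot = sktransform.rotate(pf, angle, mode="reflect",
                                             preserve_range=True)
                for noisy in (False, True):
                    if noisy:
                        out = rot + rng.normal(0.0, noise_sd, rot.shape)
                    else:
                        out = rot
                    out_patches.append(np.clip(out, 0, 255).astype(np.uint8))
                    out_rows.append((img, x, y,
                                     f"flip={int(flip)},rot={int(angle)},"
                                     f"noise={int(noisy)}"))
    reps = 48
    return PatchSet(np.stack(out_patches),
                    np.repeat(patchset.labels, reps),
                    np.repeat(patchset.source_ids, reps),
                    np.repeat(patchset.split, reps),
                    pd.DataFrame(out_rows, columns=["image", "x", "y", "augmentation"]))


def split_dataset(patchset: PatchSet, fractions: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> PatchSet:
    """Assign train/val/test splits at the source-annotation level.

    Sources (not patches) are shuffled and partitioned per class so each
    class appears in every split, and every augmented descendant of a source
    inherits its split — no augmented copy of a held-out patch can reach the
    training set.  Returns a new :class:`PatchSet`; the input is untouched.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    split = np.full(len(patchset), "", dtype=object)
    src = pd.DataFrame({"source": patchset.source_ids, "label": patchset.labels})
    for _, group in src.groupby("label"):
        sources = np.sort(group["source"].unique())
        sources = sources[rng.permutation(len(sources))]
        n = len(sources)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts = {
            "train": sources[:n_train],
            "val": sources[n_train:n_train + n_val],
            "test": sources[n_train + n_val:],
        }
        for name, ids in parts.items():
            split[np.isin(patchset.source_ids, ids)] = name
    return PatchSet(patchset.patches, patchset.labels, patchset.source_ids,
                    split, patchset.provenance, skipped=patchset.skipped)


@dataclass
class TrainSpec:
    """Training hyperparameters for the patch classifier."""

    epochs: int = 4
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0


@dataclass
class Classifier:
    """A trained patch classifier: P(active) in [0, 1] per patch.

    Wraps the LeNet with its normalisation convention and training metadata
    (seed, epochs, per-split accuracy).  After training the weights are
    frozen: the same patch always maps to the same likelihood.
    """

    net: LeNet5
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """Per-class probabilities for (N, S, S, 3) uint8 patches."""
        return self.net.predict_proba(patches)

    def activity_likelihood(self, patches: np.ndarray) -> np.ndarray:
        """P(active) per patch — the network output C(p)."""
        return self.predict_proba(patches)[:, ACTIVE]

    def save(self, path) -> None:
        """Weights as ``.npz`` with a JSON metadata sidecar."""
        path = Path(path)
        np.savez(path, **self.net.state_dict())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"classes": list(CLASSES), "input_size": self.net.input_size,
             "in_scale": self.net.in_scale, "in_offset": self.net.in_offset,
             **self.metadata}, indent=2, default=str))

    @classmethod
    def load(cls, path) -> "Classifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = LeNet5(input_size=int(meta.get("input_size", PATCH_SIZE)),
                     n_classes=len(meta.get("classes", CLASSES)),
                     in_scale=float(meta.get("in_scale", 1.0)),
                     in_offset=float(meta.get("in_offset", 0.0)))
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            net.load_state_dict({k: z[k] for k in z.files})
        return cls(net, metadata=meta)


def train_classifier(patchset: PatchSet, spec: TrainSpec | None = None,
                     seed: int | None = None) -> Classifier:
    """Train the LeNet patch classifier on the 'train' split.

    Requires non-empty train and val splits with every class present in
    training.  Per-split accuracies (train/val/test) are evaluated after
    training and stored in the classifier metadata.
    """
    spec = spec or TrainSpec()
    if seed is not None:
        spec = TrainSpec(spec.epochs, spec.learning_rate, spec.batch_size, seed)
    train = patchset.for_split("train")
    val = patchset.for_split("val")
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and val splits must be non-empty")
    present = set(np.unique(train.labels))
    missing = [CLASSES[c] for c in sorted(set(np.unique(patchset.labels)) - present)]
    if missing:
        raise ValueError(f"class(es) absent from the training split: {missing}")

    net = LeNet5(input_size=patchset.size, n_classes=len(CLASSES), seed=spec.seed,
                 in_scale=1.0 / 255.0, in_offset=-0.5)
    history = net.fit(train.patches, train.labels, val.patches, val.labels,
                      epochs=spec.epochs, lr=spec.learning_rate,
                      batch_size=spec.batch_size, seed=spec.seed)
    clf = Classifier(net)
    accuracies = {}
    for name in ("train", "val", "test"):
        part = patchset.for_split(name)
        if len(part):
            accuracies[name] = net.accuracy(part.patches, part.labels)
    clf.metadata = {"seed": spec.seed, "epochs": spec.epochs,
                    "learning_rate": spec.learning_rate,
                    "batch_size": spec.batch_size,
                    "history": history, "accuracy": accuracies}
    return clf


def classify_pixels(frame: ImageFrame, polyp_mask: np.ndarray,
                    classifier: Classifier, stride: int = 2,
                    batch: int = 512) -> np.ndarray:
    """Activity likelihood for every pixel of the polyp mask.

    Each masked pixel is classified from the 46x46 patch centred on it (the
    frame is reflect-padded so border pixels have full patches).  With
    ``stride > 1`` only a subgrid is evaluated and the remaining masked
    pixels take the value of their nearest evaluated neighbour — a large
    speed-up at a small, configurable cost in gamma.  Returns a float raster
    with NaN outside the mask.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not polyp_mask.any():
        raise ValueError("empty polyp mask")
    if polyp_mask.shape != frame.pixels.shape[:2]:
        raise ValueError("mask and frame dimensions differ")
    size = classifier.net.input_size
    half = size // 2
    padded = np.pad(frame.pixels, ((half, half), (half, half), (0, 0)),
                    mode="reflect")
    eval_mask = polyp_mask.copy()
    if stride > 1:
        sub = np.zeros_like(polyp_mask)
        sub[::stride, ::stride] = True
        if (polyp_mask & sub).any():
            eval_mask = polyp_mask & sub
    ys, xs = np.nonzero(eval_mask)
    lik_at = np.empty(len(ys), dtype=np.float32)
    for i in range(0, len(ys), batch):
        yy, xx = ys[i:i + batch], xs[i:i + batch]
        tiles = np.stack([padded[y:y + size, x:x + size] for y, x in zip(yy, xx)])
        lik_at[i:i + batch] = classifier.activity_likelihood(tiles)
    lik = np.full(polyp_mask.shape, np.nan, dtype=np.float32)
    lik[ys, xs] = lik_at
    if stride > 1:
        _, (iy, ix) = ndimage.distance_transform_edt(~eval_mask, return_indices=True)
        filled = lik[iy, ix]
        lik = np.where(polyp_mask, filled, np.nan)
    return lik


def polyp_activity(active: np.ndarray, polyp_mask: np.ndarray) -> float:
    """The activity fraction gamma = |active & mask| / |mask|.

    ``active`` is the boolean activity map (threshold a likelihood raster at
    0.5 to get it); only pixels inside the polyp mask count.
    """
    if active.shape != polyp_mask.shape:
        raise ValueError("raster and mask must be congruent")
    n_mask = int(polyp_mask.sum())
    if n_mask == 0:
        raise ValueError("empty polyp mask")
    return float(np.logical_and(active, polyp_mask).sum() / n_mask)


def activity_series(frames: list[ImageFrame], polyp_mask: np.ndarray,
                    classifier: Classifier, stride: int = 2,
                    threshold: float = 0.5) -> pd.DataFrame:
    """gamma_t over a time-ordered, registered frame sequence.

    Returns columns ``timestamp, gamma, n_masked_px``; frames that fail are
    listed in ``result.attrs['failed']`` and appear as gaps (absent rows).
    """
    rows, failed = [], []
    order = np.argsort([f.timestamp.value for f in frames])
    for i in order:
        frame = frames[i]
        try:
            lik = classify_pixels(frame, polyp_mask, classifier, stride=stride)
            gamma = polyp_activity(lik >= threshold, polyp_mask)
        except ValueError as exc:
            logger.warning("frame %s excluded: %s", frame.timestamp, exc)
            failed.append((frame.timestamp, str(exc)))
            continue
        rows.append((frame.timestamp, gamma, int(polyp_mask.sum())))
    if not rows:
        raise RuntimeError("every frame failed; no activity series computed")
    df = pd.DataFrame(rows, columns=["timestamp", "gamma", "n_masked_px"])
    df.attrs["failed"] = failed
    return df


def observer_agreement(a: pd.DataFrame, b: pd.DataFrame,
                       match_radius: float = 23.0) -> float:
    """Agreement between two point-annotation sets on the same images.

    Points are greedily matched nearest-first within ``match_radius`` (per
    image); agreement is the number of matched pairs with equal class over
    the number of matched pairs plus all unmatched points, so both missed
    detections and label conflicts count as disagreement.
    """
    if len(a) == 0 and len(b) == 0:
        raise ValueError("both annotation sets are empty")
    n_match_eq = n_match = n_unmatched = 0
    images = sorted(set(a["image"]) | set(b["image"]))
    for img in images:
        pa = a[a["image"] == img].reset_index(drop=True)
        pb = b[b["image"] == img].reset_index(drop=True)
        if len(pa) == 0 or len(pb) == 0:
            n_unmatched += len(pa) + len(pb)
            continue
        d = np.hypot(pa["x"].to_numpy()[:, None] - pb["x"].to_numpy()[None, :],
                     pa["y"].to_numpy()[:, None] - pb["y"].to_numpy()[None, :])
        pairs = np.argwhere(d <= match_radius)
        order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
        used_a, used_b = set(), set()
        for i, j in pairs[order]:
            if i in used_a or j in used_b:
                continue
            used_a.add(i)
            used_b.add(j)
            n_match += 1
            if pa.loc[i, "class"] == pb.loc[j, "class"]:
                n_match_eq += 1
        n_unmatched += (len(pa) - len(used_a)) + (len(pb) - len(used_b))
    if n_match + n_unmatched == 0:
        raise ValueError("no points to compare")
    return n_match_eq / (n_match + n_unmatched)


def manual_gamma(annotations: pd.DataFrame, polyp_mask: np.ndarray | None = None) -> float:
    """Count-based activity from annotations: fraction of points marked active.

    With a mask given, only points inside it contribute.  This is the manual
    counterpart that gamma_t is rank-correlated against in the accuracy
    protocol.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation set")
    pts = annotations
    if polyp_mask is not None:
        inside = [bool(polyp_mask[int(y), int(x)])
                  for x, y in zip(pts["x"], pts["y"])]
        pts = pts[np.asarray(inside, dtype=bool)]
        if len(pts) == 0:
            raise ValueError("no annotations inside the mask")
    return float((pts["class"] == "active").mean())
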