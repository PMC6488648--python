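"""End-to-end orchestration: one config in, a reproducible run directory out.

A run executes synth (optional) -> colour series -> polyp activity -> series
alignment -> wavelet analysis, persisting every intermediate under the output
directory so stages communicate only through artifacts on disk.  The config
fixes every seed and every stage parameter; the run report records per-stage
counts, accuracies, the correlation table and the config hash, so identical
configs reproduce identical reports.

Input modes (exactly one):

- ``synth``: generate a synthetic sequence + annotations + sensors and run the
  full chain against known ground truth;
- ``inputs`` with an image directory: run the full chain on real frames;
- ``inputs`` with pre-extracted series tables (the deposited data-matrix
  layout: one ``timestamp,value`` table per series): run alignment and
  wavelet analysis only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from coralwatch import align as al
from coralwatch import colorseries as cs
from coralwatch import polyps as pl
from coralwatch import synth as sy
from coralwatch import wavelets as wv
from coralwatch.align import IrregularSeries
from coralwatch.imagery import ImageFrame, load_frames, save_frames

__all__ = [
    "ConfigError",
    "DataError",
    "PipelineConfig",
    "RunReport",
    "read_sensor_table",
    "read_series_csv",
    "recovery_benchmark_config",
    "run_pipeline",
    "summarize_accuracy",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


class DataError(RuntimeError):
    """Input data missing, malformed or inconsistent."""


_DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "coralwatch_run",
    "synth": None,
    "inputs": None,
    "color": {
        "gains": [1.0, 1.0, 1.0],
        "som_shape": [8, 8],
        "seed_pixels_per_class": 2500,
        "fail_threshold": 0.2,
    },
    "polyps": {
        "disc_radius": 23,
        "stride": 4,
        "n_background": 100,
        "epochs": 3,
        "learning_rate": 1e-3,
        "batch_size": 128,
        "threshold": 0.5,
    },
    "align": {"step_hours": 1.0, "max_gap_hours": 24.0},
    "wavelets": {"dj": 1.0 / 12.0, "max_period": None, "omega0": 6.0,
                 "coherence_pair": None, "n_surrogates": 0},
}

_SYNTH_DEFAULTS: dict = {
    "n_frames": 100,
    "shape": [512, 512],
    "n_polyps": 30,
    "color_start": 0.0,
    "color_end": 15.0,
    "activity_base": 0.5,
    "activity_diel_amplitude": 0.25,
    "activity_ramp": None,   # [start, end] overrides the diel trajectory
    "jitter_sd": 1.0,
    "missing_fraction": 0.05,
    "n_annotated": 13,
    "annotators": ["expert1", "expert2", "expert3"],
    "annotator_error_rate": 0.0,
    "position_sd": 0.0,
    "start": "2015-04-03 00:00:00",
    "sensors": {
        "temperature": {
            "trend": [[0.0, 7.2], [2400.0, 8.5]],
            "components": [[12.4, 0.05, 0.0]],
            "ar1": 0.6, "noise_sd": 0.05, "interval_min": 60.0,
        },
        "depth": {
            "trend": [[0.0, 255.0]],
            "components": [[12.4, 0.8, 0.0]],
            "ar1": 0.3, "noise_sd": 0.05, "interval_min": 60.0,
        },
        "current_north": {
            "components": [[24.0, 0.08, 0.0], [707.0, 0.03, 1.0]],
            "ar1": 0.5, "noise_sd": 0.02, "interval_min": 10.0,
        },
    },
}


def recovery_benchmark_config(seed: int, output_dir: str) -> "PipelineConfig":
    """The standard synthetic parameter-recovery benchmark.

    A 100-frame hourly sequence of 512x512 frames over a 30-polyp colony,
    with an injected tissue-redness ramp (a* 0 -> 15), an activity ramp
    (0.1 -> 0.9), one-pixel camera jitter and 5% dropped frames; 13 frames
    annotated by three synthetic experts.  The chain recovers both ramps and
    reports classifier accuracy, so it closes the loop from rendering to
    extraction under one config.
    """
    return PipelineConfig({
        "seed": int(seed),
        "output_dir": output_dir,
        "synth": {"n_frames": 100, "shape": [512, 512], "n_polyps": 30,
                  "n_annotated": 13, "missing_fraction": 0.05,
                  "color_start": 0.0, "color_end": 15.0,
                  "activity_ramp": [0.1, 0.9], "jitter_sd": 1.0},
        "polyps": {"epochs": 2, "stride": 5},
    })


def _merge(defaults: dict, override: dict | None) -> dict:
    out = dict(defaults)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for modes)."""

    raw: dict

    def __post_init__(self) -> None:
        cfg = _merge(_DEFAULTS, self.raw)
        if (cfg["synth"] is None) == (cfg["inputs"] is None):
            raise ConfigError("exactly one of 'synth' and 'inputs' must be set")
        if cfg["synth"] is not None:
            cfg["synth"] = _merge(_SYNTH_DEFAULTS, cfg["synth"])
        self.cfg = cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        return cls(raw)

    def __getitem__(self, key):
        return self.cfg[key]

    def hash(self) -> str:
        blob = json.dumps(self.cfg, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """What a pipeline run produced, in reproducible summary form."""

    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    accuracies: dict = field(default_factory=dict)
    correlations: list = field(default_factory=list)
    spectral_peaks: dict = field(default_factory=dict)
    ground_truth_recovery: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


# ---------------------------------------------------------------------------
# table IO


def read_sensor_table(path, column_map: dict[str, str] | None = None,
                      timestamp_column: str = "timestamp") -> dict[str, IrregularSeries]:
    """Read a sensor CSV into one :class:`IrregularSeries` per mapped column.

    Dialect quirks of instrument exports are tolerated: semicolon delimiters
    are sniffed from the header (decimal commas are then assumed) and the
    choice is logged.  Non-numeric cells and blank cells become gaps, counted
    in the log; a duplicated timestamp is an error naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"sensor table {path} does not exist")
    header = path.open().readline()
    if ";" in header and "," not in header.split(";")[0]:
        df = pd.read_csv(path, sep=";", decimal=",")
        logger.info("%s: semicolon/decimal-comma dialect", path.name)
    else:
        df = pd.read_csv(path)
    if timestamp_column not in df.columns:
        raise DataError(f"{path}: no timestamp column {timestamp_column!r}")
    try:
        ts = pd.to_datetime(df[timestamp_column], utc=True,
                            format="mixed").dt.tz_localize(None)
    except (ValueError, TypeError):
        ts = pd.to_datetime(df[timestamp_column], unit="s")  # epoch seconds
    dup = ts.duplicated()
    if dup.any():
        row = int(np.argmax(dup.to_numpy()))
        raise DataError(f"{path}: duplicated timestamp {ts.iloc[row]} at row {row}")
    order = np.argsort(ts.to_numpy())
    ts = ts.iloc[order]
    df = df.iloc[order]
    if column_map is None:
        column_map = {c: c for c in df.columns if c != timestamp_column}
    out = {}
    for col, name in column_map.items():
        if col not in df.columns:
            raise DataError(f"{path}: no column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(vals)
        n_gap = int((~keep).sum())
        if n_gap:
            logger.info("%s/%s: %d non-numeric or blank cells become gaps",
                        path.name, col, n_gap)
        if keep.sum() == 0:
            raise DataError(f"{path}: column {col!r} has no numeric values")
        out[name] = IrregularSeries(pd.DatetimeIndex(ts[keep]), vals[keep], name=name)
    return out


def read_series_csv(path, value_column: str | None = None,
                    name: str = "") -> IrregularSeries:
    """Read a single ``timestamp,value`` series table."""
    tables = read_sensor_table(path)
    if value_column is None:
        if len(tables) != 1:
            raise DataError(f"{path}: specify value_column among {list(tables)}")
        series = next(iter(tables.values()))
    else:
        if value_column not in tables:
            raise DataError(f"{path}: no column {value_column!r}")
        series = tables[value_column]
    series.name = name or series.name
    return series


def _write_series(series: IrregularSeries, path: Path) -> None:
    pd.DataFrame({"timestamp": series.timestamps, "value": series.values}
                 ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stages


def stage_synth(config: PipelineConfig, outdir: Path) -> dict:
    """Generate and persist the synthetic scene, annotations and sensors."""
    scfg = config["synth"]
    seed = int(config["seed"])
    n = int(scfg["n_frames"])
    t_hours = np.arange(n, dtype=float)
    colors = np.linspace(float(scfg["color_start"]), float(scfg["color_end"]), n)
    if scfg["activity_ramp"] is not None:
        a0, a1 = scfg["activity_ramp"]
        activity = np.linspace(float(a0), float(a1), n)
    else:
        activity = (float(scfg["activity_base"])
                    + float(scfg["activity_diel_amplitude"])
                    * np.sin(2 * np.pi * t_hours / 24.0))
    activity = np.clip(activity, 0.02, 0.98)
    frames, truths = sy.generate_sequence(
        n, colors, activity, jitter_sd=float(scfg["jitter_sd"]),
        missing_fraction=float(scfg["missing_fraction"]), seed=seed,
        shape=tuple(scfg["shape"]), n_polyps=int(scfg["n_polyps"]),
        start=scfg["start"])
    frame_dir = outdir / "frames"
    save_frames(frames, frame_dir)

    # per-frame ground truth table
    truth_df = pd.DataFrame({
        "timestamp": [f.timestamp for f in frames],
        "redness_a": [t.redness_a for t in truths],
        "active_fraction": [t.active_fraction for t in truths],
    })
    truth_df.to_csv(outdir / "truth.csv", index=False)

    # annotated frames are spread over the whole record, the way expert
    # annotation campaigns sample it — training patches must cover the
    # record's colour drift or the classifier faces covariate shift
    n_ann = min(int(scfg["n_annotated"]), len(frames))
    ann_idx = np.unique(np.linspace(0, len(frames) - 1, n_ann).round().astype(int))
    ann_ids = [frames[i].timestamp.isoformat() for i in ann_idx]
    annotations = sy.generate_annotations(
        [truths[i] for i in ann_idx],
        annotator_error_rate=float(scfg["annotator_error_rate"]),
        position_sd=float(scfg["position_sd"]), seed=seed + 1,
        annotators=tuple(scfg["annotators"]), image_ids=ann_ids)
    annotations.to_csv(outdir / "annotations.csv", index=False)

    # seed pixels for the coral/background labeller, from the reference truth
    rng = np.random.default_rng(seed + 2)
    n_seed = int(config["color"]["seed_pixels_per_class"])
    region = truths[0].coral_region
    rows = []
    for cls, where in (("coral", region), ("background", ~region)):
        idx = np.argwhere(where)
        pick = idx[rng.choice(len(idx), min(n_seed, len(idx)), replace=False)]
        rows += [(ann_ids[0], int(x), int(y), cls) for y, x in pick]
    pd.DataFrame(rows, columns=["image", "x", "y", "class"]
                 ).to_csv(outdir / "coral_seed.csv", index=False)

    sensor_dir = outdir / "sensors"
    sensor_dir.mkdir(exist_ok=True)
    span_h = float(n)
    for i, (name, sspec) in enumerate(sorted(scfg["sensors"].items())):
        spec = sy.SignalSpec(
            components=[tuple(c) for c in sspec.get("components", [])],
            trend_anchors=[tuple(a) for a in sspec.get("trend", [])],
            ar1_coefficient=float(sspec.get("ar1", 0.0)),
            noise_sd=float(sspec.get("noise_sd", 0.0)),
            gaps=[tuple(g) for g in sspec.get("gaps", [])],
            sampling_interval_minutes=float(sspec.get("interval_min", 60.0)))
        series = sy.generate_sensor_series(spec, span_h, seed=seed + 10 + i,
                                           start=scfg["start"], name=name)
        _write_series(series, sensor_dir / f"{name}.csv")
    return {"n_frames": len(frames), "n_annotations": len(annotations),
            "n_sensors": len(scfg["sensors"])}


def _train_labeller(frames: list[ImageFrame], seed_df: pd.DataFrame,
                    config: PipelineConfig) -> cs.SOMLabeller:
    ccfg = config["color"]
    by_ts = {f.timestamp.isoformat(): f for f in frames}
    feats_cache: dict[str, np.ndarray] = {}
    x_list, y_list = [], []
    for image, group in seed_df.groupby("image"):
        if image not in by_ts:
            raise DataError(f"seed pixels refer to unknown image {image!r}")
        if image not in feats_cache:
            feats_cache[image] = cs.extract_gabor_features(by_ts[image])
        feats = feats_cache[image]
        x_list.append(feats[group["y"].to_numpy(), group["x"].to_numpy()])
        y_list.append((group["class"] == "coral").to_numpy().astype(int))
    return cs.train_pixel_labeller(
        np.concatenate(x_list), np.concatenate(y_list),
        som_shape=tuple(ccfg["som_shape"]), seed=int(config["seed"]) + 3)


def stage_color(config: PipelineConfig, outdir: Path) -> dict:
    """Train the pixel labeller and compute/persist xi_t."""
    frames = load_frames(outdir / "frames")
    if not frames:
        raise DataError("no frames found; run the synth stage or point "
                        "'inputs' at an image directory")
    seed_path = outdir / "coral_seed.csv"
    if not seed_path.exists():
        raise DataError("no coral_seed.csv with labelled seed pixels")
    labeller = _train_labeller(frames, pd.read_csv(seed_path), config)
    gains = tuple(config["color"]["gains"])
    xi = cs.color_series(frames, labeller, gains=gains,
                         fail_threshold=float(config["color"]["fail_threshold"]))
    cdir = outdir / "color"
    cdir.mkdir(exist_ok=True)
    xi.to_csv(cdir / "xi.csv", index=False)
    return {"n_points": len(xi), "n_failed": len(xi.attrs["failed"])}


def stage_polyps(config: PipelineConfig, outdir: Path) -> dict:
    """Mask, patches, classifier training and gamma_t."""
    pcfg = config["polyps"]
    seed = int(config["seed"])
    frames = load_frames(outdir / "frames")
    ann_path = outdir / "annotations.csv"
    if not frames or not ann_path.exists():
        raise DataError("polyp stage needs frames and annotations.csv")
    annotations = pd.read_csv(ann_path)
    annotations.index = np.arange(len(annotations))

    reference = frames[0]
    registered = [reference]
    for f in frames[1:]:
        aligned, _ = cs.register_frame(f, reference)
        registered.append(aligned)
    by_ts = {f.timestamp.isoformat(): f for f in registered}

    mask = pl.build_polyp_mask(annotations, reference.pixels.shape[:2],
                               disc_radius=int(pcfg["disc_radius"]))
    sets = []
    for image, group in annotations.groupby("image"):
        if image not in by_ts:
            raise DataError(f"annotations refer to unknown image {image!r}")
        sets.append(pl.extract_patches(by_ts[image], group, image_id=image))
    sets.append(pl.sample_background(reference, mask,
                                     n=int(pcfg["n_background"]), seed=seed + 4))
    patches = pl.PatchSet.concat(sets)
    patches = pl.split_dataset(patches, seed=seed + 5)
    augmented = pl.augment_patches(patches, seed=seed + 6)
    clf = pl.train_classifier(augmented, pl.TrainSpec(
        epochs=int(pcfg["epochs"]), learning_rate=float(pcfg["learning_rate"]),
        batch_size=int(pcfg["batch_size"]), seed=seed + 7))

    pdir = outdir / "polyps"
    pdir.mkdir(exist_ok=True)
    clf.save(pdir / "classifier.npz")
    gamma = pl.activity_series(registered, mask, clf,
                               stride=int(pcfg["stride"]),
                               threshold=float(pcfg["threshold"]))
    gamma.to_csv(pdir / "gamma.csv", index=False)

    acc = summarize_accuracy(clf, annotations, gamma, mask)
    acc.to_csv(pdir / "accuracy.csv", index=False)
    return {"n_patches": len(patches), "n_augmented": len(augmented),
            "n_points": len(gamma), "n_failed": len(gamma.attrs["failed"]),
            "accuracy": clf.metadata["accuracy"]}


def summarize_accuracy(classifier: pl.Classifier, annotations: pd.DataFrame,
                       gamma: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """The accuracy surface: per-split accuracy, observer agreement, and the
    rank correlation of gamma_t against the count-based manual activity."""
    rows = [("classifier_accuracy_" + k, v)
            for k, v in classifier.metadata["accuracy"].items()]
    annotators = sorted(annotations["annotator"].unique())
    if len(annotators) >= 2:
        agreements = []
        for i in range(len(annotators)):
            for j in range(i + 1, len(annotators)):
                a = annotations[annotations["annotator"] == annotators[i]]
                b = annotations[annotations["annotator"] == annotators[j]]
                agreements.append(pl.observer_agreement(a, b))
        rows.append(("inter_observer_agreement", float(np.mean(agreements))))
    manual, auto = [], []
    g_by_ts = {pd.Timestamp(t).isoformat(): g
               for t, g in zip(gamma["timestamp"], gamma["gamma"])}
    for image, group in annotations.groupby("image"):
        if image in g_by_ts:
            manual.append(pl.manual_gamma(group))
            auto.append(g_by_ts[image])
    if len(manual) >= 3 and np.ptp(manual) > 0 and np.ptp(auto) > 0:
        r, _ = al.correlation(auto, manual, method="spearman")
        rows.append(("gamma_vs_manual_spearman", r))
    return pd.DataFrame(rows, columns=["metric", "value"])


def _load_image_series(config: PipelineConfig, outdir: Path
                       ) -> tuple[IrregularSeries | None, IrregularSeries | None]:
    gamma = xi = None
    gpath = outdir / "polyps" / "gamma.csv"
    xpath = outdir / "color" / "xi.csv"
    inputs = config["inputs"] or {}
    if gpath.exists():
        gamma = read_series_csv(gpath, value_column="gamma", name="gamma")
    elif inputs.get("gamma_csv"):
        gamma = read_series_csv(inputs["gamma_csv"],
                                value_column=inputs.get("gamma_column"), name="gamma")
    if xpath.exists():
        xi = read_series_csv(xpath, value_column="xi_a", name="xi")
    elif inputs.get("xi_csv"):
        xi = read_series_csv(inputs["xi_csv"],
                             value_column=inputs.get("xi_column"), name="xi")
    return gamma, xi


def _load_sensors(config: PipelineConfig, outdir: Path) -> dict[str, IrregularSeries]:
    sensors: dict[str, IrregularSeries] = {}
    sdir = outdir / "sensors"
    if sdir.exists():
        for path in sorted(sdir.glob("*.csv")):
            sensors[path.stem] = read_series_csv(path, name=path.stem)
    inputs = config["inputs"] or {}
    for name, spec in (inputs.get("sensors") or {}).items():
        if isinstance(spec, str):
            sensors[name] = read_series_csv(spec, name=name)
        else:
            sensors[name] = read_series_csv(spec["path"],
                                            value_column=spec.get("column"),
                                            name=name)
    return sensors


def stage_align(config: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    """Hourly grids, daily averages and the pairwise correlation table."""
    acfg = config["align"]
    gamma, xi = _load_image_series(config, outdir)
    sensors = _load_sensors(config, outdir)
    if gamma is None and xi is None:
        raise DataError("nothing to align: no image-derived series found")
    adir = outdir / "aligned"
    adir.mkdir(exist_ok=True)
    image_series = {n: s for n, s in (("gamma", gamma), ("xi", xi)) if s is not None}
    step = float(acfg["step_hours"])
    guard = acfg["max_gap_hours"]
    guard = None if guard in (None, "none") else float(guard)

    for name, series in {**image_series, **sensors}.items():
        hourly = al.to_hourly(series, step_hours=step, max_gap_hours=guard)
        pd.DataFrame({"timestamp": hourly.timestamps, "value": hourly.values}
                     ).to_csv(adir / f"{name}_hourly.csv", index=False)

    correlations = []
    for yname, yser in image_series.items():
        for xname, xser in sensors.items():
            paired = al.pair_series(yser, xser, max_gap_hours=guard)
            paired.to_csv(adir / f"paired_{yname}_{xname}.csv", index=False)
            dy = al.daily_average(yser)
            dx = al.daily_average(xser)
            days = dy.timestamps.intersection(dx.timestamps)
            for method in ("pearson", "spearman"):
                try:
                    r_h, n_h = al.correlation(paired["y"], paired["x"], method)
                    correlations.append((yname, xname, "hourly", method, r_h, n_h))
                except (al.UndefinedCorrelationError, ValueError):
                    pass
                try:
                    yv = dy.to_pandas().loc[days].to_numpy()
                    xv = dx.to_pandas().loc[days].to_numpy()
                    r_d, n_d = al.correlation(yv, xv, method)
                    correlations.append((yname, xname, "daily", method, r_d, n_d))
                except (al.UndefinedCorrelationError, ValueError):
                    pass
    corr_df = pd.DataFrame(correlations,
                           columns=["image_series", "sensor", "resolution",
                                    "method", "r", "n"])
    corr_df.to_csv(adir / "correlations.csv", index=False)
    return ({"n_series_aligned": len(image_series) + len(sensors),
             "n_correlations": len(corr_df)},
            correlations)


def stage_wavelets(config: PipelineConfig, outdir: Path) -> dict:
    """Global spectra for every series and coherence for the configured pair.

    The spectral stage interpolates across *all* gaps (no max-gap guard): the
    transform needs a gapless grid, and the guard exists to protect the
    correlation tables, not this stage.
    """
    wcfg = config["wavelets"]
    gamma, xi = _load_image_series(config, outdir)
    sensors = _load_sensors(config, outdir)
    series = {n: s for n, s in (("gamma", gamma), ("xi", xi)) if s is not None}
    series.update(sensors)
    if not series:
        raise DataError("no series for the wavelet stage")
    wdir = outdir / "wavelets"
    wdir.mkdir(exist_ok=True)
    dj = float(wcfg["dj"])
    peaks = {}
    hourly_cache = {}
    for name, ser in series.items():
        hourly = al.to_hourly(ser, max_gap_hours=None)
        hourly_cache[name] = hourly
        spec = wv.cwt_morlet(hourly, dj=dj,
                             max_period=wcfg["max_period"],
                             omega0=float(wcfg["omega0"]))
        wv.power_significance(spec, wv.fit_ar1(hourly.values))
        periods, curve = wv.global_spectrum(spec)
        pd.DataFrame({"period_h": periods, "power": curve}
                     ).to_csv(wdir / f"global_{name}.csv", index=False)
        peaks[name] = float(periods[int(np.argmax(curve))])
        if name in ("gamma", "xi"):
            wv.save_spectrum(spec, wdir / f"power_{name}")

    pair = wcfg["coherence_pair"]
    auto_pair = pair is None
    if auto_pair and "gamma" in series and sensors:
        pair = ["gamma", sorted(sensors)[0]]
    if pair is not None:
        xn, yn = pair
        hx = hourly_cache.get(xn) or al.to_hourly(series[xn], max_gap_hours=None)
        hy = hourly_cache.get(yn) or al.to_hourly(series[yn], max_gap_hours=None)
        # the coherence needs both series on one grid: clip to the overlap
        common = hx.timestamps.intersection(hy.timestamps)
        if len(common) < 64:
            if auto_pair:
                logger.info("record too short for a coherence analysis; skipped")
                return {"global_peaks_h": peaks}
            raise DataError(f"coherence pair {xn}/{yn}: insufficient overlap")
        gx = hx.to_pandas().loc[common]
        gy = hy.to_pandas().loc[common]
        res = wv.wavelet_coherence(
            al.RegularSeries(common[0], hx.step_hours, gx.to_numpy(), name=xn),
            al.RegularSeries(common[0], hy.step_hours, gy.to_numpy(), name=yn),
            dj=dj, max_period=wcfg["max_period"], omega0=float(wcfg["omega0"]))
        if int(wcfg["n_surrogates"]) >= 100:
            wv.coherence_significance(gx.to_numpy(), gy.to_numpy(),
                                      n_surrogates=int(wcfg["n_surrogates"]),
                                      seed=int(config["seed"]) + 20,
                                      dj=dj, max_period=wcfg["max_period"],
                                      result=res)
        np.savetxt(wdir / f"coherence_{xn}_{yn}.csv", res.coherence,
                   delimiter=",")
        np.savetxt(wdir / f"phase_{xn}_{yn}.csv", res.phase, delimiter=",")
        header = {
            "pair": [xn, yn], "dt_hours": res.dt_hours,
            "periods_h": res.periods.tolist(),
            "times": [t.isoformat() for t in res.times],
            "coi_periods_h": res.coi_periods.tolist(),
            "omega0": float(wcfg["omega0"]), "dj": dj,
        }
        (wdir / f"coherence_{xn}_{yn}.json").write_text(
            json.dumps(header, indent=2))
        sa_periods, sa_curve = wv.scale_averaged_coherence(res)
        pd.DataFrame({"period_h": sa_periods, "coherence": sa_curve}
                     ).to_csv(wdir / f"scale_avg_coherence_{xn}_{yn}.csv",
                              index=False)
    return {"global_peaks_h": peaks}


def run_pipeline(config: PipelineConfig | dict, output_dir=None) -> RunReport:
    """Execute every applicable stage and write ``report.json``.

    Stage failures abort with a stage-named diagnostic; partial outputs remain
    in the run directory.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    outdir = Path(output_dir if output_dir is not None else config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), seed=int(config["seed"]))

    stages: list[tuple[str, callable]] = []
    has_images = config["synth"] is not None or bool(
        (config["inputs"] or {}).get("images_dir"))
    if config["synth"] is not None:
        stages.append(("synth", stage_synth))
    elif has_images:
        stages.append(("ingest", _stage_ingest))
    if has_images:
        stages.append(("color", stage_color))
        stages.append(("polyps", stage_polyps))
    stages.append(("align", None))      # handled specially below
    stages.append(("wavelets", stage_wavelets))

    for name, fn in stages:
        try:
            if name == "align":
                counts, correlations = stage_align(config, outdir)
                report.correlations = correlations
            else:
                counts = fn(config, outdir)
            logger.info("stage %s: %s", name, counts)
        except (ConfigError, DataError):
            raise
        except Exception as exc:
            raise DataError(f"stage {name!r} failed: {exc}") from exc
        if name == "polyps":
            report.accuracies = counts.pop("accuracy", {})
        if name == "wavelets":
            report.spectral_peaks = counts.pop("global_peaks_h", {})
        report.counts[name] = counts

    if config["synth"] is not None:
        report.ground_truth_recovery = _ground_truth_recovery(outdir)
    report.artifacts = sorted(
        [str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()]
        + ["report.json"])
    report.to_json(outdir / "report.json")
    return report


def _stage_ingest(config: PipelineConfig, outdir: Path) -> dict:
    """Copy-in mode for real inputs: frames dir, annotations, seed pixels."""
    import shutil

    inputs = config["inputs"]
    frames = load_frames(inputs["images_dir"])
    if not frames:
        raise DataError(f"no frames under {inputs['images_dir']}")
    save_frames(frames, outdir / "frames")
    for key, dest in (("annotations_csv", "annotations.csv"),
                      ("coral_seed_csv", "coral_seed.csv")):
        if inputs.get(key):
            shutil.copy(inputs[key], outdir / dest)
    return {"n_frames": len(frames)}


def _ground_truth_recovery(outdir: Path) -> dict:
    """Score the recovered series against the injected trajectories."""
    truth = pd.read_csv(outdir / "truth.csv", parse_dates=["timestamp"])
    out = {}
    xi_path = outdir / "color" / "xi.csv"
    if xi_path.exists():
        xi = pd.read_csv(xi_path, parse_dates=["timestamp"])
        merged = truth.merge(xi, on="timestamp")
        if len(merged) >= 3:
            r, n = al.correlation(merged["xi_a"], merged["redness_a"], "pearson")
            out["xi_vs_truth_pearson"] = {"r": r, "n": n}
    g_path = outdir / "polyps" / "gamma.csv"
    if g_path.exists():
        g = pd.read_csv(g_path, parse_dates=["timestamp"])
        merged = truth.merge(g, on="timestamp")
        if len(merged) >= 3 and np.ptp(merged["active_fraction"]) > 0:
            r, n = al.correlation(merged["gamma"], merged["active_fraction"],
                                  "spearman")
            out["gamma_vs_truth_spearman"] = {"r": r, "n": n}
    return out
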