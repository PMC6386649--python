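"""End-to-end studies on the synthetic paired-device benchmark.

Three orchestrated studies mirror the validation protocol:

1. **Agreement study** — per-axis Pearson correlation of the two devices'
   trimmed 1-second RMS series, for the shaker protocol (7 speeds per
   axis), the treadmill protocol (6 speeds) and every daily activity.
2. **Window sweep** — random-forest pooled accuracy for the five
   classification tasks at each feature window length.
3. **Full validation** — per device: the five classification tasks with
   all four model families at the headline window length, METs
   regression, importance rankings, and a between-device accuracy delta
   summary.

Every result is exactly reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import models as md
from . import signal_io as sio
from . import synthetic as syn
from .errors import LinkageError
from .labels import TASKS, build_mets_dataset, labels_for

logger = logging.getLogger("accelval")

HEADLINE_WINDOW = 16.0  # seconds; the length used for the headline models
TRIM_KEEP_SHAKER = 120.0  # middle 2 min of each 3-min shaker run
TRIM_KEEP_TREADMILL = 120.0  # middle 2 min of each 3-min treadmill run
TRIM_KEEP_ACTIVITY = 300.0  # middle 5 min of each 8-min daily activity

SWEEP_FOREST_SIZE = 100  # forest size for the window sweep (see methods note)


@dataclass
class ExperimentConfig:
    """Settings shared by the three studies."""

    benchmark: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    window_lengths: tuple[float, ...] = ft.DEFAULT_WINDOW_LENGTHS
    tasks: tuple[str, ...] = TASKS
    model_kinds: tuple[str, ...] = md.MODEL_KINDS
    headline_window: float = HEADLINE_WINDOW
    seed: int = 1

    def __post_init__(self):
        if not self.tasks or not self.window_lengths:
            raise ValueError("need at least one task and one window length")


def _log(msg: str):
    logger.info(msg)


def trim_keep(rec: sio.AccelRecording, keep: float) -> sio.AccelRecording:
    """Trim to the centered ``keep`` seconds, capped at the full duration."""
    if keep >= rec.duration:
        return rec
    return sio.trim_middle(rec, keep)


def _paired_rms(
    truth: sio.AccelRecording,
    devices,
    seed: int,
    keep: float,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-axis trimmed 1-s RMS values for each device recording of a truth signal."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for d_idx, profile in enumerate(devices):
        rec = syn.record_with_device(truth, profile, seed=seed + 7919 * d_idx)
        rec = trim_keep(rec, keep)
        out[profile.name] = {
            axis: sio.rms_per_second(rec, axis).values for axis in sio.AXES
        }
    return out


def _correlate_protocol(segments: list[dict], devices) -> list[dict]:
    """Per-axis correlation of concatenated paired RMS series over runs."""
    names = [d.name for d in devices]
    rows = []
    for axis in sio.AXES:
        a = np.concatenate([seg[names[0]][axis] for seg in segments])
        b = np.concatenate([seg[names[1]][axis] for seg in segments])
        rows.append(
            {"axis": axis, "r": sio.paired_correlation(a, b), "n_seconds": len(a)}
        )
    return rows


def shaker_agreement(config: ExperimentConfig, peak_amplitude: float = 1.0) -> pd.DataFrame:
    """Shaker protocol: 7 speeds x 3 shake axes, both devices, trimmed RMS.

    The shaker runs at constant displacement, so acceleration amplitude
    grows with the square of the speed setting; per data axis, the RMS
    series of all 21 runs are concatenated before correlating.
    """
    devices = config.benchmark.devices
    segments = []
    for a_idx, shake_axis in enumerate(sio.AXES):
        for f_idx, freq in enumerate(syn.SHAKER_FREQUENCIES):
            truth = simulate_shaker_run(freq, shake_axis, peak_amplitude)
            segments.append(
                _paired_rms(
                    truth, devices, seed=config.seed + 101 * a_idx + 13 * f_idx,
                    keep=TRIM_KEEP_SHAKER,
                )
            )
    rows = _correlate_protocol(segments, devices)
    return pd.DataFrame(
        [{"activity": "shaker", **row} for row in rows],
        columns=["activity", "axis", "r", "n_seconds"],
    )


def simulate_shaker_run(
    freq: float, shake_axis: str, peak_amplitude: float = 1.0, duration: float = 180.0
) -> sio.AccelRecording:
    return syn.simulate_shaker(
        freq, shake_axis, duration, amplitude=syn.shaker_amplitude(freq, peak=peak_amplitude)
    )


def treadmill_agreement(config: ExperimentConfig) -> pd.DataFrame:
    """Treadmill protocol: 6 speeds, 3 min each, both devices, trimmed RMS."""
    devices = config.benchmark.devices
    segments = []
    for s_idx, speed in enumerate(syn.TREADMILL_SPEEDS):
        truth = syn.simulate_treadmill(speed, duration=180.0, seed=config.seed + 17 * s_idx)
        segments.append(
            _paired_rms(truth, devices, seed=config.seed + 500 + s_idx, keep=TRIM_KEEP_TREADMILL)
        )
    rows = _correlate_protocol(segments, devices)
    return pd.DataFrame(
        [{"activity": "treadmill", **row} for row in rows],
        columns=["activity", "axis", "r", "n_seconds"],
    )


def run_agreement_study(
    config: ExperimentConfig, bundle: syn.BenchmarkBundle | None = None
) -> pd.DataFrame:
    """Between-device RMS agreement for every protocol.

    Returns one row per (protocol-or-activity, axis) with the Pearson r of
    the trimmed 1-second RMS series and the number of seconds compared.
    Daily-activity rows pool the aligned RMS pairs over that activity's
    sessions in the benchmark.
    """
    _log("agreement study: shaker")
    tables = [shaker_agreement(config), treadmill_agreement(config)]
    _log("agreement study: daily activities")
    if bundle is None:
        bundle = syn.generate_benchmark(config.benchmark)
    names = [d.name for d in config.benchmark.devices]
    by_activity: dict[str, list] = {}
    for session in bundle.sessions:
        for name in names:
            if name not in session.recordings:
                raise LinkageError(
                    f"session ({session.participant_id}, {session.activity_name}) "
                    f"missing device {name!r}"
                )
        seg = {}
        for name in names:
            rec = trim_keep(session.recordings[name], TRIM_KEEP_ACTIVITY)
            seg[name] = {axis: sio.rms_per_second(rec, axis).values for axis in sio.AXES}
        by_activity.setdefault(session.activity_name, []).append(seg)
    for activity in bundle.config.taxonomy:
        rows = _correlate_protocol(by_activity[activity], config.benchmark.devices)
        tables.append(
            pd.DataFrame(
                [{"activity": activity, **row} for row in rows],
                columns=["activity", "axis", "r", "n_seconds"],
            )
        )
    return pd.concat(tables, ignore_index=True)


def benchmark_features(
    bundle: syn.BenchmarkBundle,
    device: str,
    window_length: float,
    keep: float = TRIM_KEEP_ACTIVITY,
) -> pd.DataFrame:
    """Windowed 15-feature table for one device across all sessions.

    Each session is first trimmed to its centered ``keep`` seconds (capped
    at the session duration, so shorter walking sessions keep everything).
    """
    spec = ft.WindowSpec(window_length)
    frames = []
    for session in bundle.sessions:
        rec = trim_keep(session.recordings[device], keep)
        frames.append(
            ft.featurize(
                rec, spec,
                participant_id=session.participant_id,
                activity_name=session.activity_name,
            )
        )
    return pd.concat(frames, ignore_index=True)


def task_dataset(
    feature_table: pd.DataFrame, taxonomy, task: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """(features X, labels y) for one classification task."""
    X = feature_table[list(ft.FEATURE_NAMES)]
    y = labels_for(feature_table["activity"], taxonomy, task)
    return X, y


def evaluate_task(
    feature_table: pd.DataFrame,
    taxonomy,
    task: str,
    model_kind: str = "random_forest",
    seed: int = 1,
    grids: dict | None = None,
) -> md.ModelResult:
    """Nested-CV evaluation of one (task, model) on a feature table."""
    X, y = task_dataset(feature_table, taxonomy, task)
    plan = md.nested_split(len(X), outer_folds=5, seed=seed, labels=y)
    return md.train_and_evaluate(X, y, model_kind, plan, seed=seed, task=task, grids=grids)


def run_window_sweep(
    config: ExperimentConfig,
    bundle: syn.BenchmarkBundle | None = None,
    device: str | None = None,
    forest_size: int = SWEEP_FOREST_SIZE,
) -> pd.DataFrame:
    """Random-forest pooled accuracy for each task x window length.

    Returns the tasks-by-lengths accuracy grid with a ``best_length``
    flag column appended per task row. The sweep uses a reduced forest
    (``forest_size`` trees) since it fits 5 x len(lengths) forests, some
    on very large 1-second-window tables.
    """
    if bundle is None:
        bundle = syn.generate_benchmark(config.benchmark)
    if device is None:
        device = config.benchmark.devices[0].name
    grids = {"random_forest": [{"n_estimators": forest_size, "max_features": "sqrt"}]}
    grid = {}
    for length in config.window_lengths:
        _log(f"window sweep: extracting {length} s windows")
        table = benchmark_features(bundle, device, length)
        for task in config.tasks:
            _log(f"window sweep: task={task} length={length}")
            result = evaluate_task(
                table, bundle.config.taxonomy, task,
                model_kind="random_forest", seed=config.seed, grids=grids,
            )
            grid[(task, length)] = result.overall_accuracy
    out = pd.DataFrame(
        [
            {
                "task": task,
                **{f"{length:g}s": grid[(task, length)] for length in config.window_lengths},
            }
            for task in config.tasks
        ]
    )
    length_cols = [f"{l:g}s" for l in config.window_lengths]
    out["best_length"] = out[length_cols].idxmax(axis=1)
    return out


@dataclass
class ValidationReport:
    """Full-validation output: per-device results plus device deltas."""

    classification: dict  # (device, task, model_kind) -> ModelResult
    regression: dict  # (device, model_kind) -> RegressionResult
    device_deltas: pd.DataFrame  # per-task |accuracy difference| (best model)
    window_length: float
    seed: int


def run_full_validation(
    config: ExperimentConfig, bundle: syn.BenchmarkBundle | None = None
) -> ValidationReport:
    """The headline study: both devices, five tasks, four model families,
    METs regression, and a between-device accuracy-delta summary.

    Models are trained separately per device, never pooled across devices.
    """
    if bundle is None:
        _log("generating benchmark")
        bundle = syn.generate_benchmark(config.benchmark)
    taxonomy = bundle.config.taxonomy
    classification = {}
    regression = {}
    for device in [d.name for d in config.benchmark.devices]:
        _log(f"extracting {config.headline_window:g} s features for {device}")
        table = benchmark_features(bundle, device, config.headline_window)
        for task in config.tasks:
            for kind in config.model_kinds:
                _log(f"{device}: task={task} model={kind}")
                classification[(device, task, kind)] = evaluate_task(
                    table, taxonomy, task, model_kind=kind, seed=config.seed
                )
        obs, _skipped = build_mets_dataset(table, bundle.met_table())
        Xr = pd.DataFrame(
            [o.mean_features for o in obs], columns=list(ft.FEATURE_NAMES)
        )
        yr = np.array([o.met for o in obs])
        plan = md.nested_split(len(Xr), outer_folds=5, seed=config.seed)
        for kind in config.model_kinds:
            _log(f"{device}: METs regression model={kind}")
            regression[(device, kind)] = md.train_and_evaluate_regression(
                Xr, yr, kind, plan, seed=config.seed
            )
    dev_a, dev_b = [d.name for d in config.benchmark.devices]
    delta_rows = []
    for task in config.tasks:
        acc = {
            dev: max(
                classification[(dev, task, kind)].overall_accuracy
                for kind in config.model_kinds
            )
            for dev in (dev_a, dev_b)
        }
        delta_rows.append(
            {
                "task": task,
                f"accuracy_{dev_a}": acc[dev_a],
                f"accuracy_{dev_b}": acc[dev_b],
                "abs_delta": abs(acc[dev_a] - acc[dev_b]),
            }
        )
    return ValidationReport(
        classification=classification,
        regression=regression,
        device_deltas=pd.DataFrame(delta_rows),
        window_length=config.headline_window,
        seed=config.seed,
    )


def report_to_json(report: ValidationReport) -> dict:
    """Machine-readable summary of a full-validation report."""
    return {
        "window_length": report.window_length,
        "seed": report.seed,
        "classification": [
            {
                "device": device,
                "task": task,
                "model": kind,
                "overall_accuracy": r.overall_accuracy,
                "fold_accuracies": r.fold_accuracies,
                "fold_mean_accuracy": r.fold_mean_accuracy,
                "balanced_accuracy": r.per_class_balanced_accuracy,
                "confusion_normalized": r.confusion.to_dict(),
                "importance": r.importance,
                "retained_features": r.retained_features,
                "chosen_params": [
                    {k: (v if v is None or isinstance(v, (int, float, str)) else str(v))
                     for k, v in p.items()}
                    for p in r.chosen_params
                ],
            }
            for (device, task, kind), r in report.classification.items()
        ],
        "regression": [
            {
                "device": device,
                "model": kind,
                "rmse": r.rmse,
                "r_squared": r.r_squared,
                "per_fold_rmse": r.per_fold_rmse,
                "importance": r.importance,
            }
            for (device, kind), r in report.regression.items()
        ],
        "device_deltas": report.device_deltas.to_dict(orient="records"),
    }


def write_report(report: ValidationReport, out_dir) -> Path:
    """Write the validation report: JSON summary plus delimited confusion
    matrices (predicted-label rows, actual-label columns)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "validation_report.json").write_text(
        json.dumps(report_to_json(report), indent=2)
    )
    for (device, task, kind), r in report.classification.items():
        r.confusion.to_csv(out / f"confusion_{device}_{task}_{kind}.csv")
    report.device_deltas.to_csv(out / "device_deltas.csv", index=False)
    return out


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
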