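"""Experiment grids: DTW-KNN over treatments/windows/K, the experimental
CNN over image modes/kernels, and the neuroevolved CNN, with the study's
treatment nomenclature, result tables, resumable caching, and the
compact-letter cross-method comparison.

Treatment codes follow the published scheme, e.g. ``GFCR3K520150`` =
Gaussian Frequency-domain smoothing, with (C) restriction window, 3 classes,
K = 5, window 0.20, sigma 150; ``RSR2K5`` = raw, without (S) restrictions,
2 classes, K = 5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import (AugmentConfig, IMAGE_MODES, KERNEL_SIZES, TrainConfig,
                  augment_dataset, build_ecnn, prepare_tensors,
                  train_and_evaluate)
from .deepga import DeepGAConfig, decode, evolve, fitness
from .dtw import DTWConfig, DTWKNNClassifier, K_VALUES, KNNConfig, WINDOW_FRACTIONS
from .metrics import (ExperimentResult, HoldoutConfig, compare_methods,
                      repeated_holdout, round2)
from .profiles import (FREQUENCY_SIGMAS, SPATIAL_SIGMAS, IntensityProfile,
                       SmoothingConfig, apply_treatment,
                       extract_cohort_profiles)
from .synth import CohortConfig, StripImage, generate_cohort

__all__ = [
    "ExperimentGrid",
    "treatment_name",
    "ecnn_name",
    "default_smoothings",
    "run_grid",
    "compare_report",
    "desk_grid",
]

_MODE_PREFIX = {"raw": "R", "gaussian_spatial": "GE", "gaussian_frequency": "GF"}
_MODE_TITLE = {"color": "Color", "gray": "Gray", "fourier": "Fourier"}


def _sigma_code(sigma: float) -> str:
    return f"{sigma:g}".replace(".", "")


def treatment_name(mode: str, n_classes: int, k: int,
                   window_fraction: float = 0.0,
                   sigma: float | None = None) -> str:
    """Published nomenclature for one KNN grid cell."""
    restricted = "C" if window_fraction > 0 else "S"
    name = f"{_MODE_PREFIX[mode]}{restricted}R{n_classes}K{k}"
    if window_fraction > 0:
        name += f"{int(round(window_fraction * 100)):02d}"
    if sigma is not None and mode != "raw":
        name += _sigma_code(sigma)
    return name


def ecnn_name(mode: str, n_classes: int, kernel: int) -> str:
    return f"ECNN{n_classes}C{_MODE_TITLE[mode]}{kernel}x{kernel}"


def default_smoothings() -> tuple[SmoothingConfig, ...]:
    """The full treatment axis: raw, spatial sigmas, frequency sigmas."""
    return (
        (SmoothingConfig("raw"),)
        + tuple(SmoothingConfig("gaussian_spatial", s) for s in SPATIAL_SIGMAS)
        + tuple(SmoothingConfig("gaussian_frequency", s) for s in FREQUENCY_SIGMAS)
    )


@dataclass
class ExperimentGrid:
    """One experiment family: a task (class set), a method, and its axes.

    The two-class task drops the benign class (cancer vs no pathology) from
    the same cohort rather than regenerating it.
    """

    task: str = "three_class"
    method: str = "knn_dtw"
    smoothings: tuple[SmoothingConfig, ...] = field(
        default_factory=default_smoothings)
    windows: tuple[float, ...] = WINDOW_FRACTIONS
    ks: tuple[int, ...] = K_VALUES
    image_modes: tuple[str, ...] = IMAGE_MODES
    kernels: tuple[int, ...] = KERNEL_SIZES
    image_size: int = 256
    epochs_by_mode: dict = field(
        default_factory=lambda: {"color": 20, "gray": 20, "fourier": 70})
    holdout: HoldoutConfig = field(default_factory=HoldoutConfig)
    augment: AugmentConfig | None = None
    deepga: DeepGAConfig | None = None
    jitter_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("three_class", "two_class"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.method not in ("knn_dtw", "ecnn", "deepga_cnn"):
            raise ValueError(f"unknown method {self.method!r}")
        for m in self.image_modes:
            if m not in IMAGE_MODES:
                raise ValueError(f"unknown image mode {m!r}")
        for k in self.kernels:
            if k not in KERNEL_SIZES:
                raise ValueError(f"unknown kernel size {k}")

    @property
    def n_classes(self) -> int:
        return 3 if self.task == "three_class" else 2

    @property
    def aggregation(self) -> str:
        return "micro_ovr" if self.n_classes == 3 else "per_class"


def desk_grid(**overrides) -> ExperimentGrid:
    """Scaled-down grid preset used by fast runs and the test suite:
    64x64 rasters, 5-epoch CNN training, population-4 / 3-generation GA."""
    from .deepga import GenomeBounds

    base = ExperimentGrid(
        image_size=64,
        epochs_by_mode={"color": 5, "gray": 5, "fourier": 5},
        holdout=HoldoutConfig(n_runs=3),
        deepga=DeepGAConfig(
            population_size=4, n_generations=3, tournament_size=2,
            fitness_epochs=5,
            bounds=GenomeBounds(filters=(2, 8), kernels=(3, 5),
                                neurons=(2, 16), n_conv=(1, 3), n_dense=(1, 2)),
        ),
    )
    return replace(base, **overrides)


def _strips_for_task(data, grid: ExperimentGrid) -> list[StripImage]:
    if isinstance(data, CohortConfig):
        strips = generate_cohort(data)
    else:
        strips = list(data)
    if grid.task == "two_class":
        strips = [s for s in strips if s.label != "benign"]
    return strips


def _fingerprint(payload: dict) -> str:
    return hashlib.md5(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Cache:
    def __init__(self, out_dir: str | Path | None, name: str):
        self.path = (Path(out_dir) / f"cache_{name}.json") if out_dir else None
        self.rows: dict[str, dict] = {}
        if self.path and self.path.exists():
            self.rows = json.loads(self.path.read_text())

    def get(self, key: str) -> dict | None:
        return self.rows.get(key)

    def put(self, key: str, row: dict) -> None:
        self.rows[key] = row
        if self.path:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text(json.dumps(self.rows, indent=1))


def _result_row(name: str, result: ExperimentResult, fingerprint: str) -> dict:
    mean = result.mean_report
    return {
        "treatment": name,
        "accuracy": round2(mean.accuracy),
        "precision": round2(mean.precision),
        "sensitivity": round2(mean.sensitivity),
        "specificity": round2(mean.specificity),
        "run_accuracies": json.dumps([r.accuracy for r in result.per_run]),
        "fingerprint": fingerprint,
    }


def _knn_rows(grid: ExperimentGrid, strips, cache: _Cache) -> list[dict]:
    raw = extract_cohort_profiles(strips, grid.seed,
                                  jitter_fraction=grid.jitter_fraction)
    labels = [p.label for p in raw]
    rows = []
    for smoothing in grid.smoothings:
        treated = (raw if smoothing.mode == "raw"
                   else [apply_treatment(p, smoothing) for p in raw])
        for window in grid.windows:
            for k in grid.ks:
                name = treatment_name(smoothing.mode, grid.n_classes, k,
                                      window, smoothing.sigma or None)
                key = _fingerprint({
                    "cell": name, "holdout": grid.holdout, "seed": grid.seed,
                    "jitter": grid.jitter_fraction,
                })
                cached = cache.get(key)
                if cached is not None:
                    rows.append(cached)
                    continue
                cfg = KNNConfig(k=k, dtw=DTWConfig(window))
                result = repeated_holdout(
                    (treated, labels),
                    lambda run: DTWKNNClassifier(cfg),
                    grid.holdout,
                    aggregation=grid.aggregation,
                    positive_class="cancer" if grid.n_classes == 2 else None,
                )
                row = _result_row(name, result, key)
                cache.put(key, row)
                rows.append(row)
    return rows


def _maybe_augment(grid: ExperimentGrid, strips: list[StripImage]):
    if grid.augment is None:
        return strips
    return augment_dataset(strips, grid.augment)


def _ecnn_rows(grid: ExperimentGrid, strips, cache: _Cache) -> list[dict]:
    strips = _maybe_augment(grid, strips)
    rows = []
    for mode in grid.image_modes:
        dataset = prepare_tensors(strips, mode, grid.image_size)
        shape = dataset[0].shape  # NCHW
        input_shape = (shape[2], shape[3], shape[1])
        for kernel in grid.kernels:
            name = ecnn_name(mode, grid.n_classes, kernel)
            key = _fingerprint({
                "cell": name, "holdout": grid.holdout, "seed": grid.seed,
                "size": grid.image_size, "epochs": grid.epochs_by_mode[mode],
                "augment": grid.augment,
            })
            cached = cache.get(key)
            if cached is not None:
                rows.append(cached)
                continue
            spec = build_ecnn(kernel, grid.n_classes, input_shape)
            train_cfg = TrainConfig(epochs=grid.epochs_by_mode[mode],
                                    seed=grid.seed)
            result = train_and_evaluate(
                spec, dataset, train_cfg, grid.holdout,
                aggregation=grid.aggregation,
                positive_class="cancer" if grid.n_classes == 2 else None,
            )
            row = _result_row(name, result, key)
            cache.put(key, row)
            rows.append(row)
    return rows


def _deepga_rows(grid: ExperimentGrid, strips, cache: _Cache) -> list[dict]:
    if grid.deepga is None:
        raise ValueError("deepga_cnn grid needs a DeepGAConfig")
    strips = _maybe_augment(grid, strips)
    dataset = prepare_tensors(strips, "gray", grid.image_size)
    name = f"CNN{grid.n_classes}-DeepGA"
    key = _fingerprint({
        "cell": name, "holdout": grid.holdout, "seed": grid.seed,
        "size": grid.image_size, "ga": grid.deepga, "augment": grid.augment,
    })
    cached = cache.get(key)
    if cached is not None:
        return [cached]
    best, _history = evolve(dataset, grid.deepga)
    shape = dataset[0].shape
    spec = decode(best, (shape[2], shape[3], shape[1]), grid.n_classes)
    train_cfg = TrainConfig(epochs=grid.deepga.fitness_epochs, seed=grid.seed)
    result = train_and_evaluate(
        spec, dataset, train_cfg, grid.holdout,
        aggregation=grid.aggregation,
        positive_class="cancer" if grid.n_classes == 2 else None,
    )
    row = _result_row(name, result, key)
    cache.put(key, row)
    return [row]


def run_grid(grid: ExperimentGrid, data,
             out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run every cell of the grid and return the result table.

    ``data`` is a :class:`CohortConfig` (the cohort is generated) or a list
    of labeled strips.  Rows carry the published treatment nomenclature and
    are sorted by accuracy descending.  With ``out_dir`` set, completed
    cells are cached by config fingerprint, so reruns skip them and yield
    an identical table.
    """
    strips = _strips_for_task(data, grid)
    cache = _Cache(out_dir, f"{grid.method}_{grid.task}")
    if grid.method == "knn_dtw":
        rows = _knn_rows(grid, strips, cache)
    elif grid.method == "ecnn":
        rows = _ecnn_rows(grid, strips, cache)
    else:
        rows = _deepga_rows(grid, strips, cache)
    table = pd.DataFrame(rows).sort_values(
        ["accuracy", "treatment"], ascending=[False, True]
    ).reset_index(drop=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{grid.method}_{grid.task}.csv", index=False)
    return table


def compare_report(
    tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Best row per method family plus compact significance letters.

    ``tables`` maps a family name to its result table; the family's best
    (highest-accuracy) row enters the comparison, whose per-run accuracies
    feed pairwise Welch tests with Holm correction.  Families that are not
    significantly different share a letter.  Optionally writes the
    letter-annotated box plot.
    """
    best_rows = {}
    samples = {}
    for family, table in tables.items():
        row = table.iloc[0]
        best_rows[row["treatment"]] = row
        samples[row["treatment"]] = json.loads(row["run_accuracies"])
    letters = (compare_methods(samples, alpha=alpha)
               if len(samples) > 1 else {next(iter(samples), ""): "a"})
    report = pd.DataFrame([
        {
            "treatment": name,
            "accuracy": row["accuracy"],
            "precision": row["precision"],
            "sensitivity": row["sensitivity"],
            "specificity": row["specificity"],
            "letters": letters[name],
        }
        for name, row in best_rows.items()
    ]).sort_values("accuracy", ascending=False).reset_index(drop=True)
    if plot_path is not None:
        _letter_boxplot(samples, letters, report, plot_path)
    return report


def _letter_boxplot(samples, letters, report, plot_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = report["treatment"].tolist()
    fig, ax = plt.subplots(figsize=(1.6 * len(order) + 2, 4.5))
    ax.boxplot([samples[name] for name in order], tick_labels=order)
    for i, name in enumerate(order, start=1):
        top = max(samples[name])
        ax.annotate(letters[name], (i, top), textcoords="offset points",
                    xytext=(0, 6), ha="center", fontweight="bold")
    ax.set_ylabel("accuracy (%)")
    ax.set_title("Per-run classification accuracy by method")
    plt.setp(ax.get_xticklabels(), rotation=20, ha="right")
    fig.tight_layout()
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
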