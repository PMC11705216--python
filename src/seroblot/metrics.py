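"""Confusion-matrix metrics, the repeated holdout protocol, and the
compact-letter comparison of classifiers.

Accuracy is correct predictions over total.  Sensitivity, specificity and
precision are one-vs-rest quantities: per class c, TP/FP/FN/TN are read off
the confusion matrix with c as positive, then either pooled over classes
before dividing (``micro_ovr``), averaged across classes (``macro_ovr``), or
reported for a single designated positive class (``per_class``, the 2-class
use with cancer positive).

Useful identities under micro one-vs-rest pooling (any class distribution):

* sensitivity = accuracy,
* specificity = 1 - (1 - accuracy) / (C - 1).

The second follows from pooled TN = (C-2)*total + trace and pooled
FP = total - trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .synth import CLASS_ORDER

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "HoldoutConfig",
    "ExperimentResult",
    "confusion",
    "metrics_from_confusion",
    "micro_specificity_from_accuracy",
    "holdout_split",
    "repeated_holdout",
    "compare_methods",
    "round2",
]


def round2(x: float) -> float:
    """Percent formatting used in the result tables: 2 decimals, half-up."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """CxC counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be CxC for C classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def ovr_counts(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) with the given class as positive."""
        cm = self.counts
        tp = int(cm[class_index, class_index])
        fp = int(cm[:, class_index].sum() - tp)
        fn = int(cm[class_index, :].sum() - tp)
        tn = int(cm.sum() - tp - fp - fn)
        return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Accuracy / precision / sensitivity / specificity as percentages.

    Undefined ratios (zero denominator) are carried as NaN and excluded from
    macro averages.
    """

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    aggregation: str = "micro_ovr"

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def rounded(self) -> "MetricsReport":
        return MetricsReport(
            *(round2(v) for v in (self.accuracy, self.precision,
                                  self.sensitivity, self.specificity)),
            aggregation=self.aggregation,
        )


@dataclass(frozen=True)
class HoldoutConfig:
    """Repeated random 70/30 holdout, stratified by class, n_runs splits."""

    train_fraction: float = 0.70
    n_runs: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ExperimentResult:
    """Per-run metrics and their arithmetic mean for one configuration."""

    per_run: list[MetricsReport]
    mean_report: MetricsReport
    fingerprint: str = ""
    confusions: list[ConfusionMatrix] = field(default_factory=list)

    @property
    def accuracies(self) -> list[float]:
        return [r.accuracy for r in self.per_run]


def confusion(true_labels, predicted_labels,
              classes: tuple[str, ...] | None = None) -> ConfusionMatrix:
    """Count matrix; classes default to the canonical order restricted to the
    labels present (unknown labels sorted after the canonical ones)."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    if classes is None:
        present = set(true_labels) | set(predicted_labels)
        classes = tuple(
            [c for c in CLASS_ORDER if c in present]
            + sorted(present - set(CLASS_ORDER))
        )
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: {t!r}/{p!r}")
        cm[index[t], index[p]] += 1
    return ConfusionMatrix(cm, classes)


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def metrics_from_confusion(
    cm: ConfusionMatrix,
    aggregation: str = "micro_ovr",
    positive_class: str | None = None,
) -> MetricsReport:
    """Accuracy plus one-vs-rest precision/sensitivity/specificity.

    ``micro_ovr`` pools TP/FP/FN/TN over classes before dividing;
    ``macro_ovr`` averages the per-class ratios (NaNs excluded);
    ``per_class`` reports the designated positive class (default: first
    class in canonical order).
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = 100.0 * np.trace(cm.counts) / cm.total
    per = np.array([cm.ovr_counts(i) for i in range(len(cm.classes))],
                   dtype=np.float64)  # rows: (tp, fp, fn, tn)
    if aggregation == "micro_ovr":
        tp, fp, fn, tn = per.sum(axis=0)
        prec, sens, spec = _ratio(tp, tp + fp), _ratio(tp, tp + fn), _ratio(
            tn, tn + fp)
    elif aggregation == "macro_ovr":
        with np.errstate(invalid="ignore", divide="ignore"):
            precs = 100.0 * per[:, 0] / (per[:, 0] + per[:, 1])
            senss = 100.0 * per[:, 0] / (per[:, 0] + per[:, 2])
            specs = 100.0 * per[:, 3] / (per[:, 3] + per[:, 1])
        prec, sens, spec = (float(np.nanmean(v)) for v in (precs, senss, specs))
    elif aggregation == "per_class":
        pos = positive_class if positive_class is not None else cm.classes[0]
        if pos not in cm.classes:
            raise ValueError(f"positive class {pos!r} not among {cm.classes}")
        tp, fp, fn, tn = cm.ovr_counts(cm.classes.index(pos))
        prec, sens, spec = _ratio(tp, tp + fp), _ratio(tp, tp + fn), _ratio(
            tn, tn + fp)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return MetricsReport(float(accuracy), float(prec), float(sens), float(spec),
                         aggregation=aggregation)


def micro_specificity_from_accuracy(accuracy_pct: float, n_classes: int) -> float:
    """The micro one-vs-rest identity: spec = 1 - (1 - acc) / (C - 1)."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return 100.0 - (100.0 - accuracy_pct) / (n_classes - 1)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def holdout_split(
    labels, config: HoldoutConfig, run_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive (train, test) index arrays for one run.

    Stratified splits keep each class's train share at
    ``round(train_fraction * n_c)`` (clamped so both sides stay non-empty);
    deterministic given (seed, run_index).
    """
    labels = np.asarray(list(labels))
    n = labels.size
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, run_index]))
    if not config.stratified:
        perm = rng.permutation(n)
        n_train = min(max(_round_half_up(config.train_fraction * n), 1), n - 1)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    train_idx, test_idx = [], []
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(
                f"class {cls!r} has {idx.size} sample(s); stratified holdout "
                "needs at least 2 per class"
            )
        perm = rng.permutation(idx)
        n_train = min(max(_round_half_up(config.train_fraction * idx.size), 1),
                      idx.size - 1)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    fields = ("accuracy", "precision", "sensitivity", "specificity")
    means = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    return MetricsReport(**means, aggregation=reports[0].aggregation)


def repeated_holdout(
    dataset,
    classifier_factory,
    config: HoldoutConfig,
    aggregation: str = "micro_ovr",
    positive_class: str | None = None,
    classes: tuple[str, ...] | None = None,
) -> ExperimentResult:
    """Train/evaluate over ``n_runs`` independent stratified splits.

    ``dataset`` is an ``(items, labels)`` pair; ``classifier_factory`` is
    called with the run index and must return an estimator with
    ``fit(items, labels)`` and ``predict(items)``.  The mean report is the
    arithmetic mean of the per-run reports.
    """
    items, labels = dataset
    items = list(items)
    labels = list(labels)
    per_run: list[MetricsReport] = []
    confusions: list[ConfusionMatrix] = []
    for run in range(config.n_runs):
        tr, te = holdout_split(labels, config, run)
        clf = classifier_factory(run)
        clf.fit([items[i] for i in tr], [labels[i] for i in tr])
        pred = list(clf.predict([items[i] for i in te]))
        cm = confusion([labels[i] for i in te], pred, classes=classes)
        per_run.append(metrics_from_confusion(cm, aggregation, positive_class))
        confusions.append(cm)
    return ExperimentResult(per_run, _mean_report(per_run), confusions=confusions)


def _pairwise_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Welch two-sided t; exact-equality rule for zero-variance pairs."""
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    import warnings

    with warnings.catch_warnings():
        # near-identical samples trip scipy's precision-loss warning; the
        # Holm step keeps such pairs conservative anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(x, y, equal_var=False).pvalue
    return float(p) if np.isfinite(p) else 1.0


def compare_methods(samples: dict[str, list[float]],
                    alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display over per-run accuracy samples.

    Pairwise Welch tests with Holm step-down correction at ``alpha``;
    methods that are not significantly different share a letter.  Letters
    are assigned greedily scanning methods by descending mean.
    """
    from statsmodels.stats.multitest import multipletests

    names = list(samples)
    if len(names) == 1:
        return {names[0]: "a"}
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in samples.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"method {k!r} needs >= 2 runs")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = [_pairwise_pvalue(arrays[a], arrays[b]) for a, b in pairs]
    reject = multipletests(raw, alpha=alpha, method="holm")[0]
    differs = {pair: bool(r) for pair, r in zip(pairs, reject)}

    def different(a: str, b: str) -> bool:
        return differs.get((a, b), differs.get((b, a), False))

    ranked = sorted(names, key=lambda k: -arrays[k].mean())
    groups: list[list[str]] = []
    for name in ranked:
        placed = False
        for grp in groups:
            if not any(different(name, member) for member in grp):
                grp.append(name)
                placed = True
        if not placed:
            groups.append([name])
    letters = {name: "" for name in names}
    for i, grp in enumerate(groups):
        for name in grp:
            letters[name] += chr(ord("a") + i)
    return letters
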