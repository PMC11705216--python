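"""Dynamic time warping for unequal-length lane profiles, plus DTW-KNN.

The distance is the minimal cumulative absolute-difference cost over monotone
warping paths with steps (1,0), (0,1), (1,1).  A Sakoe-Chiba restriction
window is expressed as a fraction ``w`` of the longer series; the band
half-width is ``max(ceil(w * max(n, m)), |n - m|)`` so a feasible path always
exists even when the series lengths differ by more than the window
(0 means unrestricted).  Windows used in the study: 0, 0.06, 0.10, 0.20.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .profiles import IntensityProfile
from .synth import CLASS_ORDER

__all__ = [
    "WINDOW_FRACTIONS",
    "K_VALUES",
    "DTWConfig",
    "KNNConfig",
    "dtw_distance",
    "knn_predict",
    "distance_matrix",
    "DTWKNNClassifier",
]

WINDOW_FRACTIONS = (0.0, 0.06, 0.10, 0.20)
K_VALUES = (1, 3, 5, 7, 10)


@dataclass(frozen=True)
class DTWConfig:
    """Restriction-window setting; 0 disables the window entirely."""

    window_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.window_fraction <= 1.0:
            raise ValueError("window_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class KNNConfig:
    """K-nearest-neighbor settings over the DTW distance."""

    k: int = 5
    dtw: DTWConfig = field(default_factory=DTWConfig)
    label_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@njit(fastmath=False)
def _dtw_band(a, b, band):  # pragma: no cover - exercised via dtw_distance
    n, m = a.size, b.size
    inf = np.inf
    acc = np.full((n + 1, m + 1), inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        lo = 1 if band < 0 else max(1, i - band)
        hi = m if band < 0 else min(m, i + band)
        for j in range(lo, hi + 1):
            cost = abs(a[i - 1] - b[j - 1])
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost + best
    return acc[n, m]


def _as_values(profile) -> np.ndarray:
    values = getattr(profile, "values", profile)
    return np.ascontiguousarray(values, dtype=np.float64).ravel()


def band_width(n: int, m: int, window_fraction: float) -> int:
    """Effective band half-width; -1 encodes an unrestricted search."""
    if window_fraction <= 0.0:
        return -1
    return max(math.ceil(window_fraction * max(n, m)), abs(n - m))


def dtw_distance(a, b, config: DTWConfig | None = None) -> float:
    """DTW distance between two profiles (or plain sequences).

    Symmetric, non-negative, zero on identical inputs.
    """
    config = config or DTWConfig()
    va, vb = _as_values(a), _as_values(b)
    if va.size == 0 or vb.size == 0:
        raise ValueError("profiles must be non-empty")
    return float(_dtw_band(va, vb, band_width(va.size, vb.size,
                                              config.window_fraction)))


def _tie_rank(label: str, label_order: tuple[str, ...]) -> tuple[int, str]:
    try:
        return (label_order.index(label), "")
    except ValueError:
        return (len(label_order), label)


def knn_predict(
    train: list[IntensityProfile],
    query,
    config: KNNConfig | None = None,
) -> str:
    """Majority label among the k DTW-nearest training profiles.

    Deterministic tie chain: neighbors tied at the cutoff distance are taken
    in training order; vote ties go to the class with the smallest summed
    distance among its voting neighbors, then to the fixed label order.
    """
    config = config or KNNConfig()
    if not train:
        raise ValueError("training set must be non-empty")
    if config.k > len(train):
        raise ValueError(f"k={config.k} exceeds training-set size {len(train)}")
    dists = [dtw_distance(p, query, config.dtw) for p in train]
    order = sorted(range(len(train)), key=lambda i: (dists[i], i))[: config.k]
    votes: dict[str, int] = {}
    summed: dict[str, float] = {}
    for i in order:
        lab = train[i].label
        votes[lab] = votes.get(lab, 0) + 1
        summed[lab] = summed.get(lab, 0.0) + dists[i]
    return min(
        votes,
        key=lambda lab: (-votes[lab], summed[lab], _tie_rank(lab, config.label_order)),
    )


def distance_matrix(
    profiles: list[IntensityProfile], config: DTWConfig | None = None
) -> np.ndarray:
    """Full symmetric pairwise DTW matrix (exportable as CSV for debugging)."""
    config = config or DTWConfig()
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dtw_distance(profiles[i], profiles[j], config)
    return mat


class DTWKNNClassifier:
    """Scikit-learn-style wrapper so the repeated-holdout driver can use it."""

    def __init__(self, config: KNNConfig | None = None):
        self.config = config or KNNConfig()
        self._train: list[IntensityProfile] = []

    def fit(self, profiles: list[IntensityProfile], labels=None):
        if labels is not None:
            profiles = [
                IntensityProfile(p.values, lab, p.source_id, p.treatment)
                if p.label != lab
                else p
                for p, lab in zip(profiles, labels)
            ]
        self._train = list(profiles)
        return self

    def predict(self, profiles: list[IntensityProfile]) -> list[str]:
        return [knn_predict(self._train, p, self.config) for p in profiles]
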