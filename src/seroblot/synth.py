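"""Synthetic Western-blot strip cohort generator.

Real serological strips are nitrocellulose lanes scanned as light membranes
with dark bands where serum IgG bound tumor-line antigens.  This module
fabricates a labeled cohort of such strips with the class structure reported
for breast-pathology sera:

* ``cancer`` and ``healthy`` sera each react with a small, class-typical set
  of antigens, so their band patterns are homogeneous within class and
  mutually distinct (disjoint band positions);
* ``benign`` sera are heterogeneous, sharing bands with both of the other
  classes on top of bands of their own.

Bands are negative Gaussian bumps on a light background (dark = reactive),
constant across the strip width, plus pixel noise.  Everything is driven by
a single integer seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "CLASS_ORDER",
    "BandSpec",
    "ClassSignature",
    "CohortConfig",
    "StripImage",
    "make_class_signatures",
    "render_strip",
    "generate_cohort",
    "separable_cohort",
    "to_color",
    "save_cohort",
    "montage",
]

#: Fixed class order used everywhere (confusion matrices, tie-breaking).
CLASS_ORDER = ("cancer", "benign", "healthy")

# Brown-on-cream palette approximating a diaminobenzidine-stained membrane.
_CREAM = np.array([245.0, 235.0, 215.0])
_BROWN = np.array([92.0, 58.0, 32.0])


@dataclass(frozen=True)
class BandSpec:
    """One candidate antigen band.

    center
        Position along the migration axis as a fraction of strip height,
        row 0 = top of strip = highest molecular weight.
    amplitude
        Peak darkening in intensity units (subtracted from the background).
    width
        Gaussian standard deviation in pixels along the migration axis.
    """

    center: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 1.0:
            raise ValueError(f"band center {self.center} outside [0, 1]")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("band width must be > 0")


@dataclass(frozen=True)
class ClassSignature:
    """Per-class band repertoire and how many bands one strip expresses.

    ``band_catalog`` holds the class's own candidate bands.  For the benign
    class, ``overlap_sources`` additionally references the cancer and healthy
    catalogs; a benign strip draws a configurable fraction of its bands from
    each of those, operationalising the sharing of band patterns with both
    other classes.
    """

    label: str
    band_catalog: tuple[BandSpec, ...]
    diversity: int
    overlap_sources: dict[str, tuple[BandSpec, ...]] = field(default_factory=dict)
    overlap_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.diversity < 1:
            raise ValueError("diversity must be >= 1")
        n_avail = len(self.band_catalog) + sum(
            len(v) for v in self.overlap_sources.values()
        )
        if self.diversity > n_avail:
            raise ValueError(
                f"diversity {self.diversity} exceeds catalog size {n_avail}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout and rendering parameters.

    Defaults mirror the study cohort: 49 women without breast pathology,
    50 with benign breast pathology, 50 with breast cancer (149 strips).
    """

    n_healthy: int = 49
    n_benign: int = 50
    n_cancer: int = 50
    image_height: int = 300
    image_width: int = 60
    background_level: float = 220.0
    noise_sd: float = 6.0
    seed: int = 0
    #: minimum separation (fraction of height) between cancer and healthy
    #: band centers so the two homogeneous classes stay distinct
    min_separation: float = 0.025

    def __post_init__(self) -> None:
        if min(self.n_healthy, self.n_benign, self.n_cancer) < 0:
            raise ValueError("class counts must be >= 0")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_healthy + self.n_benign + self.n_cancer


@dataclass
class StripImage:
    """One patient lane: 2-D grayscale (or HxWx3 color) raster in [0, 255]."""

    pixels: np.ndarray
    label: str
    patient_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-plane")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("color strips must have exactly 3 planes")
        if min(self.pixels.shape[:2]) < 1:
            raise ValueError("raster dimensions must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3


def _spread_centers(rng: np.random.Generator, n: int, lo: float = 0.06,
                    hi: float = 0.94) -> np.ndarray:
    """n jittered grid positions in [lo, hi]; neighbors never collide."""
    slots = np.linspace(lo, hi, n)
    gap = (hi - lo) / max(n - 1, 1)
    return slots + rng.uniform(-0.2 * gap, 0.2 * gap, size=n)


def make_class_signatures(
    seed: int,
    config: CohortConfig | None = None,
    *,
    n_per_catalog: int = 4,
    diversity_homogeneous: int = 3,
    diversity_benign: int = 6,
) -> tuple[ClassSignature, ClassSignature, ClassSignature]:
    """Build the (cancer, benign, healthy) signatures for one cohort.

    Cancer and healthy get equal, low diversity and catalogs with disjoint,
    well-separated band centers.  Benign gets strictly higher diversity and
    draws from the union of the other catalogs plus unique bands of its own.
    """
    config = config or CohortConfig()
    if diversity_benign <= diversity_homogeneous:
        raise ValueError("benign diversity must exceed cancer/healthy diversity")
    if diversity_homogeneous > n_per_catalog:
        raise ValueError("catalog too small for requested diversity")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5167]))

    centers = _spread_centers(rng, 3 * n_per_catalog)
    owners = rng.permutation(
        np.repeat(np.arange(3), n_per_catalog)
    )  # 0=cancer, 1=healthy, 2=benign-unique

    def catalog(owner: int) -> tuple[BandSpec, ...]:
        return tuple(
            BandSpec(
                center=float(c),
                amplitude=float(rng.uniform(120.0, 200.0)),
                width=float(rng.uniform(2.5, 5.0)) * config.image_height / 300.0,
            )
            for c in centers[owners == owner]
        )

    cancer_cat, healthy_cat, benign_cat = catalog(0), catalog(1), catalog(2)
    c_pos = np.array([b.center for b in cancer_cat])
    h_pos = np.array([b.center for b in healthy_cat])
    if np.abs(c_pos[:, None] - h_pos[None, :]).min() < config.min_separation:
        # jittered grid guarantees this for the defaults; guard anyway
        raise ValueError("cancer/healthy band centers closer than min_separation")

    cancer = ClassSignature("cancer", cancer_cat, diversity_homogeneous)
    healthy = ClassSignature("healthy", healthy_cat, diversity_homogeneous)
    benign = ClassSignature(
        "benign",
        benign_cat,
        diversity_benign,
        overlap_sources={"cancer": cancer_cat, "healthy": healthy_cat},
    )
    return cancer, benign, healthy


def _choose_bands(sig: ClassSignature, rng: np.random.Generator) -> list[BandSpec]:
    if not sig.overlap_sources:
        idx = rng.choice(len(sig.band_catalog), size=sig.diversity, replace=False)
        return [sig.band_catalog[i] for i in sorted(idx)]
    # benign: a fraction from each overlap source, remainder from own catalog
    chosen: list[BandSpec] = []
    n_each = int(round(sig.overlap_fraction * sig.diversity))
    for src in sig.overlap_sources.values():
        k = min(n_each, len(src))
        idx = rng.choice(len(src), size=k, replace=False)
        chosen.extend(src[i] for i in idx)
    n_own = min(sig.diversity - len(chosen), len(sig.band_catalog))
    if n_own > 0:
        idx = rng.choice(len(sig.band_catalog), size=n_own, replace=False)
        chosen.extend(sig.band_catalog[i] for i in idx)
    return chosen


def render_strip(
    signature: ClassSignature,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
    patient_id: str = "anon",
) -> StripImage:
    """Render one strip: light background minus Gaussian bands plus noise.

    Band amplitudes are rescaled per strip (uniform 0.7-1.1) to mimic
    serum-to-serum intensity variation; centers get a small positional
    jitter.  Output clipped to [0, 255].
    """
    config = config or CohortConfig()
    h, w = config.image_height, config.image_width
    rows = np.arange(h, dtype=np.float64)
    profile = np.full(h, config.background_level)
    for band in _choose_bands(signature, rng):
        amp = band.amplitude * rng.uniform(0.7, 1.1)
        center = np.clip(band.center + rng.normal(0.0, 0.004), 0.0, 1.0) * (h - 1)
        profile = profile - amp * np.exp(-((rows - center) ** 2) / (2 * band.width**2))
    img = np.tile(profile[:, None], (1, w))
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return StripImage(np.clip(img, 0.0, 255.0), signature.label, patient_id)


def generate_cohort(config: CohortConfig | None = None) -> list[StripImage]:
    """Generate the full labeled cohort (cancer, benign, healthy strips).

    Bit-identical output for identical config (including seed).
    """
    config = config or CohortConfig()
    cancer, benign, healthy = make_class_signatures(config.seed, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0110]))
    strips: list[StripImage] = []
    plan = [
        (cancer, config.n_cancer, "C"),
        (benign, config.n_benign, "B"),
        (healthy, config.n_healthy, "H"),
    ]
    for sig, n, prefix in plan:
        for i in range(n):
            strips.append(
                render_strip(sig, rng, config, patient_id=f"{prefix}{i + 1:03d}")
            )
    return strips


def separable_cohort(n_per_class: int = 20, size: int = 32,
                     seed: int = 0) -> list[StripImage]:
    """Trivially separable two-class fixture: all-dark vs all-light squares.

    Synthetic smoke-test input for classifier plumbing (not blot-like);
    labels reuse the cancer/healthy pair.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EB]))
    strips = []
    for label, level, prefix in (("cancer", 60.0, "D"), ("healthy", 200.0, "L")):
        for i in range(n_per_class):
            px = np.clip(level + rng.normal(0.0, 8.0, size=(size, size)),
                         0.0, 255.0)
            strips.append(StripImage(px, label, f"{prefix}{i + 1:03d}"))
    return strips


def to_color(strip: StripImage) -> StripImage:
    """Deterministic brown-on-cream tint of a grayscale strip."""
    if strip.is_color:
        return strip
    t = strip.pixels / 255.0
    rgb = _BROWN[None, None, :] + t[:, :, None] * (_CREAM - _BROWN)[None, None, :]
    return replace(strip, pixels=np.clip(rgb, 0.0, 255.0))


def save_cohort(strips: list[StripImage], out_dir: str | Path) -> Path:
    """Write strips as PNGs plus a ``manifest.csv`` (patient_id, label, file)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "label", "file"])
        for strip in strips:
            fname = f"{strip.patient_id}.png"
            iio.imwrite(out / fname, np.round(strip.pixels).astype(np.uint8))
            writer.writerow([strip.patient_id, strip.label, fname])
    return manifest


def montage(strips: list[StripImage], gap: int = 4,
            background: float = 255.0) -> np.ndarray:
    """Side-by-side montage of equally tall strips (the multi-lane scan look)."""
    if not strips:
        raise ValueError("no strips to montage")
    h = strips[0].pixels.shape[0]
    if any(s.pixels.shape[0] != h for s in strips):
        raise ValueError("strips must share a height")
    panels: list[np.ndarray] = []
    spacer = np.full((h, gap), background)
    for i, s in enumerate(strips):
        px = s.pixels if not s.is_color else s.pixels.mean(axis=2)
        panels.append(px)
        if i < len(strips) - 1:
            panels.append(spacer)
    return np.hstack(panels)
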