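"""Synthetic feature matrices and toy images with known ground truth.

The generator emulates the structure the selection pipeline is designed to
exploit: per-class blocks of equicorrelated informative features whose means
shift with the class, noisy redundant copies of informative parents, and
pure-noise columns.  Class proportions default to a realistic six-class
imbalance (the dominant "other" category holding about a third of samples).
All randomness flows from one integer seed through spawned child streams,
one per component (labels, blocks, redundant copies, noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .feature_graph import FeatureMatrix
from .preprocess import ImageRecord

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_images", "benchmark_default"]

DEFAULT_PROPORTIONS = (0.057, 0.249, 0.084, 0.139, 0.131, 0.340)


@dataclass
class SyntheticSpec:
    n_samples: int = 1200
    n_classes: int = 6
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    n_informative: int = 8
    n_redundant: int = 16
    n_noise: int = 64
    block_correlation: float = 0.6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_features == 0:
            raise ValueError("spec yields zero features")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")

    @property
    def n_features(self) -> int:
        return self.n_informative * self.n_classes + self.n_redundant + self.n_noise


@dataclass
class GroundTruth:
    informative_idx: list[int]
    redundant_map: dict[int, int]
    noise_idx: list[int]

    def __post_init__(self) -> None:
        all_idx = set(self.informative_idx) | set(self.redundant_map) | set(self.noise_idx)
        d = len(self.informative_idx) + len(self.redundant_map) + len(self.noise_idx)
        if all_idx != set(range(d)):
            raise ValueError("informative/redundant/noise sets must partition [0, d)")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "informative_idx": self.informative_idx,
                    "redundant_map": {str(k): v for k, v in self.redundant_map.items()},
                    "noise_idx": self.noise_idx,
                },
                fh,
                indent=2,
            )


def generate(spec: SyntheticSpec) -> tuple[FeatureMatrix, GroundTruth]:
    """Draw a feature matrix with planted informative/redundant/noise structure.

    Informative block b (one per class) is an equicorrelated Gaussian with
    pairwise correlation ``block_correlation``, its mean shifted by
    ``effect_size`` standard deviations for samples of class b.  Redundant
    columns copy a seeded informative parent plus N(0, noise_sd^2).  Noise
    columns are i.i.d. standard normal.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_labels = np.random.default_rng(streams[0])
    rng_blocks = np.random.default_rng(streams[1])
    rng_red = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])

    n, c = spec.n_samples, spec.n_classes
    labels = rng_labels.choice(c, size=n, p=np.asarray(spec.class_proportions))

    columns: list[np.ndarray] = []
    names: list[str] = []
    informative_idx: list[int] = []
    rho = spec.block_correlation
    for cls in range(c):
        # equicorrelated construction: sqrt(rho)*shared + sqrt(1-rho)*own
        shared = rng_blocks.standard_normal(n)
        own = rng_blocks.standard_normal((n, spec.n_informative))
        block = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * own
        block += spec.effect_size * (labels == cls)[:, None]
        for k in range(spec.n_informative):
            informative_idx.append(len(columns))
            names.append(f"inf_c{cls}_{k}")
            columns.append(block[:, k])

    redundant_map: dict[int, int] = {}
    if spec.n_redundant and informative_idx:
        parents = rng_red.choice(informative_idx, size=spec.n_redundant, replace=True)
        for m, parent in enumerate(parents):
            idx = len(columns)
            redundant_map[idx] = int(parent)
            names.append(f"red_{m}_of_{parent}")
            columns.append(columns[parent] + spec.noise_sd * rng_red.standard_normal(n))

    noise_idx: list[int] = []
    for k in range(spec.n_noise):
        noise_idx.append(len(columns))
        names.append(f"noise_{k}")
        columns.append(rng_noise.standard_normal(n))

    values = np.column_stack(columns)
    features = FeatureMatrix(values, labels, names)
    truth = GroundTruth(informative_idx, redundant_map, noise_idx)
    return features, truth


def generate_images(
    n: int, blur_fraction: float = 0.3, seed: int = 0, n_classes: int = 2, size: int = 64
) -> list[ImageRecord]:
    """Small shape-textured grayscale images, a seeded fraction Gaussian-blurred.

    Sharp images carry high-frequency speckle plus a bright rectangle, so
    their Laplacian variance is large; the blurred subset is smoothed with
    sigma 2.5, collapsing that score by orders of magnitude.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= blur_fraction <= 1.0:
        raise ValueError("blur_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_blur = int(round(blur_fraction * n))
    blur_rows = set(rng.choice(n, size=n_blur, replace=False).tolist()) if n_blur else set()
    records = []
    for i in range(n):
        img = 60.0 * rng.random((size, size))
        r0, c0 = rng.integers(0, size // 2, size=2)
        h, w = rng.integers(size // 4, size // 2, size=2)
        img[r0 : r0 + h, c0 : c0 + w] += 120.0 + 40.0 * rng.random()
        img = np.clip(img, 0.0, 255.0)
        if i in blur_rows:
            img = ndimage.gaussian_filter(img, sigma=2.5)
        records.append(
            ImageRecord(img, int(rng.integers(0, n_classes)), f"img_{i:04d}")
        )
    return records


def benchmark_default() -> tuple[FeatureMatrix, GroundTruth]:
    """The canonical recovery benchmark: n=1200, d=128 with 48 planted informative.

    Six classes with the default imbalance, 8 informative features per class
    (equicorrelated at 0.6, class shift 1 SD), 16 redundant copies at noise
    SD 0.5, 64 pure-noise columns, fixed seed.
    """
    return generate(SyntheticSpec(seed=20240601))
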