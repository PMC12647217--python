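"""Image-level preparation: resize, intensity scaling, blur exclusion, split.

Scans are resized (area/box interpolation), min-max scaled to [0, 1] per
image, screened with a variance-of-Laplacian blur score (records scoring
below the threshold are excluded from both partitions), and the survivors
are split stratified-by-class into train/test with balanced class weights
n_retained / (C * n_c).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageRecord",
    "SplitManifest",
    "resize_normalize",
    "blur_score",
    "filter_and_split",
    "read_image_directory",
    "read_image_manifest",
    "write_manifest_csv",
]


@dataclass
class ImageRecord:
    """One image: 2-D grayscale or 3-D (H, W, C) intensity array plus label and id."""

    pixels: np.ndarray
    class_label: int
    source_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.size == 0:
            raise ValueError(f"{self.source_id}: empty pixel array")
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"{self.source_id}: pixels must be 2-D or 3-D")
        if self.class_label < 0:
            raise ValueError(f"{self.source_id}: negative class label")


@dataclass
class SplitManifest:
    """Disjoint train/test/excluded id partition plus balanced class weights."""

    train_ids: list[str]
    test_ids: list[str]
    excluded_ids: list[str]
    class_weights: dict[int, float]
    labels: dict[str, int] = field(default_factory=dict)
    blur_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        groups = [set(self.train_ids), set(self.test_ids), set(self.excluded_ids)]
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("train/test/excluded ids are not pairwise disjoint")
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be strictly positive")


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    # equal-weight channel mean; the pipeline never assumes a color standard
    if pixels.ndim == 3:
        return pixels.mean(axis=2)
    return pixels


def resize_normalize(image: ImageRecord, target_hw: tuple[int, int]) -> ImageRecord:
    """Resize to (H, W) with box/area interpolation, then min-max scale to [0, 1].

    Min-max runs per image over all channels jointly.  A constant image has
    no intensity range; it is mapped to all zeros with a warning rather than
    failing, so batch pipelines survive degenerate scans.
    """
    h, w = int(target_hw[0]), int(target_hw[1])
    if h < 1 or w < 1:
        raise ValueError("target dimensions must be >= 1")
    px = image.pixels
    if px.ndim == 2:
        channels = [px]
    else:
        channels = [px[:, :, c] for c in range(px.shape[2])]
    resized = []
    for chan in channels:
        im = Image.fromarray(chan.astype(np.float32), mode="F")
        resized.append(
            np.asarray(im.resize((w, h), resample=Image.Resampling.BOX), dtype=float)
        )
    out = resized[0] if px.ndim == 2 else np.stack(resized, axis=2)
    lo, hi = float(out.min()), float(out.max())
    if hi - lo <= 0.0:
        warnings.warn(f"{image.source_id}: constant image, normalized to zeros", stacklevel=2)
        out = np.zeros_like(out)
    else:
        out = (out - lo) / (hi - lo)
    return ImageRecord(out, image.class_label, image.source_id)


def blur_score(image: ImageRecord | np.ndarray) -> float:
    """Sharpness as the variance of the 3x3 Laplacian response (reflect boundary).

    Sharp, detail-rich images produce large Laplacian excursions; smoothing
    suppresses them, so low scores flag blurry scans.
    """
    pixels = image.pixels if isinstance(image, ImageRecord) else np.asarray(image, float)
    gray = _to_gray(pixels)
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError("blur score needs at least a 3x3 image")
    response = ndimage.laplace(gray.astype(float), mode="reflect")
    return float(response.var())


def filter_and_split(
    records: list[ImageRecord],
    blur_threshold: float = 100.0,
    train_frac: float = 0.75,
    seed: int = 0,
) -> SplitManifest:
    """Blur-screen then stratified train/test split.

    Records with ``blur_score < blur_threshold`` (strict) are excluded.  Each
    retained class is shuffled with its own child stream of ``seed`` and the
    first ``floor(train_frac * class_size)`` records go to training.  Class
    weights are total_retained / (C * class_count) over retained classes, so
    sum_c weight_c * count_c equals the retained total.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    if not records:
        raise ValueError("no records given")
    scores = {r.source_id: blur_score(r) for r in records}
    excluded = [r.source_id for r in records if scores[r.source_id] < blur_threshold]
    excluded_set = set(excluded)
    labels = {r.source_id: r.class_label for r in records}

    by_class: dict[int, list[str]] = {}
    input_classes = sorted({r.class_label for r in records})
    for r in records:
        if r.source_id not in excluded_set:
            by_class.setdefault(r.class_label, []).append(r.source_id)
    for cls in input_classes:
        if cls not in by_class:
            raise ValueError(f"class {cls} has no records left after blur exclusion")
        if len(by_class[cls]) < 2:
            raise ValueError(f"class {cls} has fewer than 2 retained records")

    streams = np.random.SeedSequence(seed).spawn(len(by_class))
    train_ids: list[str] = []
    test_ids: list[str] = []
    for stream, cls in zip(streams, sorted(by_class)):
        ids = sorted(by_class[cls])
        rng = np.random.default_rng(stream)
        rng.shuffle(ids)
        n_train = int(np.floor(train_frac * len(ids)))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])

    total = sum(len(v) for v in by_class.values())
    n_classes = len(by_class)
    class_weights = {cls: total / (n_classes * len(ids)) for cls, ids in by_class.items()}
    return SplitManifest(
        train_ids=train_ids,
        test_ids=test_ids,
        excluded_ids=excluded,
        class_weights=class_weights,
        labels=labels,
        blur_scores=scores,
    )


# ---------------------------------------------------------------------------
# image / manifest I/O
# ---------------------------------------------------------------------------


def _load_image(path: Path, label: int) -> ImageRecord:
    with Image.open(path) as im:
        pixels = np.asarray(im, dtype=float)
    return ImageRecord(pixels, label, str(path))


def read_image_directory(root: str | Path) -> list[ImageRecord]:
    """Directory-per-class layout: root/<class_name>/*.png|jpg, classes sorted by name."""
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    records = []
    for label, cdir in enumerate(class_dirs):
        for path in sorted(cdir.iterdir()):
            if path.suffix.lower() in (".png", ".jpg", ".jpeg"):
                records.append(_load_image(path, label))
    return records


def read_image_manifest(manifest_csv: str | Path) -> list[ImageRecord]:
    """CSV manifest with columns ``path,label``; paths relative to the CSV file."""
    manifest_csv = Path(manifest_csv)
    records = []
    with open(manifest_csv) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(reader.fieldnames):
            raise ValueError("image manifest needs 'path' and 'label' columns")
        for row in reader:
            path = Path(row["path"])
            if not path.is_absolute():
                path = manifest_csv.parent / path
            records.append(_load_image(path, int(row["label"])))
    return records


def write_manifest_csv(manifest: SplitManifest, path: str | Path) -> None:
    """Write ``source_id,split,label,blur_score`` rows for every input record."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "split", "label", "blur_score"])
        for split_name, ids in (
            ("train", manifest.train_ids),
            ("test", manifest.test_ids),
            ("excluded", manifest.excluded_ids),
        ):
            for sid in ids:
                writer.writerow(
                    [
                        sid,
                        split_name,
                        manifest.labels.get(sid, ""),
                        f"{manifest.blur_scores.get(sid, float('nan')):.6g}",
                    ]
                )
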