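"""BRATS-style preprocessing of co-registered multimodal MRI slices.

The pipeline runs, in order:

1. brain bounding box — the smallest box containing every pixel that is
   nonzero in any modality of any slice of a patient (BRATS volumes arrive
   skull-stripped, so nonzero == brain);
2. crop to the box and resize to 128 x 128 (bilinear for intensities,
   nearest-neighbor for label maps);
3. removal of slices whose ground truth contains no tumor pixel;
4. per-channel intensity windowing: the 1st/99th percentiles map to 0/255,
   values outside are clipped;
5. z-normalization with per-modality mean/std fitted on the training set
   only (fit on train, apply to train and validation — never the reverse).

Coordinates are 0-based with half-open boxes. Modality order is fixed:
(FLAIR, T2, T1, T1C).
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _skimage_resize

from .labels import LabelMap

__all__ = [
    "MODALITIES",
    "MultimodalSlice",
    "BoundingBox",
    "DatasetStats",
    "compute_bounding_box",
    "crop_resize",
    "filter_tumor_free",
    "window_intensity",
    "window_slice",
    "fit_stats",
    "apply_stats",
    "EmptyBrainError",
    "DegenerateModalityError",
    "load_patient_nifti",
    "preprocess_patient",
    "save_slices_npz",
]

logger = logging.getLogger(__name__)

#: Fixed channel order of every multimodal slice.
MODALITIES = ("FLAIR", "T2", "T1", "T1C")


class EmptyBrainError(ValueError):
    """No nonzero pixel in any modality of any slice of the patient."""


class DegenerateModalityError(ValueError):
    """A modality with zero variance cannot be z-normalized."""


@dataclass(frozen=True)
class MultimodalSlice:
    """One axial slice: H x W x 4 intensities in (FLAIR, T2, T1, T1C) order."""

    intensities: np.ndarray
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != len(MODALITIES):
            raise ValueError(f"expected (H, W, 4) intensities, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("non-finite intensity values")
        object.__setattr__(self, "intensities", arr)

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


@dataclass(frozen=True)
class BoundingBox:
    """0-based half-open pixel box [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self):
        if not (0 <= self.row_min < self.row_max and 0 <= self.col_min < self.col_max):
            raise ValueError(f"degenerate bounding box {self}")

    def check_within(self, height: int, width: int) -> None:
        if self.row_max > height or self.col_max > width:
            raise ValueError(
                f"box {self} exceeds image bounds {height}x{width}"
            )


@dataclass(frozen=True)
class DatasetStats:
    """Per-modality mean and standard deviation over a pixel pool."""

    mean: np.ndarray  # (4,)
    std: np.ndarray   # (4,)

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64)
        std = np.asarray(self.std, dtype=np.float64)
        if mean.shape != (len(MODALITIES),) or std.shape != (len(MODALITIES),):
            raise ValueError("stats must have one entry per modality")
        if not (std > 0).all():
            raise DegenerateModalityError(f"non-positive std: {std}")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)


def compute_bounding_box(slices: list[MultimodalSlice]) -> BoundingBox:
    """Smallest box containing every nonzero pixel of a patient.

    The support is the union over all four modalities and all provided
    slices, so a single per-patient box crops every slice of the volume
    consistently.
    """
    if not slices:
        raise ValueError("no slices given")
    support = np.zeros((slices[0].height, slices[0].width), dtype=bool)
    for s in slices:
        support |= np.any(s.intensities != 0, axis=-1)
    if not support.any():
        raise EmptyBrainError("all-zero volume: no brain support found")
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    return BoundingBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def _nearest_index_map(n_in: int, n_out: int) -> np.ndarray:
    # pixel-center mapping: output center (i + 0.5) * n_in / n_out
    return np.minimum((np.arange(n_out) + 0.5) * n_in / n_out, n_in - 1).astype(np.int64)


def crop_resize(obj, box: BoundingBox, target: int = 128):
    """Crop to ``box`` and resample to ``target`` x ``target``.

    Intensities are resampled bilinearly; label maps with nearest-neighbor
    (pixel-center index mapping), so the output label vocabulary is a subset
    of the input's.
    """
    if isinstance(obj, LabelMap):
        box.check_within(obj.height, obj.width)
        cropped = obj.values[box.row_min : box.row_max, box.col_min : box.col_max]
        ri = _nearest_index_map(cropped.shape[0], target)
        ci = _nearest_index_map(cropped.shape[1], target)
        return LabelMap(cropped[np.ix_(ri, ci)])
    if isinstance(obj, MultimodalSlice):
        box.check_within(obj.height, obj.width)
        cropped = obj.intensities[box.row_min : box.row_max, box.col_min : box.col_max, :]
        out = _skimage_resize(
            cropped, (target, target), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        return MultimodalSlice(out, obj.patient_id, obj.slice_index)
    raise TypeError(f"cannot crop_resize a {type(obj).__name__}")


def filter_tumor_free(
    slices: list[MultimodalSlice], labels: list[LabelMap]
) -> tuple[list[MultimodalSlice], list[LabelMap]]:
    """Drop (slice, label) pairs whose ground truth contains no tumor pixel."""
    if len(slices) != len(labels):
        raise ValueError(f"pairing error: {len(slices)} slices vs {len(labels)} labels")
    kept = [(s, l) for s, l in zip(slices, labels) if l.has_tumor()]
    if not kept:
        return [], []
    ks, kl = zip(*kept)
    return list(ks), list(kl)


def window_intensity(
    channel: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Percentile windowing of one channel to [0, 255].

    Values at/below the ``low_pct``-th percentile map to 0, at/above the
    ``high_pct``-th to 255, linearly in between (linear-interpolation
    percentiles on the channel's own pixel values). A constant channel has a
    degenerate window and maps to all zeros with a warning.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if not np.isfinite(channel).all():
        raise ValueError("non-finite intensity values")
    a = np.percentile(channel, low_pct)
    b = np.percentile(channel, high_pct)
    if b == a:
        warnings.warn("degenerate intensity window (constant channel); output all zeros")
        return np.zeros_like(channel)
    return np.clip((channel - a) / (b - a), 0.0, 1.0) * 255.0


def window_slice(s: MultimodalSlice, low_pct: float = 1.0, high_pct: float = 99.0) -> MultimodalSlice:
    """Window each modality of a slice independently (per-slice percentiles)."""
    out = np.stack(
        [window_intensity(s.intensities[..., d], low_pct, high_pct) for d in range(4)],
        axis=-1,
    )
    return MultimodalSlice(out, s.patient_id, s.slice_index)


def fit_stats(dataset: list[MultimodalSlice]) -> DatasetStats:
    """Per-modality mean/std over all pixels of all slices in the dataset.

    Fit on the *training* split of a fold only; applying the same stats to
    the validation split is what keeps the normalization leakage-free.
    """
    if not dataset:
        raise ValueError("empty dataset")
    pool = np.concatenate([s.intensities.reshape(-1, 4) for s in dataset], axis=0)
    mean = pool.mean(axis=0)
    std = pool.std(axis=0)
    if not (std > 0).all():
        raise DegenerateModalityError(f"zero-variance modality in dataset: std={std}")
    return DatasetStats(mean, std)


def apply_stats(s: MultimodalSlice, stats: DatasetStats) -> MultimodalSlice:
    """z-normalize a slice channel-wise with precomputed dataset statistics."""
    out = (s.intensities - stats.mean) / stats.std
    return MultimodalSlice(out, s.patient_id, s.slice_index)


# ---------------------------------------------------------------------------
# NIfTI input and NPZ output

def load_patient_nifti(
    modality_paths: dict[str, str | Path],
    seg_path: str | Path,
    patient_id: str = "",
) -> tuple[list[MultimodalSlice], list[LabelMap]]:
    """Load one patient's four modality volumes plus segmentation.

    ``modality_paths`` maps each name in :data:`MODALITIES` to a .nii/.nii.gz
    file; volumes must be co-registered and share shape. Axial slices are
    taken along the last axis.
    """
    import nibabel as nib

    vols = []
    for mod in MODALITIES:
        if mod not in modality_paths:
            raise ValueError(f"missing modality {mod}")
        vols.append(np.asarray(nib.load(str(modality_paths[mod])).dataobj, dtype=np.float64))
    seg = np.asarray(nib.load(str(seg_path)).dataobj)
    seg = np.rint(seg).astype(np.int64)
    shapes = {v.shape for v in vols} | {seg.shape}
    if len(shapes) != 1:
        raise ValueError(f"volumes not co-registered: shapes {shapes}")
    n_slices = vols[0].shape[2]
    slices, labels = [], []
    for z in range(n_slices):
        img = np.stack([v[:, :, z] for v in vols], axis=-1)
        slices.append(MultimodalSlice(img, patient_id, z))
        labels.append(LabelMap(seg[:, :, z]))
    return slices, labels


def preprocess_patient(
    slices: list[MultimodalSlice],
    labels: list[LabelMap],
    target: int = 128,
    per_slice_box: bool = False,
) -> tuple[list[MultimodalSlice], list[LabelMap]]:
    """Steps 1-4 for one patient: bounding box, crop+resize, filter, window.

    z-normalization (step 5) is deliberately absent: its statistics must be
    fitted on a training split across patients (see :func:`fit_stats`).
    ``per_slice_box=True`` computes a separate box per slice instead of one
    per patient (deforms anatomy inconsistently across the volume; provided
    for literal replication only).
    """
    if len(slices) != len(labels):
        raise ValueError("pairing error")
    out_s, out_l = [], []
    if not per_slice_box:
        box = compute_bounding_box(slices)
    for s, l in zip(slices, labels):
        b = compute_bounding_box([s]) if per_slice_box else box
        out_s.append(crop_resize(s, b, target))
        out_l.append(crop_resize(l, b, target))
    out_s, out_l = filter_tumor_free(out_s, out_l)
    out_s = [window_slice(s) for s in out_s]
    return out_s, out_l


def save_slices_npz(
    out_dir: str | Path,
    slices: list[MultimodalSlice],
    labels: list[LabelMap],
    folds: list[int] | None = None,
) -> Path:
    """Write one NPZ per slice ({image, label}) plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (s, l) in enumerate(zip(slices, labels)):
        fname = f"slice_{i:05d}.npz"
        np.savez(
            out_dir / fname,
            image=s.intensities.astype(np.float32),
            label=l.values.astype(np.int16),
        )
        entry = {"file": fname, "patient_id": s.patient_id, "slice_index": s.slice_index}
        if folds is not None:
            entry["fold"] = int(folds[i])
        manifest.append(entry)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_slices_npz(in_dir: str | Path) -> tuple[list[MultimodalSlice], list[LabelMap]]:
    """Read back a directory written by :func:`save_slices_npz`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    slices, labels = [], []
    for entry in manifest:
        with np.load(in_dir / entry["file"]) as z:
            slices.append(
                MultimodalSlice(z["image"], entry["patient_id"], entry["slice_index"])
            )
            labels.append(LabelMap(z["label"]))
    return slices, labels
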