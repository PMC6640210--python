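"""Synthetic multimodal slice phantoms with BRATS-like tumor anatomy.

Each phantom is an axial "slice" containing an elliptical brain on a zero
background and a nested tumor built from three concentric discs: the whole
tumor (radius ``r_wt``) whose outer annulus is peritumoral edema (label 2),
a tumor core (``r_tc``) whose annulus is necrotic/non-enhancing core
(label 1), and an enhancing-tumor disc (``r_et``, label 4). The nesting
ET < TC < WT therefore holds by construction.

Intensities emulate the modality-specific contrast that drives real
segmentation: edema is bright on FLAIR, enhancing tumor is bright on T1C
(gadolinium), and the necrotic core is hypointense on T2. The default
contrast table separates each tumor tissue from brain by at least three
noise standard deviations on its designated modality, so with the noise
turned off a per-modality threshold separates the tissues perfectly — the
segmentation problem posed by a phantom dataset is solvable by a small
network, which is what the learnability tests rely on.

Phantoms are geometric by design (discs and ellipses, optional smooth bias
field, additive Gaussian noise); they exercise pipeline correctness and
learnability, not anatomical realism.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .labels import LabelMap
from .preprocess import MODALITIES, MultimodalSlice

__all__ = [
    "PhantomParams",
    "TISSUES",
    "DEFAULT_CONTRAST",
    "generate_slice",
    "generate_dataset",
    "default_param_sampler",
]

#: Tissue order of the contrast table columns (brain = healthy tissue).
TISSUES = ("brain", "NET", "ED", "ET")

#: Mean intensity per (modality row, tissue column), arbitrary scanner units.
#: Designated contrasts (>= 3 noise SDs at the default noise_sd=10):
#: edema vs brain on FLAIR (+70), enhancing tumor vs brain on T1C (+80),
#: necrotic core vs brain on T2 (-60).
DEFAULT_CONTRAST = np.array(
    #  brain   NET    ED     ET
    [[100.0, 130.0, 170.0, 130.0],   # FLAIR
     [100.0,  40.0, 140.0, 120.0],   # T2
     [100.0,  80.0,  90.0, 110.0],   # T1
     [100.0,  90.0,  95.0, 180.0]],  # T1C
)

_TISSUE_LABEL = {"brain": 0, "NET": 1, "ED": 2, "ET": 4}


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast and noise of one phantom slice.

    Radii are in pixels and must nest strictly (r_et < r_tc < r_wt);
    ``r_wt = 0`` produces a tumor-free slice. The whole-tumor disc must lie
    inside the brain ellipse (centered in the image with semi-axes
    ``brain_axes``).
    """

    image_size: int = 128
    brain_axes: tuple[float, float] = (52.0, 58.0)
    tumor_center: tuple[float, float] = (76.0, 56.0)
    r_wt: float = 20.0
    r_tc: float = 13.0
    r_et: float = 7.0
    contrast_table: np.ndarray = field(default_factory=lambda: DEFAULT_CONTRAST.copy())
    noise_sd: float = 10.0
    bias_field: bool = False
    seed: int = 0

    def __post_init__(self):
        tab = np.asarray(self.contrast_table, dtype=np.float64)
        if tab.shape != (len(MODALITIES), len(TISSUES)):
            raise ValueError(f"contrast_table must be {len(MODALITIES)}x{len(TISSUES)}")
        object.__setattr__(self, "contrast_table", tab)
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.r_wt > 0:
            if not (0 < self.r_et < self.r_tc < self.r_wt):
                raise ValueError(
                    f"radii must nest strictly: r_et={self.r_et} < r_tc={self.r_tc}"
                    f" < r_wt={self.r_wt}"
                )
        elif self.r_tc > 0 or self.r_et > 0:
            raise ValueError("r_wt=0 (tumor-free) requires r_tc=r_et=0")

    def tissue_mean(self, modality: str, tissue: str) -> float:
        return float(
            self.contrast_table[MODALITIES.index(modality), TISSUES.index(tissue)]
        )


def _disc_mask(rows, cols, center, radius) -> np.ndarray:
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius ** 2


def generate_slice(
    params: PhantomParams, patient_id: str = "phantom", slice_index: int = 0
) -> tuple[MultimodalSlice, LabelMap]:
    """Render one phantom slice; deterministic given ``params.seed``."""
    n = params.image_size
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    ay, ax = params.brain_axes
    brain = ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0

    values = np.zeros((n, n), dtype=np.int64)
    if params.r_wt > 0:
        wt = _disc_mask(rows, cols, params.tumor_center, params.r_wt)
        tc = _disc_mask(rows, cols, params.tumor_center, params.r_tc)
        et = _disc_mask(rows, cols, params.tumor_center, params.r_et)
        if np.any(wt & ~brain):
            raise ValueError("tumor disc extends outside the brain ellipse")
        values[wt] = _TISSUE_LABEL["ED"]
        values[tc] = _TISSUE_LABEL["NET"]
        values[et] = _TISSUE_LABEL["ET"]
    labels = LabelMap(values)

    tissue_index = np.zeros((n, n), dtype=np.int64)  # brain
    for t, lab in (("NET", 1), ("ED", 2), ("ET", 4)):
        tissue_index[values == lab] = TISSUES.index(t)

    rng = np.random.default_rng(params.seed)
    img = np.zeros((n, n, len(MODALITIES)), dtype=np.float64)
    for d in range(len(MODALITIES)):
        chan = params.contrast_table[d, tissue_index]
        if params.bias_field:
            # smooth multiplicative inhomogeneity, random phase per channel
            ph_r, ph_c = rng.uniform(0, 2 * np.pi, size=2)
            bias = 1.0 + 0.15 * np.sin(np.pi * rows / n + ph_r) * np.sin(
                np.pi * cols / n + ph_c
            )
            chan = chan * bias
        if params.noise_sd > 0:
            chan = chan + rng.normal(0.0, params.noise_sd, size=(n, n))
        img[..., d] = np.where(brain, chan, 0.0)
    return MultimodalSlice(img, patient_id, slice_index), labels


def default_param_sampler(
    rng: np.random.Generator, image_size: int = 128
) -> PhantomParams:
    """Per-patient jitter of tumor geometry and contrast.

    Radii scale with the image size; the tumor center is placed so the
    whole-tumor disc stays inside the brain ellipse.
    """
    s = image_size / 128.0
    r_wt = rng.uniform(16.0, 24.0) * s
    r_tc = r_wt * rng.uniform(0.55, 0.7)
    r_et = r_tc * rng.uniform(0.45, 0.6)
    ay = rng.uniform(48.0, 56.0) * s
    ax = rng.uniform(52.0, 60.0) * s
    c = (image_size - 1) / 2.0
    margin = min(ay, ax) - r_wt - 2.0 * s
    offset = rng.uniform(0.0, max(margin, 0.0) * 0.6)
    angle = rng.uniform(0, 2 * np.pi)
    center = (c + offset * np.sin(angle), c + offset * np.cos(angle))
    contrast = DEFAULT_CONTRAST * (1.0 + rng.normal(0.0, 0.02, DEFAULT_CONTRAST.shape))
    return PhantomParams(
        image_size=image_size,
        brain_axes=(ay, ax),
        tumor_center=center,
        r_wt=r_wt,
        r_tc=r_tc,
        r_et=r_et,
        contrast_table=contrast,
        seed=int(rng.integers(2 ** 31)),
    )


def generate_dataset(
    n_patients: int,
    slices_per_patient: int = 3,
    param_sampler: Callable[[np.random.Generator, int], PhantomParams] | None = None,
    seed: int = 0,
    image_size: int = 128,
    noise_sd: float | None = None,
) -> tuple[list[MultimodalSlice], list[LabelMap]]:
    """Generate a phantom dataset of ``n_patients`` x ``slices_per_patient``.

    One independent random stream is spawned per patient from the master
    seed, so the dataset is reproducible (and patients could be rendered in
    parallel without changing the result). ``param_sampler(rng, image_size)``
    draws the per-patient geometry/contrast; slices within a patient share
    geometry but get fresh noise seeds. Tumor-free slices (``r_wt = 0``) are
    kept — downstream filtering is the preprocessing pipeline's job.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    sampler = param_sampler or default_param_sampler
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    slices, labels = [], []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        params = sampler(rng, image_size)
        if noise_sd is not None:
            params = replace(params, noise_sd=noise_sd)
        pid = f"phantom_{p:03d}"
        for z in range(slices_per_patient):
            sp = replace(params, seed=int(rng.integers(2 ** 31)))
            img, lab = generate_slice(sp, patient_id=pid, slice_index=z)
            slices.append(img)
            labels.append(lab)
    return slices, labels
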