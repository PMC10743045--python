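"""Lesion segmentation methods and pairwise agreement.

Three delineations per subject drive the reproducibility analysis:

* ``manual`` — in synthetic runs, a randomly perturbed copy of the ground
  truth (stand-in for an operator's slice-by-slice contour),
* ``thresholding`` — a fixed fraction of the maximum uptake inside a user
  ROI box,
* ``region_growing`` — deterministic region-based contour evolution
  (morphological Chan-Vese) seeded by the ROI.

Pairwise agreement is the Jaccard index J(X, Y) = |X∩Y| / (|X|+|Y|-|X∩Y|),
averaged over subjects per method pair.  Subjects where either
semi-automatic method fails are excluded cohort-wide, mirroring the
exclusion of unsegmentable cases from a real cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import morphological_chan_vese

from .phantoms import ScanCase, perturb_mask

__all__ = [
    "RoiBox",
    "SegmentationResult",
    "SegmentationSet",
    "AgreementMatrix",
    "METHODS",
    "roi_from_mask",
    "threshold_segment",
    "region_grow_segment",
    "jaccard",
    "agreement_matrix",
    "segment_case",
    "segment_cohort",
]

METHODS = ("manual", "thresholding", "region_growing")

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned voxel box, inclusive lower / exclusive upper corners."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(u <= lo for lo, u in zip(self.lower, self.upper)):
            raise ValueError("RoiBox is empty")
        if any(lo < 0 for lo in self.lower):
            raise ValueError("RoiBox lower corner outside grid")

    def validate_in(self, shape) -> None:
        if any(u > n for u, n in zip(self.upper, shape)):
            raise ValueError(f"RoiBox {self} exceeds grid {shape}")

    @property
    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, u) for lo, u in zip(self.lower, self.upper))

    def to_json(self) -> str:
        import json

        return json.dumps({"lower": list(self.lower), "upper": list(self.upper)})

    @classmethod
    def from_json(cls, text: str) -> "RoiBox":
        import json

        d = json.loads(text)
        return cls(tuple(d["lower"]), tuple(d["upper"]))


@dataclass
class SegmentationResult:
    mask: np.ndarray | None
    success: bool
    reason: str = ""


@dataclass
class SegmentationSet:
    """Per-subject method -> mask mapping with success flags."""

    subject_id: str
    masks: dict = field(default_factory=dict)
    success: dict = field(default_factory=dict)

    def add(self, method: str, result: SegmentationResult) -> None:
        self.success[method] = result.success
        if result.success:
            self.masks[method] = result.mask

    def complete(self, methods=METHODS) -> bool:
        return all(self.success.get(m, False) for m in methods)


def roi_from_mask(mask: np.ndarray, margin: int = 4) -> RoiBox:
    """Bounding box of a mask expanded by ``margin`` voxels, clipped to grid."""
    if not mask.any():
        raise ValueError("mask is empty")
    idx = np.nonzero(mask)
    lower = tuple(max(int(i.min()) - margin, 0) for i in idx)
    upper = tuple(min(int(i.max()) + 1 + margin, n) for i, n in zip(idx, mask.shape))
    return RoiBox(lower, upper)


def jaccard(mask_x: np.ndarray, mask_y: np.ndarray) -> float:
    """Jaccard index of two binary masks on the same grid."""
    x = np.asarray(mask_x, dtype=bool)
    y = np.asarray(mask_y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    inter = int(np.logical_and(x, y).sum())
    union = int(x.sum()) + int(y.sum()) - inter
    if union == 0:
        raise ValueError("Jaccard undefined: both masks empty")
    return inter / union


def _keep_component_at(mask: np.ndarray, voxel) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CONN26)
    lab = labels[voxel]
    if lab == 0:
        return np.zeros_like(mask)
    return labels == lab


def threshold_segment(
    image: np.ndarray, roi: RoiBox, fraction: float = 0.4
) -> SegmentationResult:
    """Threshold at ``fraction`` of the ROI maximum, keep the hot component.

    Voxels inside the ROI at or above ``fraction * max(ROI)`` form the
    candidate mask; only the 26-connected component containing the ROI's
    maximum voxel is kept (suppresses background speckle).  Failure modes:
    a constant ROI (no contrast), a mask covering essentially the whole ROI
    (threshold below background: nothing stands out), or an empty result.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    roi.validate_in(image.shape)
    crop = image[roi.slices]
    cmax = float(crop.max())
    cmin = float(crop.min())
    full = np.zeros(image.shape, dtype=bool)
    if cmax == cmin:
        full[roi.slices] = True
        return SegmentationResult(None, False, "constant intensity inside ROI")
    candidate = crop >= fraction * cmax
    peak = np.unravel_index(int(np.argmax(crop)), crop.shape)
    component = _keep_component_at(candidate, peak)
    if not component.any():
        return SegmentationResult(None, False, "empty mask after thresholding")
    if component.mean() > 0.9:
        return SegmentationResult(
            None, False, "no lesion above background: mask fills the ROI"
        )
    full[roi.slices] = component
    return SegmentationResult(full, True)


def region_grow_segment(
    image: np.ndarray,
    roi: RoiBox,
    iterations: int = 60,
    smoothing: int = 0,
    presmooth_voxels: float = 0.7,
) -> SegmentationResult:
    """Region-based contour evolution (morphological Chan-Vese) on the ROI crop.

    The crop is lightly Gaussian-filtered (``presmooth_voxels``) for noise
    robustness — morphological curvature smoothing erodes small lesions, so
    the contour itself evolves unsmoothed by default.  Initialized from a
    box shrunk 25% inside the ROI; the phase with the higher mean intensity
    is taken as the lesion, restricted to the component containing the ROI
    maximum.  Deterministic.  Fails on a contrast-free ROI or when the
    evolution returns an empty or ROI-filling mask.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    roi.validate_in(image.shape)
    crop = np.asarray(image[roi.slices], dtype=np.float64)
    if crop.max() == crop.min():
        return SegmentationResult(None, False, "no intensity contrast inside ROI")
    if presmooth_voxels > 0:
        crop = ndimage.gaussian_filter(crop, presmooth_voxels)

    init = np.zeros(crop.shape, dtype=np.int8)
    shrink = [max(1, int(round(0.25 * n / 2))) for n in crop.shape]
    init[tuple(slice(s, n - s) for s, n in zip(shrink, crop.shape))] = 1

    ls = morphological_chan_vese(
        crop, num_iter=iterations, init_level_set=init, smoothing=smoothing
    ).astype(bool)
    # the level set labels two phases; pick the brighter one as lesion
    if ls.any() and (~ls).any():
        if crop[ls].mean() < crop[~ls].mean():
            ls = ~ls
    elif not ls.any():
        return SegmentationResult(None, False, "contour evolution collapsed to empty")

    peak = np.unravel_index(int(np.argmax(crop)), crop.shape)
    component = _keep_component_at(ls, peak)
    if not component.any():
        return SegmentationResult(None, False, "lesion phase missed the ROI maximum")
    if component.mean() > 0.9:
        return SegmentationResult(None, False, "contour filled the ROI")
    full = np.zeros(image.shape, dtype=bool)
    full[roi.slices] = component
    return SegmentationResult(full, True)


def segment_case(
    case: ScanCase,
    roi: RoiBox | None = None,
    threshold_fraction: float = 0.4,
    rg_iterations: int = 60,
    rg_smoothing: int = 0,
    manual_amplitude_mm: float = 2.0,
    manual_seed: int = 0,
) -> SegmentationSet:
    """Run all three methods on one case.

    The "manual" mask is a boundary-perturbed ground truth (amplitude
    ``manual_amplitude_mm``); the ROI defaults to the truth bounding box
    with margin.
    """
    if roi is None:
        roi = roi_from_mask(case.truth_mask)
    out = SegmentationSet(subject_id=case.subject_id)
    manual = perturb_mask(
        case.truth_mask, case.spacing, manual_amplitude_mm, seed=manual_seed
    )
    out.add("manual", SegmentationResult(manual, True))
    out.add("thresholding", threshold_segment(case.image, roi, threshold_fraction))
    out.add(
        "region_growing",
        region_grow_segment(case.image, roi, rg_iterations, rg_smoothing),
    )
    return out


def segment_cohort(cases, seed: int = 0, **kwargs) -> list[SegmentationSet]:
    """Segment every case; per-case manual seeds derive from ``seed``."""
    rng = np.random.default_rng(seed)
    out = []
    for case in cases:
        out.append(
            segment_case(case, manual_seed=int(rng.integers(0, 2**31 - 1)), **kwargs)
        )
    return out


@dataclass
class AgreementMatrix:
    """Mean pairwise Jaccard over subjects, per method pair."""

    methods: tuple
    values: np.ndarray  # symmetric, diagonal 1
    n_subjects: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.methods, columns=self.methods)

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.methods.index(a), self.methods.index(b)])


def agreement_matrix(
    segmentations: list[SegmentationSet], methods=METHODS
) -> AgreementMatrix:
    """Average Jaccard per method pair over the filtered cohort.

    Subjects with any failed method are dropped cohort-wide before
    averaging (the 81 -> 78 exclusion pattern: real cohorts drop subjects
    the semi-automatic methods cannot segment).
    """
    complete = [s for s in segmentations if s.complete(methods)]
    if not complete:
        raise ValueError("no subject with all methods succeeding")
    k = len(methods)
    values = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        js = [jaccard(s.masks[methods[i]], s.masks[methods[j]]) for s in complete]
        values[i, j] = values[j, i] = float(np.mean(js))
    return AgreementMatrix(tuple(methods), values, len(complete))
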