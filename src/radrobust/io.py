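"""Volume I/O, cohort serialization and run configuration.

NIfTI is the canonical volume format: arrays are (x, y, z), spacing is
carried in the affine (diagonal mm), masks are written as 0/1 integers and
validated on read.  All tabular outputs are UTF-8 CSV with a
schema-version header line.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .filters import ExtractionConfig
from .phantoms import CohortSpec, ScanCase

__all__ = [
    "SCHEMA_VERSION",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "write_cohort",
    "read_cohort",
    "write_csv",
    "read_csv",
    "derive_seed",
    "SegmentationParams",
    "CVSettings",
    "RunConfig",
]

SCHEMA_VERSION = "radrobust-schema-1"


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from (master, tag)."""
    digest = hashlib.sha256(f"{master_seed}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(array: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), _affine(spacing))
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI volume; returns (array, spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: missing or invalid voxel spacing {spacing}")
    return np.asarray(data, dtype=np.float64), spacing


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a binary mask; any value outside {0, 1} is a validation error."""
    data, spacing = read_volume(path)
    values = np.unique(data)
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise ValueError(f"{path}: mask contains non-binary values {values[:5]}")
    return data.astype(bool), spacing


def write_cohort(cases: list[ScanCase], directory) -> Path:
    """Write paired NIfTI volume/mask files plus a cohort manifest CSV."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        write_volume(case.image, case.spacing, d / f"{case.subject_id}_image.nii.gz")
        write_mask(case.truth_mask, case.spacing, d / f"{case.subject_id}_mask.nii.gz")
        rows.append(
            {
                "subject_id": case.subject_id,
                "label": case.label,
                "spacing_x": case.spacing[0],
                "spacing_y": case.spacing[1],
                "spacing_z": case.spacing[2],
                "seed": case.params.get("seed", ""),
            }
        )
    write_csv(pd.DataFrame(rows), d / "manifest.csv")
    return d


def read_cohort(directory) -> list[ScanCase]:
    d = Path(directory)
    manifest = read_csv(d / "manifest.csv")
    cases = []
    for _, row in manifest.iterrows():
        image, spacing = read_volume(d / f"{row.subject_id}_image.nii.gz")
        mask, _ = read_mask(d / f"{row.subject_id}_mask.nii.gz")
        cases.append(
            ScanCase(
                subject_id=row.subject_id,
                image=image,
                spacing=spacing,
                truth_mask=mask,
                label=row.label,
            )
        )
    return cases


def write_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    """UTF-8 CSV with a schema-version header comment line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        df.to_csv(fh, index=index)


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


@dataclass(frozen=True)
class SegmentationParams:
    threshold_fraction: float = 0.4
    rg_iterations: int = 60
    rg_smoothing: int = 0
    manual_amplitude_mm: float = 2.0


@dataclass(frozen=True)
class CVSettings:
    k: int = 5
    reps: int = 30
    n_boot: int = 1000


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML.

    Every random stage derives its seed from ``master_seed`` via a stable
    hash of the stage name.
    """

    outdir: str = "radrobust-run"
    master_seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cv: CVSettings = field(default_factory=CVSettings)
    write_volumes: bool = False

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)

        def tup(x):
            return tuple(x) if isinstance(x, list) else x

        cohort = d.get("cohort", {})
        for key in ("radius_range_mm",):
            if key in cohort:
                cohort[key] = tup(cohort[key])
        extraction = d.get("extraction", {})
        for key in ("resample_spacing", "log_sigmas"):
            if key in extraction:
                extraction[key] = tup(extraction[key])
        return cls(
            outdir=d.get("outdir", "radrobust-run"),
            master_seed=d.get("master_seed", 0),
            cohort=CohortSpec(**cohort),
            extraction=ExtractionConfig(**extraction),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            cv=CVSettings(**d.get("cv", {})),
            write_volumes=d.get("write_volumes", False),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
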