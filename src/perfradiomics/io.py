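"""Data model and readers/writers for perfusion radiomics artifacts.

Volumes and masks travel as NIfTI-1 files (nibabel), cohort manifests and
feature tables as CSV (pandas), run configuration as YAML or JSON.  Maps and
masks are required to be pre-aligned on the same voxel grid; no resampling or
registration happens here.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "MapKind",
    "ClassLabel",
    "ParametricVolume",
    "VOIMask",
    "CohortManifest",
    "FeatureTable",
    "RunConfig",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "load_manifest",
    "write_manifest",
    "read_feature_table",
    "write_feature_table",
]


class MapKind(str, enum.Enum):
    """Which pharmacokinetic parametric map a volume holds.

    KTRANS is the DCE-MRI volume transfer constant (min^-1); RCBV is the
    leakage-corrected DSC-MRI relative cerebral blood volume (mL/100 mL).
    """

    KTRANS = "ktrans"
    RCBV = "rcbv"


class ClassLabel(str, enum.Enum):
    """Outcome class: pseudoprogression (PSP) or progressive disease (PD)."""

    PSP = "PsP"
    PD = "PD"

    @classmethod
    def parse(cls, text: str) -> "ClassLabel":
        norm = str(text).strip().lower()
        if norm in {"psp", "pseudoprogression"}:
            return cls.PSP
        if norm in {"pd", "progression", "progressive disease"}:
            return cls.PD
        raise ValueError(f"unknown class label {text!r} (expected PsP or PD)")


@dataclass
class ParametricVolume:
    """A 3D parametric map: scalar voxel grid + mm spacing + map kind.

    Axes follow (row, col, slice): the first two axes are in-plane (axial),
    the third indexes slices.  Voxel indices are 0-based.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    map_kind: MapKind
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got {self.voxels.ndim}D grid of shape "
                f"{self.voxels.shape}"
            )
        if self.voxels.size == 0:
            raise ValueError("volume grid is empty")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.map_kind = MapKind(self.map_kind)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class VOIMask:
    """Binary 3D volume-of-interest mask aligned to a companion volume."""

    voxels: np.ndarray

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got {vox.ndim}D")
        self.voxels = vox > 0.5
        if not self.voxels.any():
            raise ValueError("empty VOI: mask has no foreground voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_companion(self, volume: ParametricVolume) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )
        masked = volume.voxels[self.voxels]
        bad = np.count_nonzero(~np.isfinite(masked))
        if bad:
            raise ValueError(f"{bad} non-finite voxel(s) inside the VOI")


@dataclass
class ManifestRow:
    subject_id: str
    label: ClassLabel
    ktrans_path: str
    ktrans_mask_path: str
    rcbv_path: str
    rcbv_mask_path: str


@dataclass
class CohortManifest:
    """Cohort listing: one row per subject with paths to both maps and masks."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_id(s) in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.rows]

    @property
    def labels(self) -> list[ClassLabel]:
        return [r.label for r in self.rows]

    def class_counts(self) -> dict[ClassLabel, int]:
        counts = {ClassLabel.PD: 0, ClassLabel.PSP: 0}
        for r in self.rows:
            counts[r.label] += 1
        return counts

    def require_both_classes(self) -> None:
        counts = self.class_counts()
        missing = [k.value for k, v in counts.items() if v == 0]
        if missing:
            raise ValueError(
                f"model building requires both classes; manifest lacks {missing}"
            )


@dataclass
class FeatureTable:
    """Subjects x named radiomic features, optionally with class labels."""

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[ClassLabel] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n, p = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError("row count does not match number of subject ids")
        if p != len(self.feature_names):
            raise ValueError("column count does not match number of feature names")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if self.labels is not None:
            if len(self.labels) != n:
                raise ValueError("label count does not match row count")
            self.labels = [ClassLabel(l) for l in self.labels]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def label_array(self) -> np.ndarray:
        """Labels as 0/1 with PD (the positive class) coded 1."""
        if self.labels is None:
            raise ValueError("feature table carries no labels")
        return np.array([1 if l is ClassLabel.PD else 0 for l in self.labels])

    def select(self, names: Sequence[str]) -> "FeatureTable":
        idx = {f: i for i, f in enumerate(self.feature_names)}
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"features not in table: {missing[:5]}")
        cols = [idx[n] for n in names]
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            feature_names=list(names),
            values=self.values[:, cols],
            labels=None if self.labels is None else list(self.labels),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        if self.labels is not None:
            df.insert(1, "label", [l.value for l in self.labels])
        return df


IN_PLANE_DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
"""The four in-plane (row, col) GLCM offsets: 0, 45, 90 and 135 degrees."""


@dataclass
class RunConfig:
    """Knobs for the standard extraction/selection/modeling pipeline."""

    gray_levels: list[int] = field(default_factory=lambda: [8, 16, 32, 64, 256])
    distance: int = 1
    directions: tuple[tuple[int, int], ...] = IN_PLANE_DIRECTIONS
    summaries: tuple[str, ...] = ("avg", "range", "angvar")
    sweep_start: int = 310
    sweep_stop: int = 20
    sweep_step: int = 10
    classifier: str = "svm"
    kernel: str = "linear"
    svm_c: float = 1.0
    tree_cf: float = 0.25
    standardize: bool = True
    selection_mode: str = "pooled"
    featureset_size: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 2 for g in self.gray_levels):
            raise ValueError("all gray levels must be >= 2")
        if self.distance < 1:
            raise ValueError("GLCM distance must be >= 1 voxel")
        self.directions = tuple(tuple(d) for d in self.directions)  # type: ignore[assignment]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["directions"] = [list(d) for d in self.directions]
        data["summaries"] = list(self.summaries)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _nifti_spacing(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(
    path: str | Path, map_kind: MapKind | str, subject_id: str = ""
) -> ParametricVolume:
    """Read a 3D parametric map from a NIfTI-1 file.

    The voxel grid and mm spacing come from the file; ``map_kind`` is caller
    metadata (NIfTI has no standard slot for it).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, file has {data.ndim} dimensions")
    logger.info("read volume %s shape=%s", path, data.shape)
    return ParametricVolume(
        voxels=data,
        spacing=_nifti_spacing(img),
        map_kind=MapKind(map_kind),
        subject_id=subject_id,
    )


def read_mask(path: str | Path, companion: ParametricVolume | None = None) -> VOIMask:
    """Read a binary VOI mask from NIfTI; float-stored masks binarize at > 0.5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, file has {data.ndim} dimensions")
    mask = VOIMask(voxels=data)
    if companion is not None:
        mask.check_companion(companion)
    logger.info("read mask %s foreground=%d", path, mask.n_voxels)
    return mask


def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: ParametricVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.voxels, _affine_from_spacing(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    logger.info("wrote volume %s", path)


def write_mask(mask: VOIMask, path: str | Path, spacing: Sequence[float] = (1, 1, 1)) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.int8), _affine_from_spacing(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))
    logger.info("wrote mask %s", path)


# ---------------------------------------------------------------------------
# Manifest and feature-table CSV I/O

_MANIFEST_COLUMNS = [
    "subject_id",
    "label",
    "ktrans_path",
    "ktrans_mask_path",
    "rcbv_path",
    "rcbv_mask_path",
]


def load_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    rows = [
        ManifestRow(
            subject_id=r.subject_id,
            label=ClassLabel.parse(r.label),
            ktrans_path=r.ktrans_path,
            ktrans_mask_path=r.ktrans_mask_path,
            rcbv_path=r.rcbv_path,
            rcbv_mask_path=r.rcbv_mask_path,
        )
        for r in df.itertuples()
    ]
    logger.info("loaded manifest %s with %d subjects", path, len(rows))
    return CohortManifest(rows=rows)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "label": r.label.value,
                "ktrans_path": r.ktrans_path,
                "ktrans_mask_path": r.ktrans_mask_path,
                "rcbv_path": r.rcbv_path,
                "rcbv_mask_path": r.rcbv_mask_path,
            }
            for r in manifest.rows
        ],
        columns=_MANIFEST_COLUMNS,
    )
    df.to_csv(path, index=False)
    logger.info("wrote manifest %s", path)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with 17 significant digits (lossless for f64)."""
    table.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    logger.info("wrote feature table %s (%d x %d)", path, table.n_subjects, table.n_features)


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"feature table {path} lacks a subject_id column")
    subject_ids = df["subject_id"].astype(str).tolist()
    labels = None
    meta = ["subject_id"]
    if "label" in df.columns:
        labels = [ClassLabel.parse(l) for l in df["label"]]
        meta.append("label")
    feat = df.drop(columns=meta)
    return FeatureTable(
        subject_ids=subject_ids,
        feature_names=list(feat.columns),
        values=feat.to_numpy(dtype=np.float64),
        labels=labels,
    )
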