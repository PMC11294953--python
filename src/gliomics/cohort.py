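"""Cohort I/O: studies, segmentations, ROIs and feature tables.

A *study* is one patient's four coregistered MRI sequences (T1, T1c, T2,
FLAIR) plus an integer-labeled tumor segmentation, all on the same 1 mm
isotropic voxel grid. Two segmentation label schemes are supported for
multiregional masks, plus a whole-tumor-only binary scheme:

* ``FETS``  — 1 = necrotic core (NCR), 2 = nonenhancing tumor / edema
  (NET/ED), 4 = enhancing tumor (ET)
* ``UCSF``  — 1 = NET/NCR, 2 = ED, 4 = ET
* ``WT_ONLY`` — 1 = whole tumor

From a labeled segmentation two regions of interest are constructed:
``WT`` (whole tumor, union of all tumor labels) and ``NONENH``
(NET + NCR + ED, the tumor minus the enhancing component). Under the
whole-tumor-only scheme the nonenhancing ROI cannot be constructed and
requesting it is an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

SEQUENCES = ("T1", "T1c", "T2", "FLAIR")

MANIFEST_COLUMNS = ("patient_id", "t1", "t1c", "t2", "flair", "seg", "scheme", "idh")


class Scheme(str, Enum):
    FETS = "FETS"
    UCSF = "UCSF"
    WT_ONLY = "WT_ONLY"


class ROIKind(str, Enum):
    WT = "WT"
    NONENH = "NONENH"


#: labels allowed per scheme
_SCHEME_LABELS = {
    Scheme.FETS: {0, 1, 2, 4},
    Scheme.UCSF: {0, 1, 2, 4},
    Scheme.WT_ONLY: {0, 1},
}

#: labels forming each ROI per scheme (None = unsupported)
_ROI_LABELS = {
    (Scheme.FETS, ROIKind.WT): {1, 2, 4},
    (Scheme.FETS, ROIKind.NONENH): {1, 2},
    (Scheme.UCSF, ROIKind.WT): {1, 2, 4},
    (Scheme.UCSF, ROIKind.NONENH): {1, 2},
    (Scheme.WT_ONLY, ROIKind.WT): {1},
    (Scheme.WT_ONLY, ROIKind.NONENH): None,
}

#: ROI tag used in feature-column names
ROI_TAG = {ROIKind.WT: "ROI1", ROIKind.NONENH: "ROI2"}


class ValidationError(ValueError):
    """Input violates a structural invariant (shape, labels, duplicates)."""


class UnsupportedROIError(ValueError):
    """Requested ROI cannot be built under the segmentation's label scheme."""


class EmptyROIError(ValueError):
    """Requested ROI contains no voxels."""


@dataclass
class LabeledMask:
    voxels: np.ndarray
    scheme: Scheme

    def __post_init__(self):
        self.scheme = Scheme(self.scheme)
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValidationError(f"segmentation must be 3D, got {v.ndim}D")
        present = set(np.unique(v).astype(int).tolist())
        allowed = _SCHEME_LABELS[self.scheme]
        if not present <= allowed:
            raise ValidationError(
                f"labels {sorted(present - allowed)} not allowed under scheme "
                f"{self.scheme.value} (allowed: {sorted(allowed)})"
            )
        if not (v != 0).any():
            raise ValidationError("segmentation has no nonzero voxel")
        self.voxels = v.astype(np.int16)


@dataclass
class ROIMask:
    voxels: np.ndarray  # boolean
    roi_kind: ROIKind
    spacing_mm: tuple

    def __post_init__(self):
        self.roi_kind = ROIKind(self.roi_kind)
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"non-positive spacing {self.spacing_mm}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class MRIStudy:
    patient_id: str
    sequences: Mapping[str, np.ndarray]
    spacing_mm: tuple
    segmentation: LabeledMask

    def __post_init__(self):
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"non-positive spacing {self.spacing_mm}")
        missing = [s for s in SEQUENCES if s not in self.sequences]
        if missing:
            raise ValidationError(f"missing sequences: {missing}")
        shape = self.segmentation.voxels.shape
        for tag in SEQUENCES:
            vol = np.asarray(self.sequences[tag])
            if vol.shape != shape:
                raise ValidationError(
                    f"sequence {tag} shape {vol.shape} does not match "
                    f"segmentation shape {shape}"
                )
            if not np.isfinite(vol).all():
                raise ValidationError(f"sequence {tag} contains non-finite voxels")


def make_roi(mask: LabeledMask, roi_kind: ROIKind | str, spacing_mm=(1.0, 1.0, 1.0)) -> ROIMask:
    """Build a binary ROI from a labeled segmentation.

    ``WT`` is the union of all tumor labels; ``NONENH`` excludes the
    enhancing-tumor label (4) and is unavailable for whole-tumor-only masks.
    """
    roi_kind = ROIKind(roi_kind)
    labels = _ROI_LABELS[(mask.scheme, roi_kind)]
    if labels is None:
        raise UnsupportedROIError(
            f"ROI {roi_kind.value} is not constructible under scheme "
            f"{mask.scheme.value} (whole-tumor-only segmentation)"
        )
    voxels = np.isin(mask.voxels, sorted(labels))
    if not voxels.any():
        raise EmptyROIError(f"ROI {roi_kind.value} is empty for this segmentation")
    return ROIMask(voxels=voxels, roi_kind=roi_kind, spacing_mm=spacing_mm)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_study(row: Mapping[str, object]) -> MRIStudy:
    """Load one patient from a manifest row.

    The row maps manifest columns (``patient_id, t1, t1c, t2, flair, seg,
    scheme``) to values; voxel spacing is read from the NIfTI headers and
    must agree across all five files.
    """
    files = {"T1": row["t1"], "T1c": row["t1c"], "T2": row["t2"], "FLAIR": row["flair"]}
    sequences = {}
    spacing = None
    shape = None
    for tag in SEQUENCES:
        data, sp = _load_nifti(files[tag])
        if spacing is None:
            spacing, shape = sp, data.shape
        else:
            if data.shape != shape:
                raise ValidationError(
                    f"sequence {tag}: shape {data.shape} != {shape} of T1"
                )
            if not np.allclose(sp, spacing, rtol=1e-4):
                raise ValidationError(
                    f"sequence {tag}: spacing {sp} != {spacing} of T1"
                )
        sequences[tag] = data
    seg_data, seg_sp = _load_nifti(row["seg"])
    if seg_data.shape != shape:
        raise ValidationError(
            f"segmentation shape {seg_data.shape} != volume shape {shape}"
        )
    seg = LabeledMask(voxels=np.rint(seg_data).astype(np.int16), scheme=Scheme(str(row["scheme"])))
    return MRIStudy(
        patient_id=str(row["patient_id"]),
        sequences=sequences,
        spacing_mm=spacing,
        segmentation=seg,
    )


def save_volume(data: np.ndarray, spacing_mm, path: str | Path) -> None:
    """Write a 3D volume as NIfTI with a diagonal affine from the spacing."""
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(tuple(spacing_mm))
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# feature tables

LABEL_COLUMN = "IDH"


def validate_feature_table(table: pd.DataFrame) -> None:
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValidationError("feature table is empty")
    if table.columns.duplicated().any():
        dups = table.columns[table.columns.duplicated()].tolist()
        raise ValidationError(f"duplicate feature columns: {dups[:5]}")
    if table.index.duplicated().any():
        raise ValidationError("duplicate patient rows")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a patients × features table (index = patient_id) to CSV."""
    validate_feature_table(table)
    table.to_csv(path, index_label="patient_id", float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # pandas mangles duplicate headers on read, so inspect the raw header line
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split(",")
    if len(names) != len(set(names)):
        raise ValidationError("duplicate feature columns in CSV")
    table = pd.read_csv(path, index_col="patient_id")
    table.index = table.index.astype(str)
    validate_feature_table(table)
    return table


def split_features_labels(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a feature table into (X, y) using the IDH label column."""
    if LABEL_COLUMN not in table.columns:
        raise ValidationError(f"table has no {LABEL_COLUMN} label column")
    y = table[LABEL_COLUMN].to_numpy().astype(int)
    X = table.drop(columns=[LABEL_COLUMN])
    return X, y
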