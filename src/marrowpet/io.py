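"""NIfTI volume/mask and cohort-table I/O.

All geometry inside the package is index-space with voxel spacing carried
alongside; world coordinates exist only in the NIfTI affine written to disk.
SUV volumes are float32, masks uint8 {0,1}.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "patient_id",
    "scanner_id",
    "involved",
    "rel",
    "cellularity",
    "abs",
    "wbc",
    "ldh",
    "ki67",
]

#: tolerance on the abs = cellularity * rel / 100 identity when validating rows
ABS_TOLERANCE = 0.1


class CohortValidationError(ValueError):
    """A cohort row violates an invariant; carries the offending row index."""

    def __init__(self, row: int | None, message: str):
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


@dataclass
class SUVVolume:
    """A 3D SUV-calibrated scalar field with voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("SUV volume contains negative values")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in milliliters (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass
class BinaryMask:
    """A voxel-aligned {0,1} region sharing shape and spacing with its volume."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D mask, got {arr.ndim}D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq.tolist()}")
        self.values = arr.astype(np.uint8)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class CohortRecord:
    patient_id: str
    scanner_id: str
    involved: bool
    rel: float          # % of cellular marrow infiltrated
    cellularity: float  # % of marrow space that is cellular
    abs: float          # % of total marrow space infiltrated
    wbc: float          # x10^9 / L
    ldh: float          # U/L
    ki67: float = field(default=0.0)  # proliferation index, %

    def validate(self, row: int | None = None) -> None:
        for name in ("rel", "cellularity", "abs", "ki67"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise CohortValidationError(row, f"{name}={v} outside [0, 100]")
        expected_abs = self.cellularity * self.rel / 100.0
        if abs(self.abs - expected_abs) > ABS_TOLERANCE:
            raise CohortValidationError(
                row,
                f"abs={self.abs} inconsistent with cellularity*rel/100="
                f"{expected_abs:.3f}",
            )
        if not self.involved and self.rel != 0:
            raise CohortValidationError(row, "uninvolved patient with rel != 0")


def _affine(spacing_mm, origin) -> np.ndarray:
    aff = np.diag([spacing_mm[0], spacing_mm[1], spacing_mm[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: SUVVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.spacing_mm, vol.origin))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> SUVVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(z) for z in img.affine[:3, 3])
    return SUVVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing_mm, (0, 0, 0)))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(data, spacing)


def write_cohort(records: list[CohortRecord], path: str | Path) -> None:
    frame = cohort_frame(records)
    frame.to_csv(path, index=False)


def cohort_frame(records: list[CohortRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "scanner_id": r.scanner_id,
            "involved": int(r.involved),
            "rel": r.rel,
            "cellularity": r.cellularity,
            "abs": r.abs,
            "wbc": r.wbc,
            "ldh": r.ldh,
            "ki67": r.ki67,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def records_from_frame(frame: pd.DataFrame) -> list[CohortRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(None, f"missing columns: {missing}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        rec = CohortRecord(
            patient_id=str(row.patient_id),
            scanner_id=str(row.scanner_id),
            involved=bool(int(row.involved)),
            rel=float(row.rel),
            cellularity=float(row.cellularity),
            abs=float(getattr(row, "abs")),
            wbc=float(row.wbc),
            ldh=float(row.ldh),
            ki67=float(row.ki67),
        )
        rec.validate(row=i)
        records.append(rec)
    return records


def read_cohort(path: str | Path) -> list[CohortRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort file: {path}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(None, "no records: empty cohort file")
    if len(frame) == 0:
        raise CohortValidationError(None, "no records in cohort file")
    return records_from_frame(frame)
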