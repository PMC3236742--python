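"""NIfTI-1 volume I/O and cohort-table handling.

All imaging goes through NIfTI-1 (``.nii`` or ``.nii.gz``) via nibabel; when a
file carries both a qform and an sform, the sform wins (nibabel's default
best-affine rule, which is also the common tool convention).

Voxel index convention used throughout the package: indices are 0-based in
``(x, y, z)`` axis order, and a voxel's *linear* index enumerates x fastest,
i.e. ``lin = x + nx * (y + ny * z)`` (Fortran ravel order). Every place a 3-D
grid is flattened to a feature vector uses this order, so feature positions
are deterministic and comparable across runs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "SubjectRecord",
    "GROUPS",
    "load_volume",
    "save_volume",
    "load_cohort_table",
    "write_predictions",
    "ravel3",
    "unravel3",
]

GROUPS = ("control", "depressed")

#: CSV columns required in a cohort table.
COHORT_COLUMNS = ("subject_id", "group", "bdi", "aai")

#: CSV columns written by :func:`write_predictions`.
PREDICTION_COLUMNS = (
    "subject_id",
    "bdi_measured",
    "bdi_predicted",
    "depressed_measured",
    "depressed_predicted",
    "aai_measured",
    "aai_predicted",
    "insecure_predicted",
)

BDI_RANGE = (0, 63)
AAI_RANGE = (1.0, 9.0)


def ravel3(data: np.ndarray) -> np.ndarray:
    """Flatten the spatial axes of a 3-D array with x fastest (Fortran order)."""
    return np.ravel(data, order="F")


def unravel3(flat: np.ndarray, grid_dims: Sequence[int]) -> np.ndarray:
    """Inverse of :func:`ravel3`: reshape a flat voxel vector back to 3-D."""
    return np.reshape(flat, tuple(grid_dims), order="F")


@dataclass
class Volume:
    """A 3-D or 4-D image grid with physical voxel sizes and a world affine.

    Parameters
    ----------
    data:
        3-D array ``(x, y, z)`` or 4-D array ``(x, y, z, t)`` with time last.
    voxel_dims:
        Physical edge length of a voxel along each spatial axis, in mm.
    affine:
        4x4 voxel-to-world transform.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 3.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3-D or 4-D, got {self.data.ndim}-D")
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)  # type: ignore[assignment]
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise ValueError(f"voxel_dims must be 3 positive lengths, got {self.voxel_dims}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        """Number of time points (1 for a 3-D volume)."""
        return self.data.shape[3] if self.data.ndim == 4 else 1


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's identifiers and psychometric scores.

    ``bdi`` is the Beck Depression Inventory II total (integer, 0-63);
    ``aai`` is the Adult Attachment Interview coherence-of-mind score
    (real, 1-9; sub-point scores occur in practice, hence a float).
    """

    subject_id: str
    group: str
    bdi: int
    aai: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (BDI_RANGE[0] <= self.bdi <= BDI_RANGE[1]):
            raise ValueError(f"bdi={self.bdi} outside [{BDI_RANGE[0]}, {BDI_RANGE[1]}]")
        if not (AAI_RANGE[0] <= self.aai <= AAI_RANGE[1]):
            raise ValueError(f"aai={self.aai} outside [{AAI_RANGE[0]}, {AAI_RANGE[1]}]")


def load_volume(path: str | Path, allow_nonfinite: bool = False) -> Volume:
    """Load a NIfTI-1 volume from ``path``.

    Raises ``FileNotFoundError`` for a missing file, ``ValueError`` for a
    malformed header, and ``ValueError`` (with a voxel count) if the data
    contain NaN or infinity and ``allow_nonfinite`` is False.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        affine = np.asarray(img.affine, dtype=np.float64)
    except Exception as exc:  # nibabel raises several header-specific types
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad and not allow_nonfinite:
        raise ValueError(f"{path}: {n_bad} non-finite voxel value(s)")
    return Volume(data=data, voxel_dims=tuple(float(z) for z in zooms), affine=affine)


def save_volume(vol: Volume, path: str | Path) -> Path:
    """Write ``vol`` to ``path`` as NIfTI-1 (gzipped if the suffix is .nii.gz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data, vol.affine)
    zooms = vol.voxel_dims + ((1.0,) if vol.data.ndim == 4 else ())
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def load_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV (columns subject_id, group, bdi, aai) with validation.

    Every row must satisfy the score-range invariants; violations raise a
    ``ValueError`` naming the offending row rather than being clamped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty cohort table") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: cohort table has no data rows")
    dupes = df["subject_id"].astype(str)[df["subject_id"].astype(str).duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate subject_id(s): {sorted(set(dupes))}")
    records = []
    for i, row in df.iterrows():
        bdi = row["bdi"]
        if float(bdi) != int(bdi):
            raise ValueError(f"{path} row {i} (subject {row['subject_id']}): bdi must be an integer, got {bdi}")
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    bdi=int(bdi),
                    aai=float(row["aai"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {i} (subject {row['subject_id']}): {exc}") from exc
    return records


def write_predictions(
    entries: Iterable[tuple[SubjectRecord, Sequence[float], Mapping[str, bool]]],
    path: str | Path,
) -> Path:
    """Write per-subject predictions to CSV.

    ``entries`` yields ``(record, (bdi_pred, aai_pred), labels)`` triples where
    ``labels`` maps ``"depressed"`` and ``"insecure"`` to the predicted
    categorical diagnoses. An empty iterable produces a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PREDICTION_COLUMNS)
        for record, scores, labels in entries:
            if len(scores) != 2:
                raise ValueError(f"expected (bdi_pred, aai_pred) for {record.subject_id}, got {scores!r}")
            writer.writerow(
                [
                    record.subject_id,
                    record.bdi,
                    f"{float(scores[0]):.6f}",
                    int(record.group == "depressed"),
                    int(bool(labels["depressed"])),
                    f"{record.aai:g}",
                    f"{float(scores[1]):.6f}",
                    int(bool(labels["insecure"])),
                ]
            )
    return path
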