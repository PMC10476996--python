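"""Reading and writing CT volumes and radiotherapy structure sets.

All arrays use a single axis convention throughout the package:
``(slice, row, col)`` with slice index increasing inferior -> superior.
NIfTI is the canonical on-disk format; a patient folder holds one CT
volume (``CT.nii.gz``) plus one binary-mask file per structure, named
``<StructureName>.nii.gz``.  A minimal DICOM path (CT series +
RT-STRUCT) is provided for cross-format testing.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

CT_FILENAME = "CT.nii.gz"

#: Names that designate the patient outline, compared case-insensitively.
BODY_NAMES = ("body", "external")


class MissingCTError(FileNotFoundError):
    """Patient folder has no CT volume."""


class NoBodyStructureError(LookupError):
    """Structure set contains no structure named BODY or External."""


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    voxels
        Array of shape ``(slices, rows, cols)``, HU or normalized.
    spacing
        Per-axis voxel size in mm, ordered ``(slice, row, col)``.
    origin
        Physical position (mm) of voxel ``(0, 0, 0)``, same ordering.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "SRC"  # slice, row, col — the package-wide convention

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class NamedStructure:
    """A named binary mask congruent with its patient's CT grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask for {self.name!r} is not binary")
        self.mask = self.mask.astype(np.uint8)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class StructureSet:
    """All structures of one patient on a common grid."""

    patient_id: str
    structures: list[NamedStructure] = field(default_factory=list)
    body_index: int | None = None

    @property
    def body(self) -> NamedStructure:
        if self.body_index is None:
            raise NoBodyStructureError(
                f"no body structure designated for patient {self.patient_id!r}"
            )
        return self.structures[self.body_index]

    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def __iter__(self):
        return iter(self.structures)

    def __len__(self) -> int:
        return len(self.structures)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _to_nifti(arr: np.ndarray, spacing, origin) -> nib.Nifti1Image:
    # internal (slice,row,col) -> on-disk (col,row,slice) so the affine is
    # diagonal in x,y,z with x=col, y=row, z=slice
    data = np.asarray(arr).transpose(2, 1, 0)
    sz, sy, sx = spacing
    oz, oy, ox = origin
    affine = np.diag([sx, sy, sz, 1.0]).astype(np.float64)
    affine[:3, 3] = (ox, oy, oz)
    return nib.Nifti1Image(data, affine)


def _from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    arr = data.transpose(2, 1, 0)
    affine = img.affine
    spacing = (abs(float(affine[2, 2])), abs(float(affine[1, 1])), abs(float(affine[0, 0])))
    origin = (float(affine[2, 3]), float(affine[1, 3]), float(affine[0, 3]))
    return arr, spacing, origin


def write_volume(volume: ImageVolume, path: Path | str) -> Path:
    """Write an ImageVolume to NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.int16 if np.issubdtype(volume.voxels.dtype, np.integer) else np.float32
    nib.save(_to_nifti(volume.voxels.astype(dtype), volume.spacing, volume.origin), path)
    return path


def write_mask(mask: np.ndarray, spacing, origin, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(np.asarray(mask, dtype=np.uint8), spacing, origin), path)
    return path


def write_patient(
    ct: ImageVolume, structures: StructureSet, out_dir: Path | str
) -> Path:
    """Write one patient folder in the canonical NIfTI layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(ct, out_dir / CT_FILENAME)
    for struct in structures:
        write_mask(struct.mask, ct.spacing, ct.origin, out_dir / f"{struct.name}.nii.gz")
    return out_dir


def load_patient(path: Path | str, format: str = "nifti") -> tuple[ImageVolume, StructureSet]:
    """Load one patient folder.

    Returns the CT in HU and one :class:`NamedStructure` per *non-empty*
    structure file; empty structures are dropped with a warning.  A
    missing CT is fatal; an unreadable structure file is skipped with a
    warning and never aborts the patient.
    """
    path = Path(path)
    if format == "dicom":
        from . import _dicom

        ct, structures = _dicom.load_dicom_patient(path)
    elif format == "nifti":
        ct_path = path / CT_FILENAME
        if not ct_path.exists():
            raise MissingCTError(f"no CT volume at {ct_path}")
        arr, spacing, origin = _from_nifti(nib.load(ct_path))
        ct = ImageVolume(arr, spacing, origin)
        structures = []
        for f in sorted(path.glob("*.nii.gz")):
            if f.name == CT_FILENAME:
                continue
            name = f.name[: -len(".nii.gz")]
            try:
                mask, _, _ = _from_nifti(nib.load(f))
                structures.append(NamedStructure(name, mask))
            except Exception as exc:  # noqa: BLE001 — per-structure robustness
                logger.warning("skipping unreadable structure file %s: %s", f, exc)
    else:
        raise ValueError(f"unknown format {format!r}")

    kept = []
    for struct in structures:
        if struct.is_empty:
            logger.warning(
                "dropping empty structure %r for patient %s", struct.name, path.name
            )
            continue
        if struct.mask.shape != ct.shape:
            logger.warning(
                "skipping structure %r: grid %s does not match CT %s",
                struct.name, struct.mask.shape, ct.shape,
            )
            continue
        kept.append(struct)
    return ct, StructureSet(patient_id=path.name, structures=kept)


def find_body(structures: StructureSet) -> NamedStructure:
    """Locate and designate the body structure ("BODY" or "External").

    Matching is case-insensitive exact match.  With multiple candidates
    the first in file order wins (warning logged); no candidate is fatal.
    """
    if len(structures) == 0:
        raise NoBodyStructureError("structure set is empty")
    matches = [
        i for i, s in enumerate(structures) if s.name.lower() in BODY_NAMES
    ]
    if not matches:
        raise NoBodyStructureError(
            f"no body structure among {structures.names()!r}"
        )
    if len(matches) > 1:
        logger.warning(
            "multiple body candidates %r; taking the first",
            [structures.structures[i].name for i in matches],
        )
    structures.body_index = matches[0]
    return structures.structures[matches[0]]


def write_structure_copy(
    structure_path: Path | str,
    class_label: str,
    patient_id: str,
    out_root: Path | str,
) -> Path:
    """Copy a structure file unmodified under ``out_root/<label>/<patient>/``.

    Name collisions get a numeric suffix rather than overwriting.
    """
    structure_path = Path(structure_path)
    dest_dir = Path(out_root) / class_label / patient_id
    dest_dir.mkdir(parents=True, exist_ok=True)
    dest = dest_dir / structure_path.name
    if dest.exists():
        stem, suffixes = structure_path.name, ""
        if stem.endswith(".nii.gz"):
            stem, suffixes = stem[: -len(".nii.gz")], ".nii.gz"
        else:
            stem, suffixes = structure_path.stem, structure_path.suffix
        counter = 1
        while dest.exists():
            dest = dest_dir / f"{stem}_{counter}{suffixes}"
            counter += 1
        logger.warning("collision for %s; writing %s", structure_path.name, dest.name)
    shutil.copyfile(structure_path, dest)
    return dest
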