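"""Synthetic pelvic CT phantoms with two delineation-guideline variants.

Each phantom has an air background, an elliptical soft-tissue body with
Gaussian noise, a high-density couch slab outside the body, bone-density
femoral heads, and a set of organ structures delivered in two variants:
variant A is the base shape, variant B is A dilated in-plane and/or
extended inferior/superior (the bladder instead uses a wall-exclusion
erosion, so B is a subset of A).  Nuisance structures carry clinical
style names drawn from the exclusion-keyword families and are labeled
"Other".  Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .rtstruct_io import ImageVolume, NamedStructure, StructureSet, write_patient

logger = logging.getLogger(__name__)

# HU palette (plumbing values, not claims)
HU_AIR = -1000.0
HU_SOFT = 40.0
HU_ORGAN = 80.0
HU_BONE = 700.0
HU_COUCH = 200.0

OTHER = "Other"

#: organ name -> (variant-A structure name, variant-B structure name)
VARIANT_NAMES = {
    "bladder": ("Bladder", "Bladder_AI1"),
    "rectum": ("Rectum", "Anorectum_AI1"),
    "femoral_l": ("FemoralHead_L", "Femur_Head_L_AI1"),
    "femoral_r": ("FemoralHead_R", "Femur_Head_R_AI1"),
    "bowel": ("BowelCavity_Dev", "BowelCavity_RTOG"),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and variant rules for one phantom family."""

    shape: tuple[int, int, int] = (64, 80, 104)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)  # mm
    organs: tuple[str, ...] = ("bladder", "rectum", "femoral_l", "femoral_r")
    dilation_mm: float = 5.0
    superior_extension_slices: int = 5
    inferior_extension_slices: int = 3
    bladder_erosion_mm: float = 5.0
    noise_std_hu: float = 12.0
    organ_hu_jitter: float = 10.0  # per-patient soft-organ HU offset range
    paint_margin_mm: float = 0.0   # radiologically visible organ = A dilated by this
    nuisance: tuple[str, ...] = ("ptv", "ring", "dose")
    jitter_vox: float = 2.0
    retry_cap: int = 5

    def __post_init__(self) -> None:
        if self.dilation_mm < 0 or self.bladder_erosion_mm < 0:
            raise ValueError("dilation/erosion radii must be >= 0")
        if self.superior_extension_slices < 0 or self.inferior_extension_slices < 0:
            raise ValueError("extensions must be >= 0")
        unknown = set(self.organs) - set(VARIANT_NAMES)
        if unknown:
            raise ValueError(f"unknown organs {sorted(unknown)}")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return (acc <= 1.0).astype(np.uint8)


def _ball_2d(radius_vox: float) -> np.ndarray:
    r = int(np.ceil(radius_vox))
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx <= radius_vox * radius_vox).astype(np.uint8)


def _dilate_inplane(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    if radius_mm <= 0:
        return mask.copy()
    footprint = _ball_2d(radius_mm / spacing[1])[None, :, :]
    return ndimage.binary_dilation(mask, structure=footprint).astype(np.uint8)


def _erode_inplane(mask: np.ndarray, radius_mm: float, spacing) -> np.ndarray:
    if radius_mm <= 0:
        return mask.copy()
    footprint = _ball_2d(radius_mm / spacing[1])[None, :, :]
    return ndimage.binary_erosion(mask, structure=footprint).astype(np.uint8)


def _extend_axially(mask: np.ndarray, inferior: int, superior: int) -> np.ndarray:
    """Replicate the end slices of the mask downward/upward."""
    out = mask.copy()
    nz = np.flatnonzero(mask.any(axis=(1, 2)))
    if nz.size == 0:
        return out
    first, last = int(nz[0]), int(nz[-1])
    for k in range(max(first - inferior, 0), first):
        out[k] |= mask[first]
    for k in range(last + 1, min(last + superior + 1, mask.shape[0])):
        out[k] |= mask[last]
    return out


def _variant_b(organ: str, base: np.ndarray, spec: PhantomSpec, body: np.ndarray) -> np.ndarray:
    if organ == "bladder":
        # wall exclusion: B is a strict subset of A
        return _erode_inplane(base, spec.bladder_erosion_mm, spec.spacing)
    out = _dilate_inplane(base, spec.dilation_mm, spec.spacing)
    out = _extend_axially(
        out, spec.inferior_extension_slices, spec.superior_extension_slices
    )
    return (out & body).astype(np.uint8)


def generate_phantom(
    spec: PhantomSpec, seed: int, patient_id: str | None = None
) -> tuple[ImageVolume, StructureSet, dict[str, str]]:
    """Build one phantom.

    Returns the CT, its structure set (body first), and a mapping from
    structure name to ground-truth class label.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(spec.retry_cap):
        result = _try_generate(spec, rng, patient_id or f"phantom_{seed:04d}")
        if result is not None:
            return result
        logger.warning("phantom organ collision (attempt %d); rejittering", attempt + 1)
    raise RuntimeError(f"phantom generation failed after {spec.retry_cap} attempts")


def _try_generate(spec: PhantomSpec, rng: np.random.Generator, patient_id: str):
    n_sl, n_r, n_c = spec.shape
    jitter = lambda: rng.uniform(-spec.jitter_vox, spec.jitter_vox)  # noqa: E731
    scale = lambda: rng.uniform(0.9, 1.1)  # noqa: E731

    body_scale = rng.uniform(0.98, 1.04)
    body = _ellipsoid(
        spec.shape,
        center=(n_sl / 2, n_r * 0.48, n_c / 2),
        radii=(n_sl, n_r * 0.40 * body_scale, n_c * 0.42 * body_scale),
    )
    body[[0, -1]] = 0  # keep an air cap so the body bbox is interior axially
    interior = ndimage.binary_erosion(body, iterations=2)

    ct = np.full(spec.shape, HU_AIR, dtype=np.float32)
    ct[body > 0] = HU_SOFT

    couch_row = int(n_r * 0.93)
    couch = np.zeros(spec.shape, dtype=np.uint8)
    couch[:, couch_row:couch_row + 3, int(n_c * 0.15):int(n_c * 0.85)] = 1
    couch &= ~body.astype(bool)
    ct[couch > 0] = HU_COUCH

    organs: dict[str, np.ndarray] = {}
    center_sl = n_sl / 2 + jitter()
    if "bladder" in spec.organs:
        organs["bladder"] = _ellipsoid(
            spec.shape,
            center=(center_sl, n_r * 0.42 + jitter(), n_c * 0.5 + jitter()),
            radii=(n_sl * 0.14 * scale(), n_r * 0.14 * scale(), n_c * 0.13 * scale()),
        )
    if "rectum" in spec.organs:
        organs["rectum"] = _ellipsoid(
            spec.shape,
            center=(center_sl - 2, n_r * 0.62 + jitter(), n_c * 0.5 + jitter()),
            radii=(n_sl * 0.22 * scale(), n_r * 0.08 * scale(), n_c * 0.06 * scale()),
        )
    if "bowel" in spec.organs:
        organs["bowel"] = _ellipsoid(
            spec.shape,
            center=(center_sl + 4, n_r * 0.35 + jitter(), n_c * 0.5 + jitter()),
            radii=(n_sl * 0.20 * scale(), n_r * 0.18 * scale(), n_c * 0.28 * scale()),
        )
    for organ, side in (("femoral_l", 0.76), ("femoral_r", 0.24)):
        if organ in spec.organs:
            organs[organ] = _ellipsoid(
                spec.shape,
                center=(center_sl, n_r * 0.52 + jitter(), n_c * side + jitter()),
                radii=(n_sl * 0.09 * scale(),) * 3,
            )

    for organ, mask in organs.items():
        if not mask.any() or np.any(mask & ~interior):
            return None  # collision with body boundary -> rejitter

    organ_hu = HU_ORGAN + rng.uniform(-spec.organ_hu_jitter, spec.organ_hu_jitter)
    for organ in ("bladder", "rectum", "bowel"):
        if organ in organs:
            painted = organs[organ]
            if spec.paint_margin_mm > 0:
                painted = _dilate_inplane(painted, spec.paint_margin_mm, spec.spacing)
                painted &= body
            ct[painted > 0] = organ_hu
    for organ in ("femoral_l", "femoral_r"):
        if organ in organs:
            ct[organs[organ] > 0] = HU_BONE

    ct += rng.normal(0.0, spec.noise_std_hu, size=spec.shape).astype(np.float32)

    structures = [NamedStructure("BODY", body)]
    labels: dict[str, str] = {"BODY": OTHER}
    for organ in spec.organs:
        name_a, name_b = VARIANT_NAMES[organ]
        mask_a = organs[organ]
        mask_b = _variant_b(organ, mask_a, spec, body)
        if not mask_b.any():
            return None
        structures.append(NamedStructure(name_a, mask_a))
        structures.append(NamedStructure(name_b, mask_b))
        labels[name_a], labels[name_b] = name_a, name_b

    for kind, (name, mask) in _nuisance_structures(
        spec, organs, body, couch, rng, center_sl
    ).items():
        structures.append(NamedStructure(name, mask))
        labels[name] = OTHER

    volume = ImageVolume(ct, spec.spacing)
    sset = StructureSet(patient_id=patient_id, structures=structures, body_index=0)
    return volume, sset, labels


def _nuisance_structures(spec, organs, body, couch, rng, center_sl):
    """Optimization/support structures with exclusion-family names.

    They are anchored to a prostate-like target ellipsoid (not an organ
    class itself) so they are geometrically distinct from every class.
    """
    n_sl, n_r, n_c = body.shape
    target = _ellipsoid(
        body.shape,
        center=(center_sl - 3, n_r * 0.52, n_c * 0.5),
        radii=(n_sl * 0.08, n_r * 0.06, n_c * 0.05),
    )
    bbody = body.astype(bool)
    out = {}
    if "ptv" in spec.nuisance:
        ptv = ndimage.binary_dilation(target, iterations=2) & bbody
        out["ptv"] = (f"PTV_{rng.integers(40, 70)}", ptv.astype(np.uint8))
    if "ring" in spec.nuisance:
        inner = ndimage.binary_dilation(target, iterations=3)
        outer = ndimage.binary_dilation(target, iterations=6)
        ring = (outer & ~inner) & bbody
        out["ring"] = ("Ring_PTV", ring.astype(np.uint8))
    if "dose" in spec.nuisance:
        box = np.zeros(body.shape, dtype=bool)
        box[int(n_sl * 0.7):int(n_sl * 0.9),
            int(n_r * 0.2):int(n_r * 0.45),
            int(n_c * 0.3):int(n_c * 0.7)] = True
        out["dose"] = ("Dose_ctrl", (box & bbody).astype(np.uint8))
    if "couch" in spec.nuisance and couch.any():
        out["couch"] = ("Couch_support", couch.astype(np.uint8))
    return out


def generate_cohort(
    n: int,
    spec: PhantomSpec,
    base_seed: int,
    out_dir: Path | str,
) -> Path:
    """Write ``n`` phantom patient folders plus a label manifest TSV.

    Folder layout matches ``rtstruct_io.load_patient`` (NIfTI).  The
    manifest has one row per structure: patient_id, structure_name,
    true_class.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        patient_id = f"phantom_{base_seed:04d}_{i:03d}"
        ct, sset, labels = generate_phantom(spec, seed=base_seed * 100_003 + i,
                                            patient_id=patient_id)
        write_patient(ct, sset, out_dir / patient_id)
        for struct in sset:
            rows.append((patient_id, struct.name, labels[struct.name]))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(("patient_id", "structure_name", "true_class"))
        writer.writerows(rows)
    logger.info("wrote %d phantom patients to %s", n, out_dir)
    return out_dir


def read_manifest(cohort_dir: Path | str) -> dict[tuple[str, str], str]:
    """Map (patient_id, structure_name) -> true class."""
    path = Path(cohort_dir) / "manifest.tsv"
    out = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for patient_id, name, cls in reader:
            out[(patient_id, name)] = cls
    return out
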