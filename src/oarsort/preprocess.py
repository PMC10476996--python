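"""Per-structure preprocessing chain producing two-channel classifier input.

Fixed step order: z-score normalize -> resample -> mask outside body ->
crop to body bounding box -> AddMap -> structure-centered slice window ->
symmetric zero pad (or in-plane downscale at inference).  Normalization
statistics are computed before resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .rtstruct_io import ImageVolume, NamedStructure

logger = logging.getLogger(__name__)


class DegenerateVolumeError(ValueError):
    """CT has no usable intensity variation above the air threshold."""


class OversizeInputError(ValueError):
    """Channel exceeds the target grid where downscaling is not allowed."""


@dataclass(frozen=True)
class PreprocessConfig:
    """One dataset profile of the preprocessing chain.

    ``grid`` is (rows, cols, slices); arrays are handled internally as
    (slice, row, col).  ``spacing`` is (slice, row, col) mm.
    """

    profile: str
    grid: tuple[int, int, int]
    spacing: tuple[float, float, float] = (3.0, 2.0, 2.0)
    slice_cap: int = 96
    air_threshold: float = -1000.0
    allow_downscale: bool = False

    def __post_init__(self) -> None:
        if self.grid[2] != self.slice_cap:
            raise ValueError(
                f"target grid slices ({self.grid[2]}) must equal slice cap "
                f"({self.slice_cap})"
            )

    @property
    def grid_src(self) -> tuple[int, int, int]:
        """Target grid in internal (slice, row, col) order."""
        rows, cols, slices = self.grid
        return (slices, rows, cols)

    @property
    def supported_extent_mm(self) -> float:
        """Maximum inferior-superior physical extent still eligible."""
        return self.slice_cap * self.spacing[0]


#: Built-in dataset profiles.  "phantom" is a desk-scale profile used by the
#: synthetic cohorts; the clinical profiles match the published grids.
PROFILES: dict[str, PreprocessConfig] = {
    "bowel": PreprocessConfig("bowel", grid=(184, 280, 96)),
    "pelvis": PreprocessConfig("pelvis", grid=(200, 328, 96)),
    "phantom": PreprocessConfig(
        "phantom", grid=(48, 64, 24), spacing=(6.0, 4.0, 4.0), slice_cap=24
    ),
}


def get_profile(name: str, allow_downscale: bool = False) -> PreprocessConfig:
    try:
        cfg = PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; have {sorted(PROFILES)}") from None
    return replace(cfg, allow_downscale=allow_downscale)


def load_config(path: Path | str, profile: str) -> PreprocessConfig:
    """Load one profile section from a YAML config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    section = doc[profile]
    cfg = PreprocessConfig(
        profile=profile,
        grid=tuple(section["grid"]),
        spacing=tuple(section.get("spacing", (3.0, 2.0, 2.0))),
        slice_cap=int(section.get("slice_cap", section["grid"][2])),
        air_threshold=float(section.get("air_threshold", -1000.0)),
        allow_downscale=bool(section.get("allow_downscale", False)),
    )
    logger.info("loaded preprocess profile %s: %s", profile, cfg)
    return cfg


@dataclass
class ClassifierSample:
    """Two congruent channels (normalized CT, AddMap) plus identity."""

    ct: np.ndarray
    addmap: np.ndarray
    structure_name: str
    label: str | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.ct.shape != self.addmap.shape:
            raise ValueError("CT and AddMap channels must share one grid")

    @property
    def channels(self) -> np.ndarray:
        """Stacked (2, slices, rows, cols) float32 tensor."""
        return np.stack([self.ct, self.addmap]).astype(np.float32)


def save_sample(sample: ClassifierSample, path: Path | str) -> Path:
    """Persist a sample as a two-channel array with a JSON sidecar."""
    import json

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), sample.channels)
    sidecar = {
        "structure_name": sample.structure_name,
        "label": sample.label,
        "patient_id": sample.patient_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npy")


def load_sample(path: Path | str) -> ClassifierSample:
    import json

    path = Path(path)
    channels = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return ClassifierSample(
        ct=channels[0], addmap=channels[1],
        structure_name=meta["structure_name"], label=meta["label"],
        patient_id=meta["patient_id"],
    )


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def zscore_normalize(ct: ImageVolume, air_threshold: float = -1000.0) -> ImageVolume:
    """Z-score the whole volume with statistics from voxels above threshold.

    Mean and population standard deviation are computed only over voxels
    with intensity strictly greater than ``air_threshold``; the affine is
    then applied to every voxel.
    """
    voxels = ct.voxels.astype(np.float64)
    selected = voxels[voxels > air_threshold]
    if selected.size < 2:
        raise DegenerateVolumeError(
            f"fewer than 2 voxels above {air_threshold} HU"
        )
    mu = float(selected.mean())
    sigma = float(selected.std())  # population std
    if sigma == 0.0:
        raise DegenerateVolumeError("zero intensity variation above threshold")
    return ImageVolume((voxels - mu) / sigma, ct.spacing, ct.origin)


def resample(volume: ImageVolume, target_spacing, mode: str) -> ImageVolume:
    """Resample to ``target_spacing`` (slice,row,col mm).

    ``mode='intensity'`` uses order-2 (quadratic) spline interpolation;
    ``mode='mask'`` uses nearest neighbor and stays binary.
    """
    if mode not in ("intensity", "mask"):
        raise ValueError(f"mode must be 'intensity' or 'mask', got {mode!r}")
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    zoom = [o / t for o, t in zip(volume.spacing, target_spacing)]
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return ImageVolume(volume.voxels.copy(), target_spacing, volume.origin)
    order = 2 if mode == "intensity" else 0
    out = ndimage.zoom(
        volume.voxels.astype(np.float32 if mode == "intensity" else np.uint8),
        zoom, order=order, mode="nearest", grid_mode=True,
    )
    if mode == "mask":
        out = (out > 0).astype(np.uint8)
    # grid_mode aligns cell edges, so the first voxel centre moves by half
    # the spacing difference
    origin = tuple(
        o + (t - s) / 2.0
        for o, s, t in zip(volume.origin, volume.spacing, target_spacing)
    )
    return ImageVolume(out, target_spacing, origin)


def mask_outside_body(volume: ImageVolume, body: NamedStructure) -> ImageVolume:
    """Zero everything outside the body mask (couch removal)."""
    if body.mask.shape != volume.shape:
        raise ValueError("body mask grid does not match volume grid")
    if not body.mask.any():
        raise ValueError("body mask is empty")
    out = np.where(body.mask > 0, volume.voxels, 0)
    return ImageVolume(out, volume.spacing, volume.origin)


def body_bounding_box(body: NamedStructure) -> tuple[slice, slice, slice]:
    """Tight axis-aligned bounding box of the body mask, as slices."""
    if not body.mask.any():
        raise ValueError("body mask is empty")
    bbox = []
    for axis in range(3):
        nz = np.flatnonzero(body.mask.any(axis=tuple(a for a in range(3) if a != axis)))
        bbox.append(slice(int(nz[0]), int(nz[-1]) + 1))
    return tuple(bbox)


def crop_to_body(volume: ImageVolume, body: NamedStructure) -> ImageVolume:
    """Crop to the body's bounding box (idempotent once tight)."""
    box = body_bounding_box(body)
    origin = tuple(
        o + s * b.start for o, s, b in zip(volume.origin, volume.spacing, box)
    )
    return ImageVolume(volume.voxels[box], volume.spacing, origin)


def make_addmap(body_mask: np.ndarray, structure_mask: np.ndarray) -> np.ndarray:
    """Joint encoding (body + structure) / 2: 1 overlap, 0.5 body, 0 air."""
    body_mask = np.asarray(body_mask)
    structure_mask = np.asarray(structure_mask)
    if body_mask.shape != structure_mask.shape:
        raise ValueError("masks must be congruent")
    for name, m in (("body", body_mask), ("structure", structure_mask)):
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError(f"{name} mask is not binary")
    outside = np.logical_and(structure_mask > 0, body_mask == 0)
    if outside.any():
        logger.warning(
            "%d structure voxels lie outside the body mask", int(outside.sum())
        )
    return (body_mask.astype(np.float32) + structure_mask.astype(np.float32)) / 2.0


def slice_eligibility(structure_mask: np.ndarray, slice_cap: int) -> bool:
    """True iff the count of nonzero 2D slices does not exceed the cap."""
    n_nonzero = int(np.count_nonzero(structure_mask.any(axis=(1, 2))))
    return n_nonzero <= slice_cap


def center_window(
    structure_mask: np.ndarray, slice_cap: int, total_slices: int | None = None
) -> tuple[int, int]:
    """Structure-centered half-open slice window of exactly ``slice_cap``.

    The center is the floor midpoint of the first and last nonzero slice.
    The window may extend beyond the volume; extraction zero-fills the
    out-of-volume part rather than shifting the window.  When the floor
    rounding would push a boundary nonzero slice out (extent close to the
    cap), the window shifts by the minimal amount that keeps every
    nonzero slice inside.
    """
    nz = np.flatnonzero(structure_mask.any(axis=(1, 2)))
    if nz.size == 0:
        raise ValueError("empty structure mask has no center window")
    first, last = int(nz[0]), int(nz[-1])
    center = (first + last) // 2
    start = center - slice_cap // 2
    if last - first < slice_cap:  # containment takes priority over centering
        start = min(max(start, last + 1 - slice_cap), first)
    return start, start + slice_cap


def extract_window(channel: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Slice out a window along axis 0, zero-filling outside the volume."""
    start, end = window
    n = channel.shape[0]
    out = np.zeros((end - start, *channel.shape[1:]), dtype=channel.dtype)
    lo, hi = max(start, 0), min(end, n)
    if lo < hi:
        out[lo - start:hi - start] = channel[lo:hi]
    return out


def pad_or_downscale(
    channel: np.ndarray, target_grid_src: tuple[int, int, int],
    allow_downscale: bool = False,
) -> np.ndarray:
    """Fit a channel to the target grid, (slice, row, col) order.

    Smaller dimensions are symmetrically zero padded (odd remainder: the
    extra voxel goes on the high-index side).  Larger in-plane dimensions
    are a fatal error in training mode and a nearest-neighbor downscale
    at inference (preserves the AddMap codomain).
    """
    target = tuple(target_grid_src)
    if channel.shape[0] > target[0]:
        raise OversizeInputError(
            f"slice count {channel.shape[0]} exceeds target {target[0]}"
        )
    if channel.shape[1] > target[1] or channel.shape[2] > target[2]:
        if not allow_downscale:
            raise OversizeInputError(
                f"in-plane size {channel.shape[1:]} exceeds target {target[1:]}"
            )
        zoom = [
            1.0,
            min(target[1] / channel.shape[1], 1.0),
            min(target[2] / channel.shape[2], 1.0),
        ]
        channel = ndimage.zoom(channel, zoom, order=0, mode="nearest", grid_mode=True)
        # rounding in zoom can leave one voxel over; trim defensively
        channel = channel[:, :target[1], :target[2]]
    pads = []
    for dim, tgt in zip(channel.shape, target):
        total = tgt - dim
        pads.append((total // 2, total - total // 2))
    return np.pad(channel, pads)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def assemble_sample(
    ct: ImageVolume,
    body: NamedStructure,
    structure: NamedStructure,
    config: PreprocessConfig,
    label: str | None = None,
    patient_id: str = "",
) -> ClassifierSample | None:
    """Run the full chain for one structure.

    Returns ``None`` (with a logged skip) when the structure exceeds the
    slice cap after resampling.
    """
    normalized = zscore_normalize(ct, config.air_threshold)
    ct_rs = resample(normalized, config.spacing, mode="intensity")
    body_rs = resample(
        ImageVolume(body.mask, ct.spacing, ct.origin), config.spacing, mode="mask"
    )
    struct_rs = resample(
        ImageVolume(structure.mask, ct.spacing, ct.origin), config.spacing, mode="mask"
    )
    body_rs_struct = NamedStructure(body.name, body_rs.voxels)

    ct_masked = mask_outside_body(ct_rs, body_rs_struct)
    struct_masked = mask_outside_body(
        ImageVolume(struct_rs.voxels, struct_rs.spacing, struct_rs.origin),
        body_rs_struct,
    )

    box = body_bounding_box(body_rs_struct)
    ct_c = ct_masked.voxels[box]
    body_c = body_rs.voxels[box]
    struct_c = struct_masked.voxels[box].astype(np.uint8)

    if not struct_c.any():
        logger.warning(
            "structure %r vanished during preprocessing; skipped", structure.name
        )
        return None
    if not slice_eligibility(struct_c, config.slice_cap):
        logger.info(
            "structure %r exceeds %d slices (> %.0f mm); skipped",
            structure.name, config.slice_cap, config.supported_extent_mm,
        )
        return None

    addmap = make_addmap(body_c, struct_c)
    window = center_window(struct_c, config.slice_cap, ct_c.shape[0])
    ct_w = extract_window(ct_c, window)
    addmap_w = extract_window(addmap, window)

    ct_final = pad_or_downscale(ct_w, config.grid_src, config.allow_downscale)
    addmap_final = pad_or_downscale(addmap_w, config.grid_src, config.allow_downscale)
    return ClassifierSample(
        ct=ct_final.astype(np.float32),
        addmap=addmap_final.astype(np.float32),
        structure_name=structure.name,
        label=label,
        patient_id=patient_id,
    )
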