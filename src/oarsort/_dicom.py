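"""Minimal DICOM codec: CT series + RT-STRUCT, explicit VR little endian.

Supports exactly what the phantom exporter emits plus enough generality
to parse defined- and undefined-length sequences.  Not a general DICOM
implementation: single frame per file, identity image orientation,
MONOCHROME2 int16 pixels, no compressed transfer syntaxes.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
from skimage import draw, measure

from .rtstruct_io import ImageVolume, NamedStructure, StructureSet, MissingCTError

logger = logging.getLogger(__name__)

_UID_ROOT = "1.2.826.0.1.3680043.10.1097"  # arbitrary org root for phantoms
SOP_CT = "1.2.840.10008.5.1.4.1.1.2"
SOP_RTSTRUCT = "1.2.840.10008.5.1.4.1.1.481.3"
TS_EXPLICIT_LE = "1.2.840.10008.1.2.1"

_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

# tags used by the writer, with their VRs
Tag = tuple[int, int]


def _uid(*parts: int) -> str:
    return ".".join([_UID_ROOT, *map(str, parts)])


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _pad(value: bytes, pad_byte: bytes) -> bytes:
    return value + pad_byte if len(value) % 2 else value


def _encode_value(vr: bytes, value) -> bytes:
    if vr == b"US":
        return struct.pack("<H", int(value))
    if vr == b"UL":
        return struct.pack("<I", int(value))
    if vr == b"OW":
        return bytes(value)
    if vr == b"SQ":
        return b"".join(_encode_item(item) for item in value)
    text = value if isinstance(value, str) else "\\".join(str(v) for v in value)
    raw = text.encode("ascii")
    return _pad(raw, b"\x00" if vr == b"UI" else b" ")


def _encode_element(group: int, elem: int, vr: bytes, value) -> bytes:
    body = _encode_value(vr, value)
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(body)) + body
    return head + struct.pack("<H", len(body)) + body


def _encode_item(elements: list[tuple[int, int, bytes, object]]) -> bytes:
    body = b"".join(_encode_element(*el) for el in elements)
    return struct.pack("<HH", 0xFFFE, 0xE000) + struct.pack("<I", len(body)) + body


def _write_file(path: Path, elements: list[tuple[int, int, bytes, object]],
                sop_class: str, sop_instance: str) -> None:
    meta = b"".join([
        _encode_element(0x0002, 0x0002, b"UI", sop_class),
        _encode_element(0x0002, 0x0003, b"UI", sop_instance),
        _encode_element(0x0002, 0x0010, b"UI", TS_EXPLICIT_LE),
    ])
    meta = _encode_element(0x0002, 0x0000, b"UL", len(meta)) + meta
    dataset = b"".join(_encode_element(*el) for el in sorted(elements, key=lambda e: (e[0], e[1])))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + dataset)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _parse_dataset(buf: bytes, pos: int, end: int) -> tuple[dict, int]:
    """Parse explicit-VR-LE elements in buf[pos:end] into {tag: value}."""
    out: dict[Tag, object] = {}
    while pos < end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        if (group, elem) == (0xFFFE, 0xE00D):  # item delimiter
            pos += 4
            break
        vr = buf[pos:pos + 2]
        pos += 2
        if vr in _LONG_VRS:
            pos += 2
            (length,) = struct.unpack_from("<I", buf, pos)
            pos += 4
        else:
            (length,) = struct.unpack_from("<H", buf, pos)
            pos += 2
        if vr == b"SQ":
            items, pos = _parse_sequence(buf, pos, length)
            out[(group, elem)] = items
            continue
        if length == 0xFFFFFFFF:
            raise ValueError("undefined length outside SQ is unsupported")
        raw = buf[pos:pos + length]
        pos += length
        out[(group, elem)] = _decode_value(vr, raw)
    return out, pos


def _parse_sequence(buf: bytes, pos: int, length: int) -> tuple[list[dict], int]:
    items: list[dict] = []
    end = pos + length if length != 0xFFFFFFFF else len(buf)
    while pos < end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        pos += 4
        (item_len,) = struct.unpack_from("<I", buf, pos)
        pos += 4
        if (group, elem) == (0xFFFE, 0xE0DD):  # sequence delimiter
            break
        if (group, elem) != (0xFFFE, 0xE000):
            raise ValueError(f"malformed sequence at offset {pos - 8}")
        item_end = pos + item_len if item_len != 0xFFFFFFFF else end
        item, pos = _parse_dataset(buf, pos, item_end)
        items.append(item)
        if length != 0xFFFFFFFF and pos >= end:
            break
    return items, pos


def _decode_value(vr: bytes, raw: bytes):
    if vr == b"US":
        return struct.unpack("<H", raw)[0]
    if vr == b"UL":
        return struct.unpack("<I", raw)[0]
    if vr in (b"OW", b"OB", b"UN"):
        return raw
    text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
    if vr == b"DS":
        parts = [float(p) for p in text.split("\\") if p != ""]
        return parts if len(parts) != 1 else parts[0]
    if vr == b"IS":
        parts = [int(p) for p in text.split("\\") if p != ""]
        return parts if len(parts) != 1 else parts[0]
    return text


def read_dicom(path: Path | str) -> dict:
    buf = Path(path).read_bytes()
    if buf[128:132] != b"DICM":
        raise ValueError(f"{path} is not a DICOM part-10 file")
    dataset, _ = _parse_dataset(buf, 132, len(buf))
    ts = dataset.get((0x0002, 0x0010))
    if ts not in (None, TS_EXPLICIT_LE):
        raise ValueError(f"unsupported transfer syntax {ts!r}")
    return dataset


# ---------------------------------------------------------------------------
# CT series + RT-STRUCT export
# ---------------------------------------------------------------------------

def export_dicom_patient(ct: ImageVolume, structures: StructureSet,
                         out_dir: Path | str, seed: int = 0) -> Path:
    """Write a CT series (one file per slice) and one RT-STRUCT file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_slices, n_rows, n_cols = ct.shape
    sz, sy, sx = ct.spacing
    oz, oy, ox = ct.origin
    study_uid, series_uid = _uid(seed, 1), _uid(seed, 2)

    pixels = np.clip(np.rint(ct.voxels), -32768, 32767).astype("<i2")
    for k in range(n_slices):
        sop_uid = _uid(seed, 3, k)
        elements = [
            (0x0008, 0x0016, b"UI", SOP_CT),
            (0x0008, 0x0018, b"UI", sop_uid),
            (0x0008, 0x0060, b"CS", "CT"),
            (0x0010, 0x0020, b"LO", structures.patient_id),
            (0x0018, 0x0050, b"DS", f"{sz:g}"),
            (0x0020, 0x000D, b"UI", study_uid),
            (0x0020, 0x000E, b"UI", series_uid),
            (0x0020, 0x0013, b"IS", str(k + 1)),
            (0x0020, 0x0032, b"DS", [f"{ox:g}", f"{oy:g}", f"{oz + k * sz:g}"]),
            (0x0020, 0x0037, b"DS", ["1", "0", "0", "0", "1", "0"]),
            (0x0028, 0x0002, b"US", 1),
            (0x0028, 0x0004, b"CS", "MONOCHROME2"),
            (0x0028, 0x0010, b"US", n_rows),
            (0x0028, 0x0011, b"US", n_cols),
            (0x0028, 0x0030, b"DS", [f"{sy:g}", f"{sx:g}"]),
            (0x0028, 0x0100, b"US", 16),
            (0x0028, 0x0101, b"US", 16),
            (0x0028, 0x0102, b"US", 15),
            (0x0028, 0x0103, b"US", 1),
            (0x0028, 0x1052, b"DS", "0"),
            (0x0028, 0x1053, b"DS", "1"),
            (0x7FE0, 0x0010, b"OW", pixels[k].tobytes()),
        ]
        _write_file(out_dir / f"CT.{k + 1:04d}.dcm", elements, SOP_CT, sop_uid)

    roi_items, contour_items = [], []
    for number, struct_ in enumerate(structures, start=1):
        roi_items.append([
            (0x3006, 0x0022, b"IS", str(number)),
            (0x3006, 0x0026, b"LO", struct_.name),
        ])
        contour_items.append([
            (0x3006, 0x0040, b"SQ", _mask_to_contour_items(struct_.mask, ct)),
            (0x3006, 0x0084, b"IS", str(number)),
        ])
    rs_uid = _uid(seed, 4)
    elements = [
        (0x0008, 0x0016, b"UI", SOP_RTSTRUCT),
        (0x0008, 0x0018, b"UI", rs_uid),
        (0x0008, 0x0060, b"CS", "RTSTRUCT"),
        (0x0010, 0x0020, b"LO", structures.patient_id),
        (0x0020, 0x000D, b"UI", study_uid),
        (0x3006, 0x0002, b"SH", "phantom"),
        (0x3006, 0x0020, b"SQ", roi_items),
        (0x3006, 0x0039, b"SQ", contour_items),
    ]
    _write_file(out_dir / "RS.struct.dcm", elements, SOP_RTSTRUCT, rs_uid)
    return out_dir


def _mask_to_contour_items(mask: np.ndarray, ct: ImageVolume) -> list[list]:
    sz, sy, sx = ct.spacing
    oz, oy, ox = ct.origin
    items = []
    for k in np.flatnonzero(mask.any(axis=(1, 2))):
        padded = np.pad(mask[k].astype(float), 1)
        for contour in measure.find_contours(padded, 0.5):
            rc = contour - 1.0  # undo pad
            xyz = []
            for r, c in rc[:-1]:  # drop closing duplicate point
                xyz += [f"{ox + c * sx:.4f}", f"{oy + r * sy:.4f}", f"{oz + k * sz:.4f}"]
            items.append([
                (0x3006, 0x0042, b"CS", "CLOSED_PLANAR"),
                (0x3006, 0x0046, b"IS", str(len(rc) - 1)),
                (0x3006, 0x0050, b"DS", xyz),
            ])
    return items


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_dicom_patient(path: Path | str) -> tuple[ImageVolume, list[NamedStructure]]:
    path = Path(path)
    ct_slices, rtstructs = [], []
    for f in sorted(path.glob("*.dcm")):
        try:
            ds = read_dicom(f)
        except ValueError as exc:
            logger.warning("skipping unreadable DICOM file %s: %s", f, exc)
            continue
        modality = ds.get((0x0008, 0x0060))
        if modality == "CT":
            ct_slices.append(ds)
        elif modality == "RTSTRUCT":
            rtstructs.append(ds)
    if not ct_slices:
        raise MissingCTError(f"no CT series in {path}")

    ct_slices.sort(key=lambda ds: ds[(0x0020, 0x0032)][2])
    first = ct_slices[0]
    sy, sx = first[(0x0028, 0x0030)]
    positions = [ds[(0x0020, 0x0032)] for ds in ct_slices]
    sz = (positions[-1][2] - positions[0][2]) / max(len(positions) - 1, 1)
    if sz <= 0:
        sz = float(first.get((0x0018, 0x0050), 1.0))
    n_rows, n_cols = first[(0x0028, 0x0010)], first[(0x0028, 0x0011)]
    slope = float(first.get((0x0028, 0x1053), 1.0))
    intercept = float(first.get((0x0028, 0x1052), 0.0))
    voxels = np.stack([
        np.frombuffer(ds[(0x7FE0, 0x0010)], dtype="<i2").reshape(n_rows, n_cols)
        for ds in ct_slices
    ]).astype(np.float32) * slope + intercept
    origin = (positions[0][2], positions[0][1], positions[0][0])
    ct = ImageVolume(voxels, (sz, sy, sx), origin)

    structures: list[NamedStructure] = []
    for ds in rtstructs:
        names = {
            item[(0x3006, 0x0022)]: item[(0x3006, 0x0026)]
            for item in ds.get((0x3006, 0x0020), [])
        }
        for item in ds.get((0x3006, 0x0039), []):
            number = item[(0x3006, 0x0084)]
            name = names.get(number, f"ROI_{number}")
            mask = _contours_to_mask(item.get((0x3006, 0x0040), []), ct)
            structures.append(NamedStructure(name, mask))
    return ct, structures


def _contours_to_mask(contour_items: list[dict], ct: ImageVolume) -> np.ndarray:
    sz, sy, sx = ct.spacing
    oz, oy, ox = ct.origin
    mask = np.zeros(ct.shape, dtype=np.uint8)
    for item in contour_items:
        data = item.get((0x3006, 0x0050))
        if not data:
            continue
        pts = np.asarray(data, dtype=float).reshape(-1, 3)
        k = int(round((pts[0, 2] - oz) / sz))
        if not 0 <= k < ct.shape[0]:
            logger.warning("contour at z=%.2f outside CT extent; skipped", pts[0, 2])
            continue
        rows = (pts[:, 1] - oy) / sy
        cols = (pts[:, 0] - ox) / sx
        rr, cc = draw.polygon(rows, cols, shape=ct.shape[1:])
        mask[k, rr, cc] = 1
    return mask
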