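"""Minimal DICOM series codec (explicit VR little endian).

Writes a secondary-capture-style series: one single-frame file per slice
with pixel spacing, spacing between slices, per-slice patient position,
instance number and trigger time.  This is a deliberately small dialect —
enough for lossless self round-trips with standard encoding; vendor tags
and other transfer syntaxes are out of scope.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_CLASS_SECONDARY_CAPTURE = "1.2.840.10008.5.1.4.1.1.7"
_UID_ROOT = "1.2.826.0.1.3680043.10.1405"  # generic org root for generated UIDs

# tag constants (group, element)
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_TRIGGER_TIME = (0x0018, 0x1060)
TAG_SLICE_THICKNESS = (0x0018, 0x0050)
TAG_SPACING_BETWEEN_SLICES = (0x0018, 0x0088)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _pad_even(b: bytes, pad: bytes = b" ") -> bytes:
    return b + pad if len(b) % 2 else b


def _element(tag: tuple[int, int], vr: str, value: bytes) -> bytes:
    group, elem = tag
    if vr in ("OB", "OW", "SQ", "UN", "UT"):
        return struct.pack("<HH2sHI", group, elem, vr.encode(), 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr.encode(), len(value)) + value


def _ds(*values: float) -> bytes:
    return _pad_even("\\".join(f"{v:.10g}" for v in values).encode())


def _us(value: int) -> bytes:
    return struct.pack("<H", value)


def _ui(value: str) -> bytes:
    return _pad_even(value.encode(), pad=b"\x00")


def _write_slice(
    path: Path,
    pixels: np.ndarray,
    pixel_spacing: tuple[float, float],
    slice_spacing: float,
    position: tuple[float, float, float],
    instance_number: int,
    trigger_time_ms: float,
    signed: bool,
) -> None:
    dtype = "<i2" if signed else "<u2"
    pixel_bytes = np.ascontiguousarray(pixels.astype(dtype)).tobytes()
    if len(pixel_bytes) % 2:
        pixel_bytes += b"\x00"

    body = b"".join(
        [
            _element(TAG_SOP_CLASS, "UI", _ui(SOP_CLASS_SECONDARY_CAPTURE)),
            _element(
                TAG_SOP_INSTANCE, "UI", _ui(f"{_UID_ROOT}.{instance_number + 1}")
            ),
            _element(TAG_SLICE_THICKNESS, "DS", _ds(slice_spacing)),
            _element(TAG_TRIGGER_TIME, "DS", _ds(trigger_time_ms)),
            _element(TAG_SPACING_BETWEEN_SLICES, "DS", _ds(slice_spacing)),
            _element(TAG_IMAGE_POSITION, "DS", _ds(*position)),
            _element(TAG_INSTANCE_NUMBER, "IS", _pad_even(str(instance_number).encode())),
            _element(TAG_SAMPLES_PER_PIXEL, "US", _us(1)),
            _element(TAG_ROWS, "US", _us(pixels.shape[0])),
            _element(TAG_COLUMNS, "US", _us(pixels.shape[1])),
            _element(TAG_PIXEL_SPACING, "DS", _ds(*pixel_spacing)),
            _element(TAG_BITS_ALLOCATED, "US", _us(16)),
            _element(TAG_BITS_STORED, "US", _us(16)),
            _element(TAG_HIGH_BIT, "US", _us(15)),
            _element(TAG_PIXEL_REPRESENTATION, "US", _us(1 if signed else 0)),
            _element(TAG_PIXEL_DATA, "OW", pixel_bytes),
        ]
    )

    meta = b"".join(
        [
            _element((0x0002, 0x0010), "UI", _ui(TRANSFER_SYNTAX_EXPLICIT_LE)),
        ]
    )
    meta = _element((0x0002, 0x0000), "UL", struct.pack("<I", len(meta))) + meta
    path.write_bytes(b"\x00" * 128 + b"DICM" + meta + body)


def _read_elements(buf: bytes) -> dict[tuple[int, int], bytes]:
    elements: dict[tuple[int, int], bytes] = {}
    offset = 0
    while offset + 8 <= len(buf):
        group, elem, vr = struct.unpack_from("<HH2s", buf, offset)
        vr = vr.decode("ascii", "replace")
        if vr in ("OB", "OW", "SQ", "UN", "UT"):
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            start = offset + 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            start = offset + 8
        elements[(group, elem)] = buf[start : start + length]
        offset = start + length
    return elements


def read_slice(path: Path):
    """Read one slice file -> (pixels, pixel_spacing, slice_spacing, position,
    instance_number, trigger_time_ms)."""
    raw = Path(path).read_bytes()
    if raw[128:132] != b"DICM":
        raise ValueError(f"{path} is not a DICOM part-10 file")
    el = _read_elements(raw[132:])
    ts = el.get((0x0002, 0x0010), b"").rstrip(b"\x00 ").decode()
    if ts and ts != TRANSFER_SYNTAX_EXPLICIT_LE:
        raise ValueError(f"unsupported transfer syntax {ts!r}")

    def ds(tag):
        return [float(x) for x in el[tag].decode().strip().split("\\")]

    rows = struct.unpack("<H", el[TAG_ROWS])[0]
    cols = struct.unpack("<H", el[TAG_COLUMNS])[0]
    signed = struct.unpack("<H", el[TAG_PIXEL_REPRESENTATION])[0] == 1
    dtype = "<i2" if signed else "<u2"
    pixels = np.frombuffer(el[TAG_PIXEL_DATA][: rows * cols * 2], dtype=dtype)
    pixels = pixels.reshape(rows, cols)
    return (
        pixels,
        tuple(ds(TAG_PIXEL_SPACING)),
        ds(TAG_SPACING_BETWEEN_SLICES)[0],
        tuple(ds(TAG_IMAGE_POSITION)),
        int(el[TAG_INSTANCE_NUMBER].decode().strip()),
        ds(TAG_TRIGGER_TIME)[0],
    )


def write_series(
    directory,
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    trigger_time_ms: float = 0.0,
) -> list[Path]:
    """Write a 3D array as one file per slice along the LAST axis.

    ``spacing`` is (axis0, axis1, slice) in the array's own axis order;
    ``origin`` is the world position of voxel (0, 0, 0) in that same order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signed = np.issubdtype(volume.dtype, np.signedinteger)
    paths = []
    for k in range(volume.shape[2]):
        position = (origin[0], origin[1], origin[2] + k * spacing[2])
        out = directory / f"slice_{k:04d}.dcm"
        _write_slice(
            out,
            volume[:, :, k],
            pixel_spacing=(spacing[0], spacing[1]),
            slice_spacing=spacing[2],
            position=position,
            instance_number=k,
            trigger_time_ms=trigger_time_ms,
            signed=signed,
        )
        paths.append(out)
    return paths


def read_series(directory):
    """Read a directory written by :func:`write_series`.

    Returns ``(volume, spacing, origin, trigger_time_ms)`` with slices
    stacked along the last axis in instance-number order.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {directory}")
    slices = [read_slice(f) for f in files]
    slices.sort(key=lambda s: s[4])
    pixels, pixel_spacing, slice_spacing, position0, _, trigger = slices[0]
    volume = np.stack([s[0] for s in slices], axis=2)
    spacing = (pixel_spacing[0], pixel_spacing[1], slice_spacing)
    return volume, spacing, position0, trigger
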