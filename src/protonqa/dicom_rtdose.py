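"""Minimal DICOM RT Dose reader/writer (explicit VR little endian).

Implements exactly the subset of the DICOM file format needed to exchange
regular-lattice RT Dose objects: a 128-byte preamble + ``DICM``, explicit-VR
little-endian data elements, and the RT Dose module attributes (dose-grid
scaling, grid frame offsets, pixel geometry, 32-bit unsigned pixel data).

The writer chooses the dose-grid scaling so that 32-bit quantization error is
below 1e-4 of the maximum dose.  The reader validates the attributes it relies
on and raises :class:`DicomFormatError` naming the offending attribute; it
supports identity image orientation only (the synthetic pipeline's convention:
columns → x, rows → y, frames → z = depth).
"""

from __future__ import annotations

import struct
import uuid

import numpy as np

from .grids import DoseGrid

__all__ = ["DicomFormatError", "read_rtdose", "write_rtdose"]

_EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
# VRs that use the 4-byte length form with 2 reserved bytes
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_MODALITY = (0x0008, 0x0060)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_NUM_FRAMES = (0x0028, 0x0008)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLUMNS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_DOSE_UNITS = (0x3004, 0x0002)
TAG_GRID_FRAME_OFFSETS = (0x3004, 0x000C)
TAG_DOSE_GRID_SCALING = (0x3004, 0x000E)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


class DicomFormatError(ValueError):
    """Raised when a file is not a DICOM RT Dose object this codec can read."""


def _new_uid() -> str:
    # UUID-derived UID under the standard "2.25" root
    return f"2.25.{uuid.uuid4().int}"


# -- encoding --------------------------------------------------------------


def _encode_element(group: int, element: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB") else b" "
    head = struct.pack("<HH2s", group, element, vr)
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    if len(value) > 0xFFFF:
        raise ValueError("value too long for short-form VR")
    return head + struct.pack("<H", len(value)) + value


def _txt(s: str) -> bytes:
    return s.encode("ascii")


def _ds(values) -> bytes:
    return _txt("\\".join(format(float(v), ".10g") for v in np.atleast_1d(values)))


def write_rtdose(grid: DoseGrid, path) -> None:
    """Write a DoseGrid as a DICOM RT Dose file readable by :func:`read_rtdose`."""
    if grid.values.size == 0:
        raise ValueError("cannot write an empty grid")
    nx, ny, nz = grid.shape
    max_dose = float(grid.values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    pixels = np.round(grid.values / scaling).astype(np.uint32)
    # frames-major ordering: [frame(z)][row(y)][col(x)]
    pixel_bytes = np.ascontiguousarray(pixels.transpose(2, 1, 0)).astype("<u4").tobytes()

    sop_instance = _new_uid()
    meta_elems = b"".join(
        [
            _encode_element(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _encode_element(0x0002, 0x0002, b"UI", _txt(_RTDOSE_SOP_CLASS)),
            _encode_element(0x0002, 0x0003, b"UI", _txt(sop_instance)),
            _encode_element(0x0002, 0x0010, b"UI", _txt(_EXPLICIT_VR_LE)),
            _encode_element(0x0002, 0x0012, b"UI", _txt("2.25.0.1")),
        ]
    )
    meta = _encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_elems))) + meta_elems

    offsets = grid.spacing[2] * np.arange(nz)
    body = b"".join(
        [
            _encode_element(*TAG_SOP_CLASS, b"UI", _txt(_RTDOSE_SOP_CLASS)),
            _encode_element(0x0008, 0x0018, b"UI", _txt(sop_instance)),
            _encode_element(*TAG_MODALITY, b"CS", b"RTDOSE"),
            _encode_element(0x0008, 0x103E, b"LO", _txt(grid.description[:64])),
            _encode_element(*TAG_IMAGE_POSITION, b"DS", _ds(grid.origin)),
            _encode_element(*TAG_IMAGE_ORIENTATION, b"DS", _ds([1, 0, 0, 0, 1, 0])),
            _encode_element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            _encode_element(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
            _encode_element(*TAG_NUM_FRAMES, b"IS", _txt(str(nz))),
            _encode_element(*TAG_ROWS, b"US", struct.pack("<H", ny)),
            _encode_element(*TAG_COLUMNS, b"US", struct.pack("<H", nx)),
            # PixelSpacing is row pitch (y) then column pitch (x)
            _encode_element(*TAG_PIXEL_SPACING, b"DS", _ds([grid.spacing[1], grid.spacing[0]])),
            _encode_element(*TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 32)),
            _encode_element(0x0028, 0x0101, b"US", struct.pack("<H", 32)),
            _encode_element(0x0028, 0x0102, b"US", struct.pack("<H", 31)),
            _encode_element(*TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 0)),
            _encode_element(*TAG_DOSE_UNITS, b"CS", b"GY"),
            _encode_element(0x3004, 0x0004, b"CS", b"PHYSICAL"),
            _encode_element(0x3004, 0x000A, b"CS", b"PLAN"),
            _encode_element(*TAG_GRID_FRAME_OFFSETS, b"DS", _ds(offsets)),
            _encode_element(*TAG_DOSE_GRID_SCALING, b"DS", _ds([scaling])),
            _encode_element(*TAG_PIXEL_DATA, b"OW", pixel_bytes),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM" + meta + body)


# -- decoding --------------------------------------------------------------


def _parse_elements(buf: bytes, start: int) -> dict:
    """Parse explicit-VR little-endian elements into {tag: (vr, value-bytes)}."""
    elems: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    pos = start
    n = len(buf)
    while pos + 8 <= n:
        group, element = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6]
        if not (vr.isalpha() and vr.isupper()):
            raise DicomFormatError(
                f"tag ({group:04X},{element:04X}): not explicit-VR little-endian encoding"
            )
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            pos += 8
        if length == 0xFFFFFFFF:
            raise DicomFormatError(
                f"tag ({group:04X},{element:04X}): undefined-length values are not supported"
            )
        if pos + length > n:
            raise DicomFormatError(f"tag ({group:04X},{element:04X}): truncated value")
        elems[(group, element)] = (vr, buf[pos : pos + length])
        pos += length
    return elems


def _require(elems: dict, tag: tuple[int, int], name: str) -> tuple[bytes, bytes]:
    if tag not in elems:
        raise DicomFormatError(f"missing required attribute {name} ({tag[0]:04X},{tag[1]:04X})")
    return elems[tag]


def _decode_ds(raw: bytes, name: str) -> np.ndarray:
    try:
        return np.array([float(p) for p in raw.decode("ascii").strip("\x00 ").split("\\")])
    except ValueError as exc:
        raise DicomFormatError(f"cannot parse {name}: {raw!r}") from exc


def _decode_us(raw: bytes) -> int:
    return struct.unpack("<H", raw[:2])[0]


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose file into a DoseGrid (dose-grid scaling applied)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomFormatError(f"{path}: missing DICM magic — not a DICOM part-10 file")
    elems = _parse_elements(buf, 132)

    ts = elems.get(TAG_TRANSFER_SYNTAX)
    if ts is not None and ts[1].decode("ascii").strip("\x00 ") != _EXPLICIT_VR_LE:
        raise DicomFormatError(
            f"unsupported TransferSyntaxUID {ts[1]!r}; only explicit VR little endian is handled"
        )
    modality = _require(elems, TAG_MODALITY, "Modality")[1].decode("ascii").strip("\x00 ")
    if modality != "RTDOSE":
        raise DicomFormatError(f"Modality is {modality!r}, expected 'RTDOSE'")

    scaling = float(_decode_ds(_require(elems, TAG_DOSE_GRID_SCALING, "DoseGridScaling")[1],
                               "DoseGridScaling")[0])
    nx = _decode_us(_require(elems, TAG_COLUMNS, "Columns")[1])
    ny = _decode_us(_require(elems, TAG_ROWS, "Rows")[1])
    nz = int(_require(elems, TAG_NUM_FRAMES, "NumberOfFrames")[1].decode("ascii").strip("\x00 "))
    spacing_rc = _decode_ds(_require(elems, TAG_PIXEL_SPACING, "PixelSpacing")[1], "PixelSpacing")
    origin = _decode_ds(
        _require(elems, TAG_IMAGE_POSITION, "ImagePositionPatient")[1], "ImagePositionPatient"
    )

    if TAG_IMAGE_ORIENTATION in elems:
        iop = _decode_ds(elems[TAG_IMAGE_ORIENTATION][1], "ImageOrientationPatient")
        if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
            raise DicomFormatError(
                f"ImageOrientationPatient {iop.tolist()} is not identity; unsupported orientation"
            )

    offsets = _decode_ds(
        _require(elems, TAG_GRID_FRAME_OFFSETS, "GridFrameOffsetVector")[1],
        "GridFrameOffsetVector",
    )
    if len(offsets) != nz:
        raise DicomFormatError(
            f"GridFrameOffsetVector length {len(offsets)} != NumberOfFrames {nz}"
        )
    if nz > 1:
        steps = np.diff(offsets)
        if np.any(steps <= 0) or np.ptp(steps) > 1e-6 * max(abs(steps[0]), 1.0):
            raise DicomFormatError(
                "GridFrameOffsetVector is not uniformly increasing — non-uniform slice spacing"
            )
        dz = float(steps[0])
    else:
        dz = 1.0

    bits = _decode_us(_require(elems, TAG_BITS_ALLOCATED, "BitsAllocated")[1])
    if bits not in (16, 32):
        raise DicomFormatError(f"BitsAllocated {bits} unsupported (expected 16 or 32)")
    signed = _decode_us(elems.get(TAG_PIXEL_REPRESENTATION, (b"US", b"\x00\x00"))[1]) == 1
    dtype = {16: "<i2" if signed else "<u2", 32: "<i4" if signed else "<u4"}[bits]

    raw = _require(elems, TAG_PIXEL_DATA, "PixelData")[1]
    expected = nx * ny * nz * (bits // 8)
    if len(raw) < expected:
        raise DicomFormatError(f"PixelData holds {len(raw)} bytes, expected {expected}")
    pixels = np.frombuffer(raw[:expected], dtype=dtype).reshape(nz, ny, nx)
    values = pixels.transpose(2, 1, 0).astype(float) * scaling

    return DoseGrid(
        values=values,
        origin=(float(origin[0]), float(origin[1]), float(origin[2])),
        spacing=(float(spacing_rc[1]), float(spacing_rc[0]), dz),
        description=elems.get((0x0008, 0x103E), (b"LO", b""))[1].decode("ascii").strip("\x00 "),
    )
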