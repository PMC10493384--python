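"""Minimal DICOM series support (read-only public surface).

Only the subset needed to ingest uncompressed CT series is implemented:
explicit-VR little-endian transfer syntax, 16-bit signed/unsigned pixels,
single-frame monochrome slices.  No installed package in the target
environment reads DICOM, hence this hand-rolled parser; anything outside the
subset raises :class:`FormatError` rather than guessing.

``write_dicom_series`` exists so the test suite and the synthetic-data module
can fabricate series to read back; it is not a general-purpose DICOM writer.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError
from .volumes import AcquisitionMeta, CTVolume

_EXPLICIT_LE = "1.2.840.10008.1.2.1"
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

# (group, element) -> short name
_TAGS = {
    (0x0008, 0x0070): "manufacturer",
    (0x0018, 0x0060): "kvp",
    (0x0018, 0x1152): "exposure",
    (0x0020, 0x0032): "position",
    (0x0020, 0x0037): "orientation",
    (0x0028, 0x0010): "rows",
    (0x0028, 0x0011): "cols",
    (0x0028, 0x0030): "pixel_spacing",
    (0x0028, 0x0100): "bits_allocated",
    (0x0028, 0x0103): "pixel_representation",
    (0x0028, 0x1052): "intercept",
    (0x0028, 0x1053): "slope",
    (0x7FE0, 0x0010): "pixel_data",
}


def _parse_file(path: Path) -> dict:
    raw = path.read_bytes()
    if len(raw) < 132 or raw[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM magic (not part-10 DICOM)")
    pos = 132
    out: dict = {}
    n = len(raw)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", raw, pos)
        vr = raw[pos + 4 : pos + 6]
        if not (vr.isalpha() and vr.isupper()):
            raise FormatError(f"{path}: implicit-VR or corrupt element at offset {pos}")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", raw, pos + 8)
            body = pos + 12
        else:
            (length,) = struct.unpack_from("<H", raw, pos + 6)
            body = pos + 8
        if length == 0xFFFFFFFF or vr == b"SQ":
            raise FormatError(f"{path}: sequences/undefined lengths unsupported")
        value = raw[body : body + length]
        if len(value) < length:
            raise FormatError(f"{path}: truncated element ({group:04x},{elem:04x})")
        key = _TAGS.get((group, elem))
        if key is not None:
            out[key] = (vr, value)
        if group == 0x0002 and elem == 0x0010:
            ts = value.rstrip(b"\x00").decode("ascii")
            if ts != _EXPLICIT_LE:
                raise FormatError(f"{path}: unsupported transfer syntax {ts}")
        pos = body + length
    return out


def _str(field) -> str:
    return field[1].rstrip(b"\x00 ").decode("ascii")


def _floats(field) -> list[float]:
    return [float(x) for x in _str(field).split("\\")]


def _us(field) -> int:
    return struct.unpack("<H", field[1][:2])[0]


def read_dicom_series(directory) -> CTVolume:
    """Read every .dcm file in *directory* into one HU volume.

    Slices are ordered along the acquisition normal; non-uniform inter-slice
    spacing (tolerance 1e-3 mm) is a :class:`FormatError`.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise OSError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        d = _parse_file(f)
        for req in ("rows", "cols", "position", "orientation", "pixel_spacing", "pixel_data"):
            if req not in d:
                raise FormatError(f"{f}: missing required element '{req}'")
        if d.get("bits_allocated") is not None and _us(d["bits_allocated"]) != 16:
            raise FormatError(f"{f}: only 16-bit pixel data supported")
        rows, cols = _us(d["rows"]), _us(d["cols"])
        signed = d.get("pixel_representation") is not None and _us(d["pixel_representation"]) == 1
        dtype = np.int16 if signed else np.uint16
        pixels = np.frombuffer(d["pixel_data"][1][: rows * cols * 2], dtype=dtype)
        if pixels.size != rows * cols:
            raise FormatError(f"{f}: pixel data size mismatch")
        slope = _floats(d["slope"])[0] if "slope" in d else 1.0
        intercept = _floats(d["intercept"])[0] if "intercept" in d else 0.0
        hu = pixels.astype(np.float64).reshape(rows, cols) * slope + intercept
        slices.append((d, hu))

    d0 = slices[0][0]
    iop = _floats(d0["orientation"])
    row_dir = np.array(iop[:3])  # direction across columns (increasing x index)
    col_dir = np.array(iop[3:])  # direction down rows
    normal = np.cross(row_dir, col_dir)
    order = sorted(slices, key=lambda s: float(np.dot(_floats(s[0]["position"]), normal)))
    zpos = [float(np.dot(_floats(s[0]["position"]), normal)) for s in order]
    if len(zpos) > 1:
        gaps = np.diff(zpos)
        if np.any(gaps <= 0) or (np.max(gaps) - np.min(gaps)) > 1e-3:
            raise FormatError(f"{directory}: non-uniform inter-slice spacing {sorted(set(np.round(gaps, 4)))}")
        dz = float(np.mean(gaps))
    else:
        dz = 1.0
    ps = _floats(d0["pixel_spacing"])  # [row spacing (y), column spacing (x)]
    # voxels[i, j, k]: i along row_dir, j along col_dir, k along normal
    vox = np.stack([hu.T for _, hu in order], axis=-1)
    direction = np.column_stack([row_dir, col_dir, normal])
    meta = AcquisitionMeta(
        kvp=_floats(d0["kvp"])[0] if "kvp" in d0 else None,
        mas=float(_str(d0["exposure"])) if "exposure" in d0 else None,
        scanner=_str(d0["manufacturer"]) if "manufacturer" in d0 else "",
    )
    origin = tuple(_floats(order[0][0]["position"]))
    return CTVolume(vox, (ps[1], ps[0], dz), origin, direction, meta)


# ---------------------------------------------------------------------------
# Writer (synthetic series for tests only)
# ---------------------------------------------------------------------------

def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in (b"UI", b"OB", b"OW", b"UN", b"UL", b"US") else b" "
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def write_dicom_series(
    volume: CTVolume,
    directory,
    slope: float = 1.0,
    intercept: float = 0.0,
    slice_positions=None,
) -> None:
    """Write *volume* as a synthetic explicit-VR-LE CT series (test fixture use).

    Stored values are ``(HU - intercept) / slope`` rounded to int16.
    ``slice_positions`` overrides the per-slice offsets along the normal (mm),
    allowing deliberately non-uniform series.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = volume.shape
    row_dir = volume.direction[:, 0]
    col_dir = volume.direction[:, 1]
    normal = volume.direction[:, 2]
    if slice_positions is None:
        slice_positions = [k * volume.spacing[2] for k in range(nz)]
    meta_group = _element(0x0002, 0x0010, b"UI", _EXPLICIT_LE.encode())
    meta_group = (
        _element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_group))) + meta_group
    )
    preamble = b"\x00" * 128 + b"DICM" + meta_group
    ds_fmt = lambda vals: "\\".join(f"{v:.6f}" for v in vals).encode()
    for k in range(nz):
        stored = np.round((volume.voxels[:, :, k] - intercept) / slope).astype(np.int16)
        pos = np.asarray(volume.origin) + normal * slice_positions[k]
        body = b"".join(
            [
                _element(0x0008, 0x0016, b"UI", b"1.2.840.10008.5.1.4.1.1.2"),
                _element(0x0008, 0x0018, b"UI", f"1.2.826.0.1.999999.1.{k + 1}".encode()),
                _element(0x0008, 0x0060, b"CS", b"CT"),
                _element(0x0008, 0x0070, b"LO", (volume.meta.scanner or "SYNTH").encode()),
                _element(
                    0x0018, 0x0060, b"DS", f"{volume.meta.kvp:.1f}".encode()
                )
                if volume.meta.kvp is not None
                else b"",
                _element(0x0018, 0x1152, b"IS", f"{int(volume.meta.mas)}".encode())
                if volume.meta.mas is not None
                else b"",
                _element(0x0020, 0x0013, b"IS", f"{k + 1}".encode()),
                _element(0x0020, 0x0032, b"DS", ds_fmt(pos)),
                _element(0x0020, 0x0037, b"DS", ds_fmt([*row_dir, *col_dir])),
                _element(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
                _element(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
                _element(0x0028, 0x0010, b"US", struct.pack("<H", ny)),
                _element(0x0028, 0x0011, b"US", struct.pack("<H", nx)),
                _element(0x0028, 0x0030, b"DS", ds_fmt([volume.spacing[1], volume.spacing[0]])),
                _element(0x0028, 0x0100, b"US", struct.pack("<H", 16)),
                _element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
                _element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
                _element(0x0028, 0x0103, b"US", struct.pack("<H", 1)),
                _element(0x0028, 0x1052, b"DS", f"{intercept:.1f}".encode()),
                _element(0x0028, 0x1053, b"DS", f"{slope:.1f}".encode()),
                _element(0x7FE0, 0x0010, b"OW", stored.T.tobytes()),
            ]
        )
        (directory / f"slice_{k:04d}.dcm").write_bytes(preamble + body)
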