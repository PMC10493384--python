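"""CT volume and mask containers with NIfTI / DICOM-series I/O.

All world coordinates are millimetres in one fixed LPS-style frame; voxel
indexing is 0-based with ``voxels[i, j, k]`` mapping to world space through
``origin + direction @ (spacing * (i, j, k))``.  Hounsfield units are floats
in memory and 16-bit signed integers on disk.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, GeometryError

__all__ = [
    "AcquisitionMeta",
    "CTVolume",
    "MaskSet",
    "load_volume",
    "save_volume",
    "save_masks",
    "load_masks",
]

HU_AIR = -1024.0
HU_MAX = 4000.0
GEOM_TOL = 1e-5


@dataclass
class AcquisitionMeta:
    """CT acquisition parameters carried alongside the voxel data.

    kvp : tube voltage in kVp (the study used 80, 100 and 120).
    mas : tube current-time product in mAs (the study used 50).
    scanner : free-text scanner label (e.g. "SIEMENS Somatom Force").
    """

    kvp: float | None = None
    mas: float | None = None
    scanner: str = ""

    def to_dict(self) -> dict:
        return {"kvp": self.kvp, "mas": self.mas, "scanner": self.scanner}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(kvp=d.get("kvp"), mas=d.get("mas"), scanner=d.get("scanner", ""))


def _as_direction(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    if d.shape != (3, 3):
        raise GeometryError(f"direction must be 3x3, got {d.shape}")
    return d


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units with its spatial geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise GeometryError("CTVolume requires a 3-D voxel array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = _as_direction(self.direction)
        det = abs(np.linalg.det(self.direction))
        if abs(det - 1.0) > 1e-6 or not np.allclose(
            self.direction @ self.direction.T, np.eye(3), atol=1e-6
        ):
            raise GeometryError("direction cosines must be orthonormal (|det| = 1)")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index -> world (mm) affine."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ (self.direction @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        m = np.linalg.inv(self.direction @ np.diag(self.spacing))
        return (pts - np.asarray(self.origin)) @ m.T

    def center_world(self) -> np.ndarray:
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.index_to_world(c)[0]

    def geometry_matches(self, other, tol: float = GEOM_TOL) -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    def validate(self) -> list[str]:
        """Return a list of soft-invariant warnings (empty if clean).

        HU outside the nominal CT range [-1024, 4000] is reported, not
        clipped: Gaussian noise models parameterized from real scans
        legitimately spill a few HU past the encoder floor.
        """
        notes = []
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_AIR or hi > HU_MAX:
            notes.append(f"HU range [{lo:.1f}, {hi:.1f}] exceeds nominal [{HU_AIR}, {HU_MAX}]")
        return notes

    def with_voxels(self, voxels: np.ndarray) -> "CTVolume":
        return CTVolume(voxels, self.spacing, self.origin, self.direction.copy(), self.meta)


@dataclass
class MaskSet:
    """Named binary masks sharing one voxel geometry."""

    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    direction: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.direction = _as_direction(self.direction)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise GeometryError(f"masks disagree on shape: {shapes}")
        for name in self.masks:
            self.masks[name] = np.asarray(self.masks[name]).astype(bool)

    @classmethod
    def from_volume(cls, volume: CTVolume, masks: dict[str, np.ndarray] | None = None) -> "MaskSet":
        ms = cls(volume.spacing, volume.origin, volume.direction.copy(), dict(masks or {}))
        for m in ms.masks.values():
            if m.shape != volume.shape:
                raise GeometryError("mask shape does not match volume shape")
        return ms

    @property
    def shape(self):
        for m in self.masks.values():
            return m.shape
        return None

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask).astype(bool)
        if self.shape is not None and mask.shape != self.shape:
            raise GeometryError("mask shape mismatch")
        self.masks[name] = mask

    def geometry_matches(self, volume, tol: float = GEOM_TOL) -> bool:
        return (
            (self.shape is None or self.shape == tuple(volume.shape))
            and np.allclose(self.spacing, volume.spacing, atol=tol)
            and np.allclose(self.origin, volume.origin, atol=tol)
            and np.allclose(self.direction, volume.direction, atol=tol)
        )

    def pairwise_disjoint(self) -> bool:
        total = None
        for m in self.masks.values():
            if total is None:
                total = m.astype(np.uint8).copy()
            else:
                total += m
        return total is None or int(total.max(initial=0)) <= 1


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _nifti_sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".meta.json")
    return path.with_suffix(".meta.json")


def save_volume(volume: CTVolume, path, format: str = "nifti") -> None:
    """Write a volume as NIfTI-1 (.nii / .nii.gz) plus a JSON metadata sidecar.

    Integral HU grids are stored as int16 (CT convention, lossless); anything
    else as float32.
    """
    if format != "nifti":
        raise FormatError(f"unsupported write format: {format}")
    path = Path(path)
    vox = volume.voxels
    if np.issubdtype(vox.dtype, np.integer) or np.all(vox == np.round(vox)):
        data = np.round(vox).astype(np.int16)
    else:
        data = vox.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:  # unwritable path, bad extension
        raise OSError(f"cannot write NIfTI to {path}: {exc}") from exc
    meta = volume.meta.to_dict()
    if any(v not in (None, "") for v in meta.values()):
        _nifti_sidecar(path).write_text(json.dumps(meta, indent=1))


def _volume_from_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"degenerate spacing in {path}")
    direction = lin / spacing
    vox = np.asanyarray(img.dataobj).astype(np.float64)
    meta = AcquisitionMeta()
    sidecar = _nifti_sidecar(path)
    if sidecar.exists():
        meta = AcquisitionMeta.from_dict(json.loads(sidecar.read_text()))
    return CTVolume(vox, tuple(spacing), tuple(aff[:3, 3]), direction, meta)


def load_volume(path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    DICOM rescale slope/intercept are applied so voxels are in HU.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file or directory: {path}")
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return _volume_from_nifti(path)
    if format == "dicom_dir":
        from ._dicom import read_dicom_series

        return read_dicom_series(path)
    raise FormatError(f"unknown format: {format}")


# ---------------------------------------------------------------------------
# Mask persistence: one multi-label NIfTI when masks are disjoint, otherwise
# one binary NIfTI per compartment; a JSON sidecar names the labels.
# ---------------------------------------------------------------------------

_MASKSET_JSON = "maskset.json"


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]", "_", name)


def save_masks(maskset: MaskSet, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4)
    aff[:3, :3] = maskset.direction @ np.diag(maskset.spacing)
    aff[:3, 3] = maskset.origin
    manifest: dict = {"names": maskset.names}
    if maskset.pairwise_disjoint() and maskset.masks:
        labels = np.zeros(maskset.shape, dtype=np.uint16)
        label_of = {}
        for i, (name, m) in enumerate(maskset.masks.items(), start=1):
            labels[m] = i
            label_of[name] = i
        nib.save(nib.Nifti1Image(labels, aff), str(out_dir / "labels.nii.gz"))
        manifest.update(format="labels", labels=label_of, file="labels.nii.gz")
    else:
        files = {}
        for i, (name, m) in enumerate(maskset.masks.items()):
            fname = f"mask_{i:03d}_{_safe_name(name)}.nii.gz"
            nib.save(nib.Nifti1Image(m.astype(np.uint8), aff), str(out_dir / fname))
            files[name] = fname
        manifest.update(format="binary", files=files)
    (out_dir / _MASKSET_JSON).write_text(json.dumps(manifest, indent=1))


def load_masks(path) -> MaskSet:
    path = Path(path)
    manifest_path = path / _MASKSET_JSON
    if not manifest_path.exists():
        raise FormatError(f"no {_MASKSET_JSON} in {path}")
    manifest = json.loads(manifest_path.read_text())
    names = manifest["names"]
    if len(set(names)) != len(names):
        raise FormatError(f"compartment name collision in {manifest_path}")
    masks: dict[str, np.ndarray] = {}
    geom = None
    if manifest["format"] == "labels":
        img = nib.load(str(path / manifest["file"]))
        labels = np.asanyarray(img.dataobj)
        geom = img.affine
        for name in names:
            masks[name] = labels == manifest["labels"][name]
    else:
        shape = None
        for name in names:
            img = nib.load(str(path / manifest["files"][name]))
            m = np.asanyarray(img.dataobj) > 0
            if shape is None:
                shape, geom = m.shape, img.affine
            elif m.shape != shape:
                raise FormatError(f"mask '{name}' shape {m.shape} != {shape}")
            masks[name] = m
    lin = geom[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return MaskSet(tuple(spacing), tuple(geom[:3, 3]), lin / spacing, masks)
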