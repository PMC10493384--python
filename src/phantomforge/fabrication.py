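"""Infill calibration, print planning and STL surface export.

Fused-deposition printing approximates tissue density by the infill
percentage of PLA: the denser the lattice, the higher the CT number of the
printed part.  A :class:`CalibrationCurve` maps infill % to expected mean HU
— a monotone piecewise-linear interpolant through cube-phantom measurements,
anchored at air (0 % infill) and at the fully dense material (100 %).  Its
inverse turns per-compartment HU targets into an :class:`InfillPlan`, and
marching cubes turns each compartment mask into a printable closed mesh.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure
from sklearn.isotonic import IsotonicRegression

from .errors import ConfigError, FitError, GeometryError
from .volumes import CTVolume

__all__ = [
    "CalibrationSample",
    "CalibrationCurve",
    "InfillPlan",
    "SurfaceMesh",
    "DEFAULT_ANCHORS",
    "measure_cubes",
    "fit_calibration",
    "plan_infill",
    "extract_surface",
    "mesh_volume",
    "write_stl",
    "read_stl",
    "export_print_plan",
    "load_print_plan",
]

# Anchor HU at the infill extremes: air at 0 %; at 100 % the densest target
# tissue of the source scan (bone, patient mean HU from the study's Table of
# compartment statistics).  Both overridable per fit.
DEFAULT_ANCHORS = (-1000.0, 470.78)


@dataclass(frozen=True)
class CalibrationSample:
    infill: float      # percent
    mean_hu: float
    sd_hu: float = 0.0
    roi_voxels: int = 1

    def __post_init__(self):
        if not (0.0 <= self.infill <= 100.0):
            raise ConfigError(f"infill must be in [0, 100], got {self.infill}")
        if self.roi_voxels <= 0:
            raise ConfigError("roi_voxels must be positive")


@dataclass
class CalibrationCurve:
    """Monotone piecewise-linear infill % <-> mean HU mapping."""

    infills: np.ndarray   # ascending knots, includes 0 and 100
    hus: np.ndarray       # non-decreasing knot values
    samples: list[CalibrationSample] = field(default_factory=list)

    def __post_init__(self):
        self.infills = np.asarray(self.infills, dtype=float)
        self.hus = np.asarray(self.hus, dtype=float)
        if self.infills.ndim != 1 or self.infills.shape != self.hus.shape:
            raise ConfigError("infills and hus must be 1-D arrays of equal length")
        if np.any(np.diff(self.infills) <= 0):
            raise ConfigError("infill knots must be strictly increasing")
        if np.any(np.diff(self.hus) < -1e-9):
            raise ConfigError("calibration mapping must be non-decreasing in infill")

    @property
    def hu_span(self) -> tuple[float, float]:
        return float(self.hus[0]), float(self.hus[-1])

    def forward(self, infill) -> np.ndarray | float:
        out = np.interp(infill, self.infills, self.hus)
        return float(out) if np.isscalar(infill) else out

    def inverse(self, hu) -> np.ndarray | float:
        """Lowest infill whose expected HU reaches *hu* (values outside the
        curve's HU span clamp to 0 / 100)."""
        h, keep = np.unique(self.hus, return_index=True)  # first infill per HU
        out = np.interp(hu, h, self.infills[keep])
        return float(out) if np.isscalar(hu) else out

    def to_dict(self) -> dict:
        return {"infills": self.infills.tolist(), "hus": self.hus.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(np.asarray(d["infills"]), np.asarray(d["hus"]))

    @classmethod
    def linear(cls, hu_at_0: float, hu_at_100: float) -> "CalibrationCurve":
        return cls(np.array([0.0, 100.0]), np.array([hu_at_0, hu_at_100]))


def measure_cubes(volume: CTVolume, cube_centers, roi_side_mm: float = 10.0,
                  infills=None) -> list[CalibrationSample]:
    """Mean/SD HU in a cubic ROI centred on each calibration cube.

    *cube_centers* are world-mm positions; *infills* (optional, same length)
    attaches the nominal infill of each cube to its sample.
    """
    samples = []
    half = roi_side_mm / 2.0
    for i, center in enumerate(cube_centers):
        idx_c = volume.world_to_index(center)[0]
        half_vox = half / np.asarray(volume.spacing)
        lo = np.round(idx_c - half_vox).astype(int)
        hi = np.round(idx_c + half_vox).astype(int)
        if np.any(lo < 0) or np.any(hi >= volume.shape):
            raise GeometryError(f"ROI at {center} extends outside the volume")
        roi = volume.voxels[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        samples.append(
            CalibrationSample(
                infill=float(infills[i]) if infills is not None else 0.0,
                mean_hu=float(roi.mean()),
                sd_hu=float(roi.std(ddof=1)) if roi.size > 1 else 0.0,
                roi_voxels=int(roi.size),
            )
        )
    return samples


def fit_calibration(
    samples: list[CalibrationSample],
    anchors: tuple[float, float] = DEFAULT_ANCHORS,
) -> CalibrationCurve:
    """Monotone interpolant through the cube samples and the two anchors.

    Noisy (non-monotone) sample means are monotonized by isotonic regression
    over infill before interpolation, then clipped into the anchor span.
    """
    hu0, hu100 = float(anchors[0]), float(anchors[1])
    if not (np.isfinite(hu0) and np.isfinite(hu100)) or hu100 <= hu0:
        raise FitError(f"anchors must be finite with hu_at_100 > hu_at_0, got {anchors}")
    pts = sorted(samples, key=lambda s: s.infill)
    levels = sorted({s.infill for s in pts})
    if len(levels) < 2:
        raise FitError(f"need >= 2 distinct infill levels, got {len(levels)}")
    if len({s.mean_hu for s in pts}) == 1:
        warnings.warn("all calibration samples have identical HU: degenerate fit")
    x = np.array([s.infill for s in pts])
    y = np.array([s.mean_hu for s in pts])
    w = np.array([max(s.roi_voxels, 1) for s in pts], dtype=float)
    y_mono = IsotonicRegression(increasing=True).fit(x, y, sample_weight=w).predict(levels)
    y_mono = np.clip(y_mono, hu0, hu100)
    knots_x, knots_y = [], []
    if levels[0] > 0.0:
        knots_x.append(0.0)
        knots_y.append(hu0)
    knots_x.extend(levels)
    knots_y.extend(y_mono)
    if levels[-1] < 100.0:
        knots_x.append(100.0)
        knots_y.append(hu100)
    knots_y = np.maximum.accumulate(knots_y)  # anchor clipping kept monotone
    return CalibrationCurve(np.asarray(knots_x), np.asarray(knots_y), samples=pts)


@dataclass
class InfillPlan:
    """Per-compartment infill assignment plus the HU each choice predicts."""

    entries: dict[str, dict]  # name -> {infill, target_hu, predicted_hu}
    scaffold_floor: float = 10.0
    step: float = 2.5
    material: str = "PLA"

    def infill_of(self, name: str) -> float:
        return self.entries[name]["infill"]

    def to_dict(self) -> dict:
        return {
            "entries": self.entries,
            "scaffold_floor": self.scaffold_floor,
            "step": self.step,
            "material": self.material,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InfillPlan":
        return cls(d["entries"], d["scaffold_floor"], d["step"], d.get("material", "PLA"))


def plan_infill(
    stats: dict[str, float],
    curve: CalibrationCurve,
    scaffold_floor: float = 10.0,
    step: float = 2.5,
    load_bearing: set[str] = frozenset({"lungs"}),
) -> InfillPlan:
    """Invert the calibration at each compartment's target mean HU.

    Targets outside the curve's HU span clamp to the nearest end (with a
    warning); infills are quantized to *step* and load-bearing compartments
    (by default the air lungs, which need a minimal scaffold to print) are
    floored at *scaffold_floor*.
    """
    lo, hi = curve.hu_span
    entries = {}
    for name, target in stats.items():
        t = float(target)
        if t < lo or t > hi:
            warnings.warn(
                f"{name}: target {t:.1f} HU outside calibration span [{lo:.1f}, {hi:.1f}]; clamped"
            )
            t = min(max(t, lo), hi)
        infill = curve.inverse(t)
        infill = round(infill / step) * step
        if name in load_bearing:
            infill = max(infill, scaffold_floor)
        infill = float(min(max(infill, 0.0), 100.0))
        entries[name] = {
            "infill": infill,
            "target_hu": float(target),
            "predicted_hu": float(curve.forward(infill)),
        }
    return InfillPlan(entries, scaffold_floor=scaffold_floor, step=step)


# ---------------------------------------------------------------------------
# Surface meshes and STL
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    vertices: np.ndarray   # (n, 3) world mm
    triangles: np.ndarray  # (m, 3) vertex indices
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ConfigError("triangle index out of range")

    def is_closed(self) -> bool:
        """Every undirected edge shared by exactly two triangles."""
        edges = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        return bool(edges) and all(c == 2 for c in edges.values())


def extract_surface(
    mask: np.ndarray, geometry: CTVolume, name: str = "", upsample: int = 2
) -> SurfaceMesh:
    """Closed triangulated 0.5-isosurface of a binary mask, vertices in world mm.

    The mask is zero-padded by one voxel so surfaces touching the volume
    border still close, and replicated ``upsample``× per axis first so the
    isosurface sits at the half-voxel boundary (marching cubes on the raw
    binary grid would chamfer every voxel to an octahedron and underestimate
    enclosed volume badly for thin structures).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    k = max(int(upsample), 1)
    fine = mask
    for ax in range(3):
        fine = np.repeat(fine, k, axis=ax)
    spacing_f = np.asarray(geometry.spacing, dtype=float) / k
    padded = np.pad(fine.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing_f))
    # undo the one-fine-voxel pad and re-centre the fine grid on voxel centres
    verts_index_mm = verts - spacing_f * (1.0 + (k - 1) / 2.0)
    world = verts_index_mm @ geometry.direction.T + np.asarray(geometry.origin)
    return SurfaceMesh(world, faces, name=name)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in mm^3 via the divergence theorem (signed tetrahedra)."""
    v = mesh.vertices
    t = mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))


def write_stl(mesh: SurfaceMesh, path, dialect: str = "binary") -> None:
    """Write an STL file (binary default, ASCII option).

    Degenerate zero-area triangles are dropped with a warning.
    """
    v, t = mesh.vertices, mesh.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    n = np.cross(b - a, c - a)
    norms = np.linalg.norm(n, axis=1)
    keep = norms > 1e-12
    if not np.all(keep):
        warnings.warn(f"{mesh.name or 'mesh'}: dropped {int((~keep).sum())} degenerate triangle(s)")
    a, b, c, n, norms = a[keep], b[keep], c[keep], n[keep], norms[keep]
    n = n / norms[:, None]
    path = Path(path)
    if dialect == "binary":
        header = (f"phantomforge {mesh.name}".encode("ascii", "replace"))[:80].ljust(80, b"\x00")
        count = struct.pack("<I", len(a))
        tri = np.empty((len(a), 12), dtype="<f4")
        tri[:, 0:3], tri[:, 3:6], tri[:, 6:9], tri[:, 9:12] = n, a, b, c
        rec = np.zeros(len(a), dtype=[("data", "<f4", 12), ("attr", "<u2")])
        rec["data"] = tri
        path.write_bytes(header + count + rec.tobytes())
    elif dialect == "ascii":
        lines = [f"solid {mesh.name}"]
        for ni, ai, bi, ci in zip(n, a, b, c):
            lines.append(f"  facet normal {ni[0]:.9e} {ni[1]:.9e} {ni[2]:.9e}")
            lines.append("    outer loop")
            for p in (ai, bi, ci):
                lines.append(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.name}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ConfigError(f"unknown STL dialect {dialect!r}")


def read_stl(path) -> SurfaceMesh:
    """Read binary or ASCII STL back into a (vertex-welded) mesh."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:5] == b"solid" and b"facet" in raw[:500]:
        tris = []
        for line in raw.decode("ascii").splitlines():
            line = line.strip()
            if line.startswith("vertex"):
                tris.append([float(x) for x in line.split()[1:4]])
        pts = np.asarray(tris, dtype=np.float64).reshape(-1, 3, 3)
        name = raw.decode("ascii").splitlines()[0][len("solid"):].strip()
    else:
        (count,) = struct.unpack_from("<I", raw, 80)
        rec = np.frombuffer(raw, dtype=[("data", "<f4", 12), ("attr", "<u2")], count=count, offset=84)
        pts = rec["data"][:, 3:12].astype(np.float64).reshape(-1, 3, 3)
        name = raw[:80].rstrip(b"\x00").decode("ascii", "replace")
    flat = pts.reshape(-1, 3)
    verts, inverse = np.unique(flat.round(decimals=6), axis=0, return_inverse=True)
    return SurfaceMesh(verts, inverse.reshape(-1, 3), name=name)


def export_print_plan(plan: InfillPlan, meshes: list[SurfaceMesh], out_dir,
                      dialect: str = "binary") -> Path:
    """One STL per compartment plus a JSON manifest binding files to infills."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = {m.name for m in meshes}
    missing = names.symmetric_difference(plan.entries)
    if missing:
        raise ConfigError(f"plan/mesh name mismatch: {sorted(missing)}")
    manifest = {"material": plan.material, "scaffold_floor": plan.scaffold_floor,
                "step": plan.step, "entries": {}}
    for mesh in meshes:
        fname = f"{mesh.name}.stl"
        write_stl(mesh, out_dir / fname, dialect=dialect)
        entry = dict(plan.entries[mesh.name])
        entry["file"] = fname
        manifest["entries"][mesh.name] = entry
    (out_dir / "print_plan.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "print_plan.json"


def load_print_plan(manifest_path) -> InfillPlan:
    d = json.loads(Path(manifest_path).read_text())
    entries = {
        name: {k: v for k, v in e.items() if k != "file"} for name, e in d["entries"].items()
    }
    return InfillPlan(entries, d["scaffold_floor"], d["step"], d.get("material", "PLA"))
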