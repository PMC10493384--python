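"""Digital chest phantoms and virtual phantom acquisitions with known truth.

The generator emulates the study's source data: a contrast-enhanced chest CT
with eight tissue compartments — air lung, lung interstitium, fat, muscle,
vascular tree, bone, and a ~6.2 cm paramediastinal lung lesion split into
vascularized (inferior-medial border) and non-vascularized sub-regions.
Geometry is parametric-analytic (ellipsoids, cylinders, arcs) so the
ground-truth masks are exact; per-compartment HU are Gaussian with
means/SDs taken from the study's published compartment statistics
(``hu_preset``).  A "virtual phantom acquisition" applies an infill→HU
transfer, voxel noise and a known rigid misalignment, closing the loop for
segmentation, registration and reproducibility tests without any external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .compartments import CompartmentScheme
from .errors import ConfigError, SpecError
from .fabrication import CalibrationCurve, InfillPlan
from .registration import RigidTransform, apply_transform
from .volumes import AcquisitionMeta, CTVolume, MaskSet

__all__ = [
    "PATIENT_HU",
    "PHANTOM_HU",
    "hu_preset",
    "DigitalChestSpec",
    "VirtualScanConfig",
    "make_digital_chest",
    "simulate_phantom_scan",
    "make_cube_phantom",
    "reference_calibration_curve",
    "transfer_from_plan",
    "sample_compartment",
]

# Published per-compartment HU statistics (mean, SD): the patient scan and the
# printed phantom re-acquired on two scanners at three tube voltages.
PATIENT_HU: dict[str, tuple[float, float]] = {
    "fat": (-82.02, 28.87),
    "interstitium": (-518.86, 191.52),
    "lesion_v": (84.4, 28.55),
    "lesion_nv": (-36.27, 142.68),
    "muscle": (29.54, 26.34),
    "bone": (470.78, 199.89),
    "lungs": (-868.57, 44.76),
    "vascular": (138.72, 42.75),
}

PHANTOM_HU: dict[tuple[str, int], dict[str, tuple[float, float]]] = {
    ("SIEMENS", 80): {
        "fat": (-658.75, 56.72), "interstitium": (-727.52, 67.85),
        "lesion_v": (-361.11, 58.63), "lesion_nv": (-506.53, 55.44),
        "muscle": (-474.81, 80.13), "bone": (-147.23, 96.69),
        "lungs": (-932.64, 63.12), "vascular": (-304.1, 47.22),
    },
    ("SIEMENS", 100): {
        "fat": (-657.77, 55.87), "interstitium": (-726.23, 67.48),
        "lesion_v": (-359.87, 59.15), "lesion_nv": (-508.97, 55.31),
        "muscle": (-471.14, 80.55), "bone": (-136.81, 101.34),
        "lungs": (-933.78, 64.03), "vascular": (-298.12, 45.99),
    },
    ("SIEMENS", 120): {
        "fat": (-656.75, 55.46), "interstitium": (-724.37, 66.69),
        "lesion_v": (-356.65, 56.12), "lesion_nv": (-503.22, 52.05),
        "muscle": (-469.16, 79.16), "bone": (-132.16, 103.66),
        "lungs": (-933.17, 63.89), "vascular": (-294.87, 43.93),
    },
    ("GE", 80): {
        "fat": (-643.17, 113.21), "interstitium": (-725.37, 75.17),
        "lesion_v": (-358.18, 63.01), "lesion_nv": (-505.96, 73.14),
        "muscle": (-473.61, 96.74), "bone": (-184.17, 145.21),
        "lungs": (-919.68, 58.57), "vascular": (-308.82, 68.49),
    },
    ("GE", 100): {
        "fat": (-642.79, 106.38), "interstitium": (-719.7, 75.4),
        "lesion_v": (-355.08, 60.24), "lesion_nv": (-502.99, 69.43),
        "muscle": (-469.0, 94.9), "bone": (-176.17, 145.63),
        "lungs": (-919.71, 60.31), "vascular": (-302.6, 64.75),
    },
    ("GE", 120): {
        "fat": (-643.41, 101.0), "interstitium": (-718.37, 75.83),
        "lesion_v": (-353.47, 61.05), "lesion_nv": (-503.26, 71.31),
        "muscle": (-468.31, 94.9), "bone": (-172.53, 147.35),
        "lungs": (-921.15, 61.11), "vascular": (-299.42, 65.08),
    },
}

# scan-field air and (optional) skin are not tabulated in the study;
# values chosen once as CT-typical (see docs/methods.md)
_EXTRA_HU = {"background": (-1000.0, 10.0), "skin": (-5.0, 20.0)}


def hu_preset(label: str, scanner: str = "SIEMENS", kvp: int = 80) -> dict[str, tuple[float, float]]:
    """Return a per-compartment (mean HU, SD HU) model.

    ``"patient"`` — the source scan's statistics; ``"phantom"`` — the printed
    phantom's statistics for (scanner, kvp); a combined string like
    ``"phantom-SIEMENS-80kVp"`` also works.
    """
    if label.lower().startswith("phantom-"):
        _, scanner, kv = label.split("-")
        kvp = int(kv.lower().removesuffix("kvp"))
        label = "phantom"
    if label == "patient":
        model = dict(PATIENT_HU)
    elif label == "phantom":
        key = (scanner.upper(), int(kvp))
        if key not in PHANTOM_HU:
            raise ConfigError(f"no phantom preset for {key}")
        model = dict(PHANTOM_HU[key])
    else:
        raise ConfigError(f"unknown preset {label!r}")
    model.update(_EXTRA_HU)
    return model


def reference_calibration_curve() -> CalibrationCurve:
    """Infill↔HU relation implied by the study's printed infill plan.

    Piecewise-linear through the (infill %, patient mean HU) pairs of the
    printed plan — interstitium 35 %, fat 40 %, NV-lesion 50 %, muscle 55 %,
    V-lesion 62.5 %, vascular 70 % — anchored at air (0 %, −1000 HU) and bone
    (100 %, patient bone mean).  The patient HU ordering happens to be
    monotone in the printed infills, so this curve exists; it serves as the
    synthetic "true" printer response.
    """
    pairs = [
        (0.0, -1000.0),
        (35.0, PATIENT_HU["interstitium"][0]),
        (40.0, PATIENT_HU["fat"][0]),
        (50.0, PATIENT_HU["lesion_nv"][0]),
        (55.0, PATIENT_HU["muscle"][0]),
        (62.5, PATIENT_HU["lesion_v"][0]),
        (70.0, PATIENT_HU["vascular"][0]),
        (100.0, PATIENT_HU["bone"][0]),
    ]
    x, y = zip(*pairs)
    return CalibrationCurve(np.asarray(x), np.asarray(y))


def transfer_from_plan(curve: CalibrationCurve, plan: InfillPlan) -> dict[str, float]:
    """Per-compartment expected phantom HU implied by a print plan and a
    (true) printer response curve."""
    return {name: float(curve.forward(e["infill"])) for name, e in plan.entries.items()}


# ---------------------------------------------------------------------------
# Digital chest
# ---------------------------------------------------------------------------

@dataclass
class DigitalChestSpec:
    """Parametric chest: body cylinder, two lung ellipsoids, spine/sternum/rib
    bone, a small vascular tree and one spherical lesion (V/NV split by a
    plane facing the inferior-medial border).

    Geometry is expressed as fractions of the field of view except the lesion
    diameter (mm, default 62: the source lesion's maximum axial diameter).
    ``noise_sd`` of None uses the per-compartment preset SDs; a scalar
    overrides every compartment (0 gives a piecewise-constant volume).
    """

    shape: tuple[int, int, int] = (128, 128, 80)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    hu_model: dict[str, tuple[float, float]] | None = None  # None -> patient preset
    noise_sd: float | None = None
    lesion_diameter_mm: float = 62.0
    lesion_offset_frac: tuple[float, float, float] = (0.18, 0.0, -0.36)  # of lung semi-axes
    v_fraction: float = 0.4
    include_skin: bool = False
    truncate_to: CompartmentScheme | None = None  # strict mode: clip HU into scheme ranges
    seed: int = 0

    # body / lung / bone / vessel geometry (fractions of the extent)
    body_semi_frac: tuple[float, float] = (0.417, 0.326)
    fat_inner_frac: float = 0.88
    skin_inner_frac: float = 0.96
    lung_center_frac: tuple[float, float, float] = (0.208, 0.474, 0.5)  # |x offset|, y, z
    lung_semi_frac: tuple[float, float, float] = (0.146, 0.219, 0.367)
    air_core_frac: float = 0.82
    spine_yr: tuple[float, float] = (0.74, 0.036)
    sternum_yr: tuple[float, float] = (0.219, 0.021)
    rib_band: tuple[float, float] = (0.80, 0.86)
    vessel_radius_frac: float = 0.0208
    branch_radius_frac: float = 0.0091


def _coords(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def make_digital_chest(spec: DigitalChestSpec | None = None) -> tuple[CTVolume, MaskSet]:
    """Build the digital chest: HU volume plus exact ground-truth masks.

    Deterministic per ``spec.seed``; masks are pairwise disjoint by
    construction (a single label painting, later tissues overwrite earlier).
    """
    spec = spec or DigitalChestSpec()
    ex, ey, ez = (n * s for n, s in zip(spec.shape, spec.spacing))
    X, Y, Z = _coords(spec.shape, spec.spacing)
    cx, cy = ex / 2, ey / 2
    a, b = spec.body_semi_frac[0] * ex, spec.body_semi_frac[1] * ey

    r_body = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2)
    body = r_body <= 1.0

    names = ["lungs", "interstitium", "fat", "muscle", "vascular", "bone",
             "lesion_nv", "lesion_v"] + (["skin"] if spec.include_skin else [])
    code = {n: i + 1 for i, n in enumerate(names)}
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[body] = code["muscle"]
    labels[(r_body > spec.fat_inner_frac) & body] = code["fat"]
    if spec.include_skin:
        labels[(r_body > spec.skin_inner_frac) & body] = code["skin"]

    # lungs
    lx, ly, lz = spec.lung_center_frac
    sa, sb, sc = (spec.lung_semi_frac[0] * ex, spec.lung_semi_frac[1] * ey,
                  spec.lung_semi_frac[2] * ez)
    lung_centers = [(cx - lx * ex, ly * ey, lz * ez), (cx + lx * ex, ly * ey, lz * ez)]
    for lcx, lcy, lcz in lung_centers:
        r_lung = np.sqrt(((X - lcx) / sa) ** 2 + ((Y - lcy) / sb) ** 2 + ((Z - lcz) / sc) ** 2)
        labels[r_lung <= 1.0] = code["interstitium"]
        labels[r_lung <= spec.air_core_frac] = code["lungs"]

    # bone: spine + sternum columns, rib arcs (thin shell slabs, lateral/posterior)
    sy, sr = spec.spine_yr[0] * ey, spec.spine_yr[1] * ex
    labels[(np.sqrt((X - cx) ** 2 + (Y - sy) ** 2) <= sr) & body] = code["bone"]
    ty, tr = spec.sternum_yr[0] * ey, spec.sternum_yr[1] * ex
    labels[(np.sqrt((X - cx) ** 2 + (Y - ty) ** 2) <= tr) & body] = code["bone"]
    kk = np.arange(spec.shape[2])[None, None, :]
    rib_slab = (kk % 8) < 2
    ribs = (r_body > spec.rib_band[0]) & (r_body <= spec.rib_band[1]) \
        & (Y > cy - 0.05 * ey) & np.broadcast_to(rib_slab, spec.shape)
    labels[ribs & body] = code["bone"]

    # vascular tree: mediastinal trunk + two branch pairs into the lungs
    vr = spec.vessel_radius_frac * ex
    trunk = (np.sqrt((X - cx) ** 2 + (Y - 0.417 * ey) ** 2) <= vr) \
        & (Z >= 0.25 * ez) & (Z <= 0.79 * ez)
    labels[trunk & body] = code["vascular"]
    br = spec.branch_radius_frac * ex
    for yb, zb in ((0.443 * ey, 0.625 * ez), (0.474 * ey, 0.54 * ez)):
        branch = (np.sqrt((Y - yb) ** 2 + (Z - zb) ** 2) <= br) \
            & (np.abs(X - cx) <= 0.286 * ex)
        labels[branch & body] = code["vascular"]

    # lesion in the left lung, inferior-medial, V sub-region toward the
    # inferior-medial border
    lcx, lcy, lcz = lung_centers[0]
    off = spec.lesion_offset_frac
    lesion_c = np.array([lcx + off[0] * sa, lcy + off[1] * sb, lcz + off[2] * sc])
    radius = spec.lesion_diameter_mm / 2.0
    d2 = (X - lesion_c[0]) ** 2 + (Y - lesion_c[1]) ** 2 + (Z - lesion_c[2]) ** 2
    lesion = d2 <= radius ** 2
    if not lesion.any():
        raise SpecError("lesion does not cover any voxel")
    r_lung_left = np.sqrt(((X - lcx) / sa) ** 2 + ((Y - lcy) / sb) ** 2
                          + ((Z - lcz) / sc) ** 2)
    inside = (r_lung_left[lesion] <= 1.0).mean()
    if inside < 0.95:
        raise SpecError(
            f"lesion lies outside the lung ({inside:.0%} of its voxels inside)"
        )
    # split plane normal toward the medial(-x toward mediastinum: +x here)-inferior border
    n_vec = np.array([1.0, 0.0, -1.0]) / np.sqrt(2.0)
    proj = ((X - lesion_c[0]) * n_vec[0] + (Z - lesion_c[2]) * n_vec[2])[lesion]
    thr = np.quantile(proj, 1.0 - spec.v_fraction)
    proj_full = (X - lesion_c[0]) * n_vec[0] + (Z - lesion_c[2]) * n_vec[2]
    labels[lesion] = code["lesion_nv"]
    labels[lesion & (proj_full >= thr)] = code["lesion_v"]

    # HU synthesis
    model = dict(spec.hu_model or hu_preset("patient"))
    for extra, val in _EXTRA_HU.items():
        model.setdefault(extra, val)
    rng = np.random.default_rng(spec.seed)
    bg_mean, bg_sd = model["background"]
    sd_of = (lambda s: s) if spec.noise_sd is None else (lambda s: float(spec.noise_sd))
    bg_sd = sd_of(bg_sd)
    vox = (rng.normal(bg_mean, bg_sd, spec.shape) if bg_sd > 0
           else np.full(spec.shape, float(bg_mean)))
    for name in names:
        m = labels == code[name]
        if name not in model:
            raise ConfigError(f"hu_model lacks compartment {name!r}")
        mean, sd = model[name]
        sd = sd_of(sd)
        vals = rng.normal(mean, sd, int(m.sum())) if sd > 0 else np.full(int(m.sum()), mean)
        if spec.truncate_to is not None and name in spec.truncate_to.names:
            lo, hi = spec.truncate_to[name].range.as_tuple()
            vals = np.clip(vals, lo, hi)
        vox[m] = vals

    volume = CTVolume(
        vox, spec.spacing, meta=AcquisitionMeta(kvp=80, mas=50, scanner="SIEMENS")
    )
    masks = {n: labels == code[n] for n in names}
    return volume, MaskSet.from_volume(volume, masks)


# ---------------------------------------------------------------------------
# Virtual phantom acquisition
# ---------------------------------------------------------------------------

@dataclass
class VirtualScanConfig:
    """How the printed phantom appears on a (virtual) CT scanner.

    transfer : per-compartment expected HU of the printed material (build it
        from an infill plan with :func:`transfer_from_plan`).
    noise_sd : scalar or per-compartment HU noise (default 20 HU, a typical
        chest-CT quantum-noise magnitude).
    misalignment : rigid pose of the phantom on the scanner bed relative to
        the source CT frame (None = perfectly aligned).
    """

    transfer: dict[str, float]
    noise_sd: float | dict[str, float] = 20.0
    misalignment: RigidTransform | None = None
    meta: AcquisitionMeta = field(default_factory=lambda: AcquisitionMeta(kvp=80, mas=50, scanner="SIEMENS"))
    seed: int = 0

    def sd_for(self, name: str) -> float:
        if isinstance(self.noise_sd, dict):
            if name not in self.noise_sd:
                raise ConfigError(f"noise_sd lacks compartment {name!r}")
            return float(self.noise_sd[name])
        return float(self.noise_sd)


def simulate_phantom_scan(truth: MaskSet, config: VirtualScanConfig) -> CTVolume:
    """Virtual CT of the printed phantom.

    Each compartment's voxels are drawn ``Gaussian(transfer[name], noise_sd)``
    on a −1024 HU background, then the volume is resampled under the known
    rigid misalignment.  Deterministic per ``config.seed``.  Values are NOT
    clipped at the CT floor, preserving the Gaussian model exactly.
    """
    if not truth.pairwise_disjoint():
        raise ConfigError("truth masks must be pairwise disjoint")
    missing = [n for n in truth.names if n not in config.transfer]
    if missing:
        raise ConfigError(f"transfer lacks compartments: {missing}")
    rng = np.random.default_rng(config.seed)
    vox = np.full(truth.shape, -1024.0)
    for name in truth.names:
        m = truth.masks[name]
        sd = config.sd_for(name)
        mean = float(config.transfer[name])
        vox[m] = rng.normal(mean, sd, int(m.sum())) if sd > 0 else mean
    volume = CTVolume(vox, truth.spacing, truth.origin, truth.direction.copy(), config.meta)
    if config.misalignment is not None:
        volume = apply_transform(volume, config.misalignment, volume, "linear")
    return volume


# ---------------------------------------------------------------------------
# Calibration-cube phantom
# ---------------------------------------------------------------------------

def make_cube_phantom(
    infills,
    curve_true: CalibrationCurve | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    cube_side_mm: float = 20.0,
    gap_mm: float = 10.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[CTVolume, dict]:
    """Row of 2-cm PLA cubes at the given infill percentages.

    Cube HU is Gaussian(curve_true(infill), noise_sd) on a −1000 HU air
    background; the layout records each cube's world-mm centre.
    """
    infills = [float(f) for f in infills]
    if any(not 0 <= f <= 100 for f in infills):
        raise ConfigError("infills must lie in [0, 100]")
    curve_true = curve_true or reference_calibration_curve()
    side_vox = np.round(cube_side_mm / np.asarray(spacing)).astype(int)
    pitch = cube_side_mm + gap_mm
    nx = int(np.ceil((len(infills) * pitch + gap_mm) / spacing[0]))
    ny = int(np.ceil((cube_side_mm + 2 * gap_mm) / spacing[1]))
    nz = int(np.ceil((cube_side_mm + 2 * gap_mm) / spacing[2]))
    rng = np.random.default_rng(seed)
    vox = np.full((nx, ny, nz), -1000.0)
    centers = []
    cy, cz = ny * spacing[1] / 2, nz * spacing[2] / 2
    for i, infill in enumerate(infills):
        cx = gap_mm + cube_side_mm / 2 + i * pitch
        lo = np.round(
            (np.array([cx, cy, cz]) - cube_side_mm / 2) / np.asarray(spacing)
        ).astype(int)
        hi = lo + side_vox
        if np.any(lo < 0) or np.any(hi > (nx, ny, nz)):
            raise SpecError(f"cube {i} does not fit in the volume")
        block = vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        mean = float(curve_true.forward(infill))
        block[:] = rng.normal(mean, noise_sd, block.shape) if noise_sd > 0 else mean
        centers.append([cx, cy, cz])
    layout = {"infills": infills, "centers_mm": centers, "cube_side_mm": cube_side_mm}
    volume = CTVolume(vox, spacing, meta=AcquisitionMeta(kvp=80, mas=50, scanner="SIEMENS"))
    return volume, layout


def sample_compartment(
    name: str, mean: float, sd: float, n_voxels: int = 100_000, seed: int = 0
) -> tuple[CTVolume, np.ndarray]:
    """A block volume whose first *n_voxels* voxels form one compartment drawn
    from Gaussian(mean, sd); returns (virtual scan, compartment mask).

    Runs through :func:`simulate_phantom_scan` so the sampling path is the
    same one the full pipeline uses.
    """
    side = 50
    nz = int(np.ceil(n_voxels / side**2))
    shape = (side, side, nz)
    flat = np.zeros(side * side * nz, dtype=bool)
    flat[:n_voxels] = True
    mask = flat.reshape(shape)
    geom = CTVolume(np.zeros(shape), (1.0, 1.0, 1.0))
    truth = MaskSet.from_volume(geom, {name: mask})
    cfg = VirtualScanConfig(transfer={name: mean}, noise_sd={name: sd}, seed=seed)
    return simulate_phantom_scan(truth, cfg), mask
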