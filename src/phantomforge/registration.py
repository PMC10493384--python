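"""Rigid co-registration with a localized mutual-information metric.

The phantom re-acquisition is aligned to the source CT by a rigid transform
(3 Euler angles + translation about a fixed rotation centre).  The
similarity metric is mutual information estimated, at every iteration, from
intensity samples drawn inside one random cubic subregion of the fixed
image; optimization is standard gradient descent with a decaying step
``a_k = a / (k + A)**alpha`` over a four-level Gaussian pyramid (smoothing
without downsampling).  Everything is implemented on top of
``scipy.ndimage``; no external registration binaries are involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, RegistrationError
from .volumes import CTVolume, MaskSet

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "RegistrationResult",
    "local_mutual_information",
    "register_rigid",
    "apply_transform",
    "transform_delta",
]

_CLAMP = (-1024.0, 2400.0)


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """R = Rz @ Ry @ Rx."""
    ca, sa = np.cos(rx), np.sin(rx)
    cb, sb = np.cos(ry), np.sin(ry)
    cc, sc = np.cos(rz), np.sin(rz)
    return np.array(
        [
            [cb * cc, cc * sa * sb - ca * sc, sc * sa + ca * cc * sb],
            [cb * sc, ca * cc + sa * sb * sc, ca * sb * sc - cc * sa],
            [-sb, cb * sa, ca * cb],
        ]
    )


def _euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    ry = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
    rx = np.arctan2(R[2, 1], R[2, 2])
    rz = np.arctan2(R[1, 0], R[0, 0])
    return float(rx), float(ry), float(rz)


@dataclass
class RigidTransform:
    """World-mm rigid map ``y = R (x - c) + c + t``."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Euler rad, R = Rz Ry Rx
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.rotation = tuple(float(r) for r in self.rotation)
        self.translation = tuple(float(t) for t in self.translation)
        self.center = tuple(float(c) for c in self.center)

    @property
    def matrix(self) -> np.ndarray:
        return _euler_matrix(*self.rotation)

    def apply(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        return (pts - c) @ self.matrix.T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        t_inv = -(R.T @ np.asarray(self.translation))
        return RigidTransform(_euler_from_matrix(R.T), tuple(t_inv), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to ``x -> self(other(x))``, centred at self.center."""
        Rs, Ro = self.matrix, other.matrix
        cs, co = np.asarray(self.center), np.asarray(other.center)
        ts, to = np.asarray(self.translation), np.asarray(other.translation)
        R = Rs @ Ro
        t = Rs @ (Ro @ (cs - co) + co + to - cs) + ts
        return RigidTransform(_euler_from_matrix(R), tuple(t), tuple(cs))

    def to_dict(self) -> dict:
        return {
            "rotation_rad": list(self.rotation),
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
            "convention": "euler ZYX, y = R(x-c)+c+t, world mm",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rotation_rad"]), tuple(d["translation_mm"]), tuple(d["center_mm"]))


def transform_delta(a: RigidTransform, b: RigidTransform) -> tuple[float, float]:
    """(rotation deg, translation mm at the rotation centre) between two transforms.

    Measured on the composition ``a ∘ b⁻¹``: 0 when the two agree.
    """
    comp = a.compose(b.inverse())
    tr = np.trace(comp.matrix)
    angle = float(np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))))
    c = np.asarray(a.center)
    shift = float(np.linalg.norm(comp.apply(c)[0] - c))
    return angle, shift


# ---------------------------------------------------------------------------
# Metric
# ---------------------------------------------------------------------------

def _interp(arr: np.ndarray, idx: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(
        arr.astype(np.float64, copy=False), idx.T, order=order, mode="constant", cval=np.nan
    )


def _mi_from_pairs(f: np.ndarray, m: np.ndarray, bins: int,
                   f_edges=None, m_edges=None) -> float:
    """Mutual information (nats) of paired samples, histogram estimator."""
    f = np.clip(f, *_CLAMP)
    m = np.clip(m, *_CLAMP)
    if f_edges is None:
        f_edges = np.linspace(f.min(), f.max() + 1e-6, bins + 1)
    if m_edges is None:
        m_edges = np.linspace(m.min(), m.max() + 1e-6, bins + 1)
    joint, _, _ = np.histogram2d(f, m, bins=[f_edges, m_edges])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def local_mutual_information(
    fixed: CTVolume,
    moving: CTVolume,
    transform: RigidTransform,
    subregion_center,
    subregion_edge: float,
    bins: int = 32,
    rng: np.random.Generator | None = None,
    samples: int = 3000,
) -> float:
    """Negated MI estimated inside one cubic subregion of the fixed domain.

    Sample points are drawn uniformly in the cube (world mm), the fixed and
    transformed-moving intensities interpolated trilinearly, and MI computed
    from their joint histogram.  Returned negated (minimization convention).
    A subregion with fewer than two distinct fixed intensities is degenerate:
    the metric is 0 with a warning.
    """
    if bins < 8:
        raise ConfigError("bins must be >= 8")
    rng = rng or np.random.default_rng()
    center = np.asarray(subregion_center, dtype=float)
    pts = center + rng.uniform(-subregion_edge / 2, subregion_edge / 2, size=(samples, 3))
    fvals = _interp(fixed.voxels, fixed.world_to_index(pts))
    mvals = _interp(moving.voxels, moving.world_to_index(transform.apply(pts)))
    ok = ~(np.isnan(fvals) | np.isnan(mvals))
    if ok.sum() < 2 or np.ptp(np.clip(fvals[ok], *_CLAMP)) < 1e-9:
        warnings.warn("degenerate metric subregion (<2 distinct fixed intensities)")
        return 0.0
    return -_mi_from_pairs(fvals[ok], mvals[ok], bins)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    levels: int = 4
    smoothing_sigmas: tuple = (8.0, 4.0, 2.0, 0.0)  # mm, coarse -> fine
    downsample: bool = False  # Gaussian pyramid without downsampling
    metric: str = "local_mi"  # or "mi" (whole-domain sampling)
    subregion_edge: float = 40.0  # mm
    samples_per_iter: int = 3000
    iters_per_level: int = 100
    step_size: float = 0.6  # finest-level gradient-descent gain a (mm)
    step_A: float = 10.0
    step_alpha: float = 0.602
    bins: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if len(self.smoothing_sigmas) != self.levels:
            raise ConfigError("smoothing_sigmas must have one sigma per level")
        if self.downsample:
            raise ConfigError("downsampling pyramid not supported (smoothing only)")
        if self.metric not in ("local_mi", "mi"):
            raise ConfigError(f"unknown metric {self.metric!r}")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    metric_trace: list = field(default_factory=list)
    converged: bool = False
    level_means: list = field(default_factory=list)


def _world_bbox(volume: CTVolume) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(volume.shape) - 1
    corners = np.array(
        [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])], dtype=float
    )
    w = volume.index_to_world(corners)
    return w.min(axis=0), w.max(axis=0)


def register_rigid(fixed: CTVolume, moving: CTVolume, config: RegistrationConfig | None = None
                   ) -> RegistrationResult:
    """Estimate the rigid transform mapping *moving* into *fixed* space.

    The returned transform T satisfies ``resampled(x) = moving(T(x))``, i.e.
    it is the transform to hand to :func:`apply_transform` together with the
    fixed geometry.  Deterministic for a fixed ``config.seed``.
    """
    config = config or RegistrationConfig()
    rng = np.random.default_rng(config.seed)
    flo, fhi = _world_bbox(fixed)
    mlo, mhi = _world_bbox(moving)
    if np.any(fhi < mlo) or np.any(mhi < flo):
        raise RegistrationError("fixed and moving fields of view do not overlap")

    center = tuple(fixed.center_world())
    half_extent = float(np.mean((fhi - flo) / 2.0))
    scales = np.array([half_extent] * 3 + [1.0] * 3)  # rad -> mm equivalents
    q = np.zeros(6)  # scaled parameters
    delta = 0.5  # finite-difference step, scaled units (mm)

    edge = config.subregion_edge
    lo_c = flo + edge / 2.0
    hi_c = fhi - edge / 2.0
    if np.any(hi_c < lo_c):
        raise ConfigError("subregion_edge larger than the fixed field of view")

    trace: list[float] = []
    level_means: list[float] = []
    for level in range(config.levels):
        sigma_mm = config.smoothing_sigmas[level]
        if sigma_mm > 0:
            f_arr = ndimage.gaussian_filter(
                fixed.voxels.astype(np.float64), sigma_mm / np.asarray(fixed.spacing)
            )
            m_arr = ndimage.gaussian_filter(
                moving.voxels.astype(np.float64), sigma_mm / np.asarray(moving.spacing)
            )
        else:
            f_arr = fixed.voxels.astype(np.float64)
            m_arr = moving.voxels.astype(np.float64)
        a0 = config.step_size * (2 ** (config.levels - 1 - level))
        level_trace = []
        for k in range(config.iters_per_level):
            if config.metric == "local_mi":
                sub_center = rng.uniform(lo_c, hi_c)
                pts = sub_center + rng.uniform(-edge / 2, edge / 2, (config.samples_per_iter, 3))
            else:
                pts = rng.uniform(flo, fhi, (config.samples_per_iter, 3))
            fvals = _interp(f_arr, fixed.world_to_index(pts))
            fok = ~np.isnan(fvals)
            if fok.sum() < 50:
                level_trace.append(0.0)
                trace.append(0.0)
                continue
            pts, fvals = pts[fok], np.clip(fvals[fok], *_CLAMP)
            if np.ptp(fvals) < 1e-9:
                level_trace.append(0.0)
                trace.append(0.0)
                continue
            f_edges = np.linspace(fvals.min(), fvals.max() + 1e-6, config.bins + 1)

            def metric_at(q_try, m_edges=None, want_edges=False):
                params = q_try / scales
                T = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
                mvals = _interp(m_arr, moving.world_to_index(T.apply(pts)))
                ok = ~np.isnan(mvals)
                if ok.sum() < 50:
                    return (0.0, None) if want_edges else 0.0
                mv = np.clip(mvals[ok], *_CLAMP)
                if m_edges is None:
                    m_edges = np.linspace(mv.min(), mv.max() + 1e-6, config.bins + 1)
                val = -_mi_from_pairs(fvals[ok], mv, config.bins, f_edges, m_edges)
                return (val, m_edges) if want_edges else val

            f0, m_edges = metric_at(q, want_edges=True)
            if np.isnan(f0):
                raise RegistrationError(f"metric diverged (NaN) at level {level} iter {k}; trace={trace}")
            level_trace.append(f0)
            trace.append(f0)
            if m_edges is None:
                continue
            grad = np.zeros(6)
            for p in range(6):
                dq = np.zeros(6)
                dq[p] = delta
                grad[p] = (metric_at(q + dq, m_edges) - metric_at(q - dq, m_edges)) / (2 * delta)
            norm = np.linalg.norm(grad)
            if norm < 1e-12:
                continue
            a_k = a0 / (k + config.step_A) ** config.step_alpha
            q = q - a_k * grad / norm
        informative = [v for v in level_trace if v != 0.0]
        level_means.append(float(np.mean(informative)) if informative else 0.0)

    params = q / scales
    transform = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
    # convergence: within the final level the moving average of the stochastic
    # metric must not have increased (tolerance scaled to the spread of the
    # local metric across random subregions)
    informative = [v for v in level_trace if v != 0.0]
    if len(informative) >= 6:
        h = max(3, len(informative) // 4)
        tol = 0.5 * float(np.std(informative)) + 1e-6
        converged = float(np.mean(informative[-h:])) <= float(np.mean(informative[:h])) + tol
    else:
        converged = bool(informative)
    return RegistrationResult(transform, trace, converged, level_means)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def apply_transform(
    target: CTVolume | MaskSet,
    transform: RigidTransform,
    reference: CTVolume,
    interpolation: str = "linear",
) -> CTVolume | MaskSet:
    """Resample *target* onto *reference* geometry through a rigid transform.

    Output voxel at reference-world position x takes the target value at
    ``transform(x)``.  Masks must use nearest-neighbour interpolation and
    stay strictly binary; out-of-field voxels fill with -1024 (images) or 0
    (masks).
    """
    if isinstance(target, MaskSet):
        if interpolation != "nearest":
            raise ConfigError("masks must be resampled with nearest-neighbour interpolation")
        out = {}
        idx = _reference_to_target_indices(reference, transform, target)
        for name, m in target.masks.items():
            vals = ndimage.map_coordinates(
                m.astype(np.uint8), idx, order=0, mode="constant", cval=0
            )
            out[name] = vals.reshape(reference.shape).astype(bool)
        return MaskSet(reference.spacing, reference.origin, reference.direction.copy(), out)

    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ConfigError(f"unknown interpolation {interpolation!r}")
    idx = _reference_to_target_indices(reference, transform, target)
    vals = ndimage.map_coordinates(
        target.voxels.astype(np.float64), idx, order=order, mode="constant", cval=-1024.0
    )
    return CTVolume(
        vals.reshape(reference.shape),
        reference.spacing,
        reference.origin,
        reference.direction.copy(),
        target.meta,
    )


def _reference_to_target_indices(reference, transform: RigidTransform, target) -> np.ndarray:
    """Fractional target-voxel indices for every reference voxel (3, N)."""
    # affine chain: ref index -> ref world -> transform -> target world -> target index
    lin_r = reference.direction @ np.diag(reference.spacing)
    R = transform.matrix
    c = np.asarray(transform.center)
    t = np.asarray(transform.translation)
    lin_t = target.direction @ np.diag(target.spacing)
    origin_t = np.asarray(target.origin)
    inv_t = np.linalg.inv(lin_t)
    # combined linear map and offset: idx_t = M @ idx_r + b
    M = inv_t @ R @ lin_r
    b = inv_t @ (R @ (np.asarray(reference.origin) - c) + c + t - origin_t)
    shape = reference.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx_r = np.stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(np.float64)
    return M @ idx_r + b[:, None]
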