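"""Eight-compartment Hounsfield-range segmentation.

A :class:`CompartmentScheme` tiles the CT number axis with named closed
integer intervals (air lungs, lung interstitium, fat, muscle, vascular tree,
bone, and the two lesion sub-regions).  Raw masks come from plain
thresholding or seeded region growing; overlapping claims are then resolved
by priority through Boolean subtraction, so the final masks are pairwise
disjoint and, inside the body, leave no HU gap unaccounted for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError, SegmentationError
from .volumes import CTVolume, MaskSet

__all__ = [
    "HURange",
    "Compartment",
    "CompartmentScheme",
    "CoverageReport",
    "SegmentationResult",
    "builtin_scheme",
    "scheme_from_transfer",
    "validate_partition",
    "threshold_mask",
    "region_grow",
    "subtract_masks",
    "segment_compartments",
    "body_mask",
]

DOMAIN = (-1024, 2400)


@dataclass(frozen=True)
class HURange:
    """Closed integer interval of Hounsfield units [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ConfigError(f"HURange lo {self.lo} > hi {self.hi}")

    def contains(self, hu) -> np.ndarray:
        return (np.asarray(hu) >= self.lo) & (np.asarray(hu) <= self.hi)

    def intersect(self, other: "HURange"):
        lo, hi = max(self.lo, other.lo), min(self.hi, other.hi)
        return HURange(lo, hi) if lo <= hi else None

    def as_tuple(self):
        return (self.lo, self.hi)


@dataclass(frozen=True)
class Compartment:
    """One tissue class: HU range, overlap priority, extraction method, infill."""

    name: str
    range: HURange
    priority: int = 0
    method: str = "threshold"  # or "region_grow"
    seeds: tuple | None = None  # voxel indices; None -> auto-seed policy
    infill: float | None = None  # PLA infill percent assigned for printing

    def __post_init__(self):
        if self.method not in ("threshold", "region_grow"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.infill is not None and not (0 <= self.infill <= 100):
            raise ConfigError(f"infill must be in [0, 100], got {self.infill}")


@dataclass
class CompartmentScheme:
    compartments: list[Compartment]
    domain: HURange = field(default_factory=lambda: HURange(*DOMAIN))
    label: str = "custom"

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate compartment names: {names}")
        for c in self.compartments:
            if c.range.lo < self.domain.lo or c.range.hi > self.domain.hi:
                raise ConfigError(f"{c.name} range {c.range} outside domain {self.domain}")

    def __getitem__(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.compartments]

    def infill_map(self) -> dict[str, float]:
        return {c.name: c.infill for c in self.compartments if c.infill is not None}

    def with_seeds(self, seeds: dict[str, list]) -> "CompartmentScheme":
        comps = [
            replace(c, seeds=tuple(tuple(s) for s in seeds[c.name])) if c.name in seeds else c
            for c in self.compartments
        ]
        return CompartmentScheme(comps, self.domain, self.label)


# ---------------------------------------------------------------------------
# Built-in schemes: the study's printed patient and phantom HU ranges.
# ---------------------------------------------------------------------------

# priorities: lesion sub-compartments > vascular > bone > base tissues;
# air lungs > interstitium resolves their 2-HU printed boundary overlap.
_PATIENT = [
    ("lungs", -1024, -749, 30, "threshold", 10.0),
    ("interstitium", -750, -125, 20, "threshold", 35.0),
    ("fat", -124, -25, 10, "threshold", 40.0),
    ("muscle", -24, 150, 10, "threshold", 55.0),
    ("vascular", 70, 225, 60, "threshold", 70.0),
    ("bone", 226, 2400, 50, "threshold", 100.0),
    ("lesion_nv", -425, -375, 79, "region_grow", 50.0),
    ("lesion_v", 61, 374, 80, "region_grow", 62.5),
]

# Phantom (printed-object) re-segmentation ranges.  Two printed bounds are
# self-contradictory and repaired: bone "-236/-361" -> -236..domain max,
# V-lesion "586/-432" -> -586/-432.
_PHANTOM = [
    ("lungs", -1024, -809, 30, "threshold", None),
    ("interstitium", -808, -684, 20, "region_grow", None),
    ("fat", -808, -615, 10, "threshold", None),
    ("muscle", -614, -357, 10, "threshold", None),
    ("vascular", -356, -237, 60, "threshold", None),
    ("bone", -236, 2400, 50, "threshold", None),
    ("lesion_nv", -431, -237, 79, "region_grow", None),
    ("lesion_v", -586, -432, 80, "region_grow", None),
]


def builtin_scheme(label: str) -> CompartmentScheme:
    """Return the study's eight-compartment scheme, ``"patient"`` or ``"phantom"``.

    The patient scheme carries the printed per-compartment PLA infill values.
    Skin is intentionally absent: the study names it among the compartments
    but assigns it no HU range (see :func:`segment_compartments`'s optional
    morphological skin shell instead).
    """
    table = {"patient": _PATIENT, "phantom": _PHANTOM}.get(label)
    if table is None:
        raise ConfigError(f"unknown scheme label {label!r} (expected 'patient' or 'phantom')")
    comps = [
        Compartment(n, HURange(lo, hi), priority=p, method=m, infill=f)
        for n, lo, hi, p, m, f in table
    ]
    return CompartmentScheme(comps, HURange(*DOMAIN), label)


def scheme_from_transfer(
    transfer: dict[str, float],
    like: CompartmentScheme | None = None,
    domain: tuple[float, float] = DOMAIN,
) -> CompartmentScheme:
    """Build a re-segmentation scheme adapted to known compartment HU targets.

    Ranges are the Voronoi cells of the target values on the HU axis
    (boundaries at midpoints between neighbouring targets, rounded to
    integers), clipped to *domain*.  Methods and priorities are copied from
    *like* (default: the builtin patient scheme) so lesion sub-compartments
    keep their region-growing extraction and top priority.
    """
    like = like or builtin_scheme("patient")
    order = sorted(transfer, key=lambda n: transfer[n])
    lo_d, hi_d = domain
    comps = []
    for i, name in enumerate(order):
        lo = lo_d if i == 0 else int(round((transfer[order[i - 1]] + transfer[name]) / 2)) + 1
        hi = hi_d if i == len(order) - 1 else int(round((transfer[name] + transfer[order[i + 1]]) / 2))
        try:
            src = like[name]
            prio, method = src.priority, src.method
        except KeyError:
            prio, method = 0, "threshold"
        comps.append(Compartment(name, HURange(lo, hi), priority=prio, method=method))
    return CompartmentScheme(comps, HURange(lo_d, hi_d), label="adapted")


# ---------------------------------------------------------------------------
# Coverage analysis
# ---------------------------------------------------------------------------

@dataclass
class CoverageReport:
    gaps: list[tuple[float, float]] = field(default_factory=list)
    overlaps: list[tuple[str, str, float, float]] = field(default_factory=list)
    out_of_domain_voxels: int = 0
    exterior_voxels: int = 0
    unassigned_voxels: int = 0
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gaps": [list(g) for g in self.gaps],
            "overlaps": [list(o) for o in self.overlaps],
            "out_of_domain_voxels": self.out_of_domain_voxels,
            "exterior_voxels": self.exterior_voxels,
            "unassigned_voxels": self.unassigned_voxels,
            "notes": self.notes,
        }


def validate_partition(scheme: CompartmentScheme) -> CoverageReport:
    """List every maximal HU interval covered by zero (gap) or >= 2 compartments.

    Exact on the integer HU grid of the scheme's domain (ranges are closed
    integer intervals as printed in the source segmentation protocol).
    """
    lo, hi = int(scheme.domain.lo), int(scheme.domain.hi)
    grid = np.arange(lo, hi + 1)
    count = np.zeros(grid.size, dtype=int)
    for c in scheme.compartments:
        count[c.range.contains(grid)] += 1
    report = CoverageReport()
    for start, end in _runs(count == 0):
        report.gaps.append((float(grid[start]), float(grid[end])))
    for a_i in range(len(scheme.compartments)):
        for b_i in range(a_i + 1, len(scheme.compartments)):
            a, b = scheme.compartments[a_i], scheme.compartments[b_i]
            inter = a.range.intersect(b.range)
            if inter is not None:
                report.overlaps.append((a.name, b.name, inter.lo, inter.hi))
    return report


def _runs(flags: np.ndarray):
    """Yield (start, end) index pairs of maximal True runs."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    yield from zip(starts, ends)


# ---------------------------------------------------------------------------
# Mask construction primitives
# ---------------------------------------------------------------------------

def threshold_mask(volume: CTVolume, hu_range: HURange) -> np.ndarray:
    """Binary mask of voxels with lo <= HU <= hi (closed interval)."""
    return hu_range.contains(volume.voxels)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def region_grow(
    volume: CTVolume, hu_range: HURange, seeds, connectivity: int = 26
) -> np.ndarray:
    """Flood-fill from *seeds* through voxels whose HU lies in *hu_range*.

    Every seed must itself be in range (precondition).  Growth is clipped at
    the volume border; no wraparound.
    """
    if connectivity not in _STRUCTS:
        raise ConfigError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    in_range = hu_range.contains(volume.voxels)
    seeds = [tuple(int(i) for i in s) for s in seeds]
    if not seeds:
        raise SegmentationError("region_grow requires at least one seed")
    for s in seeds:
        if not in_range[s]:
            raise SegmentationError(
                f"seed {s} has HU {volume.voxels[s]:.1f} outside range {hu_range.as_tuple()}"
            )
    labels, _ = ndimage.label(in_range, structure=_STRUCTS[connectivity])
    keep = {labels[s] for s in seeds}
    return np.isin(labels, sorted(keep))


def subtract_masks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Boolean subtraction a AND NOT b."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise GeometryError(f"mask shape mismatch {a.shape} vs {b.shape}")
    return a.astype(bool) & ~b.astype(bool)


def body_mask(volume: CTVolume, threshold: float = -900.0) -> np.ndarray:
    """Patient/phantom support: largest connected component above *threshold*,
    interior cavities filled.  Excludes the air of the scan field."""
    fg = volume.voxels > threshold
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros(volume.shape, dtype=bool)
    largest = np.argmax(ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    return ndimage.binary_fill_holes(labels == largest)


def _auto_seed(in_range: np.ndarray, connectivity: int = 26):
    """Deterministic seed policy: a voxel of the largest in-range connected
    component (the component voxel nearest its centroid)."""
    labels, n = ndimage.label(in_range, structure=_STRUCTS[connectivity])
    if n == 0:
        return None
    largest = np.argmax(
        ndimage.sum_labels(in_range, labels, index=np.arange(1, n + 1))
    ) + 1
    coords = np.argwhere(labels == largest)
    centroid = coords.mean(axis=0)
    return tuple(coords[np.argmin(((coords - centroid) ** 2).sum(axis=1))])


@dataclass
class SegmentationResult:
    maskset: MaskSet          # post-subtraction, pairwise disjoint
    raw_maskset: MaskSet      # pre-subtraction, may overlap
    coverage_report: CoverageReport

    def __post_init__(self):
        assert self.maskset.pairwise_disjoint(), "post-subtraction masks must be disjoint"


def segment_compartments(
    volume: CTVolume,
    scheme: CompartmentScheme,
    body: np.ndarray | str | None = "auto",
    connectivity: int = 26,
    skin_shell_voxels: int = 0,
) -> SegmentationResult:
    """Partition *volume* into the scheme's compartments.

    Raw masks are built per compartment (threshold or seeded region growing,
    auto-seeding from the largest in-range component when no seeds are
    given); overlaps are then resolved by priority via Boolean subtraction,
    the lower-priority compartment losing contested voxels.  Priority ties
    are broken by scheme order (earlier wins).

    ``body`` restricts segmentation to the patient/phantom support:
    ``"auto"`` derives it with :func:`body_mask`, ``None`` disables the
    restriction, or pass an explicit boolean array.  ``skin_shell_voxels > 0``
    adds a morphological ``skin`` compartment (outer shell of the body mask),
    which has no HU range of its own.
    """
    report = validate_partition(scheme)
    if isinstance(body, str):
        if body != "auto":
            raise ConfigError(f"body must be 'auto', None or an array, got {body!r}")
        body = body_mask(volume)
    if body is not None and body.shape != volume.shape:
        raise GeometryError("body mask shape mismatch")

    raw: dict[str, np.ndarray] = {}
    for comp in scheme.compartments:
        in_range = threshold_mask(volume, comp.range)
        if body is not None:
            in_range &= body
        if comp.method == "threshold":
            raw[comp.name] = in_range
            continue
        seeds = [tuple(int(i) for i in s) for s in (comp.seeds or [])]
        usable = [s for s in seeds if in_range[s]]
        if seeds and not usable:
            report.notes.append(
                f"{comp.name}: all explicit seeds out of range; falling back to auto-seed"
            )
        if not usable:
            auto = _auto_seed(in_range, connectivity)
            if auto is None:
                report.notes.append(
                    f"{comp.name}: no in-range voxel to auto-seed from; mask left empty"
                )
                raw[comp.name] = np.zeros(volume.shape, dtype=bool)
                continue
            usable = [auto]
        seeds = usable
        masked_vol = volume if body is None else volume.with_voxels(
            np.where(body, volume.voxels, scheme.domain.lo - 1)
        )
        raw[comp.name] = region_grow(masked_vol, comp.range, seeds, connectivity)

    # priority resolution: paint low priority first, higher overwrites
    order = sorted(
        range(len(scheme.compartments)),
        key=lambda i: (scheme.compartments[i].priority, -i),
    )
    owner = np.full(volume.shape, -1, dtype=np.int16)
    for i in order:
        owner[raw[scheme.compartments[i].name]] = i
    final = {
        c.name: (owner == i) for i, c in enumerate(scheme.compartments)
    }

    if skin_shell_voxels > 0:
        if body is None:
            raise ConfigError("skin shell requires a body mask")
        interior = ndimage.binary_erosion(body, iterations=skin_shell_voxels)
        shell = body & ~interior
        for m in final.values():
            np.logical_and(m, ~shell, out=m)
        final["skin"] = shell

    # bookkeeping: unassigned / out-of-domain / exterior voxels
    assigned = np.zeros(volume.shape, dtype=bool)
    for m in final.values():
        assigned |= m
    in_dom = scheme.domain.contains(volume.voxels)
    report.out_of_domain_voxels = int((~in_dom).sum())
    if report.out_of_domain_voxels:
        # "no gaps" rule: HU above the domain joins the highest-range compartment
        top = max(scheme.compartments, key=lambda c: c.range.hi)
        high = volume.voxels > scheme.domain.hi
        if body is not None:
            high &= body
        final[top.name] |= high & ~assigned
        assigned |= high
    if body is not None:
        report.exterior_voxels = int((~body).sum())
        report.unassigned_voxels = int((body & ~assigned).sum())
    else:
        report.unassigned_voxels = int((~assigned).sum())

    geom = dict(spacing=volume.spacing, origin=volume.origin, direction=volume.direction.copy())
    return SegmentationResult(
        maskset=MaskSet(masks=final, **geom),
        raw_maskset=MaskSet(masks=raw, **geom),
        coverage_report=report,
    )
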