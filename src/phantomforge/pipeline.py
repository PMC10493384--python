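"""End-to-end workflows: patient CT → print plan, phantom scans → report.

``run_design`` chains segmentation → compartment statistics → infill
planning → meshing → STL/manifest export.  ``run_assess`` registers each
phantom acquisition into the reference frame, re-segments it there (the
study's default; mask re-use is available for ablation) and assembles the
reproducibility report.  Every run emits a ``RunManifest`` with input
checksums, configuration snapshot and seeds, sufficient to reproduce the
deterministic stages bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .assessment import ReproReport, build_report, compartment_stats, export_report
from .compartments import CompartmentScheme, builtin_scheme, segment_compartments
from .errors import ConfigError, RegistrationError
from .fabrication import CalibrationCurve, export_print_plan, extract_surface, plan_infill
from .registration import RegistrationConfig, apply_transform, register_rigid
from .volumes import CTVolume, MaskSet, save_masks

log = logging.getLogger("phantomforge")

__all__ = ["RunManifest", "run_design", "run_assess"]


def _checksum(volume: CTVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(volume.voxels).tobytes())
    h.update(np.asarray(volume.spacing).tobytes())
    h.update(np.asarray(volume.origin).tobytes())
    h.update(np.ascontiguousarray(volume.direction).tobytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # name -> sha256
    outputs: dict = field(default_factory=dict)  # name -> file
    seeds: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)   # {stage, seconds}
    errors: dict = field(default_factory=dict)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))

    def stage(self, name: str, t0: float) -> None:
        dt = time.perf_counter() - t0
        self.stages.append({"stage": name, "seconds": round(dt, 3)})
        log.info("stage %-14s %6.2f s", name, dt)


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_design(
    volume: CTVolume,
    scheme: CompartmentScheme | str = "patient",
    calibration: CalibrationCurve | None = None,
    out_dir=None,
    scaffold_floor: float = 10.0,
    step: float = 2.5,
    seeds: dict[str, list] | None = None,
    masks: MaskSet | None = None,
) -> tuple[dict, RunManifest]:
    """Patient CT → compartment masks, infill plan and printable STL models.

    Returns ``(artifacts, manifest)`` where artifacts holds the
    ``segmentation`` result, per-compartment ``stats``, the ``plan`` and the
    ``meshes``; when *out_dir* is given, masks, STLs, ``plan.json`` and
    ``manifest.json`` are written there.  Passing *masks* skips the automatic
    segmentation and plans from the provided (e.g. operator-curated) masks,
    as a semi-automatic clinical workflow would.
    """
    if isinstance(scheme, str):
        scheme = builtin_scheme(scheme)
    if seeds:
        scheme = scheme.with_seeds(seeds)
    if calibration is None:
        raise ConfigError("run_design requires a CalibrationCurve")
    manifest = RunManifest(
        command="design",
        config={"scheme": scheme.label, "scaffold_floor": scaffold_floor, "step": step},
        inputs={"volume": _checksum(volume)},
        started=_now(),
    )
    if masks is None:
        t0 = time.perf_counter()
        seg = segment_compartments(volume, scheme)
        manifest.stage("segment", t0)
        maskset = seg.maskset
    else:
        seg = None
        maskset = masks
        manifest.config["masks"] = "provided"

    t0 = time.perf_counter()
    stats = {
        name: compartment_stats(volume, mask, name=name)
        for name, mask in maskset.masks.items()
        if mask.any()
    }
    manifest.stage("stats", t0)

    t0 = time.perf_counter()
    plan = plan_infill(
        {n: s.mean_hu for n, s in stats.items()},
        calibration,
        scaffold_floor=scaffold_floor,
        step=step,
    )
    manifest.stage("plan_infill", t0)

    t0 = time.perf_counter()
    meshes = [
        extract_surface(maskset.masks[name], volume, name=name)
        for name in plan.entries
        if maskset.masks[name].any()
    ]
    plan.entries = {m.name: plan.entries[m.name] for m in meshes}
    manifest.stage("mesh", t0)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        t0 = time.perf_counter()
        save_masks(maskset, out_dir / "masks")
        export_print_plan(plan, meshes, out_dir / "print")
        (out_dir / "plan.json").write_text(json.dumps(plan.to_dict(), indent=1, sort_keys=True))
        if seg is not None:
            (out_dir / "coverage.json").write_text(
                json.dumps(seg.coverage_report.to_dict(), indent=1)
            )
        manifest.stage("export", t0)
        manifest.outputs = {"masks": "masks/", "print": "print/", "plan": "plan.json"}
        if seg is not None:
            manifest.outputs["coverage"] = "coverage.json"
        manifest.finished = _now()
        manifest.save(out_dir / "manifest.json")
    else:
        manifest.finished = _now()
    return {"segmentation": seg, "stats": stats, "plan": plan, "meshes": meshes}, manifest


def run_assess(
    reference_volume: CTVolume,
    reference_masks: MaskSet,
    acquisitions: list[CTVolume],
    reg_config: RegistrationConfig | None = None,
    out_dir=None,
    scheme: CompartmentScheme | None = None,
    mode: str = "resegment",
    seed: int = 0,
) -> tuple[ReproReport, RunManifest]:
    """Phantom acquisitions → registered, re-segmented reproducibility report.

    Each acquisition is rigidly registered to *reference_volume*, resampled
    into its geometry and — in the default ``resegment`` mode — re-segmented
    there with *scheme* (required); ``reuse`` mode instead carries the
    reference masks over unchanged (ablation).  A registration failure flags
    that acquisition and the others proceed.
    """
    if mode not in ("resegment", "reuse"):
        raise ConfigError(f"unknown mode {mode!r}")
    if mode == "resegment" and scheme is None:
        raise ConfigError("resegment mode requires a scheme")
    reg_config = reg_config or RegistrationConfig()
    manifest = RunManifest(
        command="assess",
        config={"mode": mode, "registration": reg_config.__dict__.copy(),
                "scheme": getattr(scheme, "label", None)},
        inputs={"reference": _checksum(reference_volume)},
        seeds={"registration_base": reg_config.seed, "seed": seed},
        started=_now(),
    )
    per_acq = []
    for i, acq in enumerate(acquisitions):
        label = f"acq{i}_{acq.meta.scanner}_{acq.meta.kvp}"
        manifest.inputs[label] = _checksum(acq)
        cfg = RegistrationConfig(**{**reg_config.__dict__, "seed": reg_config.seed + i})
        t0 = time.perf_counter()
        try:
            reg = register_rigid(reference_volume, acq, cfg)
        except RegistrationError as exc:
            manifest.errors[label] = str(exc)
            log.warning("registration failed for %s: %s", label, exc)
            continue
        manifest.stage(f"register:{label}", t0)
        resampled = apply_transform(acq, reg.transform, reference_volume, "linear")
        if mode == "resegment":
            t0 = time.perf_counter()
            seg = segment_compartments(resampled, scheme)
            masks = seg.maskset
            manifest.stage(f"segment:{label}", t0)
        else:
            masks = reference_masks
        per_acq.append((acq.meta, masks, resampled))

    report = build_report(reference_masks, per_acq, reference_volume=reference_volume)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files = export_report(report, out_dir)
        manifest.outputs = {p.name: p.name for p in files}
        manifest.finished = _now()
        manifest.save(out_dir / "manifest.json")
    else:
        manifest.finished = _now()
    return report, manifest
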