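"""Reproducibility assessment: Dice overlap and per-compartment HU statistics.

Builds the patient-vs-phantom comparison tables (one Dice Similarity
Coefficient and one mean±SD HU entry per compartment per acquisition) and
renders them as CSV/JSON plus two figure analogues: per-compartment HU
distributions and a Hounsfield-scale ladder diagram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError
from .volumes import AcquisitionMeta, CTVolume, MaskSet

__all__ = [
    "DSCResult",
    "CompartmentStats",
    "ReproReport",
    "dice",
    "compartment_stats",
    "build_report",
    "export_report",
]


@dataclass(frozen=True)
class DSCResult:
    name: str
    dsc: float
    size_a: int
    size_b: int
    intersection: int
    both_empty: bool = False


def dice(a: np.ndarray, b: np.ndarray, name: str = "") -> DSCResult:
    """Dice similarity 2|A∩B| / (|A| + |B|).

    Both masks empty is returned as 1.0 with a flag (vacuous agreement);
    exactly one empty is 0.0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise GeometryError(f"mask shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    if na + nb == 0:
        warnings.warn(f"dice({name or 'masks'}): both masks empty; returning 1.0")
        return DSCResult(name, 1.0, 0, 0, 0, both_empty=True)
    return DSCResult(name, 2.0 * inter / (na + nb), na, nb, inter)


@dataclass(frozen=True)
class CompartmentStats:
    name: str
    mean_hu: float
    sd_hu: float
    voxel_count: int
    volume_mm3: float


def compartment_stats(
    volume: CTVolume, mask: np.ndarray, name: str = "", population_sd: bool = False
) -> CompartmentStats:
    """Mean and SD (sample SD by default, ddof=1) of HU over the mask voxels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.shape:
        raise GeometryError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    n = int(mask.sum())
    if n == 0:
        warnings.warn(f"compartment_stats({name or 'mask'}): empty mask")
        return CompartmentStats(name, float("nan"), float("nan"), 0, 0.0)
    vals = volume.voxels[mask]
    ddof = 0 if population_sd else 1
    sd = float(vals.std(ddof=ddof)) if n > ddof else 0.0
    return CompartmentStats(name, float(vals.mean()), sd, n, n * volume.voxel_volume_mm3)


def _acq_label(meta: AcquisitionMeta) -> str:
    scanner = meta.scanner or "scanner"
    kvp = f"{meta.kvp:g}kVp" if meta.kvp is not None else "?kVp"
    return f"{scanner} {kvp}"


@dataclass
class ReproReport:
    """Compartment × acquisition DSC and HU tables, patient vs phantom."""

    dsc_table: pd.DataFrame            # rows compartments, columns acquisitions
    hu_mean_table: pd.DataFrame
    hu_sd_table: pd.DataFrame
    reference_hu: pd.DataFrame         # columns mean, sd (reference acquisition)
    acquisitions: list[dict] = field(default_factory=list)
    reference_label: str = "patient"

    def summary(self) -> pd.Series:
        """Per-compartment mean DSC across acquisitions."""
        return self.dsc_table.mean(axis=1)

    def rounded(self, dsc_decimals: int = 2, hu_decimals: int = 2) -> "ReproReport":
        return ReproReport(
            self.dsc_table.round(dsc_decimals),
            self.hu_mean_table.round(hu_decimals),
            self.hu_sd_table.round(hu_decimals),
            self.reference_hu.round(hu_decimals),
            self.acquisitions,
            self.reference_label,
        )

    def to_dict(self) -> dict:
        return {
            "reference_label": self.reference_label,
            "acquisitions": self.acquisitions,
            "dsc": self.dsc_table.to_dict(),
            "hu_mean": self.hu_mean_table.to_dict(),
            "hu_sd": self.hu_sd_table.to_dict(),
            "reference_hu": self.reference_hu.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReproReport":
        def df(key):
            frame = pd.DataFrame(d[key])
            frame.index.name = "compartment"
            return frame
        return cls(
            df("dsc"), df("hu_mean"), df("hu_sd"), df("reference_hu"),
            d.get("acquisitions", []), d.get("reference_label", "patient"),
        )


def build_report(
    reference_masks: MaskSet,
    per_acquisition: list[tuple[AcquisitionMeta, MaskSet, CTVolume]],
    reference_volume: CTVolume | None = None,
    compartments: list[str] | None = None,
    exclude: tuple[str, ...] = ("skin",),
) -> ReproReport:
    """Assemble the reproducibility tables in the reference geometry.

    Every acquisition's masks must already be resampled into the reference
    geometry.  A compartment missing from an acquisition is reported as NaN,
    not fatal.  ``skin`` (no HU range of its own) is excluded by default.
    """
    names = [
        n for n in (compartments or reference_masks.names) if n not in exclude
    ]
    dsc_cols, mean_cols, sd_cols, acqs = {}, {}, {}, []
    for meta, masks, vol in per_acquisition:
        if not masks.geometry_matches(
            reference_volume if reference_volume is not None else vol
        ):
            raise GeometryError(
                f"acquisition {_acq_label(meta)}: masks not in reference geometry"
            )
        label = _acq_label(meta)
        acqs.append({"scanner": meta.scanner, "kvp": meta.kvp, "mas": meta.mas, "label": label})
        d_col, m_col, s_col = {}, {}, {}
        for n in names:
            if n not in masks.masks:
                d_col[n] = m_col[n] = s_col[n] = float("nan")
                continue
            d_col[n] = dice(reference_masks.masks[n], masks.masks[n], name=n).dsc
            st = compartment_stats(vol, masks.masks[n], name=n)
            m_col[n], s_col[n] = st.mean_hu, st.sd_hu
        dsc_cols[label] = d_col
        mean_cols[label] = m_col
        sd_cols[label] = s_col

    ref_rows = {}
    for n in names:
        if reference_volume is not None and n in reference_masks.masks:
            st = compartment_stats(reference_volume, reference_masks.masks[n], name=n)
            ref_rows[n] = {"mean": st.mean_hu, "sd": st.sd_hu}
        else:
            ref_rows[n] = {"mean": float("nan"), "sd": float("nan")}
    idx = pd.Index(names, name="compartment")
    return ReproReport(
        dsc_table=pd.DataFrame(dsc_cols, index=idx),
        hu_mean_table=pd.DataFrame(mean_cols, index=idx),
        hu_sd_table=pd.DataFrame(sd_cols, index=idx),
        reference_hu=pd.DataFrame.from_dict(ref_rows, orient="index").reindex(idx),
        acquisitions=acqs,
    )


def export_report(report: ReproReport, out_dir, formats=("csv", "json", "figures")) -> list[Path]:
    """Write the report as CSV/JSON tables and figure analogues (PNG).

    CSV/JSON carry raw values; the printed CSV tables are rounded to 2
    decimals to match the source tables' precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        rounded = report.rounded()
        for frame, fname in (
            (rounded.dsc_table, "dsc_table.csv"),
            (rounded.hu_mean_table, "hu_mean_table.csv"),
            (rounded.hu_sd_table, "hu_sd_table.csv"),
        ):
            frame.to_csv(out_dir / fname)
            written.append(out_dir / fname)
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=1, allow_nan=True))
        written.append(p)
    if "figures" in formats:
        written += _figures(report, out_dir)
    return written


def _figures(report: ReproReport, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(report.dsc_table.index)
    x = np.arange(len(names))
    # HU distribution analogue: reference vs each acquisition, mean +/- SD
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.errorbar(
        x - 0.15, report.reference_hu["mean"], yerr=report.reference_hu["sd"],
        fmt="o", capsize=3, label=report.reference_label,
    )
    ncols = len(report.hu_mean_table.columns)
    for i, col in enumerate(report.hu_mean_table.columns):
        off = -0.05 + 0.3 * (i + 1) / max(ncols, 1)
        ax.errorbar(
            x + off, report.hu_mean_table[col], yerr=report.hu_sd_table[col],
            fmt="s", ms=3, capsize=2, alpha=0.8, label=col,
        )
    ax.set_xticks(x, names, rotation=30, ha="right")
    ax.set_ylabel("HU (mean ± SD)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p1 = out_dir / "hu_distributions.png"
    fig.savefig(p1, dpi=110)
    plt.close(fig)

    # Hounsfield-scale ladder: compartments positioned on the HU axis
    fig, ax = plt.subplots(figsize=(5, 6))
    phantom_mean = report.hu_mean_table.mean(axis=1)
    for n in names:
        rv, pv = report.reference_hu.loc[n, "mean"], phantom_mean.loc[n]
        ax.plot([0, 1], [rv, pv], "-o", ms=4)
        ax.annotate(n, (0, rv), xytext=(-5, 0), textcoords="offset points",
                    ha="right", va="center", fontsize=7)
        ax.annotate(n, (1, pv), xytext=(5, 0), textcoords="offset points",
                    ha="left", va="center", fontsize=7)
    ax.set_xticks([0, 1], [report.reference_label, "phantom"])
    ax.set_xlim(-0.8, 1.8)
    ax.set_ylabel("mean HU")
    fig.tight_layout()
    p2 = out_dir / "hu_ladder.png"
    fig.savefig(p2, dpi=110)
    plt.close(fig)
    return [p1, p2]
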