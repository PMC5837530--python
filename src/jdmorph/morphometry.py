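"""Per-subject summary measures: tissue/ROI mean JD and annualized rates."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .grids import JacobianMap, LabelVolume

__all__ = [
    "annualized_atrophy_rate",
    "compartment_volume",
    "tissue_mean_jd",
    "roi_mean_jd",
    "percent_significant_voxels",
    "summarize_subject",
]

log = logging.getLogger(__name__)


def annualized_atrophy_rate(
    baseline_volume: float, followup_volume: float, interval_years: float
) -> float:
    """Percent volume change per year:
    100 * (followup - baseline) / baseline / interval."""
    if baseline_volume <= 0:
        raise ValueError("baseline_volume must be > 0")
    if interval_years <= 0:
        raise ValueError("interval_years must be > 0")
    return 100.0 * (followup_volume - baseline_volume) / baseline_volume / interval_years


def compartment_volume(labels: LabelVolume, classes, voxel_size_mm: float | None = None) -> float:
    """Volume (mm^3) of all voxels whose label class is in ``classes``."""
    if isinstance(classes, str):
        classes = (classes,)
    if not classes:
        raise ValueError("classes must be nonempty")
    mask = labels.mask_of_class(*classes)
    n = int(mask.sum())
    if n == 0:
        warnings.warn(f"empty selection for classes {tuple(classes)}", RuntimeWarning)
    vs = labels.voxel_size_mm if voxel_size_mm is None else voxel_size_mm
    return n * vs**3


def tissue_mean_jd(jd: JacobianMap, mask: np.ndarray) -> tuple[float, float, int]:
    """(mean, SD, voxel count) of the JD over a tissue mask (NaNs excluded)."""
    if mask.shape != jd.shape3:
        raise ValueError("mask grid does not match JD map")
    vals = jd.data[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(vals.mean()), float(vals.std(ddof=0)), int(vals.size)


def roi_mean_jd(
    jd: JacobianMap,
    labels: LabelVolume,
    subject_id: str = "",
    include_noncortical: bool = False,
) -> pd.DataFrame:
    """Long-format table of per-ROI mean JD (cortical gyri/sulci by default).

    One row per nonempty ROI: (subject id, ROI id, name, class, mean JD,
    voxel count). ROIs with zero voxels are omitted and logged.
    """
    jd.same_grid(labels)
    classes = ("gyrus", "sulcus")
    if include_noncortical:
        classes = classes + ("subcortical-GM", "WM")
    rows = []
    for rid in labels.ids_of_class(*classes):
        name, cls = labels.table[rid]
        m = labels.data == rid
        vals = jd.data[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            log.warning("ROI %s (%d) empty; omitted", name, rid)
            continue
        rows.append(
            dict(
                id=subject_id, roi_id=rid, roi_name=name, roi_class=cls,
                mean_jd=float(vals.mean()), voxel_count=int(vals.size),
            )
        )
    return pd.DataFrame(rows)


def percent_significant_voxels(
    corrected_p_map: np.ndarray, mask: np.ndarray, alpha: float = 0.05
) -> float:
    """Percent of in-mask voxels with corrected p below alpha."""
    p = np.asarray(corrected_p_map, dtype=float)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return 100.0 * float((p[mask] < alpha).sum()) / n


def summarize_subject(
    subject_id: str,
    annual_jd: JacobianMap,
    labels: LabelVolume,
    baseline_volumes: dict[str, float] | None = None,
    followup_volumes: dict[str, float] | None = None,
    interval_years: float | None = None,
) -> dict:
    """One summary row per subject: tissue mean JD and derived %/yr rates.

    The JD-based rate is 100 * (mean annual JD - 1); when baseline/follow-up
    compartment volumes are supplied the direct volumetric rate is added too.
    """
    gm_mask = labels.mask_of_class("gyrus", "sulcus", "subcortical-GM")
    wm_mask = labels.mask_of_class("WM")
    brain = labels.brain_mask
    row: dict = {"id": subject_id}
    for name, mask in (("gm", gm_mask), ("wm", wm_mask), ("brain", brain)):
        mean, sd, n = tissue_mean_jd(annual_jd, mask)
        row[f"{name}_mean_jd"] = mean
        row[f"{name}_jd_sd"] = sd
        row[f"{name}_voxels"] = n
        row[f"{name}_rate_pct_yr"] = 100.0 * (mean - 1.0)
    if baseline_volumes and followup_volumes and interval_years:
        for name in baseline_volumes:
            row[f"{name}_vol_rate_pct_yr"] = annualized_atrophy_rate(
                baseline_volumes[name], followup_volumes[name], interval_years
            )
    return row
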