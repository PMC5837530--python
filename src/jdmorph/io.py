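"""NIfTI and CSV I/O.

Images, label volumes, displacement fields (4-D, last axis = vector
component in mm) and Jacobian maps (with a JSON sidecar recording the
annualized flag and interval) are written as NIfTI-1 through nibabel;
cohort tables as CSV with a fixed, validated column set.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import DisplacementField, JacobianMap, LabelVolume, ScalarVolume

__all__ = [
    "write_volume", "read_volume",
    "write_labels", "read_labels",
    "write_field", "read_field",
    "write_jd", "read_jd",
    "write_cohort", "read_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = (
    "id", "group", "age_years", "sex", "scanner", "interval_years",
    "tsi_months", "lesion", "microbleed", "pta", "gcs", "icv_mm3",
)


def write_volume(vol: ScalarVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), path)
    return path


def read_volume(path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(np.asarray(img.dataobj, dtype=np.float32), img.affine)


def write_labels(labels: LabelVolume, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.data.astype(np.int16), labels.affine), path)
    table_path = path.with_suffix("").with_suffix(".labels.csv")
    pd.DataFrame(
        [(k, n, c) for k, (n, c) in sorted(labels.table.items())],
        columns=["label", "name", "class"],
    ).to_csv(table_path, index=False)
    return path


def read_labels(path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    table_path = path.with_suffix("").with_suffix(".labels.csv")
    tdf = pd.read_csv(table_path)
    table = {
        int(lab): (str(name), str(cls))
        for lab, name, cls in zip(tdf["label"], tdf["name"], tdf["class"])
    }
    return LabelVolume(np.asarray(img.dataobj, dtype=np.int16), img.affine, table)


def write_field(field: DisplacementField, path) -> Path:
    path = Path(path)
    arr = np.moveaxis(field.data.astype(np.float32), 0, -1)  # (nx,ny,nz,3)
    nib.save(nib.Nifti1Image(arr, field.affine), path)
    return path


def read_field(path) -> DisplacementField:
    img = nib.load(str(path))
    arr = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    return DisplacementField(arr, img.affine)


def write_jd(jd: JacobianMap, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(jd.data.astype(np.float32), jd.affine), path)
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(
        json.dumps({"annualized": jd.annualized, "interval_years": jd.interval_years})
    )
    return path


def read_jd(path) -> JacobianMap:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return JacobianMap(
        np.asarray(img.dataobj, dtype=np.float32), img.affine,
        annualized=bool(meta.get("annualized", False)),
        interval_years=float(meta.get("interval_years", 1.0)),
    )


def write_cohort(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    table.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        import warnings

        warnings.warn(f"cohort CSV has unknown column(s): {extra}", RuntimeWarning)
    if (df["interval_years"] <= 0).any():
        raise ValueError("interval_years must be > 0 for all subjects")
    return df


def check_pair_grids(baseline: ScalarVolume, followup: ScalarVolume) -> None:
    """Fail if a subject's two time points disagree in grid or affine."""
    try:
        baseline.same_grid(followup)
    except ValueError as e:
        raise ValueError(f"baseline/follow-up grid mismatch: {e}") from e
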