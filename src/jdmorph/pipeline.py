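"""End-to-end orchestration: simulate -> register -> jd -> summarize ->
voxelwise -> cohort-stats -> power, with any contiguous sub-span runnable on
the outputs of a previous run."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from . import io as jio
from . import morphometry, phantom, power
from .config import RunConfig, stage_seed
from .grids import JacobianMap, ScalarVolume
from .inference import DesignMatrix, permutation_correct
from .registration import annualize_jd, jacobian_map, register_symmetric, smooth_volume

__all__ = ["run_pipeline", "RunRecord", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "register", "jd", "summarize", "voxelwise", "cohort-stats", "power")


@dataclass
class RunRecord:
    config_hash: str
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: Path) -> Path:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_span(stages) -> list[str]:
    idx = [STAGES.index(s) for s in stages]
    if sorted(idx) != list(range(min(idx), max(idx) + 1)):
        raise ValueError(f"stages must form a contiguous span of {STAGES}")
    return [STAGES[i] for i in sorted(idx)]


class _Pipeline:
    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.record = RunRecord(config_hash=config.content_hash(), version=_version())
        self._cohort = None
        self._labels = None

    # -- lazy inputs -------------------------------------------------------
    @property
    def cohort(self) -> pd.DataFrame:
        if self._cohort is None:
            self._cohort = jio.read_cohort(self.out / "cohort.csv")
        return self._cohort

    @property
    def labels(self):
        if self._labels is None:
            self._labels = jio.read_labels(self.out / "labels.nii")
            self._labels.meta = {"spec": self.cfg.phantom}
        return self._labels

    def _emit(self, rel: str):
        p = self.out / rel
        self.record.manifest[rel] = _sha256(p)

    def _filtered_cohort(self) -> pd.DataFrame:
        if not self.cfg.exclude_lesions:
            return self.cohort
        keep = cohort_stats.lesion_free(self.cohort)
        return self.cohort[keep]

    # -- stages ------------------------------------------------------------
    def simulate(self):
        cfg = self.cfg
        sim = phantom.simulate_cohort(
            cfg.n_case, cfg.n_control, cfg.atrophy, cfg.phantom,
            seed=stage_seed(cfg.seed, "simulate"), render_images=True,
        )
        jio.write_volume(sim.template, self.out / "template.nii")
        jio.write_labels(sim.labels, self.out / "labels.nii")
        jio.write_cohort(sim.table, self.out / "cohort.csv")
        for rel in ("template.nii", "labels.nii", "labels.labels.csv", "cohort.csv"):
            self._emit(rel)
        for sid, (bl, fu) in sim.images.items():
            d = self.out / "subjects" / sid
            d.mkdir(parents=True, exist_ok=True)
            jio.write_volume(bl, d / "baseline.nii")
            jio.write_volume(fu, d / "followup.nii")
            gt = sim.ground_truths[sid]
            jio.write_jd(
                JacobianMap(gt.annual_jd.data, gt.annual_jd.affine, annualized=True,
                            interval_years=gt.interval_years),
                d / "truth_annual_jd.nii",
            )
            for rel in ("baseline.nii", "followup.nii", "truth_annual_jd.nii",
                        "truth_annual_jd.json"):
                self._emit(f"subjects/{sid}/{rel}")
        self._cohort = sim.table
        self._labels = sim.labels

    def register(self):
        for row in self.cohort.itertuples(index=False):
            d = self.out / "subjects" / row.id
            bl = jio.read_volume(d / "baseline.nii")
            fu = jio.read_volume(d / "followup.nii")
            jio.check_pair_grids(bl, fu)
            res = register_symmetric(bl, fu, self.cfg.registration)
            jio.write_volume(res.midpoint, d / "midpoint.nii")
            jio.write_field(res.full_warp, d / "warp.nii")
            self._emit(f"subjects/{row.id}/midpoint.nii")
            self._emit(f"subjects/{row.id}/warp.nii")

    def jd(self):
        for row in self.cohort.itertuples(index=False):
            d = self.out / "subjects" / row.id
            warp = jio.read_field(d / "warp.nii")
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                raw = jacobian_map(warp, mask=self.labels.brain_mask)
                annual = annualize_jd(raw, float(row.interval_years))
            for w in wlist:
                self.record.warnings.append(f"{row.id}: {w.message}")
            jio.write_jd(annual, d / "annual_jd.nii")
            self._emit(f"subjects/{row.id}/annual_jd.nii")
            self._emit(f"subjects/{row.id}/annual_jd.json")

    def summarize(self):
        rows, roi_frames = [], []
        for row in self.cohort.itertuples(index=False):
            d = self.out / "subjects" / row.id
            annual = jio.read_jd(d / "annual_jd.nii")
            rows.append(morphometry.summarize_subject(row.id, annual, self.labels))
            roi_frames.append(morphometry.roi_mean_jd(annual, self.labels, row.id))
        pd.DataFrame(rows).to_csv(self.out / "summaries.csv", index=False)
        pd.concat(roi_frames, ignore_index=True).to_csv(self.out / "roi.csv", index=False)
        self._emit("summaries.csv")
        self._emit("roi.csv")

    def voxelwise(self):
        cfg = self.cfg
        cohort = self._filtered_cohort()
        stack = []
        for row in cohort.itertuples(index=False):
            annual = jio.read_jd(self.out / "subjects" / row.id / "annual_jd.nii")
            sm = smooth_volume(annual.as_volume(), cfg.smoothing_fwhm_mm)
            stack.append(np.nan_to_num(sm.data, nan=1.0))
        covariates = ["age_years", "sex", "scanner", "icv_mm3"]
        while covariates and len(cohort) - (2 + len(covariates)) < 2:
            dropped = covariates.pop()  # keep residual dof >= 2 on tiny cohorts
            log.info("dropping covariate %r (too few subjects)", dropped)
        design = DesignMatrix.from_cohort(cohort, covariates=tuple(covariates))
        res = permutation_correct(
            np.stack(stack), design, cfg.permutation_scheme(), cfg.tfce,
            mask=self.labels.brain_mask,
        )
        mask = self.labels.brain_mask
        pct = morphometry.percent_significant_voxels(res["corrected_p"], mask)
        jio.write_volume(
            ScalarVolume(res["corrected_p"], self.labels.affine),
            self.out / "corrected_p.nii",
        )
        (self.out / "voxelwise.json").write_text(json.dumps({
            "n_permutations": res["n_permutations"],
            "n_subjects": int(len(cohort)),
            "percent_significant": pct,
            "seed": stage_seed(cfg.seed, "permutations"),
        }, indent=2))
        self._emit("corrected_p.nii")
        self._emit("voxelwise.json")

    def cohort_stats_stage(self):
        cohort = self._filtered_cohort()
        summaries = pd.read_csv(self.out / "summaries.csv")
        roi = pd.read_csv(self.out / "roi.csv")
        summaries = summaries[summaries["id"].isin(set(cohort["id"]))]
        roi = roi[roi["id"].isin(set(cohort["id"]))]
        out = {}
        for outcome in ("gm_mean_jd", "wm_mean_jd", "brain_mean_jd"):
            fit = cohort_stats.fit_group_adjusted(summaries, cohort, outcome)
            out[outcome] = fit.coef()
            out[outcome]["n"] = fit.n
        df = cohort_stats._prepare_frame(summaries, cohort)
        part = cohort_stats.hierarchical_partition(
            df["gm_mean_jd"],
            df[["group_case", "age_years", "sex_m", "scanner_b"]],
        )
        out["partition_gm"] = {
            "independent": part.independent.to_dict(),
            "joint": part.joint.to_dict(),
            "full_r2": part.full_r2,
        }
        main, inter, lrt_p = cohort_stats.fit_sulcal_interaction(roi, cohort)
        out["sulcal_model"] = {
            "group": main.coef(), "interaction": inter.coef(), "lrt_p": lrt_p,
        }
        (self.out / "cohort_stats.json").write_text(json.dumps(out, indent=2))
        self._emit("cohort_stats.json")

    def power_stage(self):
        cohort = self._filtered_cohort()
        summaries = pd.read_csv(self.out / "summaries.csv")
        df = summaries.merge(cohort[["id", "group"]], on="id")
        rows = []
        for name, col in (("gm_jd", "gm_rate_pct_yr"), ("wm_jd", "wm_rate_pct_yr"),
                          ("brain_jd", "brain_rate_pct_yr")):
            case = -df.loc[df.group == "case", col]  # loss positive
            ctrl = -df.loc[df.group == "control", col]
            es = power.cohens_d(case.mean(), case.std(ddof=1), len(case),
                                ctrl.mean(), ctrl.std(ddof=1), len(ctrl))
            n = power.sample_size_per_arm(self.cfg.treatment_effectiveness, abs(es.d))
            lo, hi = es.ci95
            rows.append(dict(measure=name, d=es.d, ci_lo=lo, ci_hi=hi,
                             te=self.cfg.treatment_effectiveness, n_per_arm=n))
        pd.DataFrame(rows).to_csv(self.out / "power.csv", index=False)
        curve = power.power_curve(abs(rows[0]["d"]), np.round(np.arange(0.1, 1.01, 0.05), 2))
        curve.to_csv(self.out / "power_curve_gm_jd.csv", index=False)
        self._emit("power.csv")
        self._emit("power_curve_gm_jd.csv")


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("jdmorph")
    except Exception:
        return "unknown"


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute the configured contiguous span of pipeline stages.

    Stage failures abort with the stage name (and subject id where
    applicable) in the exception chain; a completed run writes
    ``run_record.json`` with the config hash, per-stage timings, collected
    warnings and a sha256 manifest of every emitted file.
    """
    stages = _check_span(config.stages)
    pipe = _Pipeline(config)
    dispatch = {
        "simulate": pipe.simulate,
        "register": pipe.register,
        "jd": pipe.jd,
        "summarize": pipe.summarize,
        "voxelwise": pipe.voxelwise,
        "cohort-stats": pipe.cohort_stats_stage,
        "power": pipe.power_stage,
    }
    for s in stages:
        t0 = time.time()
        log.info("stage %s starting (seed=%d)", s, config.seed)
        try:
            dispatch[s]()
        except Exception as e:
            raise RuntimeError(f"pipeline stage {s!r} failed: {e}") from e
        pipe.record.timings[s] = round(time.time() - t0, 3)
    config.to_yaml(pipe.out / "config.yaml")
    pipe._emit("config.yaml")
    pipe.record.to_json(pipe.out / "run_record.json")
    return pipe.record
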