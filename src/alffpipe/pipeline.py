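"""End-to-end runner chaining simulation, preprocessing, ALFF, group
statistics and brain-behavior correlation, with a reproducible manifest.

Stage order: discard -> slice timing -> motion QC -> intensity
normalization -> smoothing -> CompCor -> nuisance GLM -> ALFF ->
normalization -> group stats -> correlation.  CompCor components are
extracted from the unsmoothed series so smoothing cannot leak gray-matter
signal into the noise compartments.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alff as alff_mod
from . import brainbehavior as bb
from . import groupstats as gs
from . import io as io_mod
from . import preprocess as pp
from .errors import ConfigurationError
from .synthetic import (
    Cohort,
    GroupEffectSpec,
    PhantomSpec,
    ScoreModel,
    simulate_cohort,
)
from .types import AlffMap, BoldSeries, MotionTrace

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    The defaults mirror the emulated protocol: discard 2 of 240 volumes,
    exclude subjects moving more than 1.5 mm RMS, smooth to 8 mm FWHM,
    5 CompCor components (17 nuisance regressors total), ALFF band
    0.008-0.09 Hz, Monte-Carlo cluster correction at voxel p = 0.05 and
    FWHM 4 mm, FDR q = 0.05.
    """

    n_discard: int = 2
    slice_axis: int = 2
    ref_fraction: float = 0.5
    rms_threshold: float = 1.5
    rms_radius: float = 80.0
    norm_target: float = 10000.0
    smooth_fwhm: float = 8.0
    n_compcor: int = 5
    band: tuple[float, float] = (0.008, 0.09)
    null_value: float = 1.0
    voxel_p: float = 0.05
    mc_fwhm: float = 4.0
    mc_alpha: float = 0.05
    mc_iter: int = 10000
    deficit_alpha: float = 0.05
    fdr_q: float = 0.05
    patient_group: str = "SCD"
    control_group: str = "CTL"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if k == "band" else v for k, v in d.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_discard < 0:
            raise ConfigurationError("n_discard must be non-negative")
        if not (0 < self.band[0] < self.band[1]):
            raise ConfigurationError(f"invalid band {self.band}")
        if self.rms_threshold <= 0:
            raise ConfigurationError("rms_threshold must be positive")
        for name in ("voxel_p", "mc_alpha", "deficit_alpha", "fdr_q"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")

    def validate_against(self, tr: float) -> None:
        nyq = 1.0 / (2.0 * tr)
        if self.band[1] > nyq:
            raise ConfigurationError(
                f"band upper edge {self.band[1]} Hz above Nyquist {nyq} Hz (TR={tr}s)"
            )


def preprocess_subject(
    series: BoldSeries,
    motion: MotionTrace,
    brain_mask: np.ndarray,
    noise_masks: list[np.ndarray],
    cfg: PipelineConfig,
) -> BoldSeries:
    """Run one subject through the full nuisance pipeline."""
    series = pp.discard_initial_volumes(series, cfg.n_discard)
    motion = motion.drop_initial(cfg.n_discard) if cfg.n_discard else motion
    series = pp.slice_timing_correct(
        series, slice_axis=cfg.slice_axis, ref_fraction=cfg.ref_fraction
    )
    series = pp.normalize_intensity(series, brain_mask, target=cfg.norm_target)
    components = pp.compcor_components(series, noise_masks, n_components=cfg.n_compcor)
    series = pp.smooth_gaussian(series, cfg.smooth_fwhm)
    design = pp.build_nuisance_design(motion, components)
    return pp.regress_nuisance(series, design, brain_mask)


def alff_subject(series: BoldSeries, brain_mask: np.ndarray, cfg: PipelineConfig) -> AlffMap:
    raw = alff_mod.compute_alff(series, cfg.band[0], cfg.band[1], brain_mask)
    return alff_mod.normalize_alff(raw)


def run_pipeline(
    cohort: Cohort,
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute every stage on an in-memory cohort; returns the run manifest.

    When ``out_dir`` is given, all intermediate and final artifacts (ALFF
    maps, stat maps, cluster/correlation tables, QC report, manifest) are
    written there.
    """
    t0 = time.time()
    cfg.validate()
    cfg.validate_against(cohort.series[0].tr)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    brain, gray, noise_masks = cohort.brain_mask, cohort.gray_mask, cohort.noise_masks
    table = cohort.table.copy()

    # --- motion QC ---------------------------------------------------
    traces = {r.subject_id: m for r, m in zip(cohort.records, cohort.motion)}
    kept_ids, excluded_ids, max_rms = pp.qc_filter(
        traces, threshold=cfg.rms_threshold, radius=cfg.rms_radius
    )
    qc = pd.DataFrame(
        {
            "subject_id": list(max_rms),
            "max_rms_mm": [max_rms[s] for s in max_rms],
            "kept": [s in set(kept_ids) for s in max_rms],
        }
    )
    keep_mask = table["subject_id"].isin(kept_ids).to_numpy()
    table = table.loc[keep_mask].reset_index(drop=True)

    # --- preprocess + ALFF per subject -------------------------------
    maps: list[AlffMap] = []
    for rec, series, motion in zip(cohort.records, cohort.series, cohort.motion):
        if rec.subject_id not in set(kept_ids):
            continue
        clean = preprocess_subject(series, motion, brain, noise_masks, cfg)
        amap = alff_subject(clean, brain, cfg)
        maps.append(amap)
        if out is not None:
            io_mod.write_alff_map(out / f"{rec.subject_id}_alff.nii.gz", amap)

    groups = table["group"].to_numpy()
    ages = table["age"].to_numpy(float)

    # --- within-group one-sample t maps ------------------------------
    within = {}
    for g in sorted(set(groups)):
        idx = np.nonzero(groups == g)[0]
        if len(idx) >= 3:
            within[g] = gs.one_sample_tmap(
                [maps[i] for i in idx], null_value=cfg.null_value, mask=gray
            )
            if out is not None:
                io_mod.write_stat_map(out / f"onesample_{g}.nii.gz", within[g])

    # --- between-group ANCOVA + cluster correction -------------------
    fmap = gs.ancova_fmap(maps, groups, ages, mask=gray)
    mc_one = gs.McThreshold(
        voxel_p=cfg.voxel_p, fwhm=cfg.mc_fwhm, alpha=cfg.mc_alpha,
        n_iter=cfg.mc_iter, seed=cfg.seed, sided="one",
    )
    mc_two = gs.McThreshold(
        voxel_p=cfg.voxel_p, fwhm=cfg.mc_fwhm, alpha=cfg.mc_alpha,
        n_iter=cfg.mc_iter, seed=cfg.seed, sided="two",
    )
    k_min = gs.mc_cluster_threshold(gray, mc_one, voxel_size=maps[0].voxel_size)
    k_min_t = gs.mc_cluster_threshold(gray, mc_two, voxel_size=maps[0].voxel_size)
    f_clusters = gs.extract_clusters(fmap, cfg.voxel_p, k_min)

    # --- post-hoc patient vs control inside the ANCOVA mask ----------
    sig_mask = f_clusters.labels > 0
    tmap = gs.posthoc_tmap(
        maps, groups, cfg.patient_group, cfg.control_group, sig_mask
    )
    t_clusters = gs.extract_clusters(tmap, cfg.voxel_p, k_min_t) if sig_mask.any() else None
    clusters = t_clusters if t_clusters is not None and len(t_clusters) else f_clusters

    # --- WMH subgroup test within the patient group ------------------
    patient_idx = np.nonzero(groups == cfg.patient_group)[0]
    wmh_flags = np.array(
        [
            bb.classify_wmh_pathological(int(table["wmh_count"][i]), float(ages[i]))
            for i in patient_idx
        ]
    )
    wmh_table = None
    if len(clusters) and 2 <= int(wmh_flags.sum()) <= len(wmh_flags) - 2:
        wmh_table = gs.wmh_subgroup_test(
            [maps[i] for i in patient_idx], wmh_flags, clusters, voxel_p=cfg.voxel_p
        )

    # --- brain-behavior correlation ----------------------------------
    deficit = bb.select_deficit_scores(
        table, cfg.patient_group, cfg.control_group, alpha=cfg.deficit_alpha
    )
    corr = pd.DataFrame()
    if len(clusters) and deficit:
        regional = gs.regional_alff_matrix(maps, clusters)
        corr = bb.correlate_clusters_scores(
            table, regional, deficit, q=cfg.fdr_q,
            cluster_ids=clusters.table["cluster_id"].tolist(),
        )

    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(cfg).items()},
        "n_subjects_input": len(cohort.records),
        "n_subjects_kept": len(kept_ids),
        "excluded_subjects": excluded_ids,
        "mc_cluster_threshold_voxels": int(k_min),
        "mc_cluster_threshold_voxels_twosided": int(k_min_t),
        "ancova_df": list(fmap.df),
        "n_ancova_clusters": len(f_clusters),
        "n_posthoc_clusters": 0 if t_clusters is None else len(t_clusters),
        "deficit_scores": deficit,
        "n_correlations": len(corr),
        "n_significant_correlations": int(corr["significant"].sum()) if len(corr) else 0,
        "wmh_flagged_patients": int(wmh_flags.sum()) if len(patient_idx) else 0,
        "runtime_s": round(time.time() - t0, 2),
    }
    if out is not None:
        io_mod.write_stat_map(out / "ancova_F.nii.gz", fmap)
        io_mod.write_stat_map(out / "posthoc_t.nii.gz", tmap)
        io_mod.write_table(out / "qc_report.tsv", qc)
        io_mod.write_table(out / "clusters.tsv", clusters.table)
        if wmh_table is not None:
            io_mod.write_table(out / "wmh_subgroup.tsv", wmh_table)
        if len(corr):
            io_mod.write_table(out / "correlations.tsv", corr)
        io_mod.write_table(out / "cohort_kept.tsv", table)
        io_mod.write_manifest(out / "manifest.json", manifest)
    log.info("pipeline complete in %.1fs", manifest["runtime_s"])
    return manifest


def default_effects(
    n_per_group: int = 8,
    scd_multiplier: float = 1.0,
    target_region: str = "ACC-like",
) -> list[GroupEffectSpec]:
    """Three-group cohort layout with an optional planted patient effect."""
    scores = {
        "FSIQ": ScoreModel(mean=100.0, sd=15.0),
        "PRI": ScoreModel(mean=100.0, sd=15.0),
    }
    deficit_scores = {
        "FSIQ": ScoreModel(mean=90.0, sd=15.0),
        "PRI": ScoreModel(mean=92.0, sd=15.0),
    }
    return [
        GroupEffectSpec(
            group="CTL", n_subjects=n_per_group, age_range=(20.0, 45.0),
            score_models=scores, wmh_rate=0.0,
        ),
        GroupEffectSpec(
            group="ACTL", n_subjects=n_per_group, age_range=(18.0, 42.0),
            score_models=scores, wmh_rate=0.1,
        ),
        GroupEffectSpec(
            group="SCD", n_subjects=n_per_group, age_range=(18.0, 42.0),
            amplitude_multiplier={} if scd_multiplier == 1.0 else {target_region: scd_multiplier},
            score_models=deficit_scores, wmh_rate=0.3,
        ),
    ]


def run_demo(
    out_dir: str | Path | None = None,
    master_seed: int = 0,
    n_per_group: int = 6,
    scd_multiplier: float = 1.5,
    mc_iter: int = 2000,
) -> dict:
    """Small end-to-end demonstration on the default phantom."""
    spec = PhantomSpec(seed=master_seed)
    cohort = simulate_cohort(
        spec, default_effects(n_per_group, scd_multiplier), master_seed
    )
    cfg = PipelineConfig(mc_iter=mc_iter, seed=master_seed)
    return run_pipeline(cohort, cfg, out_dir)
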