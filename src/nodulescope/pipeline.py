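"""End-to-end orchestration of the synthetic two-modality study.

``run_pipeline`` generates a Raman and an AFM cohort from one design,
pushes them through feature extraction / classification / curve analytics,
runs the nonparametric group comparisons, and writes every table (plus a
provenance block) to the output directory. Deterministic given
(config, seed); failures on individual samples are isolated and flagged
rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import afm, raman, stats, synth
from .io import RunConfig, write_provenance, write_spectra_matrix

logger = logging.getLogger(__name__)

__all__ = ["ResultBundle", "run_pipeline"]


@dataclass
class ResultBundle:
    """Every table the pipeline produced, keyed by name."""

    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    reports: Dict[str, object] = field(default_factory=dict)


def _design(cfg: RunConfig) -> synth.CohortDesign:
    offsets = {
        g: synth.GroupOffsets(
            po4_position_shift_cm1=o.get("po4_position_shift_cm1", 0.0),
            amide_area_scale=o.get("amide_area_scale", 1.0),
            e_scale=o.get("e_scale", 1.0),
        )
        for g, o in cfg.offsets.items()
    }
    return synth.CohortDesign(
        groups=list(cfg.groups), n_per_group=cfg.n_per_group,
        offsets=offsets, seed=cfg.seed,
    )


def run_pipeline(cfg: Optional[RunConfig] = None, write: bool = True) -> ResultBundle:
    cfg = cfg or RunConfig()
    design = _design(cfg)
    bundle = ResultBundle()

    # --- Raman arm -------------------------------------------------------
    spectra, raman_truth = synth.generate_cohort(design, "raman")
    fcfg = raman.FeatureConfig(
        po4_window=tuple(cfg.po4_window),
        amide_window=tuple(cfg.amide_window),
        exclusion_threshold=cfg.exclude_below,
    )
    processed = raman.process_cohort(
        spectra, fcfg,
        smooth_window=cfg.smooth_window, smooth_order=cfg.smooth_order,
        baseline_degree=cfg.baseline_degree,
    )
    bundle.tables["raman_ground_truth"] = raman_truth
    bundle.tables["raman_features_raw"] = processed["features_raw"]
    bundle.tables["raman_features_msc"] = processed["features_msc"]

    kept_ids = {f.sample_id for f in processed["kept"]}
    corrected = [sp for sp in processed["corrected"] if sp.sample_id in kept_ids]
    if len(corrected) >= max(cfg.cv_splits, cfg.n_components + 1):
        msc = raman.msc_normalize(corrected)
        X = np.vstack([r.corrected.intensities for r in msc])
        labels = [r.corrected.group for r in msc]
        report = raman.cross_validate_plsda(
            X, labels, n_components=cfg.n_components, splits=cfg.cv_splits
        )
        bundle.reports["plsda"] = report
        bundle.tables["plsda_report"] = report.table.reset_index()
    else:
        logger.warning(
            "multivariate stage skipped: only %d spectra pass the exclusion "
            "filter", len(corrected),
        )

    groups = list(cfg.groups)
    if len(groups) >= 2:
        diffs = []
        for other in groups[1:]:
            _, _, diff = raman.group_mean_and_difference(corrected, groups[0], other) \
                if any(sp.group == other for sp in corrected) and \
                   any(sp.group == groups[0] for sp in corrected) else (None, None, None)
            if diff is not None:
                diffs.append((f"{groups[0]}-{other}", diff))
        if diffs:
            axis = diffs[0][1].wavenumbers
            dtab = pd.DataFrame({"wavenumber_cm-1": axis})
            for name, d in diffs:
                dtab[name] = d.intensities
            bundle.tables["difference_spectra"] = dtab

    # --- AFM arm ---------------------------------------------------------
    curves, afm_truth = synth.generate_cohort(design, "afm")
    geo = afm.IndenterGeometry(
        shape=cfg.geometry_shape,
        face_half_angle_deg=cfg.half_angle_deg,
        poisson_sample=cfg.poisson,
    )
    metrics = afm.analyze_curves(curves, geo, noise_band_factor=cfg.noise_band_factor)
    summaries, pooled = afm.aggregate(metrics)
    bundle.tables["afm_ground_truth"] = afm_truth
    bundle.tables["afm_curve_metrics"] = metrics
    bundle.tables["afm_nodule_medians"] = pooled

    # --- Statistics ------------------------------------------------------
    stat_rows = []
    for table, metric in (
        (processed["features_raw"], "po4_position_cm-1"),
        (processed["features_msc"], "mineral_to_matrix"),
        (metrics, "E_Pa"),
        (metrics, "W_adh_fJ"),
    ):
        if metric not in table.columns or table.empty:
            continue
        by_group = {
            str(g): sub[metric].dropna().to_numpy()
            for g, sub in table.groupby("group", sort=True)
            if sub[metric].dropna().size > 0
        }
        if len(by_group) < 2:
            continue
        grouped = stats.GroupedValues(by_group, metric=metric)
        h, p = stats.kruskal_wallis(grouped)
        stat_rows.append({"test": "kruskal_wallis", "metric": metric,
                          "statistic": h, "df": len(by_group) - 1, "p": p})
        dunn = stats.dunn_posthoc(grouped)
        for _, row in dunn.iterrows():
            stat_rows.append({
                "test": f"dunn[{row.group_a} vs {row.group_b}]", "metric": metric,
                "statistic": row.z, "df": np.nan, "p": row.p_raw,
                "p_adj": row.p_adj,
            })
    bundle.tables["stats"] = pd.DataFrame(stat_rows)

    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in bundle.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        write_spectra_matrix(out / "spectra_corrected.tsv", processed["corrected"])
        write_provenance(out, cfg)
    return bundle
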