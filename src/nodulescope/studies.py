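"""Reference study designs exercising the pipeline end to end.

Each function sets up a seeded synthetic study at the package's standard
conditions, runs the relevant pipeline stages from scratch, and returns
summary accuracy/calibration numbers. They back both the validation suite
and the ``scripts/acceptance.py`` report.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.stats import mannwhitneyu

from . import afm, raman, stats, synth

__all__ = [
    "raman_recovery_study",
    "hertz_recovery_study",
    "plsda_separation_study",
    "plsda_permutation_null_study",
    "null_calibration_study",
    "directional_detection_study",
]

BASELINE_COEFFS = [120.0, -40.0, 25.0, 0.0, 0.0, 10.0]


def _recovery_truth() -> synth.RamanGroundTruth:
    """Bone-like truth at noise SD = 2% of the phosphate amplitude."""
    base = synth.default_raman_truth(baseline_coeffs=BASELINE_COEFFS)
    return synth.RamanGroundTruth(
        band_centers=base.band_centers,
        band_amplitudes=base.band_amplitudes,
        band_sigmas=base.band_sigmas,
        baseline_coeffs=base.baseline_coeffs,
        noise_sd=0.02 * base.band_amplitudes[base.po4_index],
    )


def raman_recovery_study(n_spectra: int = 100, seed: int = 0) -> Dict[str, float]:
    """Peak-parameter recovery over seeded noisy spectra.

    Runs smoothing, baseline correction and Gaussian quantification on
    ``n_spectra`` independent noise realisations of one bone-like ground
    truth; reports mean absolute errors of the phosphate position (cm^-1)
    and relative areas/ratio (percent).
    """
    truth = _recovery_truth()
    cfg = raman.FeatureConfig()
    windows = (cfg.po4_window, cfg.amide_window)
    pos_err, po4_err, amide_err, ratio_err = [], [], [], []
    for i in range(n_spectra):
        s = synth.generate_raman_spectrum(
            truth, seed=(seed * 100003 + i) % 2**31, sample_id=f"r{i}"
        )
        sm = raman.smooth_savgol(s)
        corr, _ = raman.correct_baseline(sm, exclude_windows=windows)
        f = raman.extract_features(corr, cfg)
        pos_err.append(abs(f.po4_position - truth.po4_position))
        po4_err.append(abs(f.po4_area / truth.po4_area - 1.0))
        amide_err.append(abs(f.amide1_area / truth.amide1_area - 1.0))
        ratio_err.append(abs(f.mineral_to_matrix / truth.mineral_to_matrix - 1.0))
    return {
        "position_mae_cm1": float(np.mean(pos_err)),
        "po4_area_mae_pct": float(100.0 * np.mean(po4_err)),
        "amide1_area_mae_pct": float(100.0 * np.mean(amide_err)),
        "mineral_to_matrix_mae_pct": float(100.0 * np.mean(ratio_err)),
        "n": n_spectra,
    }


def hertz_recovery_study(
    n_curves: int = 100, seed: int = 0, noise_frac_of_setpoint: float = 0.01
) -> Dict[str, float]:
    """Young's-modulus recovery from noisy pyramidal indentation curves.

    Noise SD is ``noise_frac_of_setpoint`` of the 3650 nN setpoint; the
    sample is a 2 GPa solid with Poisson's ratio 0.3.
    """
    ramp = synth.RampDesign()
    errs = []
    for i in range(n_curves):
        truth = synth.ForceCurveGroundTruth(
            noise_sd_nN=noise_frac_of_setpoint * ramp.setpoint_nN
        )
        c = synth.generate_force_curve(
            truth, ramp=ramp, seed=(seed * 99991 + i) % 2**31
        )
        res = afm.fit_hertz(c)
        errs.append(res.youngs_modulus_Pa / truth.youngs_modulus_Pa - 1.0)
    errs = np.asarray(errs)
    return {
        "median_error_pct": float(100.0 * np.median(errs)),
        "bias_pct": float(100.0 * errs.mean()),
        "n": n_curves,
    }


def _separable_design(seed: int, n_per_group: int = 20) -> synth.CohortDesign:
    """Three treatment groups separated far beyond the within-group noise."""
    return synth.CohortDesign(
        n_per_group=n_per_group,
        seed=seed,
        offsets={
            "DBeQ": synth.GroupOffsets(
                po4_position_shift_cm1=3.0, amide_area_scale=0.5
            ),
            "bortezomib": synth.GroupOffsets(
                po4_position_shift_cm1=-3.0, amide_area_scale=1.6
            ),
        },
    )


def _cohort_matrix(seed: int):
    spectra, _ = synth.generate_cohort(_separable_design(seed), "raman")
    proc = raman.process_cohort(spectra)
    kept_ids = {f.sample_id for f in proc["kept"]}
    corrected = [sp for sp in proc["corrected"] if sp.sample_id in kept_ids]
    msc = raman.msc_normalize(corrected)
    X = np.vstack([r.corrected.intensities for r in msc])
    labels = [r.corrected.group for r in msc]
    return X, labels


def plsda_separation_study(seed: int = 0) -> Dict[str, float]:
    """Cross-validated PLS-DA on a well-separated 3x20 synthetic cohort."""
    X, labels = _cohort_matrix(seed)
    report = raman.cross_validate_plsda(X, labels, n_components=6, splits=10)
    return {
        "max_class_error": float(report.table["classification_error"].max()),
        "min_fraction_classified": float(
            report.table["fraction_classified"].min()
        ),
        "n": len(labels),
    }


def plsda_permutation_null_study(
    seed: int = 0, n_shuffles: int = 20
) -> Dict[str, float]:
    """Label-permutation null: mean CV error should sit at chance (0.5 for
    the balanced one-vs-rest error convention)."""
    X, labels = _cohort_matrix(seed)
    rng = np.random.default_rng(seed + 1)
    errs = []
    for _ in range(n_shuffles):
        perm = rng.permutation(len(labels))
        rep = raman.cross_validate_plsda(
            X, [labels[i] for i in perm], n_components=6, splits=10
        )
        errs.append(float(rep.table["classification_error"].mean()))
    return {
        "mean_error": float(np.mean(errs)),
        "n": n_shuffles,
    }


def null_calibration_study(
    n_cohorts: int = 1000, seed: int = 0, group_size: int = 50
) -> Dict[str, float]:
    """Type-I error of the Kruskal-Wallis and trend tests at alpha = 0.05
    over null cohorts (three identically distributed groups)."""
    rng = np.random.default_rng(seed)
    kw_rej = trend_rej = trend_n = 0
    edges = np.linspace(-3.0, 3.0, 6)
    for _ in range(n_cohorts):
        g = stats.GroupedValues(
            {k: rng.normal(size=group_size) for k in ("a", "b", "c")}
        )
        kw_rej += stats.kruskal_wallis(g)[1] < 0.05
        table = stats.bin_values(g, edges)
        try:
            trend_rej += stats.linear_by_linear_trend(table).p_value < 0.05
            trend_n += 1
        except ValueError:  # degenerate draw (empty marginal)
            continue
    return {
        "kw_rate_pct": float(100.0 * kw_rej / n_cohorts),
        "trend_rate_pct": float(100.0 * trend_rej / max(trend_n, 1)),
        "n": n_cohorts,
    }


def directional_detection_study(
    n_replicates: int = 100,
    seed: int = 0,
    null: bool = False,
    n_per_group: int = 40,
    axis_step_cm1: float = 2.0,
) -> Dict[str, float]:
    """End-to-end directional reproduction of the treatment contrast.

    Each replicate simulates a control and a VCP/p97-inhibited-like group
    (phosphate position +1 cm^-1, Amide area x0.7, modulus x0.5 unless
    ``null``), runs the full Raman and AFM pipelines, and tests the three
    directional hypotheses with one-sided Mann-Whitney at alpha = 0.05.
    Returns per-metric detection rates in percent.
    """
    axis = synth.default_axis(step=axis_step_cm1)
    offsets = (
        {}
        if null
        else {
            "DBeQ": synth.GroupOffsets(
                po4_position_shift_cm1=1.0, amide_area_scale=0.7, e_scale=0.5
            )
        }
    )
    hits = np.zeros(3)
    for rep in range(n_replicates):
        design = synth.CohortDesign(
            groups=("control", "DBeQ"),
            n_per_group=n_per_group,
            seed=(seed * 61 + 7919 * rep + (1 if null else 0)) % 2**31,
            offsets=offsets,
        )
        spectra, _ = synth.generate_cohort(design, "raman", axis=axis)
        proc = raman.process_cohort(spectra)
        raw, mscf = proc["features_raw"], proc["features_msc"]
        curves, _ = synth.generate_cohort(design, "afm")
        metrics = afm.analyze_curves(curves)
        ok = metrics[metrics["status"] == "ok"]

        def grp(tab, col, g):
            return tab[tab["group"] == g][col].dropna()

        p_pos = mannwhitneyu(
            grp(raw, "po4_position_cm-1", "DBeQ"),
            grp(raw, "po4_position_cm-1", "control"),
            alternative="greater",
        ).pvalue
        p_ratio = mannwhitneyu(
            grp(mscf, "mineral_to_matrix", "DBeQ"),
            grp(mscf, "mineral_to_matrix", "control"),
            alternative="greater",
        ).pvalue
        p_e = mannwhitneyu(
            grp(ok, "E_Pa", "DBeQ"),
            grp(ok, "E_Pa", "control"),
            alternative="less",
        ).pvalue
        hits += np.array([p_pos, p_ratio, p_e]) < 0.05
    rates = 100.0 * hits / n_replicates
    return {
        "position_rate_pct": float(rates[0]),
        "mineral_to_matrix_rate_pct": float(rates[1]),
        "modulus_rate_pct": float(rates[2]),
        "n": n_replicates,
    }
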