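"""Raman spectral pipeline for mineralised-nodule characterisation.

Stages, in pipeline order: Savitzky-Golay smoothing, iterative-reweighted
polynomial baseline correction, single-Gaussian peak quantification of the
phosphate nu1 (~960 cm^-1) and Amide I (~1660 cm^-1) bands, multiplicative
scatter correction (MSC) across a spectrum set, mineral-to-matrix ratio,
exclusion filtering on phosphate peak area, group mean/difference spectra,
and PLS-DA classification cross-validated with venetian blinds.

Peak position is taken from the smoothed, baseline-corrected (but
un-normalised) spectra — position is scale-invariant — while the
mineral-to-matrix ratio is recomputed on MSC-corrected spectra; both feature
tables are produced.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from sklearn.cross_decomposition import PLSRegression

from .datatypes import RamanSpectrum

__all__ = [
    "NoPeakError",
    "PeakFit",
    "SpectralFeatures",
    "MscResult",
    "FeatureConfig",
    "PlsdaModel",
    "PlsdaReport",
    "smooth_savgol",
    "correct_baseline",
    "fit_peak",
    "msc_normalize",
    "extract_features",
    "filter_by_po4_area",
    "group_mean_and_difference",
    "fit_plsda",
    "cross_validate_plsda",
    "venetian_blinds_folds",
    "process_cohort",
]

logger = logging.getLogger(__name__)

SQRT_2PI = math.sqrt(2.0 * math.pi)


class NoPeakError(ValueError):
    """Raised when a fit window contains no signal above the noise floor."""


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class PeakFit:
    """Single-Gaussian fit over a wavenumber window.

    ``area`` is the analytic Gaussian area amplitude * sigma * sqrt(2 pi);
    ``offset`` is the fitted additive constant (0 if disabled);
    ``at_boundary`` flags fits whose center hit the window edge.
    """

    center: float
    amplitude: float
    sigma: float
    area: float
    rmse: float
    window: Tuple[float, float]
    offset: float = 0.0
    at_boundary: bool = False


@dataclass
class SpectralFeatures:
    """Per-spectrum quantified features."""

    sample_id: str
    group: Optional[str]
    po4_area: float
    po4_position: float
    amide1_area: float
    mineral_to_matrix: float  # NaN when the Amide I area is not positive
    included: bool
    po4_at_boundary: bool = False

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.mineral_to_matrix)


@dataclass
class MscResult:
    """Multiplicative scatter correction of one spectrum against a reference.

    corrected = (original - offset) / slope, with (offset, slope) the OLS
    regression of the spectrum on the reference.
    """

    corrected: RamanSpectrum
    offset: float
    slope: float
    reference_id: str


@dataclass
class FeatureConfig:
    """Windows and exclusion threshold for feature extraction."""

    po4_window: Tuple[float, float] = (930.0, 990.0)
    amide_window: Tuple[float, float] = (1620.0, 1700.0)
    exclusion_threshold: float = 500.0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def smooth_savgol(
    s: RamanSpectrum, window_points: int = 5, poly_order: int = 2
) -> RamanSpectrum:
    """Savitzky-Golay least-squares polynomial convolution smoothing.

    Endpoints are handled by polynomial extrapolation of the edge window
    (scipy's ``mode="interp"``). A degree-``poly_order`` filter reproduces
    polynomials of that degree exactly.
    """
    if window_points % 2 == 0:
        raise ValueError("window_points must be odd")
    if window_points <= poly_order:
        raise ValueError("window_points must exceed poly_order")
    if len(s) < window_points:
        raise ValueError("spectrum shorter than the smoothing window")
    sm = savgol_filter(s.intensities, window_points, poly_order, mode="interp")
    return s.replace_intensities(sm)


def correct_baseline(
    s: RamanSpectrum,
    degree: int = 5,
    max_iter: int = 100,
    tol: float = 1e-6,
    eps: object = "auto",
    exclude_windows: Optional[Sequence[Tuple[float, float]]] = None,
) -> Tuple[RamanSpectrum, RamanSpectrum]:
    """Iterative reweighted polynomial background correction.

    Fits a degree-``degree`` polynomial, discards points lying above the
    current fit by more than ``eps`` (peaks), and refits until the relative
    L2 change of the baseline drops below ``tol`` or ``max_iter`` is hit.
    ``eps="auto"`` clips at 2x the robust (MAD-based) residual scale, which
    keeps the baseline centred in the noise instead of drifting to its
    lower envelope; a float gives an absolute clip height.
    ``exclude_windows`` removes known analysis bands from the baseline fit
    entirely (anchor-region practice), so broad-band wings cannot pull the
    polynomial upward under a quantified peak. Returns
    ``(corrected, baseline)``; non-convergence is logged as a warning but
    the result is still returned.
    """
    if len(s) <= degree + 1:
        raise ValueError("spectrum too short for the requested degree")
    x, y = s.wavenumbers, s.intensities
    if np.all(y == 0):
        zero = np.zeros_like(y)
        return s.replace_intensities(zero), s.replace_intensities(zero)
    allow = np.ones(y.size, dtype=bool)
    for lo, hi in exclude_windows or ():
        allow &= ~((x >= lo) & (x <= hi))
    if allow.sum() <= degree + 1:
        raise ValueError("exclusion windows leave too few baseline points")
    mask = allow.copy()
    baseline = np.zeros_like(y)
    converged = False
    for _ in range(max_iter):
        coeffs = np.polynomial.Polynomial.fit(x[mask], y[mask], degree)
        new_baseline = coeffs(x)
        denom = np.linalg.norm(baseline)
        change = np.linalg.norm(new_baseline - baseline) / (denom + 1e-300)
        baseline = new_baseline
        if change < tol:
            converged = True
            break
        resid = y - baseline
        if eps == "auto":
            r = resid[mask]
            clip = 2.0 * 1.4826 * float(np.median(np.abs(r - np.median(r))))
        else:
            clip = float(eps)  # type: ignore[arg-type]
        new_mask = allow & (y <= baseline + clip)
        if new_mask.sum() <= degree + 1:  # keep the fit solvable
            break
        mask = new_mask
    if not converged:
        logger.warning(
            "baseline correction did not converge for %r within %d iterations",
            s.sample_id,
            max_iter,
        )
    corrected = y - baseline
    return s.replace_intensities(corrected), s.replace_intensities(baseline)


# ---------------------------------------------------------------------------
# Peak quantification
# ---------------------------------------------------------------------------


def _gauss_offset(x, amp, center, sigma, offset):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + offset


def _gauss(x, amp, center, sigma):
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_peak(
    s: RamanSpectrum,
    window: Tuple[float, float],
    p0: Optional[Sequence[float]] = None,
    with_offset: bool = True,
    noise_floor: float = 0.0,
) -> PeakFit:
    """Nonlinear least-squares single-Gaussian fit over ``window``.

    The model is amp * exp(-(x-c)^2 / (2 sigma^2)) plus, by default, an
    additive constant absorbing residual background. Raises
    :class:`NoPeakError` when the window's dynamic range does not exceed
    ``noise_floor``.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if mask.sum() < 8:
        raise ValueError("fewer than 8 points in the fit window")
    x = s.wavenumbers[mask]
    y = s.intensities[mask]
    span = float(y.max() - y.min())
    if span <= noise_floor:
        raise NoPeakError(f"no signal above noise floor in window {window}")
    if p0 is None:
        base0 = float(y.min())
        amp0 = span
        c0 = float(x[np.argmax(y)])
        # moment-based width guess from the area above the floor
        width0 = max(
            float(np.trapezoid(np.clip(y - base0, 0, None), x)) / (amp0 * SQRT_2PI),
            (x[1] - x[0]),
        )
        p0 = (amp0, c0, width0) + ((base0,) if with_offset else ())
    model = _gauss_offset if with_offset else _gauss
    lower = [0.0, lo, 1e-6] + ([-np.inf] if with_offset else [])
    upper = [np.inf, hi, (hi - lo)] + ([np.inf] if with_offset else [])
    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"peak fit failed to converge in window {window}: {exc}"
        ) from exc
    amp, center, sigma = popt[:3]
    offset = float(popt[3]) if with_offset else 0.0
    resid = y - model(x, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    edge = 1e-6 * (hi - lo)
    at_boundary = bool(center <= lo + edge or center >= hi - edge)
    return PeakFit(
        center=float(center),
        amplitude=float(amp),
        sigma=float(sigma),
        area=float(amp * sigma * SQRT_2PI),
        rmse=rmse,
        window=(lo, hi),
        offset=offset,
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# Normalisation and features
# ---------------------------------------------------------------------------


def msc_normalize(
    spectra: Sequence[RamanSpectrum],
    reference: Optional[RamanSpectrum] = None,
) -> List[MscResult]:
    """Multiplicative scatter correction against a common reference.

    Each spectrum is regressed (OLS) on the reference: y ~ a + b * ref;
    the corrected spectrum is (y - a) / b. The default reference is the
    mean spectrum of the set.
    """
    spectra = list(spectra)
    if reference is None:
        if len(spectra) < 2:
            raise ValueError("need >= 2 spectra to form a mean reference")
        axis0 = spectra[0].wavenumbers
        for sp in spectra[1:]:
            if not np.array_equal(sp.wavenumbers, axis0):
                raise ValueError("all spectra must share one wavenumber axis")
        reference = RamanSpectrum(
            axis0,
            np.mean([sp.intensities for sp in spectra], axis=0),
            sample_id="mean",
        )
    else:
        for sp in spectra:
            if not np.array_equal(sp.wavenumbers, reference.wavenumbers):
                raise ValueError("spectrum axis differs from the reference axis")
    ref = reference.intensities
    ref_var = float(np.var(ref))
    if ref_var == 0:
        raise ValueError("reference spectrum has zero variance")
    ref_mean = float(ref.mean())
    out = []
    for sp in spectra:
        y = sp.intensities
        b = float(np.mean((ref - ref_mean) * (y - y.mean())) / ref_var)
        a = float(y.mean() - b * ref_mean)
        corrected = sp.replace_intensities((y - a) / b)
        out.append(
            MscResult(
                corrected=corrected, offset=a, slope=b,
                reference_id=reference.sample_id,
            )
        )
    return out


def extract_features(
    s: RamanSpectrum, config: Optional[FeatureConfig] = None
) -> SpectralFeatures:
    """Quantify one (already smoothed and baseline-corrected) spectrum.

    Fits the phosphate nu1 and Amide I windows, forms the mineral-to-matrix
    ratio and applies the exclusion rule (phosphate area below the
    threshold). A non-positive Amide I area yields an undefined (NaN) ratio.
    """
    cfg = config or FeatureConfig()
    # pure 3-parameter Gaussians: the baseline stage anchors the analysis
    # windows to zero local offset, and a free offset is near-degenerate
    # with the wings of the broad Amide I band in an 80 cm^-1 window
    po4 = fit_peak(s, cfg.po4_window, with_offset=False)
    amide = fit_peak(s, cfg.amide_window, with_offset=False)
    if amide.area > 0:
        ratio = po4.area / amide.area
    else:
        ratio = float("nan")
        logger.warning("undefined mineral-to-matrix ratio for %r", s.sample_id)
    return SpectralFeatures(
        sample_id=s.sample_id,
        group=s.group,
        po4_area=po4.area,
        po4_position=po4.center,
        amide1_area=amide.area,
        mineral_to_matrix=ratio,
        included=po4.area >= cfg.exclusion_threshold,
        po4_at_boundary=po4.at_boundary,
    )


def filter_by_po4_area(
    features: Iterable[SpectralFeatures], threshold: float = 500.0
) -> Tuple[List[SpectralFeatures], List[SpectralFeatures]]:
    """Exclude spectra whose phosphate nu1 peak area is below ``threshold``.

    Strict "less than" semantics: an area exactly at the threshold is kept.
    """
    kept, excluded = [], []
    for f in features:
        (kept if f.po4_area >= threshold else excluded).append(f)
    if not kept:
        logger.warning("exclusion filter removed every spectrum")
    logger.info("exclusion filter: kept %d, excluded %d", len(kept), len(excluded))
    return kept, excluded


def group_mean_and_difference(
    spectra: Sequence[RamanSpectrum], group_a: str, group_b: str
) -> Tuple[RamanSpectrum, RamanSpectrum, RamanSpectrum]:
    """Pointwise group means and their difference (mean_a - mean_b)."""
    in_a = [sp for sp in spectra if sp.group == group_a]
    in_b = [sp for sp in spectra if sp.group == group_b]
    if not in_a or not in_b:
        raise ValueError(f"empty group among {group_a!r}, {group_b!r}")
    axis = in_a[0].wavenumbers
    for sp in in_a + in_b:
        if not np.array_equal(sp.wavenumbers, axis):
            raise ValueError("spectra must share one wavenumber axis")
    mean_a = np.mean([sp.intensities for sp in in_a], axis=0)
    mean_b = np.mean([sp.intensities for sp in in_b], axis=0)
    return (
        RamanSpectrum(axis, mean_a, sample_id=f"mean[{group_a}]", group=group_a),
        RamanSpectrum(axis, mean_b, sample_id=f"mean[{group_b}]", group=group_b),
        RamanSpectrum(axis, mean_a - mean_b, sample_id=f"diff[{group_a}-{group_b}]"),
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PlsdaModel:
    """PLS2 regression of one-hot class codes on spectra.

    A sample is "classified" when exactly one class's predicted coded value
    exceeds ``decision_threshold``; it is then assigned to that class.
    """

    pls: PLSRegression
    classes: List[str]
    n_components: int
    decision_threshold: float = 0.5

    def predict_coded(self, X: np.ndarray) -> np.ndarray:
        return self.pls.predict(np.asarray(X, float))

    def classify(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Return (assigned class index or -1 per sample, classified mask)."""
        coded = self.predict_coded(X)
        above = coded > self.decision_threshold
        classified = above.sum(axis=1) == 1
        assigned = np.where(classified, np.argmax(coded, axis=1), -1)
        return assigned, classified


@dataclass
class PlsdaReport:
    """Per-class cross-validated classification rates (one-vs-rest)."""

    table: pd.DataFrame  # index: class; columns: fraction_classified,
    # sensitivity, specificity, classification_error
    n_components: int
    scheme: str


def _one_hot(labels: Sequence[str]) -> Tuple[np.ndarray, List[str]]:
    classes = sorted(set(labels))
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        y[i, classes.index(lab)] = 1.0
    return y, classes


def fit_plsda(
    X: np.ndarray, labels: Sequence[str], n_components: int = 6
) -> PlsdaModel:
    """Fit a PLS-DA model (PLS2/NIPALS latent variables, one-hot codes)."""
    X = np.asarray(X, float)
    n, p = X.shape
    if n_components <= 0 or n_components >= min(n, p) + 1:
        raise ValueError("n_components out of range for the data shape")
    if n <= n_components:
        raise ValueError("need more samples than components")
    Y, classes = _one_hot(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign y-residual-constant warnings
        pls.fit(X, Y)
    return PlsdaModel(pls=pls, classes=classes, n_components=n_components)


def venetian_blinds_folds(n_samples: int, splits: int = 10) -> List[np.ndarray]:
    """Fold k holds the samples at positions {i : i mod splits == k}."""
    if splits > n_samples:
        raise ValueError("more splits than samples")
    idx = np.arange(n_samples)
    return [idx[idx % splits == k] for k in range(splits)]


def cross_validate_plsda(
    X: np.ndarray,
    labels: Sequence[str],
    n_components: int = 6,
    splits: int = 10,
    decision_threshold: float = 0.5,
) -> PlsdaReport:
    """Venetian-blinds cross-validation of PLS-DA.

    Out-of-fold coded predictions are pooled, then per class (one-vs-rest,
    over classified samples only): sensitivity, specificity,
    classification_error = 1 - (sensitivity + specificity)/2, and the
    fraction of that class's samples that were classified at all.
    """
    X = np.asarray(X, float)
    labels = list(labels)
    n = X.shape[0]
    folds = venetian_blinds_folds(n, splits)
    classes = sorted(set(labels))
    coded = np.full((n, len(classes)), np.nan)
    for hold in folds:
        train = np.setdiff1d(np.arange(n), hold)
        model = fit_plsda(X[train], [labels[i] for i in train], n_components)
        # align columns in case a class is absent from this training fold
        pred = model.predict_coded(X[hold])
        for j, cls in enumerate(classes):
            if cls in model.classes:
                coded[hold, j] = pred[:, model.classes.index(cls)]
            else:
                coded[hold, j] = 0.0
    above = coded > decision_threshold
    classified = above.sum(axis=1) == 1
    assigned = np.where(classified, np.argmax(coded, axis=1), -1)
    y_true = np.array([classes.index(lab) for lab in labels])
    rows = {}
    for j, cls in enumerate(classes):
        is_cls = y_true == j
        n_cls = int(is_cls.sum())
        cls_classified = classified & is_cls
        rest_classified = classified & ~is_cls
        sens = (
            float((assigned[cls_classified] == j).mean())
            if cls_classified.any()
            else float("nan")
        )
        spec = (
            float((assigned[rest_classified] != j).mean())
            if rest_classified.any()
            else float("nan")
        )
        rows[cls] = {
            "fraction_classified": float(cls_classified.sum() / n_cls)
            if n_cls
            else float("nan"),
            "sensitivity": sens,
            "specificity": spec,
            "classification_error": 1.0 - 0.5 * (sens + spec),
        }
    table = pd.DataFrame(rows).T
    table.index.name = "class"
    return PlsdaReport(
        table=table,
        n_components=n_components,
        scheme=f"venetian_blinds(splits={splits})",
    )


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------


def process_cohort(
    spectra: Sequence[RamanSpectrum],
    config: Optional[FeatureConfig] = None,
    smooth_window: int = 5,
    smooth_order: int = 2,
    baseline_degree: int = 5,
) -> Dict[str, object]:
    """Run the univariate pipeline over a spectrum set.

    smooth -> baseline-correct -> raw features (position + areas) ->
    exclusion filter -> MSC over the kept corrected spectra -> MSC-stage
    features (areas + mineral-to-matrix). Returns a dict with the corrected
    spectra, both feature tables and the MSC results.
    """
    cfg = config or FeatureConfig()
    corrected: List[RamanSpectrum] = []
    feats: List[SpectralFeatures] = []
    windows = (cfg.po4_window, cfg.amide_window)
    for sp in spectra:
        sm = smooth_savgol(sp, smooth_window, smooth_order)
        corr, _ = correct_baseline(
            sm, degree=baseline_degree, exclude_windows=windows
        )
        corrected.append(corr)
        feats.append(extract_features(corr, cfg))
    kept, excluded = filter_by_po4_area(feats, cfg.exclusion_threshold)
    kept_ids = {f.sample_id for f in kept}
    kept_spectra = [sp for sp in corrected if sp.sample_id in kept_ids]
    msc_results: List[MscResult] = []
    msc_feats: List[SpectralFeatures] = []
    if len(kept_spectra) >= 2:
        msc_results = msc_normalize(kept_spectra)
        for r in msc_results:
            msc_feats.append(extract_features(r.corrected, cfg))
    features_raw = _features_frame(feats)
    features_msc = _features_frame(msc_feats)
    return {
        "corrected": corrected,
        "features_raw": features_raw,
        "features_msc": features_msc,
        "kept": kept,
        "excluded": excluded,
        "msc": msc_results,
    }


def _features_frame(feats: Sequence[SpectralFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "group": f.group,
                "po4_area": f.po4_area,
                "po4_position_cm-1": f.po4_position,
                "amide1_area": f.amide1_area,
                "mineral_to_matrix": f.mineral_to_matrix,
                "included": f.included,
            }
            for f in feats
        ],
        columns=[
            "sample_id",
            "group",
            "po4_area",
            "po4_position_cm-1",
            "amide1_area",
            "mineral_to_matrix",
            "included",
        ],
    )
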