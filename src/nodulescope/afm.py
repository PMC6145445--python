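"""AFM force-indentation analytics.

Approach-side: robust baseline/noise estimation, sustained-threshold
contact-point detection, and Hertz-model fitting of the Young's modulus for
pyramidal, conical or paraboloidal indenters with the cantilever-deflection
correction delta = (z0 - z) - (F - b)/k.

Retraction-side: maximum adhesion force, maximum length of adhesion
interactions (separation of the last sub-baseline excursion) and dissipated
adhesion energy (trapezoidal work over all sub-baseline regions), all
evaluated on the tip-sample separation axis s = (z - z0) + (F - b)/k.

Aggregation follows the measurement hierarchy: curves -> per-location
medians -> per-nodule medians -> pooled treatment-group distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import ForceCurve

__all__ = [
    "IndenterGeometry",
    "IndentationResult",
    "AdhesionMetrics",
    "NoduleSummary",
    "split_segments",
    "estimate_baseline",
    "detect_contact",
    "fit_hertz",
    "compute_adhesion",
    "analyze_curve",
    "analyze_curves",
    "aggregate",
]

logger = logging.getLogger(__name__)


@dataclass
class IndenterGeometry:
    """Indenter shape and elastic constants.

    pyramid: F = 0.7453 tan(alpha) * E' * delta^2   (Bilodeau, four-sided)
    cone:    F = (2/pi) tan(alpha) * E' * delta^2   (Sneddon)
    paraboloid: F = (4/3) sqrt(R) * E' * delta^(3/2)

    where E' = E/(1 - nu_s^2) for a rigid tip (default). With
    ``rigid_tip=False`` the reduced-modulus form 1/E* = (1-nu_s^2)/E +
    (1-nu_t^2)/E_t is inverted using the tip modulus ``tip_modulus_Pa``.
    """

    shape: str = "pyramid"
    face_half_angle_deg: Optional[float] = 20.0
    tip_radius_nm: Optional[float] = None
    poisson_sample: float = 0.3
    poisson_tip: float = 0.3
    rigid_tip: bool = True
    tip_modulus_Pa: float = 170e9  # silicon

    def __post_init__(self) -> None:
        if self.shape not in ("pyramid", "cone", "paraboloid"):
            raise ValueError(f"unknown indenter shape {self.shape!r}")
        if self.shape in ("pyramid", "cone"):
            if self.face_half_angle_deg is None or not (
                0.0 < self.face_half_angle_deg < 90.0
            ):
                raise ValueError("pyramid/cone require 0 < half-angle < 90 deg")
        else:
            if self.tip_radius_nm is None or self.tip_radius_nm <= 0:
                raise ValueError("paraboloid requires a positive tip radius")
        for nu in (self.poisson_sample, self.poisson_tip):
            if not (0.0 <= nu < 0.5):
                raise ValueError("Poisson's ratio must lie in [0, 0.5)")

    @property
    def prefactor_exponent(self) -> Tuple[float, float]:
        """(C, p) of F = C * E' * delta^p with delta in nm, E' in nN/nm^2."""
        if self.shape == "pyramid":
            return 0.7453 * math.tan(math.radians(self.face_half_angle_deg)), 2.0
        if self.shape == "cone":
            return (2.0 / math.pi) * math.tan(
                math.radians(self.face_half_angle_deg)
            ), 2.0
        return (4.0 / 3.0) * math.sqrt(self.tip_radius_nm), 1.5

    def modulus_from_reduced(self, e_prime_Pa: float) -> float:
        """Convert the fitted E' (Pa) to the sample Young's modulus (Pa)."""
        if self.rigid_tip:
            return e_prime_Pa * (1.0 - self.poisson_sample**2)
        inv_sample = 1.0 / e_prime_Pa - (1.0 - self.poisson_tip**2) / self.tip_modulus_Pa
        return (1.0 - self.poisson_sample**2) / inv_sample


@dataclass
class IndentationResult:
    youngs_modulus_Pa: float
    contact_point_nm: float
    fit_range_nm: Tuple[float, float]
    rmse_nN: float
    status: str = "ok"  # ok | flagged


@dataclass
class AdhesionMetrics:
    adhesion_force_nN: float
    adhesion_length_um: float
    adhesion_energy_fJ: float
    n_events: int


@dataclass
class NoduleSummary:
    nodule_id: str
    group: Optional[str]
    n_curves: int
    n_locations: int
    median_E_Pa: float
    median_F_adh_nN: float
    median_L_adh_um: float
    median_W_adh_fJ: float


# ---------------------------------------------------------------------------
# Segmentation and baseline
# ---------------------------------------------------------------------------


def split_segments(
    table: pd.DataFrame,
    curve_id: str = "",
    spring_constant_N_per_m: float = 16.0,
    setpoint_nN: float = 3650.0,
    **meta,
) -> ForceCurve:
    """Build a ForceCurve from a long-format table.

    The table needs ``height_nm`` and ``force_nN`` columns and either a
    ``segment`` column (approach/retract) or a detectable turning point
    (the single height minimum of the cycle). Approach heights are oriented
    decreasing toward the surface.
    """
    if "segment" in table.columns:
        app = table[table["segment"] == "approach"]
        ret = table[table["segment"] == "retract"]
        if len(app) == 0 or len(ret) == 0:
            raise ValueError("missing approach or retract segment")
    else:
        z = table["height_nm"].to_numpy(float)
        turn = int(np.argmin(z))
        if turn == 0 or turn == z.size - 1:
            raise ValueError("no turning point detectable: monotone height trace")
        app = table.iloc[: turn + 1]
        ret = table.iloc[turn:]
    z_app = app["height_nm"].to_numpy(float)
    f_app = app["force_nN"].to_numpy(float)
    if z_app.size >= 2 and z_app[0] < z_app[-1]:
        z_app, f_app = z_app[::-1], f_app[::-1]
    z_ret = ret["height_nm"].to_numpy(float)
    f_ret = ret["force_nN"].to_numpy(float)
    if z_ret.size >= 2 and z_ret[0] > z_ret[-1]:
        z_ret, f_ret = z_ret[::-1], f_ret[::-1]
    return ForceCurve(
        curve_id=curve_id,
        approach_height_nm=z_app,
        approach_force_nN=f_app,
        retract_height_nm=z_ret,
        retract_force_nN=f_ret,
        spring_constant_N_per_m=spring_constant_N_per_m,
        setpoint_nN=setpoint_nN,
        **meta,
    )


def estimate_baseline(
    heights_nm: np.ndarray, forces_nN: np.ndarray, fraction: float = 0.3
) -> Tuple[float, float]:
    """Robust baseline and noise from the off-contact (largest-height) end.

    Returns (median, 1.4826 * MAD) over the ``fraction`` of points farthest
    from the surface.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    z = np.asarray(heights_nm, float)
    f = np.asarray(forces_nN, float)
    n = z.size
    n_win = max(int(round(fraction * n)), 3)
    if n_win >= n:
        raise ValueError("segment shorter than the baseline window")
    far = np.argsort(z)[-n_win:]
    window = f[far]
    b = float(np.median(window))
    sigma = float(1.4826 * np.median(np.abs(window - b)))
    return b, sigma


def detect_contact(
    heights_nm: np.ndarray,
    forces_nN: np.ndarray,
    baseline_nN: float,
    noise_sd_nN: float,
    threshold_factor: float = 5.0,
    sustain: int = 5,
) -> float:
    """First sustained excursion of the approach force above baseline.

    Walking from far to near, the contact point is the height of the first
    point where F - b exceeds ``threshold_factor * sigma`` for ``sustain``
    consecutive points. This estimate seeds the Hertz fit, which refines z0
    as a free parameter.
    """
    z = np.asarray(heights_nm, float)
    f = np.asarray(forces_nN, float)
    order = np.argsort(z)[::-1]  # far -> near
    zz, ff = z[order], f[order]
    thresh = threshold_factor * noise_sd_nN
    above = ff - baseline_nN > thresh
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= sustain:
            return float(zz[i - sustain + 1])
    raise ValueError("no contact detected")


# ---------------------------------------------------------------------------
# Hertz fit
# ---------------------------------------------------------------------------


def _forward_force(d0: np.ndarray, a: float, k: float, p: float) -> np.ndarray:
    """Measured force at piezo depth d0 solving F = a * (d0 - F/k)^p.

    p = 2 has the cancellation-free closed form
    F = 2 a d0^2 / (1 + 2t + sqrt(1 + 4t)), t = a d0/k; other exponents
    use a few Newton steps on the strictly monotone residual.
    """
    if p == 2.0:
        t = a * d0 / k
        return 2.0 * a * d0 * d0 / (1.0 + 2.0 * t + np.sqrt(1.0 + 4.0 * t))
    f = a * np.maximum(d0, 0.0) ** p
    for _ in range(40):
        base = np.maximum(d0 - f / k, 0.0)
        g = a * base**p - f
        gp = -p * a / k * base ** (p - 1.0) - 1.0
        step = g / gp
        f = np.maximum(f - step, 0.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return f


def fit_hertz(
    curve: ForceCurve,
    geometry: Optional[IndenterGeometry] = None,
    baseline_nN: Optional[float] = None,
    noise_sd_nN: Optional[float] = None,
    min_indentation_nm: float = 5.0,
    pre_contact_nm: float = 150.0,
    refine_window_nm: float = 50.0,
) -> IndentationResult:
    """Least-squares Hertz fit of the approach segment.

    The model is F - b = A * delta^p with the deflection-corrected
    indentation delta = (z0 - z) - (F - b)/k, solved self-consistently for
    the predicted force at each piezo depth (plugging the *measured* noisy
    force into delta would attenuate the fitted stiffness, a classic
    errors-in-variables bias). Fitted over delta in
    [``min_indentation_nm``, delta_max] plus up to ``pre_contact_nm`` of
    the zero-force region before contact — the flat stretch pins the free
    contact point, which otherwise trades against the stiffness and biases
    it upward. z0 is constrained to ``refine_window_nm`` around the
    threshold-detected estimate. A non-positive fitted modulus is returned
    flagged.
    """
    geo = geometry or IndenterGeometry()
    z = curve.approach_height_nm
    f = curve.approach_force_nN
    if baseline_nN is None or noise_sd_nN is None:
        baseline_nN, noise_sd_nN = estimate_baseline(z, f)
    z0_init = detect_contact(z, f, baseline_nN, noise_sd_nN)
    k = curve.spring_constant_N_per_m
    c_geo, p_exp = geo.prefactor_exponent
    df = f - baseline_nN
    delta_init = (z0_init - z) - df / k
    beyond = delta_init >= min_indentation_nm
    if beyond.sum() < 20:
        raise ValueError("fewer than 20 points beyond contact")
    mask = beyond | ((delta_init <= 0) & (delta_init >= -pre_contact_nm))
    zm, dfm = z[mask], df[mask]
    a_init = float(
        np.median(dfm / np.maximum(delta_init[mask], 1e-9) ** p_exp)
    )
    a_init = max(a_init, 1e-12)

    def resid(params):
        log_a, z0 = params
        d0 = np.maximum(z0 - zm, 0.0)
        return _forward_force(d0, np.exp(log_a), k, p_exp) - dfm

    sol = least_squares(
        resid,
        x0=[math.log(a_init), z0_init],
        bounds=(
            [-np.inf, z0_init - refine_window_nm],
            [np.inf, z0_init + refine_window_nm],
        ),
    )
    a_fit = float(np.exp(sol.x[0]))
    z0_fit = float(sol.x[1])
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    e_prime_Pa = a_fit / c_geo * 1e9  # nN/nm^p -> Pa for p=2 geometry units
    e_Pa = geo.modulus_from_reduced(e_prime_Pa)
    delta_fit = np.maximum((z0_fit - zm) - dfm / k, 0.0)
    status = "ok"
    if not np.isfinite(e_Pa) or e_Pa <= 0 or not sol.success:
        status = "flagged"
        logger.warning("Hertz fit flagged for curve %r", curve.curve_id)
    return IndentationResult(
        youngs_modulus_Pa=e_Pa,
        contact_point_nm=z0_fit,
        fit_range_nm=(min_indentation_nm, float(delta_fit.max(initial=0.0))),
        rmse_nN=rmse,
        status=status,
    )


# ---------------------------------------------------------------------------
# Adhesion
# ---------------------------------------------------------------------------


def compute_adhesion(
    curve: ForceCurve,
    contact_point_nm: float,
    baseline_nN: Optional[float] = None,
    noise_sd_nN: Optional[float] = None,
    noise_band_factor: float = 3.0,
    min_event_points: int = 3,
    merge_gap_nm: float = 100.0,
    axis: str = "separation",
) -> AdhesionMetrics:
    """Retraction adhesion read-outs on the tip-sample separation axis.

    s = (z - z0) + (F - b)/k (or the raw height axis with
    ``axis="height"``). Adhesion force is the deepest sub-baseline force;
    adhesion length is the separation of the last point of the last
    sub-band excursion (excursions need >= ``min_event_points`` consecutive
    points below b - noise_band to suppress isolated spikes, and excursions
    closer than ``merge_gap_nm`` are one event — noise chatter where the
    event force crosses the band is far tighter spaced than the >= 0.1 um
    separating physically distinct ruptures); adhesion energy is the
    trapezoidal work over all sub-baseline regions, in fJ.
    """
    z = curve.retract_height_nm
    f = curve.retract_force_nN
    if baseline_nN is None or noise_sd_nN is None:
        baseline_nN, noise_sd_nN = estimate_baseline(z, f)
    k = curve.spring_constant_N_per_m
    post = z >= contact_point_nm
    if post.sum() < 2:
        raise ValueError("retraction does not extend past the contact point")
    zz = z[post]
    df = f[post] - baseline_nN
    order = np.argsort(zz)
    zz, df = zz[order], df[order]
    if axis == "separation":
        s_nm = (zz - contact_point_nm) + df / k
    elif axis == "height":
        s_nm = zz - contact_point_nm
    else:
        raise ValueError("axis must be 'separation' or 'height'")
    band = noise_band_factor * noise_sd_nN
    # events: runs of >= min_event_points consecutive points below -band,
    # merged across gaps shorter than merge_gap_nm
    sub = df < -band
    raw_runs: List[Tuple[int, int]] = []
    run_start = None
    for i, flag in enumerate(np.append(sub, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_event_points:
                raw_runs.append((run_start, i - 1))
            run_start = None
    runs: List[Tuple[int, int]] = []
    for start, end in raw_runs:
        if runs and s_nm[start] - s_nm[runs[-1][1]] < merge_gap_nm:
            runs[-1] = (runs[-1][0], end)
        else:
            runs.append((start, end))
    if not runs:
        return AdhesionMetrics(0.0, 0.0, 0.0, 0)
    f_adh = float(-df.min())
    l_um = max(float(s_nm[runs[-1][1]]) / 1000.0, 0.0)
    # energy: each excursion extended outward to its zero crossings, then
    # trapezoidal work over the (merged) sub-baseline regions
    n = df.size
    regions: List[Tuple[int, int]] = []
    for start, end in runs:
        while start > 0 and df[start - 1] < 0:
            start -= 1
        while end < n - 1 and df[end + 1] < 0:
            end += 1
        if regions and start <= regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], max(regions[-1][1], end))
        else:
            regions.append((start, end))
    w_fJ = 0.0
    for start, end in regions:
        # raw df (not clipped) keeps zero-mean noise unbiased in the region
        w_fJ += float(
            -np.trapezoid(df[start : end + 1], s_nm[start : end + 1])
        ) / 1000.0
    return AdhesionMetrics(
        adhesion_force_nN=f_adh,
        adhesion_length_um=l_um,
        adhesion_energy_fJ=max(w_fJ, 0.0),
        n_events=len(runs),
    )


# ---------------------------------------------------------------------------
# Per-curve driver and aggregation
# ---------------------------------------------------------------------------


def analyze_curve(
    curve: ForceCurve, geometry: Optional[IndenterGeometry] = None, **adhesion_kw
) -> Dict[str, object]:
    """Full per-curve read-out: baseline, Hertz modulus, adhesion metrics."""
    b_app, s_app = estimate_baseline(
        curve.approach_height_nm, curve.approach_force_nN
    )
    result: Dict[str, object] = {
        "curve_id": curve.curve_id,
        "location_id": curve.location_id,
        "nodule_id": curve.nodule_id,
        "group": curve.group,
    }
    try:
        ind = fit_hertz(curve, geometry, baseline_nN=b_app, noise_sd_nN=s_app)
    except ValueError as exc:
        logger.warning("curve %r: %s", curve.curve_id, exc)
        result.update(
            E_Pa=float("nan"), contact_point_nm=float("nan"), status="flagged"
        )
        return result
    # the free-air force zero is common to both segments; the approach-side
    # estimate avoids the adhesion events sitting in the retraction tail
    adh = compute_adhesion(
        curve,
        contact_point_nm=ind.contact_point_nm,
        baseline_nN=b_app,
        noise_sd_nN=s_app,
        **adhesion_kw,
    )
    result.update(
        E_Pa=ind.youngs_modulus_Pa,
        contact_point_nm=ind.contact_point_nm,
        F_adh_nN=adh.adhesion_force_nN,
        L_adh_um=adh.adhesion_length_um,
        W_adh_fJ=adh.adhesion_energy_fJ,
        n_events=adh.n_events,
        rmse_nN=ind.rmse_nN,
        status=ind.status,
    )
    return result


def analyze_curves(
    curves: Iterable[ForceCurve], geometry: Optional[IndenterGeometry] = None,
    **adhesion_kw,
) -> pd.DataFrame:
    """Per-curve metrics table for a collection of force curves."""
    rows = [analyze_curve(c, geometry, **adhesion_kw) for c in curves]
    return pd.DataFrame(rows)


def aggregate(metrics: pd.DataFrame) -> Tuple[List[NoduleSummary], pd.DataFrame]:
    """Hierarchical aggregation: location medians -> nodule medians ->
    pooled per-group value sets.

    Flagged curves are excluded. Returns (nodule summaries, pooled table
    of per-nodule medians with group labels), the pooled table feeding the
    stats module directly.
    """
    ok = metrics[metrics["status"] == "ok"].copy()
    summaries: List[NoduleSummary] = []
    pooled_rows = []
    value_cols = ["E_Pa", "F_adh_nN", "L_adh_um", "W_adh_fJ"]
    for nodule_id, nod in ok.groupby("nodule_id", sort=True):
        loc_medians = nod.groupby("location_id")[value_cols].median()
        nodule_median = loc_medians.median()
        group = nod["group"].iloc[0]
        summaries.append(
            NoduleSummary(
                nodule_id=str(nodule_id),
                group=group,
                n_curves=len(nod),
                n_locations=loc_medians.shape[0],
                median_E_Pa=float(nodule_median["E_Pa"]),
                median_F_adh_nN=float(nodule_median["F_adh_nN"]),
                median_L_adh_um=float(nodule_median["L_adh_um"]),
                median_W_adh_fJ=float(nodule_median["W_adh_fJ"]),
            )
        )
        pooled_rows.append(
            {
                "nodule_id": nodule_id,
                "group": group,
                **{c: float(nodule_median[c]) for c in value_cols},
            }
        )
    dropped = metrics.shape[0] - ok.shape[0]
    if dropped:
        logger.warning("aggregate: excluded %d flagged curves", dropped)
    return summaries, pd.DataFrame(pooled_rows)
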