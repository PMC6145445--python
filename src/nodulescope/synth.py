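"""Seeded generators of synthetic Raman spectra and AFM force curves.

The generators emulate the measurement model the analysis pipeline inverts:

* Raman: a sum of Gaussian bands (sharp phosphate nu1 band near 960 cm^-1,
  Amide I near 1660 cm^-1, plus cosmetic bands) on a smooth polynomial
  fluorescence background, distorted by a multiplicative scatter slope and
  additive offset, with additive Gaussian noise.
* AFM: a Hertzian approach (pyramidal indenter) with the cantilever
  deflection folded in self-consistently, mirrored on retraction with
  negative-force adhesion events of known rupture separation, peak force and
  dissipated energy.

Every generated object carries its ground truth so each downstream stage is
testable by parameter recovery. All randomness flows from one integer seed;
per-sample streams are derived by mixing the sample index into the seed, so
cohorts are order-independent and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import ForceCurve, RamanSpectrum

__all__ = [
    "RamanGroundTruth",
    "AdhesionEvent",
    "ForceCurveGroundTruth",
    "RampDesign",
    "CohortDesign",
    "GroupOffsets",
    "default_raman_truth",
    "default_axis",
    "generate_raman_spectrum",
    "generate_force_curve",
    "generate_cohort",
    "hertz_prefactor",
    "hertz_force",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Bilodeau constant for a four-sided pyramidal indenter: F = 0.7453 tan(a) E' d^2
PYRAMID_C = 0.7453


def default_axis(lo: float = 600.0, hi: float = 1800.0, step: float = 1.0) -> np.ndarray:
    """Default fingerprint-region wavenumber grid (cm^-1)."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


# ---------------------------------------------------------------------------
# Raman forward model
# ---------------------------------------------------------------------------


@dataclass
class RamanGroundTruth:
    """True parameters of one synthetic spectrum.

    ``baseline_coeffs`` are polynomial coefficients (lowest order first,
    degree <= 5) in the axis mapped affinely onto [-1, 1] — the natural,
    well-conditioned domain for a fingerprint-region background.
    ``scatter_slope``/``scatter_offset`` model multiplicative scatter
    distortion: observed = slope * clean + offset.
    """

    band_centers: Sequence[float]
    band_amplitudes: Sequence[float]
    band_sigmas: Sequence[float]
    baseline_coeffs: Sequence[float] = (0.0,)
    scatter_slope: float = 1.0
    scatter_offset: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.band_centers, float)
        a = np.asarray(self.band_amplitudes, float)
        s = np.asarray(self.band_sigmas, float)
        if not (c.size == a.size == s.size):
            raise ValueError("band parameter lists must have equal length")
        if np.any(s <= 0):
            raise ValueError("band sigmas must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(np.asarray(self.baseline_coeffs, float)) > 6:
            raise ValueError("baseline polynomial degree must be <= 5")

    def band_area(self, center: float, tol: float = 1.0) -> float:
        """Analytic area (amp * sigma * sqrt(2 pi)) of the band nearest ``center``."""
        c = np.asarray(self.band_centers, float)
        i = int(np.argmin(np.abs(c - center)))
        if abs(c[i] - center) > max(tol, 30.0):
            raise ValueError(f"no band near {center} cm^-1")
        return float(self.band_amplitudes[i] * self.band_sigmas[i] * SQRT_2PI)

    @property
    def po4_index(self) -> int:
        c = np.asarray(self.band_centers, float)
        idx = np.where((c >= 930.0) & (c <= 990.0))[0]
        if idx.size == 0:
            raise ValueError("no band in the phosphate nu1 region [930, 990]")
        return int(idx[0])

    @property
    def amide1_index(self) -> int:
        c = np.asarray(self.band_centers, float)
        idx = np.where((c >= 1620.0) & (c <= 1700.0))[0]
        if idx.size == 0:
            raise ValueError("no band in the Amide I region [1620, 1700]")
        return int(idx[0])

    @property
    def po4_position(self) -> float:
        return float(self.band_centers[self.po4_index])

    @property
    def po4_area(self) -> float:
        i = self.po4_index
        return float(self.band_amplitudes[i] * self.band_sigmas[i] * SQRT_2PI)

    @property
    def amide1_area(self) -> float:
        i = self.amide1_index
        return float(self.band_amplitudes[i] * self.band_sigmas[i] * SQRT_2PI)

    @property
    def mineral_to_matrix(self) -> float:
        return self.po4_area / self.amide1_area


def default_raman_truth(
    po4_position: float = 960.0,
    po4_amplitude: float = 500.0,
    amide1_amplitude: float = 100.0,
    noise_sd: float = 0.0,
    baseline_coeffs: Sequence[float] = (0.0,),
    scatter_slope: float = 1.0,
    scatter_offset: float = 0.0,
) -> RamanGroundTruth:
    """Bone-like default band set.

    The phosphate nu1 band (~960 cm^-1, sharp) and Amide I (~1660 cm^-1,
    broad) are the two quantified bands; carbonate (1070), Amide III (1242)
    and CH2 deformation (1450) are cosmetic context bands.
    """
    return RamanGroundTruth(
        band_centers=[po4_position, 1070.0, 1242.0, 1450.0, 1660.0],
        band_amplitudes=[po4_amplitude, 40.0, 30.0, 45.0, amide1_amplitude],
        band_sigmas=[6.0, 8.0, 12.0, 12.0, 16.0],
        baseline_coeffs=list(baseline_coeffs),
        scatter_slope=scatter_slope,
        scatter_offset=scatter_offset,
        noise_sd=noise_sd,
    )


def _gaussian_sum(axis: np.ndarray, truth: RamanGroundTruth) -> np.ndarray:
    y = np.zeros_like(axis, dtype=float)
    for c, a, s in zip(truth.band_centers, truth.band_amplitudes, truth.band_sigmas):
        y += a * np.exp(-((axis - c) ** 2) / (2.0 * s * s))
    return y


def _baseline_values(axis: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    coeffs = np.asarray(coeffs, float)
    if coeffs.size == 0 or np.all(coeffs == 0):
        return np.zeros_like(axis)
    lo, hi = axis[0], axis[-1]
    u = 2.0 * (axis - lo) / (hi - lo) - 1.0 if hi > lo else np.zeros_like(axis)
    return np.polynomial.polynomial.polyval(u, coeffs)


def generate_raman_spectrum(
    truth: RamanGroundTruth,
    axis: Optional[np.ndarray] = None,
    seed: int = 0,
    sample_id: str = "s0",
    group: Optional[str] = None,
) -> RamanSpectrum:
    """Draw one spectrum from the forward model.

    intensity = scatter_slope * (sum of Gaussians + baseline polynomial)
                + scatter_offset + N(0, noise_sd^2)
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, float)
    if axis.size >= 2 and not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be strictly increasing")
    centers = np.asarray(truth.band_centers, float)
    amps = np.asarray(truth.band_amplitudes, float)
    live = centers[amps != 0]
    if live.size and (live.min() < axis[0] or live.max() > axis[-1]):
        raise ValueError("band center outside the wavenumber axis range")
    clean = _gaussian_sum(axis, truth) + _baseline_values(axis, truth.baseline_coeffs)
    y = truth.scatter_slope * clean + truth.scatter_offset
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=axis.size)
    return RamanSpectrum(axis, y, sample_id=sample_id, group=group, truth=truth)


# ---------------------------------------------------------------------------
# AFM forward model
# ---------------------------------------------------------------------------


@dataclass
class AdhesionEvent:
    """One retraction adhesion event on the tip-sample separation axis.

    The event pulls the force below baseline over ``width_um`` ending with a
    rupture (jump back to baseline) at ``rupture_separation_um``, where the
    pull force reaches ``peak_force_nN``. Triangular events ramp linearly
    (analytic energy = peak * width / 2 fJ); exponential events grow as
    exp((s - s_rupture)/lambda) with lambda = width/4 (truncated at the
    event start).
    """

    rupture_separation_um: float
    peak_force_nN: float
    shape: str = "triangular"
    width_um: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in ("triangular", "exponential"):
            raise ValueError(f"unknown adhesion event shape: {self.shape!r}")
        if self.width_um <= 0 or self.peak_force_nN < 0:
            raise ValueError("event width must be > 0 and peak force >= 0")
        if self.rupture_separation_um <= 0:
            raise ValueError("rupture separation must be positive")

    def force_at(self, separation_nm: np.ndarray) -> np.ndarray:
        """Negative (attractive) force in nN at separations in nm."""
        s = np.asarray(separation_nm, float)
        s_r = self.rupture_separation_um * 1000.0
        w = self.width_um * 1000.0
        inside = (s > s_r - w) & (s <= s_r)
        f = np.zeros_like(s)
        if self.shape == "triangular":
            f[inside] = -self.peak_force_nN * (s[inside] - (s_r - w)) / w
        else:
            lam = w / 4.0
            f[inside] = -self.peak_force_nN * np.exp((s[inside] - s_r) / lam)
        return f

    @property
    def energy_fJ(self) -> float:
        """Analytic dissipated energy (area between event and baseline)."""
        if self.shape == "triangular":
            return 0.5 * self.peak_force_nN * self.width_um
        lam_um = self.width_um / 4.0
        return self.peak_force_nN * lam_um * (1.0 - math.exp(-4.0))


@dataclass
class ForceCurveGroundTruth:
    """True parameters of one synthetic force-indentation cycle."""

    youngs_modulus_Pa: float = 2.0e9
    contact_point_nm: float = 150.0
    poisson_sample: float = 0.3
    face_half_angle_deg: float = 20.0
    adhesion_events: List[AdhesionEvent] = field(default_factory=list)
    noise_sd_nN: float = 0.0
    spring_constant_N_per_m: float = 16.0

    def __post_init__(self) -> None:
        if self.youngs_modulus_Pa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson_sample < 0.5):
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")
        if not (0.0 < self.face_half_angle_deg < 90.0):
            raise ValueError("face half-angle must lie in (0, 90) degrees")
        if self.spring_constant_N_per_m <= 0:
            raise ValueError("spring constant must be positive")
        seps = [e.rupture_separation_um for e in self.adhesion_events]
        if any(b <= a for a, b in zip(seps, seps[1:])):
            raise ValueError("rupture separations must be strictly increasing")


@dataclass
class RampDesign:
    """Piezo ramp: how far above contact the approach starts, the grid step,
    the force setpoint where the approach turns around, and how far past the
    contact point the retraction extends (the 2-4 um pull-off window)."""

    approach_span_nm: float = 600.0
    step_nm: float = 2.0
    setpoint_nN: float = 3650.0
    retract_extension_um: float = 4.0

    def __post_init__(self) -> None:
        if self.setpoint_nN <= 0:
            raise ValueError("setpoint must be positive")
        if self.step_nm <= 0 or self.approach_span_nm <= 0:
            raise ValueError("ramp step and span must be positive")


def hertz_prefactor(
    youngs_modulus_Pa: float, poisson_sample: float, face_half_angle_deg: float
) -> float:
    """Pyramidal (Bilodeau) Hertz prefactor in nN/nm^2.

    F[nN] = C * E/(1-nu^2) * d[nm]^2 with C = 0.7453 tan(alpha); the 1e-9
    factor converts Pa (= 1e-9 nN/nm^2) to the nm/nN unit system.
    """
    c = PYRAMID_C * math.tan(math.radians(face_half_angle_deg))
    return c * youngs_modulus_Pa / (1.0 - poisson_sample**2) * 1e-9


def hertz_force(
    depth_nm: np.ndarray, prefactor: float, spring_constant: float
) -> np.ndarray:
    """Measured force at piezo depth d0 = z0 - z, with cantilever deflection
    folded in self-consistently.

    The true indentation is delta = d0 - F/k, so F solves
    F = a * (d0 - F/k)^2; the physical (smaller) root, written in the
    cancellation-free form, is
    F = 2 a d0^2 / (1 + 2t + sqrt(1 + 4t)) with t = a d0 / k,
    which reduces to a*d0^2 as k -> infinity.
    """
    d0 = np.maximum(np.asarray(depth_nm, float), 0.0)
    a, k = prefactor, spring_constant
    t = a * d0 / k
    return 2.0 * a * d0 * d0 / (1.0 + 2.0 * t + np.sqrt(1.0 + 4.0 * t))


def generate_force_curve(
    truth: ForceCurveGroundTruth,
    ramp: Optional[RampDesign] = None,
    seed: int = 0,
    curve_id: str = "c0",
    location_id: str = "loc0",
    nodule_id: str = "nod0",
    group: Optional[str] = None,
) -> ForceCurve:
    """Draw one force-indentation cycle from the forward model.

    Approach: baseline (zero) force until the contact point, then the
    self-consistent Hertz force, truncated where it first reaches the
    setpoint. Retraction: the elastic part mirrored, then the adhesion
    events evaluated on the separation axis out to the retraction
    extension. Gaussian noise is added to both segments.
    """
    if ramp is None:
        ramp = RampDesign()
    z0 = truth.contact_point_nm
    a = hertz_prefactor(
        truth.youngs_modulus_Pa, truth.poisson_sample, truth.face_half_angle_deg
    )
    k = truth.spring_constant_N_per_m
    if truth.noise_sd_nN > 0 and ramp.setpoint_nN <= 3.0 * truth.noise_sd_nN:
        raise ValueError("setpoint below the noise floor")
    # approach grid descending from z0 + span; stop at the setpoint crossing
    n_app = int(math.floor(ramp.approach_span_nm / ramp.step_nm))
    z_above = z0 + ramp.approach_span_nm - ramp.step_nm * np.arange(n_app + 1)
    # continue below contact until the setpoint is reached
    d_max = math.sqrt(ramp.setpoint_nN / a) + ramp.setpoint_nN / k + 2 * ramp.step_nm
    n_below = int(math.ceil(d_max / ramp.step_nm))
    z_below = z0 - ramp.step_nm * np.arange(1, n_below + 1)
    z_app = np.concatenate([z_above, z_below])
    if z0 > z_app[0] or z0 < z_app[-1]:
        raise ValueError("contact point outside the ramp")
    f_app = hertz_force(z0 - z_app, a, k)
    cross = np.where(f_app >= ramp.setpoint_nN)[0]
    if cross.size:
        z_app = z_app[: cross[0] + 1]
        f_app = f_app[: cross[0] + 1]
    # retraction: elastic part mirrored, then adhesion tail out to the
    # retraction extension (separation axis ~ height above contact)
    z_ret_elastic = z_app[::-1]
    f_ret_elastic = f_app[::-1]
    z_tail_end = z0 + ramp.retract_extension_um * 1000.0
    n_tail = int(math.floor((z_tail_end - z_ret_elastic[-1]) / ramp.step_nm))
    z_tail = z_ret_elastic[-1] + ramp.step_nm * np.arange(1, n_tail + 1)
    f_tail = np.zeros_like(z_tail)
    z_ret = np.concatenate([z_ret_elastic, z_tail])
    f_ret = np.concatenate([f_ret_elastic, f_tail])
    above = z_ret > z0
    if truth.adhesion_events:
        sep = z_ret[above] - z0
        f_ev = np.zeros_like(sep)
        for ev in truth.adhesion_events:
            f_ev += ev.force_at(sep)
        f_ret[above] = f_ret[above] + f_ev
    if truth.noise_sd_nN > 0:
        rng = np.random.default_rng(seed)
        f_app = f_app + rng.normal(0.0, truth.noise_sd_nN, f_app.size)
        f_ret = f_ret + rng.normal(0.0, truth.noise_sd_nN, f_ret.size)
    return ForceCurve(
        curve_id=curve_id,
        approach_height_nm=z_app,
        approach_force_nN=f_app,
        retract_height_nm=z_ret,
        retract_force_nN=f_ret,
        spring_constant_N_per_m=k,
        setpoint_nN=ramp.setpoint_nN,
        location_id=location_id,
        nodule_id=nodule_id,
        group=group,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroupOffsets:
    """Per-group systematic effects relative to the control baseline."""

    po4_position_shift_cm1: float = 0.0
    amide_area_scale: float = 1.0
    e_scale: float = 1.0


@dataclass
class CohortDesign:
    """A labelled multi-group study design with per-group effect offsets.

    Within-group biological variability (defaults): phosphate peak position
    jitter SD 0.3 cm^-1, per-band amplitude CV 15%, multiplicative scatter
    slope CV 10% with offset SD 10 counts, spectral noise SD 2% of the
    phosphate amplitude; AFM modulus CV 20% with instrument-level force
    noise SD 2 nN. These set the difficulty of the recovery and detection tests.
    """

    groups: Sequence[str] = ("control", "DBeQ", "bortezomib")
    n_per_group: int = 20
    offsets: Dict[str, GroupOffsets] = field(default_factory=dict)
    seed: int = 0
    # within-group variability knobs
    position_jitter_cm1: float = 0.3
    amplitude_cv: float = 0.15
    scatter_slope_cv: float = 0.10
    scatter_offset_sd: float = 10.0
    raman_noise_frac: float = 0.02
    e_cv: float = 0.20
    afm_noise_sd_nN: float = 2.0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if len(set(self.groups)) != len(tuple(self.groups)):
            raise ValueError("group names must be unique")
        unknown = set(self.offsets) - set(self.groups)
        if unknown:
            raise ValueError(f"offsets given for unknown groups: {sorted(unknown)}")


def _sample_seed(seed: int, index: int) -> int:
    """Derive a per-sample 31-bit seed by mixing the index into the seed."""
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    design: CohortDesign,
    modality: str,
    axis: Optional[np.ndarray] = None,
    ramp: Optional[RampDesign] = None,
) -> Tuple[list, pd.DataFrame]:
    """Generate a labelled cohort plus its ground-truth table.

    Returns ``(samples, truth_table)`` where samples are RamanSpectrum or
    ForceCurve objects (modality ``"raman"`` or ``"afm"``) and the table is
    keyed by sample id.
    """
    if modality not in ("raman", "afm"):
        raise ValueError(f"unknown modality: {modality!r}")
    samples: list = []
    rows = []
    for gi, group in enumerate(design.groups):
        off = design.offsets.get(group, GroupOffsets())
        for j in range(design.n_per_group):
            index = gi * design.n_per_group + j
            sid = f"{group}_{j:03d}"
            sseed = _sample_seed(design.seed, index)
            rng = np.random.default_rng(np.random.SeedSequence(
                entropy=design.seed % (2**31), spawn_key=(index, 1)))
            if modality == "raman":
                base = default_raman_truth()
                amps = np.asarray(base.band_amplitudes, float)
                if design.amplitude_cv > 0:
                    sd = math.sqrt(math.log(1.0 + design.amplitude_cv**2))
                    amps = amps * rng.lognormal(-0.5 * sd * sd, sd, amps.size)
                amps[base.amide1_index] *= off.amide_area_scale
                centers = list(base.band_centers)
                centers[base.po4_index] += off.po4_position_shift_cm1 + rng.normal(
                    0.0, design.position_jitter_cm1
                )
                slope = 1.0
                if design.scatter_slope_cv > 0:
                    sds = math.sqrt(math.log(1.0 + design.scatter_slope_cv**2))
                    slope = rng.lognormal(-0.5 * sds * sds, sds)
                truth = RamanGroundTruth(
                    band_centers=centers,
                    band_amplitudes=amps.tolist(),
                    band_sigmas=list(base.band_sigmas),
                    baseline_coeffs=[120.0, -40.0, 25.0, 0.0, 0.0, 10.0],
                    scatter_slope=slope,
                    scatter_offset=rng.normal(0.0, design.scatter_offset_sd),
                    noise_sd=design.raman_noise_frac * amps[base.po4_index],
                )
                spec = generate_raman_spectrum(
                    truth, axis=axis, seed=sseed, sample_id=sid, group=group
                )
                samples.append(spec)
                rows.append(
                    {
                        "sample_id": sid,
                        "group": group,
                        "true_po4_position_cm-1": truth.po4_position,
                        "true_po4_area": truth.po4_area,
                        "true_amide1_area": truth.amide1_area,
                        "true_mineral_to_matrix": truth.mineral_to_matrix,
                        "true_scatter_slope": truth.scatter_slope,
                        "true_noise_sd": truth.noise_sd,
                    }
                )
            else:
                e_base = 2.0e9 * off.e_scale
                if design.e_cv > 0:
                    sde = math.sqrt(math.log(1.0 + design.e_cv**2))
                    e_true = e_base * rng.lognormal(-0.5 * sde * sde, sde)
                else:
                    e_true = e_base
                the_ramp = ramp if ramp is not None else RampDesign()
                events = [
                    AdhesionEvent(
                        rupture_separation_um=float(rng.uniform(0.8, 1.4)),
                        peak_force_nN=float(rng.uniform(40.0, 80.0)),
                        shape="exponential",
                        width_um=0.5,
                    ),
                    AdhesionEvent(
                        rupture_separation_um=float(rng.uniform(2.2, 3.2)),
                        peak_force_nN=float(rng.uniform(20.0, 50.0)),
                        shape="triangular",
                        width_um=0.6,
                    ),
                ]
                truth = ForceCurveGroundTruth(
                    youngs_modulus_Pa=e_true,
                    contact_point_nm=float(rng.uniform(120.0, 180.0)),
                    adhesion_events=events,
                    noise_sd_nN=design.afm_noise_sd_nN,
                )
                curve = generate_force_curve(
                    truth,
                    ramp=the_ramp,
                    seed=sseed,
                    curve_id=sid,
                    location_id=f"{group}_loc{j:03d}",
                    nodule_id=f"{group}_nod{j:03d}",
                    group=group,
                )
                samples.append(curve)
                rows.append(
                    {
                        "sample_id": sid,
                        "group": group,
                        "true_E_Pa": truth.youngs_modulus_Pa,
                        "true_contact_point_nm": truth.contact_point_nm,
                        "true_F_adh_nN": max(
                            (e.peak_force_nN for e in events), default=0.0
                        ),
                        "true_L_adh_um": max(
                            (e.rupture_separation_um for e in events), default=0.0
                        ),
                        "true_W_adh_fJ": sum(e.energy_fJ for e in events),
                        "true_n_events": len(events),
                    }
                )
    return samples, pd.DataFrame(rows)
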