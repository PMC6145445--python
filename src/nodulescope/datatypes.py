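"""Core in-memory containers shared across the pipeline stages.

Units are fixed package-wide: wavenumbers in cm^-1, Raman intensities in
arbitrary counts, AFM heights in nm, forces in nN, Young's modulus in Pa,
adhesion length in um and adhesion energy in fJ (1 nN * 1 um = 1 fJ).
Converters live at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

__all__ = ["RamanSpectrum", "ForceCurve"]


@dataclass
class RamanSpectrum:
    """One measured Raman spectrum.

    Attributes
    ----------
    wavenumbers : strictly increasing axis in cm^-1.
    intensities : same length, arbitrary counts, finite.
    sample_id : identifier used to join against label tables.
    group : treatment group label, if known.
    truth : optional ground-truth payload attached by the synthetic
        generator; ignored by the pipeline, used only in recovery tests.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    group: Optional[str] = None
    truth: Optional[Any] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"axis/intensity length mismatch: {self.wavenumbers.size} vs "
                f"{self.intensities.size}"
            )
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise ValueError("non-finite values in spectrum")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def replace_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        """Copy of this spectrum with a new intensity vector on the same axis."""
        return RamanSpectrum(
            wavenumbers=self.wavenumbers.copy(),
            intensities=np.asarray(intensities, dtype=float),
            sample_id=self.sample_id,
            group=self.group,
            truth=self.truth,
        )


@dataclass
class ForceCurve:
    """One AFM force-indentation cycle (approach + retraction).

    Heights are piezo heights in nm (larger = further from the surface);
    forces in nN. ``spring_constant`` is in N/m, which equals nN/nm, so no
    conversion is needed for the deflection correction.
    """

    curve_id: str
    approach_height_nm: np.ndarray
    approach_force_nN: np.ndarray
    retract_height_nm: np.ndarray
    retract_force_nN: np.ndarray
    spring_constant_N_per_m: float
    setpoint_nN: float
    location_id: str = ""
    nodule_id: str = ""
    group: Optional[str] = None
    truth: Optional[Any] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in (
            "approach_height_nm",
            "approach_force_nN",
            "retract_height_nm",
            "retract_force_nN",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.approach_height_nm.size != self.approach_force_nN.size:
            raise ValueError("approach segment length mismatch")
        if self.retract_height_nm.size != self.retract_force_nN.size:
            raise ValueError("retract segment length mismatch")
        if self.spring_constant_N_per_m <= 0:
            raise ValueError("spring constant must be positive")
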