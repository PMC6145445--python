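"""Plain-text table readers/writers and run configuration.

Interchange formats (all delimited text, never vendor binaries):

* spectra matrix table: first column ``wavenumber_cm-1``, one intensity
  column per sample (header row = sample ids);
* per-sample two-column text: wavenumber, intensity;
* force curves, long format: ``curve_id, segment, height_nm, force_nN``
  plus a metadata table ``curve_id, location_id, nodule_id, group,
  spring_constant_N_per_m, setpoint_nN``;
* labels table: ``sample_id, group``.

Numeric columns carry units in their header names to prevent silent unit
drift. Descending wavenumber axes are re-sorted ascending with a logged
note.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import ForceCurve, RamanSpectrum

__all__ = [
    "RunConfig",
    "read_spectra_matrix",
    "write_spectra_matrix",
    "read_spectrum_twocolumn",
    "write_spectrum_twocolumn",
    "read_labels",
    "read_force_curves",
    "write_force_curves",
    "write_provenance",
]

logger = logging.getLogger(__name__)

WAVENUMBER_COL = "wavenumber_cm-1"


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _validate_axis(w: np.ndarray, origin: str) -> np.ndarray:
    bad = np.where(~np.isfinite(w))[0]
    if bad.size:
        raise ValueError(f"{origin}: non-finite wavenumbers at rows {bad[:5].tolist()}")
    order = np.arange(w.size)
    if w.size >= 2 and np.all(np.diff(w) < 0):
        logger.info("%s: descending wavenumber axis re-sorted ascending", origin)
        order = order[::-1]
    elif w.size >= 2 and not np.all(np.diff(w) > 0):
        raise ValueError(f"{origin}: wavenumber axis is not strictly monotone")
    return order


def read_spectra_matrix(
    path, labels: Optional[Mapping[str, str]] = None
) -> List[RamanSpectrum]:
    """Read a multi-sample matrix table (one shared wavenumber axis)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.columns[0] != WAVENUMBER_COL:
        raise ValueError(
            f"{path}: first column must be {WAVENUMBER_COL!r}, "
            f"got {df.columns[0]!r}"
        )
    w = df[WAVENUMBER_COL].to_numpy(float)
    order = _validate_axis(w, str(path))
    spectra = []
    for col in df.columns[1:]:
        y = df[col].to_numpy(float)
        bad = np.where(~np.isfinite(y))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-finite intensities in {col!r} at rows "
                f"{bad[:5].tolist()}"
            )
        spectra.append(
            RamanSpectrum(
                w[order], y[order], sample_id=str(col),
                group=labels.get(str(col)) if labels else None,
            )
        )
    return spectra


def write_spectra_matrix(path, spectra: Sequence[RamanSpectrum]) -> None:
    axis = spectra[0].wavenumbers
    for sp in spectra[1:]:
        if not np.array_equal(sp.wavenumbers, axis):
            raise ValueError("matrix output requires one shared wavenumber axis")
    df = pd.DataFrame({WAVENUMBER_COL: axis})
    for sp in spectra:
        df[sp.sample_id] = sp.intensities
    df.to_csv(path, sep="\t", index=False)


def read_spectrum_twocolumn(path, sample_id: Optional[str] = None) -> RamanSpectrum:
    """Read one spectrum from two-column (wavenumber, intensity) text."""
    arr = np.loadtxt(path, comments=("#", "//"))
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    order = _validate_axis(arr[:, 0], str(path))
    sid = sample_id if sample_id is not None else Path(path).stem
    return RamanSpectrum(arr[order, 0], arr[order, 1], sample_id=sid)


def write_spectrum_twocolumn(path, s: RamanSpectrum) -> None:
    np.savetxt(
        path,
        np.column_stack([s.wavenumbers, s.intensities]),
        header=f"{WAVENUMBER_COL} intensity_counts",
    )


def read_labels(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: labels table needs sample_id and group columns")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------

_FC_META_COLS = [
    "curve_id",
    "location_id",
    "nodule_id",
    "group",
    "spring_constant_N_per_m",
    "setpoint_nN",
]


def read_force_curves(data_path, metadata_path) -> List[ForceCurve]:
    """Join a long-format curve table with its metadata table."""
    data = pd.read_csv(data_path, sep=None, engine="python")
    meta = pd.read_csv(metadata_path, sep=None, engine="python")
    missing = set(_FC_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing)}")
    meta = meta.set_index(meta["curve_id"].astype(str))
    curves = []
    for cid, sub in data.groupby("curve_id", sort=True):
        cid = str(cid)
        if cid not in meta.index:
            raise ValueError(f"no metadata row for curve_id {cid!r}")
        m = meta.loc[cid]
        if pd.isna(m["spring_constant_N_per_m"]):
            raise ValueError(f"missing spring constant for curve_id {cid!r}")
        from .afm import split_segments  # local import avoids a cycle

        curves.append(
            split_segments(
                sub,
                curve_id=cid,
                spring_constant_N_per_m=float(m["spring_constant_N_per_m"]),
                setpoint_nN=float(m["setpoint_nN"]),
                location_id=str(m["location_id"]),
                nodule_id=str(m["nodule_id"]),
                group=None if pd.isna(m["group"]) else str(m["group"]),
            )
        )
    return curves


def write_force_curves(data_path, metadata_path, curves: Sequence[ForceCurve]) -> None:
    frames = []
    meta_rows = []
    for c in curves:
        for segment, z, f in (
            ("approach", c.approach_height_nm, c.approach_force_nN),
            ("retract", c.retract_height_nm, c.retract_force_nN),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "curve_id": c.curve_id,
                        "segment": segment,
                        "height_nm": z,
                        "force_nN": f,
                    }
                )
            )
        meta_rows.append(
            {
                "curve_id": c.curve_id,
                "location_id": c.location_id,
                "nodule_id": c.nodule_id,
                "group": c.group,
                "spring_constant_N_per_m": c.spring_constant_N_per_m,
                "setpoint_nN": c.setpoint_nN,
            }
        )
    pd.concat(frames, ignore_index=True).to_csv(data_path, sep="\t", index=False)
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration and provenance
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully resolved run configuration; round-trips through YAML."""

    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "results"
    # synth
    groups: List[str] = field(default_factory=lambda: ["control", "DBeQ", "bortezomib"])
    n_per_group: int = 20
    offsets: Dict[str, Dict[str, float]] = field(default_factory=dict)
    # raman
    po4_window: List[float] = field(default_factory=lambda: [930.0, 990.0])
    amide_window: List[float] = field(default_factory=lambda: [1620.0, 1700.0])
    exclude_below: float = 500.0
    n_components: int = 6
    cv_splits: int = 10
    smooth_window: int = 5
    smooth_order: int = 2
    baseline_degree: int = 5
    # afm
    geometry_shape: str = "pyramid"
    half_angle_deg: float = 20.0
    poisson: float = 0.3
    noise_band_factor: float = 3.0
    # stats
    bin_edges: List[float] = field(default_factory=lambda: [0.0, 20.0, 40.0, 60.0, 80.0, 100.0])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_provenance(out_dir, config: RunConfig) -> None:
    """Record software version, config hash and seed next to the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {
                "software": f"nodulescope {__version__}",
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            fh,
            indent=2,
        )
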