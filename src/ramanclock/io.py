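"""Reading and writing spectra and donor metadata.

On-disk formats are deliberately minimal: a spectrum is a two-column text
file (comma- or whitespace-delimited, optional header) with ascending
wavenumbers in cm^-1 and intensities in arbitrary units; a donor table is a
CSV with columns donor_id, age_years, sex and optional height_cm/weight_kg.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "DonorRecord",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_donor_table",
    "write_donor_table",
]


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed."""


@dataclass
class Spectrum:
    """A sampled Raman trace.

    ``axis`` holds strictly increasing wavenumbers (cm^-1), ``intensity``
    the matching intensities (arbitrary units), ``meta`` free-text metadata
    such as donor_id and replicate index.
    """

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be one-dimensional")
        if self.axis.size != self.intensity.size:
            raise ValueError("axis and intensity must have equal length")
        if self.axis.size and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.axis.size

    def copy(self, **meta) -> "Spectrum":
        return Spectrum(self.axis.copy(), self.intensity.copy(), {**self.meta, **meta})


@dataclass
class DonorRecord:
    """One donor: identity, age, sex and optional anthropometrics.

    Sex is stored as "M"/"F" and coded M=1, F=0 for modelling
    (``sex_code``).  BMI (kg/m^2) is derived from height and weight when
    both are present.  ``rpf`` is the protein-folding intensity ratio,
    filled in by the spectral pipeline.
    """

    donor_id: str
    age: float
    sex: str
    height: float | None = None
    weight: float | None = None
    rpf: float | None = None

    # Negative ages are tolerated at record level so unclamped synthetic
    # cohorts can round-trip; tables read from disk enforce age >= 0.
    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"donor {self.donor_id!r}: sex must be 'M' or 'F'")
        if self.height is not None and self.height <= 0:
            raise ValueError(f"donor {self.donor_id!r}: height must be > 0 cm")
        if self.weight is not None and self.weight <= 0:
            raise ValueError(f"donor {self.donor_id!r}: weight must be > 0 kg")
        if self.rpf is not None and self.rpf <= 0:
            raise ValueError(f"donor {self.donor_id!r}: rpf must be > 0 when set")

    @property
    def sex_code(self) -> int:
        return 1 if self.sex == "M" else 0

    @property
    def bmi(self) -> float | None:
        if self.height is None or self.weight is None:
            return None
        return self.weight / (self.height / 100.0) ** 2


def read_spectrum(path, meta: Mapping | None = None) -> Spectrum:
    """Read a two-column wavenumber/intensity file.

    Accepts comma- or whitespace-delimited rows and an optional single
    header line; rows are sorted by ascending wavenumber and duplicate
    wavenumbers are rejected.
    """
    axis, intens = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",") if "," in line else line.split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if lineno == 1:  # tolerate one header line
                    continue
                raise SpectrumFormatError(
                    f"{path}: cannot parse line {lineno}: {line!r}"
                ) from None
            axis.append(x)
            intens.append(y)
    if len(axis) < 3:
        raise ValueError(f"{path}: a spectrum needs at least 3 points, got {len(axis)}")
    axis_arr = np.array(axis)
    order = np.argsort(axis_arr, kind="stable")
    axis_arr = axis_arr[order]
    if np.any(np.diff(axis_arr) == 0):
        raise SpectrumFormatError(f"{path}: duplicate wavenumbers")
    return Spectrum(axis_arr, np.array(intens)[order], dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path, fmt: str = "%.10g") -> None:
    """Write a spectrum as CSV with header ``wavenumber_cm1,intensity``."""
    df = pd.DataFrame(
        {"wavenumber_cm1": spectrum.axis, "intensity": spectrum.intensity}
    )
    df.to_csv(path, index=False, float_format=fmt)


_REQUIRED = ("donor_id", "age_years", "sex")


def read_donor_table(path) -> list[DonorRecord]:
    """Read donors.csv into validated records; BMI is derived on access."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if (df["age_years"] < 0).any():
        bad = df.loc[df["age_years"] < 0, "donor_id"].tolist()
        raise ValueError(f"{path}: negative age for donor(s) {bad}")
    records = []
    for _, row in df.iterrows():
        records.append(
            DonorRecord(
                donor_id=str(row["donor_id"]),
                age=float(row["age_years"]),
                sex=str(row["sex"]).strip(),
                height=_opt(row, "height_cm"),
                weight=_opt(row, "weight_kg"),
                rpf=_opt(row, "rpf") or _opt(row, "rpf_true"),
            )
        )
    return records


def _opt(row, col) -> float | None:
    if col not in row.index or pd.isna(row[col]):
        return None
    return float(row[col])


def write_donor_table(donors: Iterable[DonorRecord], path) -> None:
    rows = []
    for d in donors:
        rows.append(
            {
                "donor_id": d.donor_id,
                "age_years": d.age,
                "sex": d.sex,
                "height_cm": d.height,
                "weight_kg": d.weight,
                "rpf_true": d.rpf,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
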