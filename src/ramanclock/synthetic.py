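"""Synthetic skin-Raman spectra and donor cohorts.

No raw autopsy data accompany the protein-folding clock, so every pipeline
stage is exercised against a generator whose defaults reproduce the
published cohort's statistical structure: 132 donors (92 male / 40 female),
protein-folding ratio R_PF drawn from Normal(0.41, 0.16) truncated to
[0.16, 0.90], and age given by the deployed quadratic calibration
``age = 130.0 - 233.3 R + 99.4 R^2`` plus Gaussian noise (SD 11.15 years).
Depth-resolved scanning through the dermis is emulated as many noisy
replicate spectra per donor, each a three-band Amide I profile on a smooth
fluorescence-like baseline in which the random-coil height is exactly
R_PF x the alpha-helix height.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import DonorRecord, Spectrum
from .profiles import Band, BandLibrary, default_band_library

__all__ = [
    "CohortSpec",
    "default_band_library",
    "simulate_spectrum",
    "simulate_cohort",
    "MODEL2_COEFFICIENTS",
]

#: Quadratic age model used as the generating truth (intercept, R, R^2 terms),
#: the calibration deployed for forensic casework on the original skin cohort.
MODEL2_COEFFICIENTS: tuple[float, float, float] = (130.0, -233.3, 99.4)

# Default acquisition grid: 1 cm^-1 steps across the protein spectral zone
# with flanks for baseline anchoring.
DEFAULT_AXIS = (1500.0, 1800.0, 1.0)
# Fluorescence-like quadratic baseline, evaluated in the centred coordinate
# u = x - mid(axis): gentle positive background of ~30 units under bands of
# height ~100.
DEFAULT_BASELINE = (30.0, 0.05, 2.0e-4)


@dataclass
class CohortSpec:
    """Parameters of a simulated donor cohort.

    Defaults are the published cohort's marginals; ``model_coefficients``
    are the polynomial (ascending powers of R_PF) used as generating truth.
    """

    n_donors: int = 132
    rpf_mean: float = 0.41
    rpf_sd: float = 0.16
    rpf_range: tuple[float, float] = (0.16, 0.90)
    age_noise_sd: float = 11.15
    male_fraction: float = 92.0 / 132.0
    model_coefficients: tuple[float, ...] = MODEL2_COEFFICIENTS
    replicates_per_donor: int = 100
    seed: int = 0
    clamp_age: bool = False
    # spectral layer
    axis: tuple[float, float, float] = DEFAULT_AXIS
    alpha_amplitude: float = 100.0
    beta_fraction: float = 0.5
    noise_sd: float = 1.0
    baseline: tuple[float, ...] = DEFAULT_BASELINE
    library: BandLibrary = field(default_factory=default_band_library)

    def __post_init__(self) -> None:
        lo, hi = self.rpf_range
        if not 0 < lo < hi:
            raise ValueError("rpf_range must satisfy 0 < min < max")
        if self.rpf_sd <= 0:
            raise ValueError("rpf_sd must be > 0")
        if self.age_noise_sd < 0:
            raise ValueError("age_noise_sd must be >= 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        if self.replicates_per_donor < 1:
            raise ValueError("replicates_per_donor must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def make_axis(self) -> np.ndarray:
        lo, hi, step = self.axis
        return np.arange(lo, hi + 0.5 * step, step)

    def age_of(self, rpf) -> np.ndarray:
        """Noise-free generating age at a given folding ratio."""
        return np.polynomial.polynomial.polyval(
            np.asarray(rpf, dtype=float), self.model_coefficients
        )


def simulate_spectrum(
    bands,
    axis,
    baseline: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> Spectrum:
    """Forward-model a spectrum: band sum + polynomial baseline + noise.

    The baseline polynomial (ascending coefficients) is evaluated in the
    centred coordinate ``u = x - mid(axis)`` so that small quadratic
    coefficients stay well scaled at Raman-shift magnitudes of ~1700 cm^-1.
    Deterministic for a fixed integer seed.
    """
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2 or not np.all(np.diff(axis) > 0):
        raise ValueError("axis must be one-dimensional and strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = np.zeros_like(axis)
    for band in bands:
        y += band.profile(axis)
    if len(baseline):
        u = axis - 0.5 * (axis[0] + axis[-1])
        y += np.polynomial.polynomial.polyval(u, baseline)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=axis.size)
    return Spectrum(axis, y)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    # rejection sampling: exact truncation, trivially correct
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_cohort(spec: CohortSpec) -> tuple[list[DonorRecord], dict[str, list[Spectrum]]]:
    """Generate a donor cohort and its replicate spectra.

    Returns ``(donors, spectra)`` where ``spectra[donor_id]`` holds the
    replicate spectra whose random-coil/alpha-helix height ratio equals the
    donor's true R_PF exactly; ``DonorRecord.rpf`` carries that truth.
    Heights/weights are drawn independently of R_PF (the folding ratio shows
    no BMI association) purely so BMI bookkeeping is exercised.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rpf_range
    rpf = _truncated_normal(rng, spec.rpf_mean, spec.rpf_sd, lo, hi, spec.n_donors)
    age = spec.age_of(rpf) + rng.normal(0.0, spec.age_noise_sd, spec.n_donors)
    if spec.clamp_age:
        age = np.clip(age, 0.0, None)
    male = rng.random(spec.n_donors) < spec.male_fraction
    height = np.where(male, rng.normal(171.0, 7.0, spec.n_donors),
                      rng.normal(158.0, 7.0, spec.n_donors))
    bmi = np.clip(rng.normal(22.5, 3.5, spec.n_donors), 14.0, None)
    weight = bmi * (height / 100.0) ** 2

    axis = spec.make_axis()
    donors: list[DonorRecord] = []
    spectra: dict[str, list[Spectrum]] = {}
    for i in range(spec.n_donors):
        donor_id = f"d{i + 1:03d}"
        donors.append(
            DonorRecord(
                donor_id=donor_id,
                age=float(age[i]),
                sex="M" if male[i] else "F",
                height=round(float(height[i]), 1),
                weight=round(float(weight[i]), 1),
                rpf=float(rpf[i]),
            )
        )
        lib = spec.library.with_amplitudes(
            {
                "alpha_helix": spec.alpha_amplitude,
                "beta_sheet": spec.beta_fraction * spec.alpha_amplitude,
                "random_coil": float(rpf[i]) * spec.alpha_amplitude,
            }
        )
        reps = []
        for r in range(spec.replicates_per_donor):
            s = simulate_spectrum(lib.bands, axis, spec.baseline, spec.noise_sd, rng)
            s.meta.update(donor_id=donor_id, replicate=r)
            reps.append(s)
        spectra[donor_id] = reps
    return donors, spectra
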