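"""Pseudo-Voigt band profiles and the Amide I band library.

The Amide I envelope (~1600-1700 cm^-1, protein C=O stretching) is modelled
as a sum of pseudo-Voigt sub-bands, one per protein secondary-structure
class: alpha-helix at 1652 cm^-1, random coil at 1681 cm^-1 and beta-sheet
(default 1667 cm^-1).  Each sub-band is a height-normalised linear mix of a
Gaussian and a Lorentzian of common full width at half maximum (FWHM):

    PV(x; x0, w, eta) = eta * L(x; x0, w) + (1 - eta) * G(x; x0, w)

with G(x0) = L(x0) = 1, so the band's ``amplitude`` is its peak height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Band",
    "BandLibrary",
    "pseudo_voigt",
    "band_area",
    "default_band_library",
]

_4LN2 = 4.0 * math.log(2.0)


def pseudo_voigt(x, center: float, fwhm: float, eta: float):
    """Height-normalised pseudo-Voigt profile evaluated at ``x``.

    Parameters
    ----------
    x : array_like
        Wavenumber positions, cm^-1.
    center : float
        Band position x0, cm^-1.
    fwhm : float
        Full width at half maximum w, cm^-1; both the Gaussian and the
        Lorentzian component share it.
    eta : float
        Lorentzian fraction in [0, 1]; 0 is pure Gaussian, 1 pure Lorentzian.
    """
    x = np.asarray(x, dtype=float)
    u2 = ((x - center) / fwhm) ** 2
    gauss = np.exp(-_4LN2 * u2)
    lorentz = 1.0 / (1.0 + 4.0 * u2)
    return eta * lorentz + (1.0 - eta) * gauss


def band_area(amplitude: float, fwhm: float, eta: float) -> float:
    """Integrated area of a height-normalised pseudo-Voigt band.

    Gaussian part integrates to A*w*sqrt(pi / (4 ln 2)), Lorentzian part to
    A*w*pi/2; the pseudo-Voigt area is their eta-weighted mix.
    """
    g = math.sqrt(math.pi / _4LN2)
    l = math.pi / 2.0
    return amplitude * fwhm * (eta * l + (1.0 - eta) * g)


@dataclass
class Band:
    """One spectral sub-band.

    Attributes
    ----------
    label : str
        Secondary-structure tag, e.g. ``"alpha_helix"`` or ``"random_coil"``.
    center : float
        Band position, cm^-1.
    amplitude : float
        Peak height, arbitrary intensity units, >= 0.
    fwhm : float
        Full width at half maximum, cm^-1, > 0.
    eta : float
        Lorentzian fraction in [0, 1].
    """

    label: str
    center: float
    amplitude: float = 1.0
    fwhm: float = 18.0
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"band {self.label!r}: amplitude must be >= 0")
        if self.fwhm <= 0:
            raise ValueError(f"band {self.label!r}: fwhm must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"band {self.label!r}: eta must lie in [0, 1]")

    def profile(self, x):
        """Band intensity A * PV(x) on the wavenumber grid ``x``."""
        return self.amplitude * pseudo_voigt(x, self.center, self.fwhm, self.eta)

    @property
    def area(self) -> float:
        return band_area(self.amplitude, self.fwhm, self.eta)


@dataclass
class BandLibrary:
    """An ordered set of sub-bands plus the constraints used when fitting.

    ``center_tolerance`` bounds how far each band may shift from its library
    position during fitting; ``fwhm_bounds`` bound the fitted widths;
    ``window`` is the wavenumber interval the fit is restricted to.
    """

    bands: list[Band]
    center_tolerance: float = 5.0
    fwhm_bounds: tuple[float, float] = (8.0, 40.0)
    window: tuple[float, float] = (1570.0, 1730.0)

    def __post_init__(self) -> None:
        labels = [b.label for b in self.bands]
        if len(set(labels)) != len(labels):
            raise ValueError("band labels must be unique")
        lo, hi = self.window
        if not lo < hi:
            raise ValueError("window low must be < window high")
        wlo, whi = self.fwhm_bounds
        if not 0 < wlo < whi:
            raise ValueError("fwhm_bounds must satisfy 0 < min < max")
        for b in self.bands:
            if not lo <= b.center <= hi:
                raise ValueError(
                    f"band {b.label!r} center {b.center} outside window {self.window}"
                )

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)

    def get(self, label: str) -> Band:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(f"no band labelled {label!r}")

    def with_amplitudes(self, amplitudes: dict[str, float]) -> "BandLibrary":
        """Copy of the library with the given peak heights substituted."""
        bands = [
            replace(b, amplitude=amplitudes.get(b.label, b.amplitude))
            for b in self.bands
        ]
        return replace(self, bands=bands)


def default_band_library(
    *,
    fwhm: float = 18.0,
    eta: float = 0.5,
    beta_center: float = 1667.0,
    window: tuple[float, float] = (1570.0, 1730.0),
) -> BandLibrary:
    """The default Amide I decomposition: alpha-helix, beta-sheet, random coil.

    Centers: 1652 cm^-1 (alpha-helix) and 1681 cm^-1 (random coil) are the
    marker positions of the protein-folding ratio; the beta-sheet center
    (default 1667 cm^-1) sits between them and is configurable, as is the
    common default width.  Default relative heights alpha:beta = 1:0.5; the
    random-coil height is what the folding ratio controls and carries no
    meaningful default.
    """
    bands = [
        Band("alpha_helix", 1652.0, amplitude=100.0, fwhm=fwhm, eta=eta),
        Band("beta_sheet", beta_center, amplitude=50.0, fwhm=fwhm, eta=eta),
        Band("random_coil", 1681.0, amplitude=41.0, fwhm=fwhm, eta=eta),
    ]
    return BandLibrary(bands=bands, window=window)
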