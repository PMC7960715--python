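"""Replicate averaging, baseline correction and windowing.

Many depth-resolved replicate spectra per donor are averaged into one
spectrum, the broad fluorescence background is estimated and subtracted,
and the trace is cropped to the protein spectral zone before band fitting.

Two baseline estimators are provided.  The default is an iterative
peak-clipping polynomial fit (modpoly-style): it reproduces smooth
polynomial backgrounds exactly and stays out of the broad Amide I envelope.
Asymmetric least squares (a Whittaker smoother with asymmetric weights) is
available as an alternative; note its single stiffness parameter trades
following background curvature against sagging into wide band envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.signal import medfilt, savgol_filter

from .io import Spectrum

__all__ = [
    "PreprocessConfig",
    "average_spectra",
    "correct_baseline",
    "asymmetric_least_squares",
    "crop",
    "despike",
]


@dataclass
class PreprocessConfig:
    """Settings for the replicate-to-fit pipeline stage.

    ``window`` is the analysis interval in cm^-1 (default the Amide I region
    plus flanks); ``baseline_method`` one of "polynomial" (default),
    "asymmetric_least_squares" or "none"; ``baseline_params``
    method-specific scalars (polynomial: degree/n_iter; ALS: lam/p/n_iter);
    ``smoothing`` an odd Savitzky-Golay window width in points, or None;
    ``despike`` toggles median-filter spike removal with
    ``despike_threshold`` in robust-SD units.
    """

    window: tuple[float, float] = (1570.0, 1730.0)
    baseline_method: str = "polynomial"
    baseline_params: dict = field(default_factory=dict)
    smoothing: int | None = None
    despike: bool = False
    despike_threshold: float = 8.0

    def __post_init__(self) -> None:
        if not self.window[0] < self.window[1]:
            raise ValueError("window low must be < window high")
        if self.smoothing is not None and (self.smoothing < 3 or self.smoothing % 2 == 0):
            raise ValueError("smoothing window must be odd and >= 3")
        if self.baseline_method not in ("asymmetric_least_squares", "polynomial", "none"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")


def average_spectra(spectra, target_axis=None) -> Spectrum:
    """Pointwise mean of replicate spectra on a common wavenumber grid.

    Each spectrum is linearly interpolated onto ``target_axis`` (default:
    the first spectrum's axis); every spectrum must span the target range.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("average_spectra needs at least one spectrum")
    axis = np.asarray(
        target_axis if target_axis is not None else spectra[0].axis, dtype=float
    )
    acc = np.zeros_like(axis)
    for i, s in enumerate(spectra):
        if s.axis[0] > axis[0] or s.axis[-1] < axis[-1]:
            name = s.meta.get("donor_id", ""), s.meta.get("replicate", i)
            raise ValueError(
                f"spectrum {name} covers [{s.axis[0]}, {s.axis[-1]}] cm^-1, "
                f"not the target range [{axis[0]}, {axis[-1]}]"
            )
        acc += np.interp(axis, s.axis, s.intensity)
    meta = dict(spectra[0].meta)
    meta["n_averaged"] = len(spectra)
    return Spectrum(axis, acc / len(spectra), meta)


def asymmetric_least_squares(
    y, lam: float = 1e7, p: float = 0.01, n_iter: int = 10
) -> np.ndarray:
    """Estimate a smooth baseline under positive peaks.

    Minimises sum w_i (y_i - z_i)^2 + lam * sum (d2 z)^2 with asymmetric
    weights w_i = p where y > z and 1-p elsewhere, so the solution hugs the
    lower envelope of the signal.  lam controls stiffness, p the asymmetry.
    The default stiffness suits ~1 cm^-1 sampling, where the baseline must
    stay rigid across the ~70 cm^-1 wide Amide I envelope; lam scales
    roughly with the fourth power of points-per-bandwidth if the grid
    changes.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d.T @ d)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = sparse.diags(w, format="csc")
        z = spsolve(wmat + penalty, w * y)
        if not np.all(np.isfinite(z)):
            raise ArithmeticError(
                f"baseline solver diverged (lam={lam}, p={p}): non-finite solution"
            )
        w = np.where(y > z, p, 1.0 - p)
    return z


def _iterative_polynomial(y, x, degree: int = 3, n_iter: int = 20) -> np.ndarray:
    """Polynomial baseline by iterative peak clipping (modpoly-style)."""
    u = (x - x.mean()) / np.ptp(x)
    work = y.copy()
    for _ in range(n_iter):
        coef = np.polynomial.polynomial.polyfit(u, work, degree)
        fit = np.polynomial.polynomial.polyval(u, coef)
        work = np.minimum(work, fit)
    return fit


def correct_baseline(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Subtract the estimated fluorescence background.

    Output intensities are not clipped and may be slightly negative.
    Method "none" is the identity.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.baseline_method == "none":
        return s.copy()
    if len(s) < 10:
        raise ValueError("baseline correction needs a spectrum of length >= 10")
    if cfg.baseline_method == "asymmetric_least_squares":
        base = asymmetric_least_squares(
            s.intensity,
            lam=cfg.baseline_params.get("lam", 1e7),
            p=cfg.baseline_params.get("p", 0.01),
            n_iter=cfg.baseline_params.get("n_iter", 10),
        )
    else:
        base = _iterative_polynomial(
            s.intensity,
            s.axis,
            degree=cfg.baseline_params.get("degree", 3),
            n_iter=cfg.baseline_params.get("n_iter", 20),
        )
    out = s.copy(baseline_method=cfg.baseline_method)
    out.intensity = s.intensity - base
    return out


def crop(s: Spectrum, window) -> Spectrum:
    """Restrict a spectrum to the closed wavenumber interval ``window``."""
    lo, hi = window
    mask = (s.axis >= lo) & (s.axis <= hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] does not overlap the spectrum axis")
    return Spectrum(s.axis[mask], s.intensity[mask], dict(s.meta))


def despike(s: Spectrum, threshold: float = 8.0, kernel: int = 5) -> Spectrum:
    """Replace cosmic-ray spikes with the local median.

    A point is a spike when its residual against a running median exceeds
    ``threshold`` robust standard deviations (1.4826 x MAD).
    """
    med = medfilt(s.intensity, kernel_size=kernel)
    resid = s.intensity - med
    scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    out = s.copy()
    if scale > 0:
        spikes = np.abs(resid) > threshold * scale
        out.intensity[spikes] = med[spikes]
    return out


def smooth(s: Spectrum, window: int, polyorder: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing with an odd window width in points."""
    if window < 3 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 3")
    out = s.copy()
    out.intensity = savgol_filter(s.intensity, window, polyorder)
    return out
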