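"""Savitzky-Golay smoothing and first-derivative preprocessing.

Both operators are local least-squares polynomial fits (scipy's
``savgol_filter`` with polynomial-interpolation edge handling), so they are
linear in the spectrum and reproduce polynomials up to the fit order
exactly.  The derivative is taken with respect to wavenumber on the
ascending axis, i.e. units of AU per cm^-1, regardless of the descending
storage order.

The standard pipeline order is fixed: smooth, then differentiate (if
requested), then crop, so that filter edge effects never end up inside the
modelling region.  Peak-height statistics (the purity ratio) are computed on
smoothed, non-derivative spectra; multivariate models consume derivative
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import RegionSpec, Spectrum, SpectrumSet, crop_region

__all__ = ["PreprocessConfig", "savgol_smooth", "first_derivative", "preprocess_set"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Smoothing window/order, derivative order (0 or 1, with its own fit
    order) and the modelling region applied after filtering."""

    sg_window: int = 11
    sg_polyorder: int = 2
    derivative_order: int = 0
    deriv_polyorder: int = 3
    region: RegionSpec | None = field(default_factory=lambda: RegionSpec(((1800.0, 650.0),)))

    def __post_init__(self) -> None:
        _check_window(self.sg_window, self.sg_polyorder)
        if self.derivative_order not in (0, 1):
            raise ValueError("derivative_order must be 0 or 1")
        if self.derivative_order == 1:
            _check_window(self.sg_window, self.deriv_polyorder)


def _check_window(window: int, polyorder: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"Savitzky-Golay window must be an odd integer >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder ({polyorder}) must be smaller than the window ({window})")


def _uniform_step(wn: np.ndarray) -> float:
    d = np.diff(wn)
    step = d.mean()
    if np.max(np.abs(d - step)) > 1e-6 * abs(step):
        raise ValueError("Savitzky-Golay filtering requires a uniformly spaced grid")
    return step  # negative for the descending storage order


def savgol_smooth(s: Spectrum, window: int = 11, polyorder: int = 2) -> Spectrum:
    """Least-squares local polynomial smoothing; grid and metadata unchanged."""
    _check_window(window, polyorder)
    if len(s) < window:
        raise ValueError(f"spectrum has {len(s)} points, fewer than the window ({window})")
    _uniform_step(s.wavenumbers)
    return s.with_absorbance(savgol_filter(s.absorbance, window, polyorder, mode="interp"))


def first_derivative(s: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay first derivative d(absorbance)/d(wavenumber) in AU/cm^-1."""
    _check_window(window, polyorder)
    if len(s) < window:
        raise ValueError(f"spectrum has {len(s)} points, fewer than the window ({window})")
    step = _uniform_step(s.wavenumbers)
    dy = savgol_filter(s.absorbance, window, polyorder, deriv=1,
                       delta=abs(step), mode="interp")
    if step < 0:  # stored high->low: flip sign to differentiate along ascending axis
        dy = -dy
    return s.with_absorbance(dy)


def preprocess_set(sset: SpectrumSet, cfg: PreprocessConfig) -> SpectrumSet:
    """Smooth -> derivative (if order 1) -> crop, preserving metadata."""
    def one(s: Spectrum) -> Spectrum:
        out = savgol_smooth(s, cfg.sg_window, cfg.sg_polyorder)
        if cfg.derivative_order == 1:
            out = first_derivative(out, cfg.sg_window, cfg.deriv_polyorder)
        if cfg.region is not None:
            out = crop_region(out, cfg.region)
        return out

    return sset.map(one)
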