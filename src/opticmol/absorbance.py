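"""Chromophoric-DOM absorbance metrics.

Napierian absorption coefficients, SUVA254, spectral slopes from
log-linear regression, and the slope ratio S_R = S275-295 / S350-400.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AbsorbanceSpectrum",
    "AbsorbanceIndexSet",
    "napierian_coefficient",
    "decadic_coefficient",
    "suva254",
    "spectral_slope",
    "slope_ratio",
    "compute_indices",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Decadic absorbance vs wavelength for one sample.

    wavelengths are nm, strictly increasing; path_length is in metres
    (0.01 for the usual 1 cm cuvette).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    path_length: float = 0.01

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or wl.shape != ab.shape:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")

    def interp(self, wavelength) -> np.ndarray | float:
        """Linearly interpolated decadic absorbance at arbitrary wavelength(s)."""
        wl = np.asarray(wavelength, dtype=float)
        if np.any(wl < self.wavelengths[0]) or np.any(wl > self.wavelengths[-1]):
            raise ValueError(
                f"wavelength {wavelength} outside spectrum range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        out = np.interp(wl, self.wavelengths, self.absorbance)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AbsorbanceIndexSet:
    """Per-sample absorbance indices; a254 is Napierian, a254_decadic decadic."""

    a254: float
    a254_decadic: float
    suva254: float
    s275_295: float
    s350_400: float
    s_r: float


def napierian_coefficient(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    """Napierian absorption coefficient a(lambda) = ln(10) A(lambda) / L, in 1/m."""
    return LN10 * spec.interp(wavelength) / spec.path_length


def decadic_coefficient(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    """Decadic absorption coefficient A(lambda)/L, in 1/m."""
    return spec.interp(wavelength) / spec.path_length


def suva254(spec: AbsorbanceSpectrum, doc: float) -> float:
    """Specific UV absorbance at 254 nm, L / (mg-C m).

    Decadic absorption coefficient at 254 nm divided by DOC (mg-C/L);
    the Weishaar convention.
    """
    if doc <= 0:
        raise ValueError(f"DOC must be positive, got {doc}")
    return decadic_coefficient(spec, 254.0) / doc


def spectral_slope(spec: AbsorbanceSpectrum, lo: float, hi: float) -> float:
    """Spectral slope S over [lo, hi] nm from OLS of ln a(lambda) on lambda.

    Returns -slope so that a steeper exponential decay gives a larger
    positive S (in 1/nm). Requires >= 3 grid points with strictly positive
    absorbance in the window.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    sel = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    wl = spec.wavelengths[sel]
    ab = spec.absorbance[sel]
    if len(wl) < 3:
        raise ValueError(f"fewer than 3 grid points in [{lo}, {hi}] nm")
    bad = wl[ab <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive absorbance in slope window at wavelengths {bad.tolist()}"
        )
    slope, _ = np.polyfit(wl, np.log(ab), 1)
    return float(-slope)


def slope_ratio(s275: float, s350: float) -> float:
    """S_R = S275-295 / S350-400; NaN (missing) when the denominator is 0."""
    if s350 == 0 or not np.isfinite(s350) or not np.isfinite(s275):
        return float("nan")
    return s275 / s350


def compute_indices(spec: AbsorbanceSpectrum, doc: float) -> AbsorbanceIndexSet:
    """All absorbance indices for one sample."""
    s275 = spectral_slope(spec, 275.0, 295.0)
    s350 = spectral_slope(spec, 350.0, 400.0)
    return AbsorbanceIndexSet(
        a254=napierian_coefficient(spec, 254.0),
        a254_decadic=decadic_coefficient(spec, 254.0),
        suva254=suva254(spec, doc),
        s275_295=s275,
        s350_400=s350,
        s_r=slope_ratio(s275, s350),
    )
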