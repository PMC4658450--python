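"""Excitation-emission matrix (EEM) hygiene and scalar fluorescence indices.

Blank subtraction, absorbance-based inner-filter correction, Rayleigh
scatter excision, and the FI / freshness / HIX indices. Missing or excised
cells are carried in a boolean mask and never interpolated away, so the
trilinear decomposition downstream sees genuinely missing data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .absorbance import AbsorbanceSpectrum

__all__ = [
    "EEM",
    "FluorescenceIndexSet",
    "blank_subtract",
    "inner_filter_correct",
    "excise_scatter",
    "fluorescence_index",
    "freshness_index",
    "hix",
    "compute_fluorescence_indices",
]

log = logging.getLogger(__name__)

#: Default half-widths (nm) for first- and second-order Rayleigh excision.
DEFAULT_FIRST_ORDER_WIDTH = 15.0
DEFAULT_SECOND_ORDER_WIDTH = 15.0


@dataclass(frozen=True)
class EEM:
    """Fluorescence intensity over an excitation x emission grid.

    mask is True where a cell is missing/excised; masked cells carry no
    intensity meaning. units_tag tracks the processing state
    (raw -> blank_subtracted -> ife_corrected -> qsu).
    """

    excitation: np.ndarray
    emission: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    units_tag: str = "raw"

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "intensity", inten)
        if self.mask is None:
            object.__setattr__(self, "mask", ~np.isfinite(inten))
        else:
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if inten.shape != (len(ex), len(em)):
            raise ValueError("intensity shape must be (n_excitation, n_emission)")
        if self.mask.shape != inten.shape:
            raise ValueError("mask and intensity must share shape")
        for grid, name in ((ex, "excitation"), (em, "emission")):
            if len(grid) >= 2 and not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} grid must be strictly increasing")

    def values(self) -> np.ndarray:
        """Intensity with masked cells as NaN."""
        out = self.intensity.copy()
        out[self.mask] = np.nan
        return out

    def _ex_row(self, target: float, slack: float = 2.5) -> int:
        idx = int(np.argmin(np.abs(self.excitation - target)))
        if abs(self.excitation[idx] - target) > slack:
            raise ValueError(
                f"no excitation wavelength within {slack} nm of {target} nm"
            )
        return idx

    def emission_intensity(self, ex_target: float, em_target: float) -> float:
        """Intensity at (ex, em), linearly interpolated along emission.

        Returns NaN if a needed cell is masked or out of range.
        """
        try:
            row = self._ex_row(ex_target)
        except ValueError:
            return float("nan")
        if em_target < self.emission[0] or em_target > self.emission[-1]:
            return float("nan")
        vals = self.values()[row]
        j = int(np.searchsorted(self.emission, em_target))
        if self.emission[min(j, len(self.emission) - 1)] == em_target:
            return float(vals[min(j, len(self.emission) - 1)])
        lo, hi = j - 1, j
        if not (np.isfinite(vals[lo]) and np.isfinite(vals[hi])):
            log.warning("masked cell near ex=%s em=%s; index missing", ex_target, em_target)
            return float("nan")
        frac = (em_target - self.emission[lo]) / (self.emission[hi] - self.emission[lo])
        return float(vals[lo] + frac * (vals[hi] - vals[lo]))


@dataclass(frozen=True)
class FluorescenceIndexSet:
    fi: float
    freshness: float
    hix_ohno: float
    hix_zsolnay: float
    hix_excitation_nm: float


def blank_subtract(sample: EEM, blank: EEM) -> EEM:
    """Cellwise sample minus blank, floored at 0; grids must match exactly."""
    if not (np.array_equal(sample.excitation, blank.excitation)
            and np.array_equal(sample.emission, blank.emission)):
        raise ValueError("sample and blank EEM grids differ")
    diff = np.maximum(sample.intensity - blank.intensity, 0.0)
    return replace(sample, intensity=diff,
                   mask=sample.mask | blank.mask, units_tag="blank_subtracted")


def inner_filter_correct(eem: EEM, spec: AbsorbanceSpectrum) -> EEM:
    """Absorbance-based (ABA) inner-filter correction.

    F_corr(ex, em) = F_obs * 10^((A_ex + A_em)/2) with A the decadic
    absorbance per cm derived from the spectrum's path length. Total
    absorbance A_ex + A_em above 3.0 makes the correction unreliable and
    is logged as a warning.
    """
    a_per_cm_ex = np.asarray(spec.interp(eem.excitation)) / (spec.path_length * 100.0)
    a_per_cm_em = np.asarray(spec.interp(eem.emission)) / (spec.path_length * 100.0)
    total = a_per_cm_ex[:, None] + a_per_cm_em[None, :]
    n_high = int(np.sum((total > 3.0) & ~eem.mask))
    if n_high:
        log.warning("inner-filter correction unreliable for %d cells (A_ex+A_em > 3)", n_high)
    corrected = eem.intensity * 10.0 ** (total / 2.0)
    return replace(eem, intensity=corrected, units_tag="ife_corrected")


def excise_scatter(
    eem: EEM,
    first_width: float = DEFAULT_FIRST_ORDER_WIDTH,
    second_width: float = DEFAULT_SECOND_ORDER_WIDTH,
) -> EEM:
    """Mask first- and second-order Rayleigh scatter ridges.

    Cells with |em - ex| <= first_width or |em - 2 ex| <= second_width are
    marked missing. Idempotent.
    """
    if first_width <= 0 or second_width <= 0:
        raise ValueError("scatter widths must be positive")
    ex = eem.excitation[:, None]
    em = eem.emission[None, :]
    ridge = (np.abs(em - ex) <= first_width) | (np.abs(em - 2.0 * ex) <= second_width)
    newly = int(np.sum(ridge & ~eem.mask))
    log.info("excise_scatter masked %d new cells", newly)
    return replace(eem, mask=eem.mask | ridge)


def fluorescence_index(eem: EEM) -> float:
    """FI: emission intensity ratio I(370, 470) / I(370, 520)."""
    num = eem.emission_intensity(370.0, 470.0)
    den = eem.emission_intensity(370.0, 520.0)
    if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
        return float("nan")
    return num / den


def freshness_index(eem: EEM) -> float:
    """Freshness (beta/alpha): I(310, 380) / max I(310, 420..435)."""
    num = eem.emission_intensity(310.0, 380.0)
    try:
        row = eem._ex_row(310.0)
    except ValueError:
        return float("nan")
    vals = eem.values()[row]
    sel = (eem.emission >= 420.0) & (eem.emission <= 435.0)
    window = vals[sel]
    window = window[np.isfinite(window)]
    if not np.isfinite(num) or len(window) == 0:
        return float("nan")
    den = float(np.max(window))
    if den <= 0:
        return float("nan")
    return num / den


def _trapz_window(eem: EEM, row: int, lo: float, hi: float) -> float:
    vals = eem.values()[row]
    sel = (eem.emission >= lo) & (eem.emission <= hi)
    em = eem.emission[sel]
    v = vals[sel]
    if len(em) < 2 or not np.all(np.isfinite(v)):
        return float("nan")
    return float(np.trapezoid(v, em))


def hix(eem: EEM) -> tuple[float, float, float]:
    """Humification index on the lowest available excitation row.

    The classical definition uses excitation 254 nm; grids that start
    above that use their lowest row, which is recorded in the return.
    Returns (hix_ohno, hix_zsolnay, excitation_nm_used) where
    hix_ohno = H/(H+L) and hix_zsolnay = H/L with H the trapezoidal
    emission area over 435-480 nm and L over 300-345 nm.
    """
    if eem.excitation[0] <= 255.0:
        row = eem._ex_row(254.0, slack=1.5)
    else:
        row = 0
    ex_used = float(eem.excitation[row])
    h_area = _trapz_window(eem, row, 435.0, 480.0)
    l_area = _trapz_window(eem, row, 300.0, 345.0)
    if not (np.isfinite(h_area) and np.isfinite(l_area)):
        return float("nan"), float("nan"), ex_used
    if h_area == 0.0:
        return 0.0, 0.0, ex_used
    ohno = h_area / (h_area + l_area) if (h_area + l_area) > 0 else float("nan")
    zsolnay = h_area / l_area if l_area > 0 else float("nan")
    return ohno, zsolnay, ex_used


def compute_fluorescence_indices(eem: EEM) -> FluorescenceIndexSet:
    ohno, zsolnay, ex_used = hix(eem)
    return FluorescenceIndexSet(
        fi=fluorescence_index(eem),
        freshness=freshness_index(eem),
        hix_ohno=ohno,
        hix_zsolnay=zsolnay,
        hix_excitation_nm=ex_used,
    )
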