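"""FTICR-MS peak lists to an aligned, standardized formula x sample matrix.

Molecular formula assignment by exhaustive CHNOSP enumeration within a ppm
tolerance ([M-H]- ions), per-sample dynamic range (DR), standardized
detection limit (SDL) intensity fill, and column normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formula import (
    MolecularFormula,
    FormulaAnnotation,
    MONOISOTOPIC,
    PROTON_MASS,
    annotate,
    monoisotopic_mass,
)

__all__ = [
    "Peak",
    "AssignmentConfig",
    "Assignment",
    "FormulaAssigner",
    "assign_formula",
    "dynamic_range",
    "AssignedSample",
    "PeakMatrix",
    "sdl_standardize",
    "normalize_columns",
    "build_peak_matrix",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """One mass-spectral peak: m/z of the singly charged [M-H]- ion."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.snr < 0 or self.intensity < 0:
            raise ValueError("intensity and snr must be non-negative")


@dataclass(frozen=True)
class AssignmentConfig:
    """Enumeration bounds and filtering rules for formula assignment.

    The defaults are the conventional DOM assignment rules: CHNOSP with
    modest heteroatom caps, 0.3 <= H/C <= 2.5, O/C <= 1.2, integer DBE in
    [0, 40], and the even-electron parity requirement for [M-H]- ions.
    """

    tolerance_ppm: float = 0.2
    c_min: int = 1
    c_max: int = 60
    h_min: int = 1
    h_max: int = 120
    n_max: int = 4
    o_max: int = 40
    s_max: int = 2
    p_max: int = 1
    hc_min: float = 0.3
    hc_max: float = 2.5
    oc_max: float = 1.2
    dbe_min: float = 0.0
    dbe_max: float = 40.0
    parity_check: bool = True
    snr_min: float = 5.0
    mz_min: float = 150.0
    mz_max: float = 750.0

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")


@dataclass(frozen=True)
class Assignment:
    formula: MolecularFormula
    error_ppm: float
    ambiguous: bool
    n_candidates: int


class FormulaAssigner:
    """Exhaustive CHNOSP assigner with a precomputed candidate table.

    All (C, N, O, S, P) combinations within bounds are tabulated once with
    their H-free base masses; for a query m/z the hydrogen count follows
    analytically from the mass remainder, so each assignment is a single
    vectorized window scan over the table.
    """

    def __init__(self, cfg: AssignmentConfig | None = None):
        self.cfg = cfg or AssignmentConfig()
        cfg = self.cfg
        c = np.arange(cfg.c_min, cfg.c_max + 1)
        n = np.arange(0, cfg.n_max + 1)
        o = np.arange(0, cfg.o_max + 1)
        s = np.arange(0, cfg.s_max + 1)
        p = np.arange(0, cfg.p_max + 1)
        C, N, O, S, P = (a.ravel() for a in np.meshgrid(c, n, o, s, p, indexing="ij"))
        keep = O <= np.ceil(cfg.oc_max * C)  # O/C bound is H-independent
        self._c, self._n, self._o, self._s, self._p = C[keep], N[keep], O[keep], S[keep], P[keep]
        base = (self._c * MONOISOTOPIC["C"] + self._n * MONOISOTOPIC["N"]
                + self._o * MONOISOTOPIC["O"] + self._s * MONOISOTOPIC["S"]
                + self._p * MONOISOTOPIC["P"])
        order = np.argsort(base)
        for name in ("_c", "_n", "_o", "_s", "_p"):
            setattr(self, name, getattr(self, name)[order])
        self._base = base[order]
        self._cache: dict[float, Assignment | None] = {}

    def assign(self, mz: float, use_cache: bool = True) -> Assignment | None:
        """Assign zero or one molecular formula to an [M-H]- m/z."""
        if use_cache and mz in self._cache:
            return self._cache[mz]
        cfg = self.cfg
        m_h = MONOISOTOPIC["H"]
        neutral = mz + PROTON_MASS
        lo = np.searchsorted(self._base, neutral - (cfg.h_max + 0.5) * m_h)
        hi = np.searchsorted(self._base, neutral - (cfg.h_min - 0.5) * m_h)
        result = None
        if hi > lo:
            base = self._base[lo:hi]
            h = np.rint((neutral - base) / m_h).astype(int)
            cand_mz = base + h * m_h - PROTON_MASS
            err_ppm = (cand_mz - mz) / mz * 1e6
            c = self._c[lo:hi]
            n = self._n[lo:hi]
            o = self._o[lo:hi]
            p = self._p[lo:hi]
            s = self._s[lo:hi]
            dbe = 1.0 + c - h / 2.0 + n / 2.0 + p / 2.0
            ok = (
                (np.abs(err_ppm) <= cfg.tolerance_ppm)
                & (h >= cfg.h_min) & (h <= cfg.h_max)
                & (h >= cfg.hc_min * c) & (h <= cfg.hc_max * c)
                & (o <= cfg.oc_max * c)
                & (dbe >= cfg.dbe_min) & (dbe <= cfg.dbe_max)
            )
            if cfg.parity_check:
                ok &= (h + n + p) % 2 == 0
            idx = np.flatnonzero(ok)
            if len(idx):
                het = n[idx] + s[idx] + p[idx]
                order = np.lexsort((het, np.abs(err_ppm[idx])))
                best = idx[order[0]]
                result = Assignment(
                    formula=MolecularFormula(int(c[best]), int(h[best]), int(n[best]),
                                             int(o[best]), int(s[best]), int(p[best])),
                    error_ppm=float(err_ppm[best]),
                    ambiguous=len(idx) > 1,
                    n_candidates=len(idx),
                )
        if use_cache:
            self._cache[mz] = result
        return result


def assign_formula(mz: float, cfg: AssignmentConfig | None = None) -> Assignment | None:
    """One-shot assignment (builds a fresh table; use FormulaAssigner in loops)."""
    return FormulaAssigner(cfg).assign(mz, use_cache=False)


def dynamic_range(peaks: list[Peak]) -> float:
    """Mean of the top min(500, n) intensities over the mean of the 10 lowest."""
    if len(peaks) < 10:
        raise ValueError(f"dynamic range needs >= 10 peaks, got {len(peaks)}")
    inten = np.sort(np.asarray([p.intensity for p in peaks], dtype=float))
    top = inten[-min(500, len(inten)):]
    low = inten[:10]
    return float(top.mean() / low.mean())


@dataclass
class AssignedSample:
    """Per-sample assignment result feeding SDL standardization.

    intensities: all retained (S/N-filtered, in-range) peak intensities,
    used for DR/SDL arithmetic; formula_intensities: detected intensity per
    assigned formula.
    """

    sample_id: str
    intensities: np.ndarray
    formula_intensities: dict[MolecularFormula, float]
    ambiguous: set = field(default_factory=set)


@dataclass
class PeakMatrix:
    """Formula x sample intensity matrix after SDL fill.

    Every cell is >= its sample's SDL; `normalized` columns each sum to 1.
    """

    formulae: list[FormulaAnnotation]
    samples: list[str]
    intensities: np.ndarray
    sdl_per_sample: np.ndarray
    dr_per_sample: np.ndarray
    normalized: np.ndarray | None = None
    ambiguous: np.ndarray | None = None  # (formula, sample) bool: winner was ambiguous
    detected: np.ndarray | None = None   # (formula, sample) bool: above-SDL detection

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.neutral_mass for a in self.formulae])


def sdl_standardize(samples: list[AssignedSample]) -> PeakMatrix:
    """Align samples on the union formula set with SDL intensity fill.

    DR_min is the cohort minimum dynamic range; each sample's SDL is its
    mean top-500 intensity divided by DR_min. Any union formula that is
    undetected in a sample, or detected below the SDL, is set to that
    sample's SDL (false-negative prevention); detections at or above the
    SDL pass through unchanged.
    """
    if len(samples) < 2:
        raise ValueError("SDL standardization needs >= 2 samples")
    kept, drs, topmeans = [], [], []
    for s in samples:
        peaks = [Peak(1.0, float(v), 10.0) for v in s.intensities]
        try:
            dr = dynamic_range(peaks)
        except ValueError as exc:
            log.warning("sample %s excluded from SDL standardization: %s", s.sample_id, exc)
            continue
        inten = np.sort(np.asarray(s.intensities, dtype=float))
        kept.append(s)
        drs.append(dr)
        topmeans.append(float(inten[-min(500, len(inten)):].mean()))
    if len(kept) < 2:
        raise ValueError("fewer than 2 samples with a valid dynamic range")
    drs = np.array(drs)
    sdls = np.array(topmeans) / drs.min()
    union = sorted({f for s in kept for f in s.formula_intensities},
                   key=lambda f: (monoisotopic_mass(f), f))
    fidx = {f: i for i, f in enumerate(union)}
    mat = np.tile(sdls, (len(union), 1))
    detected = np.zeros((len(union), len(kept)), dtype=bool)
    ambiguous = np.zeros_like(detected)
    for j, s in enumerate(kept):
        for f, v in s.formula_intensities.items():
            i = fidx[f]
            if v >= sdls[j]:
                mat[i, j] = v
                detected[i, j] = True
            if f in s.ambiguous:
                ambiguous[i, j] = True
    return PeakMatrix(
        formulae=[annotate(f) for f in union],
        samples=[s.sample_id for s in kept],
        intensities=mat,
        sdl_per_sample=sdls,
        dr_per_sample=drs,
        detected=detected,
        ambiguous=ambiguous,
    )


def normalize_columns(m: PeakMatrix) -> PeakMatrix:
    """Attach the column-stochastic matrix (per-sample sum-normalized)."""
    sums = m.intensities.sum(axis=0)
    keep = sums > 0
    if not np.all(keep):
        dropped = [s for s, k in zip(m.samples, keep) if not k]
        log.warning("normalize_columns dropped zero-intensity samples: %s", dropped)
    norm = m.intensities[:, keep] / sums[keep]
    return PeakMatrix(
        formulae=m.formulae,
        samples=[s for s, k in zip(m.samples, keep) if k],
        intensities=m.intensities[:, keep],
        sdl_per_sample=m.sdl_per_sample[keep],
        dr_per_sample=m.dr_per_sample[keep],
        normalized=norm,
        ambiguous=None if m.ambiguous is None else m.ambiguous[:, keep],
        detected=None if m.detected is None else m.detected[:, keep],
    )


def build_peak_matrix(peak_lists: dict[str, list[Peak]],
                      cfg: AssignmentConfig | None = None) -> PeakMatrix:
    """Full per-sample pipeline: S/N and mass-range filtering, formula
    assignment, SDL standardization, column normalization."""
    cfg = cfg or AssignmentConfig()
    assigner = FormulaAssigner(cfg)
    assigned = []
    for sid, peaks in peak_lists.items():
        retained = [p for p in peaks if p.snr > cfg.snr_min]
        in_range = [p for p in retained if cfg.mz_min <= p.mz <= cfg.mz_max]
        n_skipped = len(retained) - len(in_range)
        if n_skipped:
            log.info("sample %s: %d peaks outside %g-%g Da skipped",
                     sid, n_skipped, cfg.mz_min, cfg.mz_max)
        formula_intensities: dict[MolecularFormula, float] = {}
        ambiguous: set = set()
        for p in in_range:
            a = assigner.assign(p.mz)
            if a is None:
                continue
            prev = formula_intensities.get(a.formula, 0.0)
            formula_intensities[a.formula] = max(prev, p.intensity)
            if a.ambiguous:
                ambiguous.add(a.formula)
        assigned.append(AssignedSample(
            sample_id=sid,
            intensities=np.array([p.intensity for p in in_range], dtype=float),
            formula_intensities=formula_intensities,
            ambiguous=ambiguous,
        ))
    return normalize_columns(sdl_standardize(assigned))
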