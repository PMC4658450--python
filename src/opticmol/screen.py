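"""Spearman rank screening of formula intensities against optical properties.

Every formula's normalized intensity profile is correlated (Spearman, with
average-rank ties) against every optical property across samples; the
significant sets at p < alpha feed class summaries, shared-formula count
matrices, van Krevelen exports, and mass / H:C / AI-mod distribution
profiles. No multiple-testing correction is applied for the paper-style
screen; Benjamini-Hochberg q-values are reported as a clearly separate
extension column.
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .fticr import PeakMatrix

__all__ = [
    "spearman_rho_p",
    "spearman_exact_p",
    "spearman_screen",
    "summarize_classes",
    "shared_formula_matrix",
    "distribution_profiles",
    "van_krevelen_export",
]

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
EXACT_P_MAX_N = 9


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Spearman p by full permutation enumeration (n <= 9).

    Ties are handled with average ranks; the null distribution is built
    from all n! orderings of one margin against the other's fixed ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > EXACT_P_MAX_N:
        raise ValueError(f"exact permutation p limited to n <= {EXACT_P_MAX_N}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    rho = float(np.sum(rx_c * ry_c) / denom)
    perms = _perm_matrix(n)
    null = (ry_c[perms] @ rx_c) / denom
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p for one pair.

    Exact permutation p for n <= 9, t-distribution approximation (with
    average-rank tie correction folded into the rank correlation) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n <= EXACT_P_MAX_N:
        return spearman_exact_p(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _t_approx_p(np.array([rho]), n)[0]


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t(n-2) approximation; |rho| = 1 gives p = 0."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return p


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (NaN-safe)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    pv = p[ok]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def spearman_screen(matrix: PeakMatrix, optics: pd.DataFrame,
                    alpha: float = DEFAULT_ALPHA,
                    min_detected: int = 5) -> pd.DataFrame:
    """Screen every (formula, optical property) pair.

    optics: DataFrame indexed by sample_id, one column per property.
    Returns a long-format DataFrame with rho, p, n_used, significance
    flags at alpha, and BH q-values (extension column, per property).
    SDL-filled constant intensity rows are excluded (rank-undefined), and
    a formula must be detected above the SDL in at least `min_detected`
    samples: SDL-filled cells are placeholders, not measurements, so a
    nearly-all-filled row has too few informative observations to rank
    (the same floor as the per-pair overlapping-sample requirement).
    """
    if matrix.normalized is None:
        raise ValueError("matrix must be column-normalized before screening")
    common = [s for s in matrix.samples if s in optics.index]
    col_of = {s: i for i, s in enumerate(matrix.samples)}
    formula_ids = np.array([str(a.formula) for a in matrix.formulae])
    if matrix.detected is not None:
        screenable = matrix.detected.sum(axis=1) >= min_detected
    else:
        screenable = np.ones(len(formula_ids), dtype=bool)
    records = []
    for prop in optics.columns:
        vals = optics.loc[common, prop].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        used = [s for s, o in zip(common, ok) if o]
        n = len(used)
        if n < 5:
            log.warning("property %s skipped: only %d overlapping samples", prop, n)
            continue
        y = vals[ok]
        sub = matrix.normalized[:, [col_of[s] for s in used]]
        variable = (np.ptp(sub, axis=1) > 0) & screenable
        if np.ptp(stats.rankdata(y)) == 0:
            log.warning("property %s skipped: constant across samples", prop)
            continue
        if n <= EXACT_P_MAX_N:
            rho = np.full(sub.shape[0], np.nan)
            p = np.full(sub.shape[0], np.nan)
            for i in np.flatnonzero(variable):
                rho[i], p[i] = spearman_exact_p(sub[i], y)
        else:
            rx = stats.rankdata(sub, axis=1)
            ry = stats.rankdata(y)
            rx_c = rx - rx.mean(axis=1, keepdims=True)
            ry_c = ry - ry.mean()
            denom = np.sqrt(np.sum(rx_c**2, axis=1) * np.sum(ry_c**2))
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(variable, (rx_c @ ry_c) / denom, np.nan)
            p = np.where(variable, _t_approx_p(rho, n), np.nan)
        q = _bh_qvalues(p)
        sig = np.isfinite(p) & (p < alpha)
        records.append(pd.DataFrame({
            "formula": formula_ids,
            "property": prop,
            "rho": rho,
            "p": p,
            "q_bh": q,
            "n_used": n,
            "significant_positive": sig & (rho > 0),
            "significant_negative": sig & (rho < 0),
        }))
    if not records:
        return pd.DataFrame(columns=["formula", "property", "rho", "p", "q_bh",
                                     "n_used", "significant_positive",
                                     "significant_negative"])
    return pd.concat(records, ignore_index=True)


def _annotation_frame(matrix: PeakMatrix) -> pd.DataFrame:
    rows = []
    weights = (matrix.normalized if matrix.normalized is not None
               else matrix.intensities).mean(axis=1)
    for a, w in zip(matrix.formulae, weights):
        f = a.formula
        rows.append({
            "formula": str(f),
            "neutral_mass": a.neutral_mass,
            "oc_ratio": a.oc_ratio,
            "hc_ratio": a.hc_ratio,
            "ai_mod": a.ai_mod,
            "dbe": a.dbe,
            "compound_class": a.compound_class.value,
            "n": f.n, "s": f.s, "p": f.p,
            "mean_intensity": w,
        })
    return pd.DataFrame(rows).set_index("formula")


def _category_masks(ann: pd.DataFrame) -> dict[str, np.ndarray]:
    """Elemental-group and compound-class membership masks.

    Accounting convention: CHON/CHOS/CHOP mean 'contains that heteroatom'
    (groups may overlap for mixed formulae); NSP is any heteroatom, so
    CHO + NSP partitions the set exactly.
    """
    masks = {
        "CHO": ((ann["n"] == 0) & (ann["s"] == 0) & (ann["p"] == 0)).to_numpy(),
        "CHON": (ann["n"] > 0).to_numpy(),
        "CHOS": (ann["s"] > 0).to_numpy(),
        "CHOP": (ann["p"] > 0).to_numpy(),
        "NSP": ((ann["n"] > 0) | (ann["s"] > 0) | (ann["p"] > 0)).to_numpy(),
    }
    for cls in ann["compound_class"].unique():
        masks[cls] = (ann["compound_class"] == cls).to_numpy()
    return masks


def summarize_classes(results: pd.DataFrame, matrix: PeakMatrix,
                      direction: str = "positive") -> pd.DataFrame:
    """Per property x category summary of the significant formula sets.

    For each optical property and each category (elemental groups and
    compound classes, plus an 'all' row) reports the count of significant
    formulae, the count-percent of the category, the intensity-weighted
    percent (share of the category's total mean normalized intensity), and
    the mean neutral mass of the significant set.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    flag = f"significant_{direction}"
    ann = _annotation_frame(matrix)
    masks = _category_masks(ann)
    masks = {"all": np.ones(len(ann), dtype=bool), **masks}
    weights = ann["mean_intensity"].to_numpy()
    masses = ann["neutral_mass"].to_numpy()
    fidx = {f: i for i, f in enumerate(ann.index)}
    rows = []
    for prop, grp in results.groupby("property", sort=False):
        sig = np.zeros(len(ann), dtype=bool)
        hits = grp.loc[grp[flag], "formula"]
        sig[[fidx[f] for f in hits if f in fidx]] = True
        for cat, mask in masks.items():
            tot_n = int(mask.sum())
            tot_w = float(weights[mask].sum())
            sel = sig & mask
            n_sig = int(sel.sum())
            rows.append({
                "property": prop,
                "category": cat,
                "n_total": tot_n,
                "n_significant": n_sig,
                "count_percent": 100.0 * n_sig / tot_n if tot_n else 0.0,
                "intensity_percent": (100.0 * float(weights[sel].sum()) / tot_w
                                      if tot_w > 0 else 0.0),
                "mean_mz": float(masses[sel].mean()) if n_sig else float("nan"),
            })
    return pd.DataFrame(rows)


def shared_formula_matrix(results: pd.DataFrame,
                          direction: str = "positive") -> pd.DataFrame:
    """Symmetric property x property matrix of shared significant formulae.

    Entry (i, j) counts formulae significant (in the stated direction) for
    both properties; the diagonal is the per-property set size.
    """
    flag = f"significant_{direction}"
    sets = {prop: set(grp.loc[grp[flag], "formula"])
            for prop, grp in results.groupby("property", sort=False)}
    props = list(sets)
    mat = np.zeros((len(props), len(props)), dtype=int)
    for i, a in enumerate(props):
        for j, b in enumerate(props):
            mat[i, j] = len(sets[a] & sets[b])
    return pd.DataFrame(mat, index=props, columns=props)


def distribution_profiles(results: pd.DataFrame, matrix: PeakMatrix,
                          direction: str = "positive",
                          mass_bin: float = 50.0, hc_bin: float = 0.1,
                          ai_bin: float = 0.05) -> pd.DataFrame:
    """Binned mass / H:C / AI-mod distributions of each significant set.

    Emits a tidy frame with raw counts and intensity-weighted counts per
    bin; empty significant sets yield an empty profile flagged by absence.
    """
    flag = f"significant_{direction}"
    ann = _annotation_frame(matrix)
    variables = {
        "neutral_mass": mass_bin,
        "hc_ratio": hc_bin,
        "ai_mod": ai_bin,
    }
    rows = []
    for prop, grp in results.groupby("property", sort=False):
        hits = grp.loc[grp[flag], "formula"]
        sub = ann.loc[[f for f in hits if f in ann.index]]
        if sub.empty:
            log.info("distribution_profiles: empty significant set for %s", prop)
            continue
        for var, width in variables.items():
            v = sub[var].to_numpy()
            w = sub["mean_intensity"].to_numpy()
            lo = np.floor(v.min() / width) * width
            nbins = int(np.ceil((v.max() - lo) / width)) + 1
            edges = lo + width * np.arange(nbins + 1)
            counts, _ = np.histogram(v, bins=edges)
            wsum, _ = np.histogram(v, bins=edges, weights=w)
            for b in range(nbins):
                if counts[b] or wsum[b]:
                    rows.append({
                        "property": prop, "variable": var,
                        "bin_left": edges[b], "bin_right": edges[b + 1],
                        "count": int(counts[b]),
                        "weighted": float(wsum[b]),
                    })
    return pd.DataFrame(rows, columns=["property", "variable", "bin_left",
                                       "bin_right", "count", "weighted"])


def van_krevelen_export(results: pd.DataFrame, matrix: PeakMatrix,
                        prop: str, direction: str = "positive") -> pd.DataFrame:
    """Tidy (O/C, H/C, class, intensity) point set for one property's
    significant formulae, ready for any plotting layer."""
    flag = f"significant_{direction}"
    ann = _annotation_frame(matrix)
    grp = results[results["property"] == prop]
    hits = grp.loc[grp[flag], "formula"]
    sub = ann.loc[[f for f in hits if f in ann.index]]
    out = sub[["oc_ratio", "hc_ratio", "compound_class", "mean_intensity",
               "neutral_mass", "ai_mod"]].reset_index()
    return out
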