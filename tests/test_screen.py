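"""Spearman screening, class summaries, shared-formula and profile tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from opticmol import (AssignedSample, MolecularFormula, normalize_columns,
                      sdl_standardize, shared_formula_matrix, spearman_exact_p,
                      spearman_rho_p, spearman_screen, summarize_classes,
                      distribution_profiles, van_krevelen_export)


def brute_force_exact_p(x, y):
    """Direct permutation enumeration, coded independently of the library."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    def rho_of(a, b):
        ac = a - np.mean(a); bc = b - np.mean(b)
        return float(np.sum(ac * bc) / math.sqrt(np.sum(ac**2) * np.sum(bc**2)))
    obs = abs(rho_of(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total


class TestSpearmanP:
    def test_exact_matches_brute_force_n7(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            _, p = spearman_exact_p(x, y)
            assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_exact_with_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 2.0, 5.0, 4.0, 4.0, 7.0])
        _, p = spearman_exact_p(x, y)
        assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_perfect_monotone(self):
        rho, p = spearman_rho_p(np.arange(10.0), np.arange(10.0) ** 3)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=57)
        y = 0.5 * x + rng.normal(size=57)
        rho, p = spearman_rho_p(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_vector_is_missing(self):
        rho, p = spearman_rho_p(np.ones(12), np.arange(12.0))
        assert math.isnan(rho) and math.isnan(p)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, p1 = spearman_rho_p(x, y)
        r2, p2 = spearman_rho_p(np.exp(x), y ** 3 + 5 * y)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


def toy_matrix(n_samples=12, seed=0):
    """Small PeakMatrix with formulae spanning several compound classes."""
    rng = np.random.default_rng(seed)
    texts = ["C24H12", "C15H12O7", "C20H18O9", "C10H16O2", "C8H15N1O3",
             "C6H12O6", "C10H20O2", "C16H20O8", "C12H22N2O4", "C18H14O8"]
    formulas = [MolecularFormula(*counts) for counts in
                ((24,12,0,0,0,0),(15,12,0,7,0,0),(20,18,0,9,0,0),
                 (10,16,0,2,0,0),(8,15,1,3,0,0),(6,12,0,6,0,0),
                 (10,20,0,2,0,0),(16,20,0,8,0,0),(12,22,2,4,0,0),
                 (18,14,0,8,0,0))]
    samples = []
    driver = np.linspace(0.0, 1.0, n_samples)
    for i in range(n_samples):
        ints = {}
        for j, f in enumerate(formulas):
            base = 1e6 * (1 + j)
            if j < 3:  # first three track the driver monotonically
                ints[f] = base * (1 + 5 * driver[i])
            else:
                ints[f] = base * float(rng.lognormal(0, 0.3))
        samples.append(AssignedSample(
            sample_id=f"S{i}", intensities=np.array(list(ints.values()) + [1.0] * 10),
            formula_intensities=ints))
    m = normalize_columns(sdl_standardize(samples))
    optics = pd.DataFrame({"driver": driver,
                           "noise": rng.normal(size=n_samples)},
                          index=[f"S{i}" for i in range(n_samples)])
    return m, optics, formulas


class TestSpearmanScreen:
    def test_monotone_plants_detected(self):
        m, optics, formulas = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.01)
        sig = res[(res["property"] == "driver") & res["significant_positive"]]
        names = set(sig["formula"])
        for f in formulas[:3]:
            assert str(f) in names

    def test_constant_rows_excluded(self):
        m, optics, _ = toy_matrix()
        # force one row constant (all SDL)
        m.normalized[5, :] = 0.01
        res = spearman_screen(m, optics)
        row = res[(res["formula"] == str(m.formulae[5].formula))
                  & (res["property"] == "driver")]
        assert row["rho"].isna().all()

    def test_flags_match_p_and_sign(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.05)
        ok = res.dropna(subset=["p"])
        assert ((ok["significant_positive"] ==
                 ((ok["p"] < 0.05) & (ok["rho"] > 0))).all())
        assert not (ok["significant_positive"] & ok["significant_negative"]).any()


class TestSummaries:
    def test_counts_against_known_plants(self):
        m, optics, formulas = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.01)
        summary = summarize_classes(res, m, direction="positive")
        drv = summary[summary["property"] == "driver"].set_index("category")
        sig = set(res[(res["property"] == "driver")
                      & res["significant_positive"]]["formula"])
        assert drv.loc["all", "n_significant"] == len(sig)
        assert (drv["n_significant"] <= drv["n_total"]).all()
        assert ((drv["count_percent"] >= 0) & (drv["count_percent"] <= 100)).all()
        assert ((drv["intensity_percent"] >= 0)
                & (drv["intensity_percent"] <= 100)).all()

    def test_elemental_accounting_reconciles(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.05)
        summary = summarize_classes(res, m, direction="positive")
        for _, grp in summary.groupby("property"):
            g = grp.set_index("category")
            # CHO + NSP partitions the significant set exactly
            assert (g.loc["CHO", "n_significant"] + g.loc["NSP", "n_significant"]
                    == g.loc["all", "n_significant"])

    def test_empty_direction(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=1e-9)
        summary = summarize_classes(res, m, direction="negative")
        assert (summary["n_significant"] == 0).all()


class TestSharedMatrix:
    def test_diagonal_and_symmetry(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.05)
        shared = shared_formula_matrix(res)
        assert np.array_equal(shared.values, shared.values.T)
        sig_driver = res[(res["property"] == "driver")
                         & res["significant_positive"]]
        assert shared.loc["driver", "driver"] == len(sig_driver)
        assert (shared.values >= 0).all()
        # off-diagonal never exceeds either diagonal
        for a in shared.index:
            for b in shared.columns:
                assert shared.loc[a, b] <= min(shared.loc[a, a], shared.loc[b, b])

    def test_disjoint_sets_give_zero(self):
        res = pd.DataFrame({
            "formula": ["C6H6", "C10H8"],
            "property": ["p1", "p2"],
            "rho": [0.9, 0.9], "p": [0.001, 0.001], "q_bh": [0.01, 0.01],
            "n_used": [10, 10],
            "significant_positive": [True, True],
            "significant_negative": [False, False],
        })
        shared = shared_formula_matrix(res)
        assert shared.loc["p1", "p2"] == 0


class TestProfilesAndVanKrevelen:
    def test_point_mass_single_formula(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.01)
        one = res[(res["property"] == "driver")].copy()
        first_sig = one[one["significant_positive"]]["formula"].iloc[0]
        one["significant_positive"] = one["formula"] == first_sig
        prof = distribution_profiles(one, m)
        mass_prof = prof[prof["variable"] == "neutral_mass"]
        assert mass_prof["count"].sum() == 1

    def test_weighted_equals_count_shape_for_equal_weights(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.05)
        m.normalized[:] = 1.0 / m.normalized.shape[0]
        prof = distribution_profiles(res, m)
        if len(prof):
            w = prof["weighted"] / prof["weighted"].sum()
            c = prof["count"] / prof["count"].sum()
            assert np.allclose(w, c, atol=1e-9)

    def test_vk_export_columns_and_emptiness(self):
        m, optics, _ = toy_matrix()
        res = spearman_screen(m, optics, alpha=0.01)
        vk = van_krevelen_export(res, m, "driver", "positive")
        assert {"oc_ratio", "hc_ratio", "compound_class"} <= set(vk.columns)
        empty = van_krevelen_export(res, m, "driver", "negative")
        assert len(empty) == 0 and list(empty.columns) == list(vk.columns)


def test_null_calibration_small():
    """Type-I error close to alpha on a modest null panel (the acceptance
    suite runs the full-size calibration)."""
    rng = np.random.default_rng(8)
    n = 57
    X = rng.normal(size=(4000, n))
    Y = rng.normal(size=(4000, n))
    rx = stats.rankdata(X, axis=1); ry = stats.rankdata(Y, axis=1)
    rxc = rx - rx.mean(1, keepdims=True); ryc = ry - ry.mean(1, keepdims=True)
    rho = (rxc * ryc).sum(1) / np.sqrt((rxc**2).sum(1) * (ryc**2).sum(1))
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    frac = (p < 0.01).mean()
    assert 0.004 < frac < 0.016
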