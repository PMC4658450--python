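"""Formula assignment, dynamic range, SDL standardization, normalization."""

import numpy as np
import pytest

from opticmol import (AssignedSample, AssignmentConfig, FormulaAssigner,
                      MolecularFormula, Peak, assign_formula, build_peak_matrix,
                      dynamic_range, monoisotopic_mass, normalize_columns,
                      parse_formula, sdl_standardize)
from opticmol.formula import MONOISOTOPIC, PROTON_MASS


def brute_force_assign(mz, cfg: AssignmentConfig):
    """Independent brute-force CHNOSP enumerator (plain nested loops over
    all six elements with mass-window pruning); returns the same winner
    convention as the optimized assigner, or None."""
    target = mz + PROTON_MASS
    tol = cfg.tolerance_ppm * 1e-6 * mz
    mc, mh, mn, mo, ms, mp = (MONOISOTOPIC[e] for e in "CHNOSP")
    candidates = []
    for p in range(cfg.p_max + 1):
        for s in range(cfg.s_max + 1):
            for n in range(cfg.n_max + 1):
                base3 = p * mp + s * ms + n * mn
                if base3 > target:
                    break
                for o in range(cfg.o_max + 1):
                    base4 = base3 + o * mo
                    if base4 + mc + mh > target + tol:
                        break
                    for c in range(cfg.c_min, cfg.c_max + 1):
                        base5 = base4 + c * mc
                        rem = target - base5
                        if rem < cfg.h_min * mh - tol:
                            break
                        h = round(rem / mh)
                        for hh in (h - 1, h, h + 1):
                            if hh < cfg.h_min or hh > cfg.h_max:
                                continue
                            err = base5 + hh * mh - target
                            if abs(err) > tol:
                                continue
                            if not (cfg.hc_min * c <= hh <= cfg.hc_max * c):
                                continue
                            if o > cfg.oc_max * c:
                                continue
                            dbe = 1 + c - hh / 2 + n / 2 + p / 2
                            if dbe < cfg.dbe_min or dbe > cfg.dbe_max:
                                continue
                            if cfg.parity_check and (hh + n + p) % 2:
                                continue
                            ppm = err / mz * 1e6
                            candidates.append((abs(ppm), n + s + p,
                                               (c, hh, n, o, s, p)))
    if not candidates:
        return None
    candidates.sort()
    c, h, n, o, s, p = candidates[0][2]
    return MolecularFormula(c, h, n, o, s, p), len(candidates)


@pytest.fixture(scope="module")
def assigner():
    return FormulaAssigner(AssignmentConfig())


class TestAssignFormula:
    def test_palmitic_acid_exact(self, assigner):
        f = parse_formula("C16H32O2")
        mz = monoisotopic_mass(f) - PROTON_MASS
        a = assigner.assign(mz)
        assert a is not None and a.formula == f
        assert abs(a.error_ppm) < 0.2

    def test_empty_candidate_set(self):
        cfg = AssignmentConfig(c_min=5, h_min=5)
        assert assign_formula(155.0, cfg) is None

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError):
            AssignmentConfig(tolerance_ppm=0.0)

    def test_agrees_with_brute_force_on_random_masses(self, assigner):
        """Oracle equivalence on a small random mass panel (the acceptance
        suite runs the full 200-mass panel)."""
        cfg = assigner.cfg
        rng = np.random.default_rng(5)
        for mz in rng.uniform(150, 750, size=25):
            mine = assigner.assign(float(mz), use_cache=False)
            oracle = brute_force_assign(float(mz), cfg)
            if oracle is None:
                assert mine is None
            else:
                assert mine is not None
                assert mine.formula == oracle[0]
                assert mine.n_candidates == oracle[1]

    def test_roundtrip_subset(self, assigner):
        rng = np.random.default_rng(9)
        recovered = 0
        total = 100
        for _ in range(total):
            c = int(rng.integers(6, 40))
            h = int(rng.integers(max(1, int(0.4 * c)), int(2.2 * c)))
            if h % 2 == 0:  # (H + N + P) must be even; here N = 1, P = 0
                h += 1
            f = MolecularFormula(c, h, n=1, o=int(rng.integers(0, c)))
            m = monoisotopic_mass(f)
            if not 150 <= m <= 750:
                recovered += 1  # out of panel range, skip as success
                continue
            a = assigner.assign(m - PROTON_MASS, use_cache=False)
            if a is not None and a.formula == f:
                recovered += 1
        assert recovered >= 0.95 * total


class TestDynamicRange:
    def test_stated_arithmetic(self):
        peaks = [Peak(200.0, 50.0, 10.0) for _ in range(10)]
        peaks += [Peak(200.0, 5000.0, 10.0) for _ in range(500)]
        assert dynamic_range(peaks) == pytest.approx(100.0)

    def test_all_equal(self):
        peaks = [Peak(200.0, 7.0, 10.0)] * 20
        assert dynamic_range(peaks) == pytest.approx(1.0)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            dynamic_range([Peak(200.0, 1.0, 10.0)] * 9)


def _sample(sid, intensities, formulas):
    return AssignedSample(sample_id=sid,
                          intensities=np.asarray(intensities, dtype=float),
                          formula_intensities=formulas)


class TestSdlStandardize:
    def test_sdl_arithmetic(self):
        fa = parse_formula("C10H12O5")
        fb = parse_formula("C20H24O10")
        # sample A: DR = 100; sample B: DR = 50 -> DR_min = 50
        int_a = [50.0] * 10 + [5000.0] * 500
        int_b = [100.0] * 10 + [5000.0] * 500
        m = sdl_standardize([
            _sample("A", int_a, {fa: 5000.0, fb: 5000.0}),
            _sample("B", int_b, {fa: 5000.0}),
        ])
        assert m.dr_per_sample == pytest.approx([100.0, 50.0])
        # SDL = topmean / DR_min
        top_a = np.sort(int_a)[-500:].mean()
        assert m.sdl_per_sample[0] == pytest.approx(top_a / 50.0)

    def test_fill_rule_for_missing_formula(self):
        fa = parse_formula("C10H12O5")
        fb = parse_formula("C20H24O10")
        ints = [50.0] * 10 + [5000.0] * 500
        m = sdl_standardize([
            _sample("A", ints, {fa: 5000.0, fb: 5000.0}),
            _sample("B", ints, {fa: 5000.0}),
        ])
        i_fb = [str(a.formula) for a in m.formulae].index(str(fb))
        j_b = m.samples.index("B")
        assert m.intensities[i_fb, j_b] == pytest.approx(m.sdl_per_sample[j_b])

    def test_every_cell_at_least_sdl(self):
        rng = np.random.default_rng(3)
        formulas = [MolecularFormula(10 + i, 14, o=3) for i in range(30)]
        samples = []
        for sid in "ABCD":
            ints = rng.lognormal(8, 1.5, size=400)
            fi = {f: float(v) for f, v in
                  zip(formulas, rng.lognormal(8, 1.5, size=len(formulas)))}
            samples.append(_sample(sid, ints, fi))
        m = sdl_standardize(samples)
        assert np.all(m.intensities >= m.sdl_per_sample[None, :] - 1e-9)

    def test_identical_samples_unchanged_above_sdl(self):
        fa = parse_formula("C10H12O5")
        ints = [50.0] * 10 + [5000.0] * 500
        m = sdl_standardize([_sample(s, ints, {fa: 5000.0}) for s in "AB"])
        assert np.allclose(m.intensities, 5000.0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            sdl_standardize([_sample("A", [1.0] * 20, {})])


class TestNormalizeColumns:
    def test_column_stochastic(self):
        fa, fb, fc = (MolecularFormula(10 + i, 14, o=3) for i in range(3))
        ints = [50.0] * 10 + [5000.0] * 500
        m = sdl_standardize([
            _sample("A", ints, {fa: 2000.0, fb: 3000.0, fc: 5000.0}),
            _sample("B", ints, {fa: 5000.0}),
        ])
        out = normalize_columns(m)
        assert np.allclose(out.normalized.sum(axis=0), 1.0, atol=1e-9)


def test_build_peak_matrix_filters_and_aligns(small_cohort):
    """End-to-end on the small synthetic cohort: the matrix contains every
    library formula that survives the S/N filter, and columns sum to 1."""
    sub = {sid: small_cohort.peaks[sid] for sid in small_cohort.sample_ids[:6]}
    matrix = build_peak_matrix(sub)
    n_lib = len(small_cohort.manifest.formulae)
    names = {str(a.formula) for a in matrix.formulae}
    lib = set(small_cohort.manifest.formulae)
    # all abundant library formulae recovered (S/N filtering removes the
    # faintest); contaminant peaks land on valid CHNOSP masses at a modest
    # rate even at 0.2 ppm
    assert len(lib & names) >= 0.95 * n_lib
    assert len(names - lib) <= 0.15 * len(names)
    assert np.allclose(matrix.normalized.sum(axis=0), 1.0, atol=1e-9)
    assert np.all(matrix.intensities >= matrix.sdl_per_sample[None, :] - 1e-9)
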