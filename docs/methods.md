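# Methods

`opticmol` implements the analysis chain that links bulk optical properties
of dissolved organic matter (DOM) to individual molecular formulae resolved
by ultrahigh-resolution mass spectrometry, for a coastal-wetland-style
cohort of ~57 water samples. This note documents the models, the defaults
that matter, the synthetic cohort used for verification, and the numerical
choices.

## Optical indices

**Absorbance.** Spectra are decadic absorbance A(λ) over 250–800 nm in a
cuvette of path length L (default 0.01 m). The chromophoric-DOM absorption
coefficient is Napierian, a(λ) = ln(10)·A(λ)/L (m⁻¹). SUVA254 follows the
Weishaar convention: the *decadic* coefficient at 254 nm divided by DOC
(L mg-C⁻¹ m⁻¹). Whether field SUVA values in this literature use decadic or
Napierian coefficients is often ambiguous, so both coefficients are
reported (`a254`, `a254_decadic`) and the SUVA column is decadic-based.
Spectral slopes S275–295 and S350–400 are ordinary least squares of
ln a(λ) on λ over the stated window, sign-flipped so steeper decay gives a
larger positive S (nm⁻¹); the slope ratio is S_R = S275–295/S350–400 and
propagates as NaN when the denominator vanishes. No iron correction is
applied. Off-grid wavelengths are linearly interpolated; on 1-nm grids
higher-order schemes are immaterial.

**Fluorescence.** EEM hygiene runs blank subtraction (floored at zero),
absorbance-based (ABA) inner-filter correction
F_corr = F_obs·10^((A_ex+A_em)/2) with A in decadic absorbance per cm
(total absorbance above 3 triggers a logged warning), multiplication by a
configurable quinine-sulfate scale factor (default 1.0 = arbitrary units),
and Rayleigh scatter excision: cells with |λem − λex| ≤ 15 nm or
|λem − 2λex| ≤ 15 nm are masked, never interpolated — interpolation would
fabricate exactly the trilinear structure PARAFAC is meant to find.
Scalar indices: FI = I(370, 470)/I(370, 520) with linear interpolation
along emission; freshness = I(310, 380)/max I(310, 420–435);
HIX from trapezoidal areas H = ∫435–480, L = ∫300–345 of the lowest
available excitation row (the classical definition uses 254 nm, but scans
here start at 260 nm; the row actually used is recorded). Both HIX
variants are emitted: Ohno H/(H+L) ∈ [0,1] and Zsolnay H/L ≥ 0. Field
reports in this literature often quote "HIX (Ohno)" ranges above 1, which
only the Zsolnay form can produce; the screen therefore defaults to the
Zsolnay variant (`hix_variant` switches it) and no guess is made about
which form any particular published table used.

## PARAFAC

The sample × excitation × emission tensor is modeled trilinearly,
X[i,j,l] ≈ Σ_r a_ir·b_jr·c_lr, with non-negativity in all three modes
(fluorescence physics). Fitting is alternating least squares: each mode
update solves row-wise *weighted* non-negative least squares in which
missing cells (scatter excision, ragged scan windows) are excluded from
the residual — not imputed. Row problems are solved by cyclic coordinate
descent on the normal equations (k ≤ ~6, so a handful of sweeps
suffices); every coordinate update decreases the observed-cell SSE, and
the fit asserts SSE monotonicity at every iteration. A component whose
loading column collapses to exactly zero in some mode can never recover
under non-negative updates and is reseeded (a logged perturbation that
restarts the monotonicity ledger). Multi-start initialization draws random
spectral loadings only; scores follow from the first update, which makes a
run equivariant to sample ordering. The best of `n_starts` runs by
residual SSE wins. Defaults: tol 1e-8 on relative SSE change, max_iter
2500, n_starts 10, seed-reproducible bit for bit.

Conventions: excitation and emission loadings are scaled to unit maximum
per component with all scale absorbed into the scores; components are
ordered by decreasing total score (their proportional contribution to
total fluorescence). Explained variance is 1 − SSE/SST on observed cells.
The core-consistency diagnostic is computed and reported but is not a
validation gate; validation is split-half: random sample halves are fitted
independently, components are greedily matched by the smaller of the
excitation- and emission-mode Tucker congruences, and the model passes
when every matched pair reaches 0.95.

**Validated spectral range.** The emission scan covers λex+10 … λex+250,
so emission above (lowest λex)+250 = 510 nm is observed only at high
excitation. Loadings there are constrained by almost no data and pin to
noise, which reliably breaks split-half agreement. The fitted window is
therefore config-driven with defaults 300–510 nm, chosen so the retained
tensor is fully observed apart from the scatter diagonals; component
maxima at the window edge are reported as edge values, which is also why
published component tables in this literature quote maxima like
"<260 (ex)" or ">500 (em)". Model application to the original,
non-normalized EEMs (after per-sample unit-max normalization for the fit)
is per-sample non-negative least squares with the spectral loadings fixed;
component fractions normalize each sample's scores to sum to one.

## FTICR-MS pipeline

Peaks are [M−H]⁻ ions, singly charged; the neutral monoisotopic mass is
mz + 1.00727646688 Da. Peaks with S/N ≤ 5 are discarded at read time and
masses outside 150–750 Da are skipped with a logged count. Formula
assignment enumerates CHNOSP combinations inside configurable bounds
(defaults C 1–60, H 1–120, N ≤ 4, O ≤ 40, S ≤ 2, P ≤ 1) and keeps
candidates within 0.2 ppm that satisfy 0.3 ≤ H/C ≤ 2.5, O/C ≤ 1.2,
integer DBE in [0, 40] (DBE = 1 + C − H/2 + N/2 + P/2), and the
even-electron parity rule (H+N+P even). The implementation tabulates all
H-free (C,N,O,S,P) base masses once and solves for the hydrogen count
analytically per query, so each assignment is a single vectorized window
scan; the tests hold it to exact agreement with a plain brute-force
enumerator. Among multiple survivors the smallest |ppm error| wins, ties
break to fewest heteroatoms, and the winner carries an ambiguity flag
rather than being dropped.

Per sample, the dynamic range DR is the mean of the top min(500, n) peak
intensities over the mean of the 10 lowest; the standardized detection
limit SDL is the sample's top-500 mean divided by the cohort's minimum DR.
The aligned matrix holds the union of assigned formulae; a formula
undetected in a sample — or detected below the SDL — is set to that
sample's SDL (false-negative prevention), and detections at or above the
SDL pass through. Columns are then normalized to sum intensity one.

Derived descriptors: the modified aromaticity index uses the
Koch–Dittmar 2006 form AI-mod = (1 + C − 0.5O − S − 0.5H)/(C − 0.5O − N −
S − P), clamped to 0 for negative numerator or non-positive denominator.
(The 2016 erratum variant differs at class boundaries; the form used here
is a deliberate, documented constant.) Compound classes are assigned in a
fixed precedence: sugars (O/C ≥ 0.9), black carbon (AI-mod ≥ 0.67),
polyphenols (0.5 ≤ AI-mod < 0.67), saturated fatty acids (H/C ≥ 2),
peptides (1.5 ≤ H/C < 2 with N > 0), unsaturated aliphatics (same H/C
band, N = 0), highly unsaturated (AI-mod < 0.5, H/C < 1.5, O/C < 0.9),
and OTHER for the remainder, which is reported separately and never
merged. Published versions of these rules contain obvious typographic
corruption (e.g. "N < 0" for peptides); the boundaries here follow the
cited sources' conventions, the only reading that yields a non-degenerate
partition.

## Spearman screen

Each formula's normalized intensity profile is correlated against each
optical property (component fractions C1–C4, a254, SUVA254, the two
slopes, S_R, FI, freshness, HIX) across samples with Spearman rank
correlation, average ranks on ties. Two-sided p-values use exact
permutation enumeration for n ≤ 9 and the t(n−2) approximation otherwise
(standard at this study's n = 57). Significance is p < α (default 0.01)
with a sign filter; no multiple-testing correction is applied, matching
the raw-α screening convention of this literature, but Benjamini–Hochberg
q-values are reported in a clearly separate column as an extension and
never feed the screen-style tables.

Two row-eligibility rules guard rank-degenerate inputs: constant rows are
excluded, and a formula must be detected above the SDL in at least 5
samples (the same floor as the ≥ 5 overlapping-samples requirement per
pair). The second rule matters because SDL-filled cells are placeholders
whose cross-sample variation tracks the per-sample SDL itself; a row
filled nearly everywhere (a one-sample contaminant, say) would otherwise
rank-correlate with anything the per-sample detection limit happens to
covary with.

Summaries of each significant set: counts and percentages per elemental
group and per compound class, where CHON/CHOS/CHOP mean "contains that
heteroatom" (groups may overlap for mixed formulae) and NSP is any
heteroatom, so CHO + NSP partitions the set exactly; both count-percent
and intensity-weighted percent (share of the category's total mean
normalized intensity) are always emitted, with mean neutral mass per set.
The shared-formula matrix counts |S_i ∩ S_j| over properties; distribution
profiles bin mass, H/C and AI-mod (default widths 50 Da, 0.1, 0.05) with
raw and intensity-weighted counts; van Krevelen exports are tidy (O/C,
H/C, class, intensity) point sets for any plotting layer.

## Synthetic cohort

The generator emulates the study's structure so every stage has
recoverable truth; defaults are the study conditions: 57 samples, 4
trilinear components, λex 260–455 nm in 5 nm steps, λem 250–705 nm in 2 nm
steps with the ragged scan window λex+10 … λex+250, 3000 library formulae
in 150–750 Da plus 150 contaminant peaks per sample.

Component spectra are placed near the conventional peak positions (A/C,
A+/C+, A_M/M, B/T). Emission bands are asymmetric — sharp blue edge,
red tail 2.2× broader — and the humic components carry a broad
quasi-exponential UV excitation tail, both photophysically realistic
features that symmetric narrow Gaussians lack; without them FI degenerates
to a near-constant (excitation 370 nm would see a single component) and
high-excitation loadings become unidentifiable. Scores are log-normal
with a planted decreasing abundance order and a shared terrestrial ↔
microbial latent axis that gives C3/C4 the strong mutual correlation this
kind of cohort exhibits. Observed EEMs are the trilinear sum attenuated by
the sample's own inner-filter factor, plus first/second-order Rayleigh
ridges (sd 4 nm, a monochromator-bandpass scale the ±15 nm excision fully
covers) and heteroscedastic noise: 1% multiplicative (shot) noise plus a
0.1% dark floor, as in a real fluorometer. Blanks carry ridge and dark
noise only. Absorbance is exponential-like with the spectral slope varying
linearly between the two window anchors; SUVA, slopes and S_R are drawn so
derived indices span the envelopes reported for subtropical wetland DOM
(DOC 3.3–20.4 mg-C L⁻¹, S_R ~0.7–3.1) — plausibility targets, never
correctness assertions.

Planted links tie chosen formulae to chosen optical drivers through
Gaussian copulas: a target population Spearman ρ_s is converted to the
normal-copula Pearson r = 2·sin(πρ_s/6), and the formula's latent normal
is mixed with the driver's normal scores, so the population Spearman
correlation is exact regardless of marginals (log-normal intensities
here). Aromatic-leaning drivers (C1, C2, SUVA254, HIX) are planted on
aromatic classes, microbial-leaning drivers (C3, C4, FI, freshness, S_R)
on aliphatic/peptide classes. Plants are restricted to mid-abundance
formulae (40th–80th percentile of base intensity): links must survive the
SDL, and plants inside the top-500 peaks would couple each sample's
detection limit to the drivers — a coupling the real workflow's
fixed-injection normalization does not produce. Exact [M−H]⁻ masses are
perturbed by ≤ 0.1 ppm (one calibration residual per formula), and
per-sample S/N floors are set so the S/N > 5 filter removes a known ~5%
tail. `expected_outputs` recomputes, from the manifest alone, expected
detected-plant counts per driver and per class using a Monte-Carlo power
table for the Spearman screen at the cohort's n.

One calibration gap is accepted deliberately: synthetic FI comes out near
0.55–0.75, below the 1.3–1.5 envelope typical of field DOM, because the
four synthetic component shapes place more long-wavelength emission at
excitation 370 nm than real cohorts do. FI still varies across samples and
enters the screen as a driver, and the rank-based screen is indifferent to
its absolute level; reshaping the components to move FI would complicate
the spectra for no verification benefit.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: ionization-efficiency bias between
compound classes, detector saturation and space-charge effects, seasonal
or site covariance structure, iron interference with absorbance, and any
coupling between optics and the overall MS intensity scale.

## Problem sizes and reproducibility

Every stochastic component takes an explicit seed and is bit-for-bit
reproducible; two pipeline runs on identical inputs produce byte-identical
data files (outputs carry a config-hash/seed provenance header, and no
timestamps). The test suite verifies parameter recovery over 20 generator
seeds at the full 57-sample study geometry with modest ALS settings
(2 starts, tol 1e-6), which the recovery results show to be sufficient;
the closed-loop check runs one full cohort end to end. The acceptance
script uses 5 seeds for the recovery summary and one cohort for the
closed loop. These sizes are the package's verification defaults; all are
plain function arguments.

## Known limitations

- The trilinear model is fit only on the validated window; fluorophores
  emitting mostly above 510 nm would be summarized by their in-window
  shoulder.
- Exact Spearman p-values are enumerated only to n = 9 (40320
  permutations at n = 8); beyond that the t-approximation's small
  discreteness error is accepted, as quantified by the null-calibration
  test.
- Ambiguous assignments keep the lowest-error winner; true isobaric
  coexistence is not modeled.
- The OTHER compound class collects formulae outside all named rules and
  is never folded into a named class, so tables here can list a category
  that published tables omit.
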