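"""Synthetic DOM cohort generator with a machine-readable ground truth.

Emulates the study structure end to end — a ~57-sample cohort with
trilinear 4-component EEMs (plus Rayleigh scatter ridges and noise),
matching blanks, exponential-like absorbance spectra with per-sample DOC,
and FTICR-MS peak lists whose formula intensities are tied to chosen
optical drivers through Gaussian copulas at stated population Spearman
correlations — so every pipeline stage has a recoverable truth. The
TruthManifest is sufficient to recompute every expected output without
re-running the generator.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from . import eem as eemmod
from .absorbance import AbsorbanceSpectrum
from .eem import EEM
from .formula import (
    MolecularFormula, classify, format_formula,
    monoisotopic_mass, CompoundClass, PROTON_MASS,
)
from .fticr import Peak
from .io import (
    write_absorbance_csv, write_eem_csv, write_peaks_csv,
)

__all__ = [
    "GeneratorConfig",
    "TruthManifest",
    "Cohort",
    "generate_cohort",
    "expected_outputs",
    "spearman_power",
    "spearman_to_pearson",
]

# Excitation/emission placement priors for the four components, near the
# conventional humic-like (A/C), long-wavelength humic (A+/C+), microbial
# humic (A_M/M) and protein-like (B/T) peak positions.
COMPONENT_PEAKS = (
    # (ex peak centers, ex widths, em center, em width, broad UV ex tail)
    # humic-like components keep a broad quasi-exponential excitation tail
    # (real CDOM absorbs across the whole scan); the protein-like band does not
    ((255.0, 310.0), (14.0, 18.0), 425.0, 28.0, True),
    ((260.0, 370.0), (14.0, 20.0), 505.0, 32.0, True),
    ((252.0, 300.0), (13.0, 16.0), 375.0, 24.0, True),
    ((275.0,), (12.0,), 325.0, 24.0, False),
)

#: Terrestrial-leaning drivers get aromatic plants; microbial-leaning
#: drivers get aliphatic/peptide plants.
AROMATIC_CLASSES = (CompoundClass.BLACK_CARBON, CompoundClass.POLYPHENOL,
                    CompoundClass.HIGHLY_UNSATURATED)
ALIPHATIC_CLASSES = (CompoundClass.UNSATURATED_ALIPHATIC, CompoundClass.PEPTIDE,
                     CompoundClass.SATURATED_FATTY_ACID)


@dataclass
class GeneratorConfig:
    """Cohort shape and noise levels; the defaults are the study conditions."""

    n_samples: int = 57
    n_components: int = 4
    ex_start: float = 260.0
    ex_stop: float = 455.0
    ex_step: float = 5.0
    em_start: float = 250.0
    em_stop: float = 705.0
    em_step: float = 2.0
    scan_lo_offset: float = 10.0    # emission scan covers ex+10 .. ex+250
    scan_hi_offset: float = 250.0
    n_formulae: int = 3000
    n_noise_peaks: int = 150        # unassignable contaminant peaks per sample
    mass_min: float = 150.0
    mass_max: float = 750.0
    mass_error_ppm: float = 0.1     # calibration residual on exact masses
    noise_level: float = 0.01       # multiplicative (shot) noise sd, fraction of signal
    dark_level: float = 0.001       # additive detector noise sd, fraction of sample max
    blank_level: float = 0.002
    scatter_amplitude: float = 0.5  # Rayleigh ridge height, fraction of max
    intensity_sigma: float = 0.45   # per-formula across-sample log-sd
    doc_range: tuple = (3.3, 20.4)
    plants_per_driver: int = 25
    plant_rhos: tuple = (0.5, 0.6, 0.7, 0.8, 0.9)
    plant_drivers: tuple = ("c1", "c2", "c3", "c4", "suva254", "hix",
                            "fi", "freshness", "s_r")

    def ex_grid(self) -> np.ndarray:
        return np.arange(self.ex_start, self.ex_stop + 1e-9, self.ex_step)

    def em_grid(self) -> np.ndarray:
        return np.arange(self.em_start, self.em_stop + 1e-9, self.em_step)


@dataclass
class TruthManifest:
    """Everything needed to recompute expected outputs from truth alone."""

    seed: int
    config: dict
    sample_ids: list
    ex_grid: list
    em_grid: list
    ex_loadings: list          # (n_ex, k)
    em_loadings: list          # (n_em, k)
    scores: list               # (n_samples, k)
    doc: list
    absorbance_params: list    # per sample dict: a254_decadic_per_m, s275, s350
    optics: dict               # driver -> per-sample true values
    formulae: list             # formula strings
    classes: list              # compound class per formula
    plants: list               # dicts: formula, driver, rho
    noise: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


@dataclass
class Cohort:
    """In-memory cohort: everything the pipeline reads, plus the manifest."""

    sample_ids: list
    eems: dict          # sample_id -> observed EEM (raw)
    blanks: dict
    spectra: dict       # sample_id -> AbsorbanceSpectrum
    doc: dict
    peaks: dict         # sample_id -> list[Peak]
    manifest: TruthManifest


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of the bivariate normal whose Gaussian copula has
    the given population Spearman rho: r = 2 sin(pi rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _gaussian(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _emission_shape(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Asymmetric fluorophore emission band: sharp blue edge, broad red
    tail (roughly log-normal), as real DOM emission spectra exhibit."""
    sd_red = 2.2 * sd
    return np.where(x < mu, _gaussian(x, mu, sd), _gaussian(x, mu, sd_red))


def _component_loadings(cfg: GeneratorConfig, rng: np.random.Generator):
    ex = cfg.ex_grid()
    em = cfg.em_grid()
    B = np.zeros((len(ex), cfg.n_components))
    C = np.zeros((len(em), cfg.n_components))
    for k in range(cfg.n_components):
        ex_mus, ex_sds, em_mu, em_sd, ex_tail = COMPONENT_PEAKS[k % len(COMPONENT_PEAKS)]
        jitter = rng.uniform(-3.0, 3.0)
        for mu, sd in zip(ex_mus, ex_sds):
            B[:, k] += _gaussian(ex, mu + jitter, sd)
        if ex_tail:
            B[:, k] += 0.3 * np.exp(-(ex - ex[0]) / 80.0)
        C[:, k] = _emission_shape(em, em_mu + jitter, em_sd)
    B /= B.max(axis=0)
    C /= C.max(axis=0)
    return B, C


def _sample_formula_library(cfg: GeneratorConfig, rng: np.random.Generator):
    """Random CHNOSP formulae within assignment bounds, spread over classes."""
    seen: set[MolecularFormula] = set()
    out: list[MolecularFormula] = []
    # oversample until the quota is met; class balance comes from the wide
    # stoichiometric priors rather than explicit quotas
    while len(out) < cfg.n_formulae:
        c = int(rng.integers(6, 41))
        hc = rng.uniform(0.35, 2.2)
        h = int(round(hc * c))
        oc = rng.uniform(0.02, 1.05)
        o = int(round(oc * c))
        n = int(rng.choice([0, 1, 2, 3, 4], p=[0.55, 0.2, 0.13, 0.08, 0.04]))
        s = int(rng.choice([0, 1, 2], p=[0.82, 0.15, 0.03]))
        p = int(rng.choice([0, 1], p=[0.95, 0.05]))
        if (h + n + p) % 2:   # even-electron parity for the neutral molecule
            h += 1 if h < 2.45 * c else -1
        if h < 1 or h > 2.5 * c or h < 0.3 * c:
            continue
        dbe = 1 + c - h / 2 + n / 2 + p / 2
        if dbe < 0 or dbe > 40:
            continue
        f = MolecularFormula(c, h, n, o, s, p)
        m = monoisotopic_mass(f)
        if not (cfg.mass_min <= m <= cfg.mass_max):
            continue
        if f in seen:
            continue
        seen.add(f)
        out.append(f)
    return out


def _normal_scores(v: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Gaussian copula driver scores)."""
    ranks = stats.rankdata(v)
    return stats.norm.ppf((ranks - 0.5) / len(v))


def generate_cohort(cfg: GeneratorConfig | None = None, seed: int = 0,
                    outdir=None) -> Cohort:
    """Generate the full synthetic cohort (optionally writing files).

    Deterministic: the same (cfg, seed) produces byte-identical outputs.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    ids = [f"S{i+1:03d}" for i in range(cfg.n_samples)]
    ex, em = cfg.ex_grid(), cfg.em_grid()

    # --- fluorescent components and per-sample scores --------------------
    B, C = _component_loadings(cfg, rng)
    latent = rng.normal(size=cfg.n_samples)   # terrestrial <-> microbial axis
    base = np.array([1.0, 0.6, 0.35, 0.2])[: cfg.n_components]
    if cfg.n_components > 4:
        base = np.concatenate([base, 0.15 * 0.8 ** np.arange(cfg.n_components - 4)])
    load_on_latent = np.array([0.5, 0.6, -0.5, -0.6])[: cfg.n_components]
    if cfg.n_components > 4:
        load_on_latent = np.concatenate([load_on_latent,
                                         np.zeros(cfg.n_components - 4)])
    eps = rng.normal(size=(cfg.n_samples, cfg.n_components))
    scores = 40.0 * base * np.exp(
        0.45 * (latent[:, None] * load_on_latent) + 0.35 * eps
    )

    # --- absorbance spectra and DOC --------------------------------------
    doc = rng.uniform(*cfg.doc_range, size=cfg.n_samples)
    suva = np.clip(2.75 + 1.1 * np.tanh(latent) + rng.normal(0, 0.25, cfg.n_samples),
                   0.8, 4.8)
    s275 = np.clip(0.025 - 0.006 * np.tanh(latent)
                   + rng.normal(0, 0.0012, cfg.n_samples), 0.016, 0.034)
    sr = np.clip(1.9 - 0.95 * np.tanh(latent) + rng.normal(0, 0.15, cfg.n_samples),
                 0.7, 3.1)
    s350 = np.clip(s275 / sr, 0.0055, 0.031)
    a254_dec = suva * doc                     # decadic coefficient, 1/m
    wl = np.arange(250.0, 801.0, 1.0)
    spectra = {}
    abs_params = []
    for i in range(cfg.n_samples):
        # slope varies linearly from s275 (anchored at 285 nm) to s350
        # (anchored at 375 nm), constant outside the anchor points
        s_of_wl = np.interp(wl, [285.0, 375.0], [s275[i], s350[i]])
        integral = np.concatenate([[0.0], np.cumsum(
            0.5 * (s_of_wl[1:] + s_of_wl[:-1]) * np.diff(wl))])
        i254 = np.interp(254.0, wl, integral)
        A = (a254_dec[i] * 0.01) * np.exp(-(integral - i254))
        spectra[ids[i]] = AbsorbanceSpectrum(wl, A, path_length=0.01)
        abs_params.append({"a254_decadic_per_m": float(a254_dec[i]),
                           "s275": float(s275[i]), "s350": float(s350[i])})

    # --- EEMs: trilinear truth, inner-filter attenuation, scatter, noise --
    scan_mask = ~((em[None, :] >= ex[:, None] + cfg.scan_lo_offset)
                  & (em[None, :] <= ex[:, None] + cfg.scan_hi_offset))
    true_tensor = np.einsum("ir,jr,lr->ijl", scores, B, C)
    eems, blanks = {}, {}
    true_fi = np.empty(cfg.n_samples)
    true_fresh = np.empty(cfg.n_samples)
    true_hix_ohno = np.empty(cfg.n_samples)
    true_hix_zsolnay = np.empty(cfg.n_samples)
    # ridge widths follow the monochromator bandpass (a few nm sd), so the
    # default +/-15 nm excision removes them to below the noise floor
    ridge1 = np.exp(-0.5 * ((em[None, :] - ex[:, None]) / 4.0) ** 2)
    ridge2 = np.exp(-0.5 * ((em[None, :] - 2.0 * ex[:, None]) / 4.0) ** 2)
    for i, sid in enumerate(ids):
        truth = true_tensor[i]
        clean = EEM(ex, em, truth, np.zeros_like(truth, dtype=bool),
                    units_tag="qsu")
        idx = eemmod.compute_fluorescence_indices(clean)
        true_fi[i], true_fresh[i] = idx.fi, idx.freshness
        true_hix_ohno[i], true_hix_zsolnay[i] = idx.hix_ohno, idx.hix_zsolnay
        spec = spectra[sid]
        a_cm_ex = np.asarray(spec.interp(ex)) / 1.0  # path 0.01 m = 1 cm
        a_cm_em = np.asarray(spec.interp(em))
        attenuation = 10.0 ** (-(a_cm_ex[:, None] + a_cm_em[None, :]) / 2.0)
        peak = truth.max()
        signal = truth * attenuation
        # shot noise scales with the detected signal; dark noise with the range
        sigma = cfg.noise_level * signal + cfg.dark_level * peak
        observed = (signal
                    + cfg.scatter_amplitude * peak * (ridge1 + 0.3 * ridge2)
                    + rng.normal(0.0, 1.0, truth.shape) * sigma)
        blank = (cfg.blank_level * peak * (ridge1 + 0.3 * ridge2)
                 + rng.normal(0.0, cfg.dark_level * peak, truth.shape))
        eems[sid] = EEM(ex, em, np.where(scan_mask, 0.0, observed),
                        scan_mask.copy(), units_tag="raw")
        blanks[sid] = EEM(ex, em, np.where(scan_mask, 0.0, blank),
                          scan_mask.copy(), units_tag="raw")

    # --- true optical table ----------------------------------------------
    fracs = scores / scores.sum(axis=1, keepdims=True)
    optics = {f"c{k+1}": fracs[:, k].tolist() for k in range(cfg.n_components)}
    optics.update({
        "a254": (np.log(10) * a254_dec).tolist(),
        "suva254": suva.tolist(),
        "s275_295": s275.tolist(),
        "s350_400": s350.tolist(),
        "s_r": (s275 / s350).tolist(),
        "fi": true_fi.tolist(),
        "freshness": true_fresh.tolist(),
        "hix": true_hix_zsolnay.tolist(),
        "hix_ohno": true_hix_ohno.tolist(),
    })

    # --- formula library, planted links, intensities ----------------------
    library = _sample_formula_library(cfg, rng)
    classes = [classify(f) for f in library]
    by_pref: dict[str, list[int]] = {"aromatic": [], "aliphatic": [], "any": []}
    for i, cl in enumerate(classes):
        if cl in AROMATIC_CLASSES:
            by_pref["aromatic"].append(i)
        elif cl in ALIPHATIC_CLASSES:
            by_pref["aliphatic"].append(i)
        by_pref["any"].append(i)
    pref_of_driver = {"c1": "aromatic", "c2": "aromatic", "suva254": "aromatic",
                      "hix": "aromatic", "c3": "aliphatic", "c4": "aliphatic",
                      "fi": "aliphatic", "freshness": "aliphatic",
                      "s_r": "aliphatic"}
    planted: set[int] = set()
    plants = []
    z = rng.normal(size=(cfg.n_formulae, cfg.n_samples))
    # plant on mid-abundance formulae: abundant enough that SDL fill never
    # erases the rank structure the copula encodes, but below the top-500
    # peaks that set each sample's SDL (so the detection limit itself stays
    # uncorrelated with the drivers)
    mu = np.log(1e7) + rng.normal(0.0, 0.9, size=cfg.n_formulae)
    lo, hi = np.quantile(mu, [0.40, 0.80])
    abundant = (mu >= lo) & (mu <= hi)
    for driver in cfg.plant_drivers:
        if driver not in optics:
            raise ValueError(f"unknown plant driver {driver!r}")
        zd = _normal_scores(np.asarray(optics[driver]))
        pool = [i for i in by_pref.get(pref_of_driver.get(driver, "any"), by_pref["any"])
                if i not in planted and abundant[i]]
        if len(pool) < cfg.plants_per_driver:
            pool = [i for i in by_pref["any"] if i not in planted and abundant[i]]
        chosen = rng.choice(np.array(pool), size=min(cfg.plants_per_driver, len(pool)),
                            replace=False)
        for j, fi_idx in enumerate(chosen):
            rho = cfg.plant_rhos[j % len(cfg.plant_rhos)]
            r = spearman_to_pearson(rho)
            z[fi_idx] = r * zd + math.sqrt(1.0 - r * r) * z[fi_idx]
            planted.add(int(fi_idx))
            plants.append({"formula": format_formula(library[fi_idx]),
                           "driver": driver, "rho": float(rho)})

    intens = np.exp(mu[:, None] + cfg.intensity_sigma * z)

    # --- peak lists --------------------------------------------------------
    mz_exact = np.array([monoisotopic_mass(f) for f in library]) - PROTON_MASS
    ppm_shift = rng.uniform(-cfg.mass_error_ppm, cfg.mass_error_ppm,
                            size=cfg.n_formulae)
    mz_obs = mz_exact * (1.0 + ppm_shift * 1e-6)
    peaks: dict[str, list[Peak]] = {}
    noise_floors = []
    for si, sid in enumerate(ids):
        inten = intens[:, si]
        floor = float(np.quantile(inten, 0.05)) / 5.0   # S/N 5 at the 5th pctile
        noise_floors.append(floor)
        plist = [Peak(float(mz_obs[fi_]), float(inten[fi_]),
                      float(inten[fi_] / floor))
                 for fi_ in range(cfg.n_formulae)]
        # unassignable contaminant peaks at random (off-grid) masses
        noise_mz = rng.uniform(cfg.mass_min, cfg.mass_max, size=cfg.n_noise_peaks)
        noise_int = np.exp(np.log(3e6) + rng.normal(0, 0.7, cfg.n_noise_peaks))
        for mzv, iv in zip(noise_mz, noise_int):
            plist.append(Peak(float(mzv), float(iv), float(iv / floor)))
        peaks[sid] = plist

    manifest = TruthManifest(
        seed=seed,
        # json round-trip normalizes tuples to lists so serialization is stable
        config=json.loads(json.dumps(dataclasses.asdict(cfg))),
        sample_ids=ids,
        ex_grid=ex.tolist(),
        em_grid=em.tolist(),
        ex_loadings=B.tolist(),
        em_loadings=C.tolist(),
        scores=scores.tolist(),
        doc=doc.tolist(),
        absorbance_params=abs_params,
        optics=optics,
        formulae=[format_formula(f) for f in library],
        classes=[c.value for c in classes],
        plants=plants,
        noise={"eem_noise_level": cfg.noise_level,
               "blank_level": cfg.blank_level,
               "intensity_sigma": cfg.intensity_sigma,
               "mass_error_ppm": cfg.mass_error_ppm,
               "snr_floor_per_sample": noise_floors},
    )
    cohort = Cohort(ids, eems, blanks, spectra,
                    {sid: float(doc[i]) for i, sid in enumerate(ids)},
                    peaks, manifest)
    if outdir is not None:
        _write_cohort(cohort, Path(outdir))
    return cohort


def _write_cohort(cohort: Cohort, outdir: Path) -> None:
    for sub in ("eem", "blank", "absorbance", "peaks"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    rows = ["sample_id,doc_mg_per_l,path_length_m,salinity,eem,blank,absorbance,peaks,parafac_fit,screen"]
    for sid in cohort.sample_ids:
        write_eem_csv(cohort.eems[sid], outdir / "eem" / f"{sid}.csv")
        write_eem_csv(cohort.blanks[sid], outdir / "blank" / f"{sid}.csv")
        write_absorbance_csv(cohort.spectra[sid], outdir / "absorbance" / f"{sid}.csv")
        write_peaks_csv(cohort.peaks[sid], outdir / "peaks" / f"{sid}.csv")
        rows.append(f"{sid},{repr(float(cohort.doc[sid]))},0.01,0.0,"
                    f"eem/{sid}.csv,blank/{sid}.csv,absorbance/{sid}.csv,"
                    f"peaks/{sid}.csv,True,True")
    (outdir / "manifest.csv").write_text("\n".join(rows) + "\n")
    (outdir / "truth_manifest.json").write_text(cohort.manifest.to_json())


# ---------------------------------------------------------------------------
# Expected outputs from truth alone

def spearman_power(rho: float, n: int, alpha: float = 0.01,
                   n_sim: int = 2000, seed: int = 12345) -> float:
    """Monte-Carlo power of the two-sided Spearman screen at a planted
    Gaussian-copula population rho (t-approximation p-values, as used at
    the study's n)."""
    rng = np.random.default_rng(seed)
    r = spearman_to_pearson(rho)
    x = rng.normal(size=(n_sim, n))
    y = r * x + math.sqrt(1 - r * r) * rng.normal(size=(n_sim, n))
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    rs = np.sum(rx * ry, axis=1) / np.sqrt(
        np.sum(rx**2, axis=1) * np.sum(ry**2, axis=1))
    with np.errstate(divide="ignore"):
        t = rs * np.sqrt((n - 2) / (1 - rs**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    return float(np.mean(p < alpha))


def expected_outputs(manifest: TruthManifest, alpha: float = 0.01,
                     n_sim: int = 2000) -> dict:
    """Expected significant counts per driver and per compound class, from
    truth alone, using Monte-Carlo detection power at each planted rho.

    Returns {'per_driver': {driver: {'expected', 'sd', 'n_planted'}},
    'per_class': ..., 'power': {rho: power}} where sd is the binomial
    standard deviation of the detected-plant count (chance significance of
    non-planted formulae adds ~alpha per pair on top of 'expected')."""
    n = len(manifest.sample_ids)
    rhos = sorted({p["rho"] for p in manifest.plants})
    power = {rho: spearman_power(rho, n, alpha, n_sim=n_sim) for rho in rhos}
    cls_of = dict(zip(manifest.formulae, manifest.classes))
    per_driver: dict[str, dict] = {}
    per_class: dict[str, dict] = {}
    for p in manifest.plants:
        w = power[p["rho"]]
        d = per_driver.setdefault(p["driver"],
                                  {"expected": 0.0, "var": 0.0, "n_planted": 0})
        d["expected"] += w
        d["var"] += w * (1 - w)
        d["n_planted"] += 1
        c = per_class.setdefault(cls_of[p["formula"]],
                                 {"expected": 0.0, "var": 0.0, "n_planted": 0})
        c["expected"] += w
        c["var"] += w * (1 - w)
        c["n_planted"] += 1
    for d in (*per_driver.values(), *per_class.values()):
        d["sd"] = math.sqrt(d.pop("var"))
    return {"per_driver": per_driver, "per_class": per_class, "power": power,
            "alpha": alpha, "n_samples": n}
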