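"""Manifest-driven end-to-end orchestration.

Runs absorbance -> EEM hygiene -> PARAFAC -> FTICR -> Spearman screen and
writes every table the analysis produces (indices, model bundle, peak
matrix, association tables, class summaries, shared-formula matrix,
distribution profiles, van Krevelen exports) plus a provenance record.
Deterministic given identical inputs and config.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .absorbance import compute_indices
from .eem import (blank_subtract, compute_fluorescence_indices, excise_scatter,
                  inner_filter_correct)
from .fticr import PeakMatrix, build_peak_matrix
from .io import (RunConfig, read_absorbance_csv, read_eem_csv, read_peaks_csv,
                 read_sample_manifest, write_csv_with_provenance)
from .parafac import (EEMTensor, fit_parafac, normalize_for_fit,
                      normalize_scores, project_scores, save_model,
                      split_half_validate)
from .screen import (distribution_profiles, shared_formula_matrix,
                     spearman_screen, summarize_classes, van_krevelen_export)

__all__ = ["run_all", "PipelineError", "optics_table"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample_id: str | None, cause: Exception):
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause
        super().__init__(f"stage={stage} sample={sample_id}: {cause}")


def _absorbance_stage(manifest: pd.DataFrame, base: Path) -> tuple[pd.DataFrame, dict]:
    rows, spectra = [], {}
    for sid, rec in manifest.iterrows():
        try:
            spec = read_absorbance_csv(base / rec["absorbance"],
                                       path_length=float(rec["path_length_m"]))
            idx = compute_indices(spec, float(rec["doc_mg_per_l"]))
        except Exception as exc:
            raise PipelineError("absorbance", sid, exc) from exc
        spectra[sid] = spec
        rows.append({"sample_id": sid, **asdict(idx)})
    return pd.DataFrame(rows).set_index("sample_id"), spectra


def _eem_stage(manifest: pd.DataFrame, base: Path, spectra: dict,
               config: RunConfig) -> tuple[dict, pd.DataFrame]:
    processed, rows = {}, []
    for sid, rec in manifest.iterrows():
        try:
            sample = read_eem_csv(base / rec["eem"])
            blank = read_eem_csv(base / rec["blank"])
            e = blank_subtract(sample, blank)
            e = inner_filter_correct(e, spectra[sid])
            if config.qsu_factor != 1.0:
                e = type(e)(e.excitation, e.emission,
                            e.intensity * config.qsu_factor, e.mask, "qsu")
            e = excise_scatter(e, config.scatter_first_width_nm,
                               config.scatter_second_width_nm)
            fl = compute_fluorescence_indices(e)
        except Exception as exc:
            raise PipelineError("eem", sid, exc) from exc
        processed[sid] = e
        rows.append({"sample_id": sid, **asdict(fl)})
    return processed, pd.DataFrame(rows).set_index("sample_id")


def _parafac_stage(manifest: pd.DataFrame, processed: dict, config: RunConfig):
    fit_ids = [sid for sid in manifest.index if bool(manifest.loc[sid, "parafac_fit"])]
    try:
        tensor = EEMTensor.from_eems(
            fit_ids, [processed[s] for s in fit_ids],
            em_range=(config.parafac_em_min, config.parafac_em_max))
        normed, _ = normalize_for_fit(tensor)
        model = fit_parafac(normed, config.parafac_k, tol=config.parafac_tol,
                            max_iter=config.parafac_max_iter,
                            n_starts=config.parafac_n_starts,
                            seed=config.parafac_seed)
        report = split_half_validate(normed, config.parafac_k,
                                     seed=config.parafac_seed,
                                     tol=config.parafac_tol,
                                     max_iter=config.parafac_max_iter,
                                     n_starts=config.parafac_n_starts,
                                     threshold=config.congruence_threshold)
        # re-apply the validated model to ALL original non-normalized EEMs
        all_ids = list(manifest.index)
        full = EEMTensor.from_eems(all_ids, [processed[s] for s in all_ids],
                                   trim=False)
        sel_ex = np.isin(full.excitation, model.excitation)
        sel_em = np.isin(full.emission, model.emission)
        full = EEMTensor(all_ids, full.excitation[sel_ex], full.emission[sel_em],
                         full.values[:, sel_ex][:, :, sel_em],
                         full.mask[:, sel_ex][:, :, sel_em])
        scores = project_scores(model, full)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("parafac", None, exc) from exc
    k = config.parafac_k
    score_df = pd.DataFrame(scores, index=full.sample_ids,
                            columns=[f"c{i+1}" for i in range(k)])
    frac_df = pd.DataFrame(normalize_scores(scores), index=full.sample_ids,
                           columns=[f"c{i+1}" for i in range(k)])
    return model, report, score_df, frac_df


def optics_table(frac_df: pd.DataFrame, abs_idx: pd.DataFrame,
                 fl_idx: pd.DataFrame, hix_variant: str = "zsolnay") -> pd.DataFrame:
    """Assemble the per-sample optical-property table for screening."""
    hix_col = "hix_ohno" if hix_variant == "ohno" else "hix_zsolnay"
    out = frac_df.copy()
    for col in ("a254", "suva254", "s275_295", "s350_400", "s_r"):
        out[col] = abs_idx[col]
    out["fi"] = fl_idx["fi"]
    out["freshness"] = fl_idx["freshness"]
    out["hix"] = fl_idx[hix_col]
    return out


def _fticr_stage(manifest: pd.DataFrame, base: Path, config: RunConfig) -> PeakMatrix:
    try:
        peak_lists = {sid: read_peaks_csv(base / rec["peaks"])
                      for sid, rec in manifest.iterrows()}
        return build_peak_matrix(peak_lists, config.assignment)
    except Exception as exc:
        raise PipelineError("fticr", None, exc) from exc


def run_all(manifest_path, config: RunConfig | None = None, outdir=None,
            base_dir=None) -> dict:
    """Execute the whole analysis; returns the in-memory results dict.

    On stage failure, partial outputs are retained and a machine-readable
    error_report.json (stage, sample, traceback) is written before the
    error propagates.
    """
    config = config or RunConfig()
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    outdir = Path(outdir) if outdir is not None else base / "results"
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seed = config.parafac_seed

    def save(df, name, index=False):
        write_csv_with_provenance(df, outdir / name, chash, seed, index=index)

    manifest = read_sample_manifest(manifest_path)
    try:
        abs_idx, spectra = _absorbance_stage(manifest, base)
        save(abs_idx.reset_index(), "absorbance_indices.csv")
        processed, fl_idx = _eem_stage(manifest, base, spectra, config)
        save(fl_idx.reset_index(), "fluorescence_indices.csv")
        model, report, score_df, frac_df = _parafac_stage(manifest, processed, config)
        save_model(model, outdir / "model")
        save(score_df.reset_index(names="sample_id"), "parafac_scores.csv")
        save(frac_df.reset_index(names="sample_id"), "parafac_fractions.csv")
        split_df = pd.DataFrame({
            "component": [f"c{i+1}" for i in range(config.parafac_k)],
            "congruence_ex": report.congruence_ex,
            "congruence_em": report.congruence_em,
        })
        split_df["passed"] = report.passed
        save(split_df, "split_half.csv")

        matrix = _fticr_stage(manifest, base, config)
        mat_df = pd.DataFrame(matrix.normalized,
                              index=[str(a.formula) for a in matrix.formulae],
                              columns=matrix.samples)
        save(mat_df.reset_index(names="formula"), "peak_matrix_normalized.csv")
        ann_rows = [{
            "formula": str(a.formula), "neutral_mass": a.neutral_mass,
            "oc_ratio": a.oc_ratio, "hc_ratio": a.hc_ratio, "ai_mod": a.ai_mod,
            "dbe": a.dbe, "compound_class": a.compound_class.value,
        } for a in matrix.formulae]
        save(pd.DataFrame(ann_rows), "formula_annotations.csv")

        screen_ids = [s for s in manifest.index if bool(manifest.loc[s, "screen"])]
        optics = optics_table(frac_df, abs_idx, fl_idx, config.hix_variant)
        optics = optics.loc[[s for s in screen_ids if s in optics.index]]
        try:
            results = spearman_screen(matrix, optics, alpha=config.alpha)
            outputs = {"associations.csv": results}
            for direction in ("positive", "negative"):
                outputs[f"class_summary_{direction}.csv"] = summarize_classes(
                    results, matrix, direction)
            shared = shared_formula_matrix(results)
            save(shared.reset_index(names="property"), "shared_matrix.csv")
            outputs["profiles.csv"] = distribution_profiles(results, matrix)
            for name, df in outputs.items():
                save(df, name)
            for prop in optics.columns:
                for direction in ("positive", "negative"):
                    vk = van_krevelen_export(results, matrix, prop, direction)
                    save(vk, f"vk_{prop}_{direction}.csv")
        except Exception as exc:
            raise PipelineError("screen", None, exc) from exc
    except PipelineError as err:
        (outdir / "error_report.json").write_text(json.dumps({
            "stage": err.stage,
            "sample_id": err.sample_id,
            "error": str(err.cause),
            "traceback": traceback.format_exc(),
        }, indent=2))
        raise

    provenance = {
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "n_samples": len(manifest),
        "parafac_explained_variance": model.explained_variance,
        "parafac_converged": model.converged,
        "split_half_passed": bool(report.passed),
        "n_formulae": len(matrix.formulae),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "absorbance_indices": abs_idx,
        "fluorescence_indices": fl_idx,
        "model": model,
        "split_half": report,
        "scores": score_df,
        "fractions": frac_df,
        "matrix": matrix,
        "optics": optics,
        "associations": results,
        "shared_matrix": shared,
        "outdir": outdir,
    }
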