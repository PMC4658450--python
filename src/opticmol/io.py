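"""Readers/writers for the pipeline's plain-text CSV dialects and run config.

All artifacts are comma-separated UTF-8 with a mandatory header row; data
files written by the pipeline carry a provenance header comment (config
hash and seed) so two runs differing only in timestamps produce identical
data files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .absorbance import AbsorbanceSpectrum
from .eem import EEM
from .fticr import AssignmentConfig, Peak

__all__ = [
    "RunConfig",
    "read_eem_csv",
    "write_eem_csv",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "read_peaks_csv",
    "write_peaks_csv",
    "read_sample_manifest",
    "write_csv_with_provenance",
    "read_csv_with_provenance",
]


@dataclass
class RunConfig:
    """Every documented pipeline default, surfaced as a named key."""

    # PARAFAC
    parafac_k: int = 4
    parafac_seed: int = 7
    parafac_tol: float = 1e-8
    parafac_max_iter: int = 2500
    parafac_n_starts: int = 10
    congruence_threshold: float = 0.95
    # validated spectral range for the fit. The emission scan covers
    # ex+10..ex+250, so emission above (lowest ex)+250 = 510 nm is only
    # observed at high excitation and cannot be validated; capping at 510
    # leaves a fully observed rectangle apart from the scatter diagonals.
    parafac_em_min: float = 300.0
    parafac_em_max: float = 510.0
    # EEM hygiene
    scatter_first_width_nm: float = 15.0
    scatter_second_width_nm: float = 15.0
    qsu_factor: float = 1.0            # quinine-sulfate scale; 1.0 = arbitrary units
    hix_variant: str = "zsolnay"       # 'zsolnay' (H/L) or 'ohno' (H/(H+L))
    # screening
    alpha: float = 0.01
    # formula assignment
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        assignment = AssignmentConfig(**raw.pop("assignment", {}))
        return cls(assignment=assignment, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# EEM CSV: first row = emission grid, first column = excitation grid,
# body = intensities, empty cell = masked. Round-trips exactly.

def write_eem_csv(eem: EEM, path) -> None:
    with open(path, "w") as fh:
        fh.write("ex_em," + ",".join(repr(float(v)) for v in eem.emission) + "\n")
        for i, ex in enumerate(eem.excitation):
            cells = []
            for j in range(len(eem.emission)):
                cells.append("" if eem.mask[i, j] else repr(float(eem.intensity[i, j])))
            fh.write(repr(float(ex)) + "," + ",".join(cells) + "\n")


def read_eem_csv(path, units_tag: str = "raw") -> EEM:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        emission = np.array([float(v) for v in header[1:]])
        excitation, rows, mask = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split(",")
            excitation.append(float(parts[0]))
            rows.append([float(v) if v else 0.0 for v in parts[1:]])
            mask.append([not v for v in parts[1:]])
    return EEM(np.array(excitation), emission, np.array(rows),
               np.array(mask, dtype=bool), units_tag=units_tag)


# ---------------------------------------------------------------------------

def write_absorbance_csv(spec: AbsorbanceSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,absorbance\n")
        for wl, ab in zip(spec.wavelengths, spec.absorbance):
            fh.write(f"{repr(float(wl))},{repr(float(ab))}\n")


def read_absorbance_csv(path, path_length: float = 0.01) -> AbsorbanceSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    return AbsorbanceSpectrum(df["wavelength_nm"].to_numpy(),
                              df["absorbance"].to_numpy(), path_length)


def write_peaks_csv(peaks: list[Peak], path) -> None:
    with open(path, "w") as fh:
        fh.write("mz,intensity,snr\n")
        for p in peaks:
            fh.write(f"{repr(float(p.mz))},{repr(float(p.intensity))},{repr(float(p.snr))}\n")


def read_peaks_csv(path) -> list[Peak]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [Peak(float(r.mz), float(r.intensity), float(r.snr))
            for r in df.itertuples()]


def read_sample_manifest(path) -> pd.DataFrame:
    """Sample manifest: sample_id, doc_mg_per_l, path_length_m, salinity,
    eem/blank/absorbance/peaks file paths, parafac_fit and screen flags."""
    df = pd.read_csv(path, comment="#")
    if df["sample_id"].duplicated().any():
        raise ValueError("sample_ids in manifest must be unique")
    for col, default in (("parafac_fit", True), ("screen", True),
                         ("path_length_m", 0.01), ("salinity", np.nan)):
        if col not in df.columns:
            df[col] = default
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------

def write_csv_with_provenance(df: pd.DataFrame, path, config_hash: str,
                              seed: int, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# opticmol config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=index)


def read_csv_with_provenance(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
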