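"""CSV readers/writers and JSON reporting.

Canonical dialect: comma-separated, dot decimals, UTF-8, mandatory header
row with units encoded as column-name suffixes (``_uM``, ``_per_s``,
``_ucal``).  Parse errors name the offending file and line.  Round trips
through these functions are lossless (floats are written with shortest
round-trippable repr).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_thermo import ItcExperiment
from .errors import InputError
from .spectral import SpectraMatrix
from .steady_state import BiSubstrateDataset
from .transient import KobsSeries


@dataclass
class AnalysisReport:
    """Module outputs keyed by stage, with provenance and warnings."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, payload: dict) -> None:
        self.stages[name] = payload

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_table(path, required: list[str], optional: list[str] = ()):
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed structure
        raise InputError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(
            f"{path}, line 1: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    for col in list(required) + [c for c in optional if c in df.columns]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header row plus 1-based numbering
            raise InputError(
                f"{path}, line {bad[0] + 2}: non-numeric value "
                f"{df[col].iloc[bad[0]]!r} in column {col!r}"
            )
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise InputError(
                f"{path}, line {row + 2}: empty cell in column {col!r}"
            )
        df[col] = coerced
    return df


# -- bi-substrate -----------------------------------------------------------

BISUBSTRATE_COLUMNS = ["alcohol_uM", "acceptor_uM", "rate_per_s", "replicate"]


def read_bisubstrate_csv(path, meta: dict | None = None) -> BiSubstrateDataset:
    df = _read_table(path, BISUBSTRATE_COLUMNS[:3], ["replicate"])
    rep = (df["replicate"].to_numpy(dtype=int)
           if "replicate" in df.columns else None)
    return BiSubstrateDataset(
        alcohol_uM=df["alcohol_uM"].to_numpy(),
        acceptor_uM=df["acceptor_uM"].to_numpy(),
        rate_per_s=df["rate_per_s"].to_numpy(),
        replicate=rep,
        meta=meta or {},
    )


def write_bisubstrate_csv(data: BiSubstrateDataset, path) -> None:
    data.to_frame().to_csv(path, index=False)


# -- kobs -------------------------------------------------------------------

def read_kobs_csv(path, ligand_role: str = "reductant",
                  meta: dict | None = None) -> KobsSeries:
    df = _read_table(path, ["conc_uM", "kobs_per_s"], ["se"])
    se = df["se"].to_numpy() if "se" in df.columns else None
    return KobsSeries(
        conc_uM=df["conc_uM"].to_numpy(),
        kobs_per_s=df["kobs_per_s"].to_numpy(),
        se=se,
        ligand_role=ligand_role,
        meta=meta or {},
    )


def write_kobs_csv(series: KobsSeries, path) -> None:
    cols = {"conc_uM": series.conc_uM, "kobs_per_s": series.kobs_per_s}
    if series.se is not None:
        cols["se"] = series.se
    pd.DataFrame(cols).to_csv(path, index=False)


# -- spectra matrix ---------------------------------------------------------

def read_spectra_csv(path) -> SpectraMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        wavelengths = df.columns.to_numpy(dtype=float)
        times = df.index.to_numpy(dtype=float)
        absorbance = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise InputError(
            f"{path}: spectra matrix must have numeric times in the first "
            f"column and wavelengths in the header row ({exc})"
        ) from exc
    return SpectraMatrix(times=times, wavelengths=wavelengths,
                         absorbance=absorbance)


def write_spectra_csv(data: SpectraMatrix, path) -> None:
    df = pd.DataFrame(data.absorbance, index=data.times,
                      columns=data.wavelengths)
    df.index.name = "time_s"
    df.to_csv(path)


def write_species_spectra_csv(wavelengths, species_spectra, path,
                              labels=None) -> None:
    """Fitted per-species spectra, one column per species."""
    species_spectra = np.asarray(species_spectra)
    if labels is None:
        labels = [f"species_{c}" for c in "ABC"[: species_spectra.shape[0]]]
    cols = {"wavelength_nm": np.asarray(wavelengths)}
    for lab, spec in zip(labels, species_spectra):
        cols[lab] = spec
    pd.DataFrame(cols).to_csv(path, index=False)


# -- ITC --------------------------------------------------------------------

ITC_COLUMNS = ["injection", "volume_uL", "heat_ucal"]


def read_itc_csv(path, cell_conc_uM: float, syringe_conc_uM: float,
                 cell_volume_uL: float = 200.0,
                 temperature_K: float = 298.15,
                 meta: dict | None = None) -> ItcExperiment:
    df = _read_table(path, ITC_COLUMNS)
    return ItcExperiment(
        cell_conc_uM=cell_conc_uM,
        syringe_conc_uM=syringe_conc_uM,
        injection_volumes_uL=df["volume_uL"].to_numpy(),
        cell_volume_uL=cell_volume_uL,
        temperature_K=temperature_K,
        heats_ucal=df["heat_ucal"].to_numpy(),
        meta=meta or {},
    )


def write_itc_csv(exp: ItcExperiment, path) -> None:
    if exp.heats_ucal is None:
        raise InputError("experiment has no heats to write")
    pd.DataFrame(
        {
            "injection": np.arange(1, exp.n_injections + 1),
            "volume_uL": exp.injection_volumes_uL,
            "heat_ucal": exp.heats_ucal,
        }
    ).to_csv(path, index=False)


# -- JSON reports -----------------------------------------------------------

class _ReportEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if hasattr(obj, "__dict__"):
            return {k: v for k, v in obj.__dict__.items()
                    if not k.startswith("_")}
        return super().default(obj)


def write_report_json(report: AnalysisReport | dict, path) -> None:
    payload = report.to_dict() if isinstance(report, AnalysisReport) else report
    Path(path).write_text(
        json.dumps(payload, indent=2, cls=_ReportEncoder) + "\n"
    )


def read_report_json(path) -> dict:
    return json.loads(Path(path).read_text())
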