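"""Readers/writers and configuration for the assay pipeline.

Interchange format is long CSV, UTF-8, dot decimal separator, columns:
subject_id, matrix, time_min, metabolite, isotopologue, replicate, area,
is_area — one row per integrated isotopologue peak. Missing area = empty
field. Control references and configs persist as YAML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import constants
from .metrics import ControlReference

logger = logging.getLogger("ureaflux")

CSV_COLUMNS = [
    "subject_id",
    "matrix",
    "time_min",
    "metabolite",
    "isotopologue",
    "replicate",
    "area",
    "is_area",
]


class SchemaError(ValueError):
    """Input CSV does not match the interchange schema."""


class AssayConfig(BaseModel):
    """Tunable assay constants; defaults reproduce the standard protocol."""

    nominal_dose_mg_per_kg: float = constants.NOMINAL_DOSE_MG_PER_KG
    time_grid: list[float] = Field(default_factory=lambda: list(constants.TIME_GRID_MIN))
    metabolites: list[str] = Field(default_factory=lambda: list(constants.METABOLITES))
    natural_abundance_15n: float = constants.NATURAL_ABUNDANCE_15N
    v_dist_l_per_kg: float = constants.DEFAULT_V_DIST_L_PER_KG
    pools_umol_l: dict[str, float] = Field(
        default_factory=lambda: dict(constants.DEFAULT_POOLS_UMOL_L)
    )
    outlier_threshold: float = constants.TRIPLICATE_OUTLIER_THRESHOLD
    stability_cv_threshold: float = constants.STABILITY_CV_THRESHOLD
    t_mode: str = "absolute"  # or "control_calibrated"
    t_calibration_target: float = 51.0  # control mean T in calibrated mode
    seed: int = 0

    @field_validator("outlier_threshold", "stability_cv_threshold")
    @classmethod
    def _threshold_range(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
        return v

    @field_validator("time_grid")
    @classmethod
    def _grid_starts_at_zero(cls, v: list[float]) -> list[float]:
        if not v or v[0] != 0:
            raise ValueError("time grid must start at 0")
        return v

    @field_validator("t_mode")
    @classmethod
    def _known_mode(cls, v: str) -> str:
        if v not in ("absolute", "control_calibrated"):
            raise ValueError("t_mode must be 'absolute' or 'control_calibrated'")
        return v


def load_config(path: str | Path) -> AssayConfig:
    with open(path, encoding="utf-8") as fh:
        return AssayConfig(**(yaml.safe_load(fh) or {}))


def save_config(config: AssayConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def read_assay_csv(path: str | Path, metabolites=None) -> pd.DataFrame:
    """Read raw peak records, rejecting malformed rows with line numbers.

    Rows with an unknown metabolite/isotopologue/matrix or an out-of-range
    replicate are dropped and logged; a header that does not cover the schema
    raises :class:`SchemaError`. An empty file returns an empty frame with a
    warning.
    """
    metabolites = set(metabolites or constants.METABOLITES)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: no data rows", path)
        return df[CSV_COLUMNS]

    ok = (
        df["metabolite"].isin(metabolites)
        & df["isotopologue"].isin(constants.ISOTOPOLOGUES)
        & df["matrix"].isin(constants.MATRICES)
        & df["replicate"].isin(constants.REPLICATES)
        & (pd.to_numeric(df["time_min"], errors="coerce") >= 0)
    )
    if (~ok).any():
        # +2: header line and 1-based numbering
        lines = (df.index[~ok] + 2).tolist()
        logger.warning(
            "%s: rejected %d malformed row(s) at line(s) %s",
            path,
            int((~ok).sum()),
            lines[:10],
        )
    df = df[ok].copy()
    df["time_min"] = df["time_min"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["area"] = pd.to_numeric(df["area"], errors="coerce")
    df["is_area"] = pd.to_numeric(df["is_area"], errors="coerce")
    return df.reset_index(drop=True)[CSV_COLUMNS]


def write_assay_csv(records: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write records in the interchange layout; the seed is recorded as a
    header comment so a fixture is self-describing."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# ureaflux fixture, seed={seed}\n")
        records[CSV_COLUMNS].to_csv(fh, index=False)


def save_reference(reference: ControlReference, path: str | Path) -> None:
    """Persist a control reference (means, RUF band) for reuse across runs."""
    payload = {
        "R_bar_C": reference.R_bar_C,
        "T_bar_C": reference.T_bar_C,
        "ruf_mean": reference.ruf_mean,
        "ruf_sd": reference.ruf_sd,
        "ruf_range": list(reference.ruf_range),
        "n_controls": reference.n_controls,
        "mean_unlabeled_signal": {
            k: float(v) for k, v in reference.mean_unlabeled_signal.items()
        },
        "t_calibration_scale": reference.t_calibration_scale,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_reference(path: str | Path) -> ControlReference:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return ControlReference(
        R_bar_C=payload["R_bar_C"],
        T_bar_C=payload["T_bar_C"],
        ruf_mean=payload["ruf_mean"],
        ruf_sd=payload["ruf_sd"],
        ruf_range=tuple(payload["ruf_range"]),
        n_controls=payload["n_controls"],
        mean_unlabeled_signal=payload.get("mean_unlabeled_signal", {}),
        t_calibration_scale=payload.get("t_calibration_scale", 1.0),
    )


META_COLUMNS = ["subject_id", "group", "matrix", "weight_kg", "dose_mg_per_kg"]


def write_metadata_csv(assays: list, path: str | Path) -> None:
    rows = [
        {
            "subject_id": a.subject_id,
            "group": a.group,
            "matrix": a.matrix,
            "weight_kg": a.weight_kg,
            "dose_mg_per_kg": a.dose_mg_per_kg,
        }
        for a in assays
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


def assays_from_records(
    records: pd.DataFrame, metadata: pd.DataFrame | None = None
) -> list:
    """Split a multi-subject record table into SubjectAssay objects.

    Metadata rows are matched on (subject_id, matrix); subjects without a
    metadata row default to 70 kg, nominal dose, group parsed from the
    subject-id prefix (text before the last underscore).
    """
    from .simulate import SubjectAssay

    meta_idx = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            meta_idx[(row["subject_id"], row["matrix"])] = row
    assays = []
    for (sid, matrix), sub in records.groupby(["subject_id", "matrix"], sort=True):
        row = meta_idx.get((sid, matrix))
        assays.append(
            SubjectAssay(
                subject_id=sid,
                group=row["group"] if row is not None else sid.rsplit("_", 1)[0],
                matrix=matrix,
                weight_kg=float(row["weight_kg"]) if row is not None else 70.0,
                dose_mg_per_kg=float(row["dose_mg_per_kg"])
                if row is not None
                else constants.NOMINAL_DOSE_MG_PER_KG,
                records=sub.reset_index(drop=True),
            )
        )
    return assays


def results_frame(results: list) -> pd.DataFrame:
    """Flatten RUFResult objects into the results CSV layout."""
    rows = []
    for r in results:
        row = {
            "assay_id": r.assay_id,
            "group": r.group,
            "matrix": r.matrix,
            "R": r.R,
            "T": r.T,
            "RUF": r.RUF if r.RUF is not None else np.nan,
            "recovery": r.recovery,
            "excluded": ";".join(r.excluded),
        }
        row.update({f"share_{m}": r.partition.get(m, np.nan) for m in constants.METABOLITES})
        rows.append(row)
    return pd.DataFrame(rows)
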