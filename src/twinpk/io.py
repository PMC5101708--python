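"""Table I/O, validation and study-report assembly.

Schemas are plain UTF-8 CSV with a header row and '.' decimal
separator:

* concentrations.csv — subject_id, pair_id, zygosity, occasion,
  time_h, conc, blq, dose_mg
* genotypes.csv — subject_id, locus, allele_count
* covariates.csv — subject_id, sex, age, bmi, + 7 diet items
* pk_parameters.csv — one row per subject-occasion plus per-subject
  means (occasion empty), Table-style parameter columns
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .simulate import DIET_ITEMS

__all__ = [
    "SchemaError",
    "read_concentrations",
    "read_genotypes",
    "read_covariates",
    "read_phenotypes",
    "summarize_pk",
    "config_hash",
]

_CONC_COLS = ["subject_id", "pair_id", "zygosity", "occasion", "time_h", "conc", "blq"]
_GENO_COLS = ["subject_id", "locus", "allele_count"]
_COVAR_COLS = ["subject_id", "sex", "age", "bmi", *DIET_ITEMS]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def _require(df: pd.DataFrame, cols: list[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_concentrations(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _CONC_COLS, path)
    df["blq"] = df["blq"].astype(bool)
    dup = df.duplicated(["subject_id", "occasion", "time_h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate sample for subject {row['subject_id']} "
            f"occasion {row['occasion']} t={row['time_h']}"
        )
    for (sid, occ), g in df.groupby(["subject_id", "occasion"]):
        t = g["time_h"].to_numpy()
        if np.any(np.diff(np.sort(t)) <= 0) or np.any(np.diff(t) <= 0):
            raise SchemaError(
                f"{path}: non-monotone sampling times for subject {sid} occasion {occ}"
            )
    return df


def read_genotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _GENO_COLS, path)
    bad = ~df["allele_count"].isin([0, 1, 2])
    if bad.any():
        raise SchemaError(
            f"{path}: allele_count outside {{0,1,2}} at row {int(np.argmax(bad.to_numpy()))}"
        )
    return df


def read_covariates(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, _COVAR_COLS, path)
    return df


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["subject_id", "pair_id", "zygosity"], path)
    return df


_SUMMARY_PARAMS = [
    ("cl_f", "Clearance (Cl/F) [l/min]"),
    ("auc_inf", "AUC_infinity [mg*min/l]"),
    ("auc_7h", "AUC_7h [mg*min/l]"),
    ("vz", "Vz [l]"),
    ("cmax", "Cmax [ug/l]"),
    ("tmax", "tmax [h]"),
    ("t_half", "t1/2 [h]"),
]


def summarize_pk(
    per_subject: pd.DataFrame, zygosity: pd.Series | None = None
) -> pd.DataFrame:
    """Per-zygosity parameter summary: mean ± SD, median, min–max and the
    max/min fold-range, for each PK parameter."""
    if zygosity is not None and "zygosity" not in per_subject.columns:
        df = per_subject.merge(
            zygosity.rename("zygosity"), left_on="subject_id", right_index=True
        )
    else:
        df = per_subject
        if "zygosity" not in df.columns:
            df = df.assign(zygosity="all")
    rows = []
    for zyg, g in df.groupby("zygosity"):
        for col, label in _SUMMARY_PARAMS:
            if col not in g:
                continue
            v = g[col].dropna().to_numpy()
            if v.size == 0:
                continue
            rows.append(
                {
                    "zygosity": zyg,
                    "parameter": label,
                    "n": v.size,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                    "median": float(np.median(v)),
                    "min": float(v.min()),
                    "max": float(v.max()),
                    "ratio_max_min": float(v.max() / v.min())
                    if v.min() > 0
                    else np.inf,
                }
            )
    return pd.DataFrame(rows)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config for provenance lines in reports."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
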