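"""CSV schemas and validated readers for the analysis pipeline.

All tabular I/O is header-first RFC-4180 CSV (UTF-8).  Concentrations are
normalized to molar on read: a ``units`` column may declare ``M`` (decimal
or scientific notation) or ``log10M`` per row.  Validation errors name the
offending rows (1-based data row numbers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose_response import ConcentrationResponseCurve

__all__ = ["SCHEMAS", "read_dataset", "curves_from_frame", "write_dataset"]

SCHEMAS = {
    "dose_response": {
        "required": ["ligand", "pathway", "conc_M", "response"],
        "optional": ["replicate", "units", "antagonist_conc_M", "depletion", "batch"],
    },
    "saturation": {"required": ["conc_M", "total_dpm", "nsb_dpm"], "optional": []},
    "competition": {"required": ["inhibitor_conc_M", "bound_dpm"], "optional": []},
    "kinetics": {"required": ["time_min", "bound_dpm", "condition"], "optional": []},
    "exposure": {
        "required": ["species", "dose_mgkg", "route", "cmax_ngml", "fu", "mw"],
        "optional": ["ratio_label", "ratio"],
    },
}


def read_dataset(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema; concentrations -> molar."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, float_precision="round_trip")
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in spec["required"] + spec["optional"]]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")

    if schema == "dose_response":
        if "units" in df.columns:
            units = df["units"].fillna("M")
            bad_units = sorted(set(units) - {"M", "log10M"})
            if bad_units:
                raise ValueError(f"{path}: unknown concentration units {bad_units}")
            conc = df["conc_M"].to_numpy(dtype=float)
            conc = np.where(units.to_numpy() == "log10M", 10.0 ** conc, conc)
            df = df.assign(conc_M=conc).drop(columns=["units"])
        _check_positive(df, "conc_M", path)
        if "antagonist_conc_M" in df.columns:
            _check_nonnegative(df, "antagonist_conc_M", path)
    elif schema in ("saturation", "competition"):
        col = "conc_M" if schema == "saturation" else "inhibitor_conc_M"
        _check_positive(df, col, path)
    elif schema == "kinetics":
        _check_nonnegative(df, "time_min", path)
    elif schema == "exposure":
        _check_positive(df, "cmax_ngml", path)
        _check_positive(df, "fu", path)
        _check_positive(df, "mw", path)
    return df


def _offending_rows(mask) -> str:
    rows = (np.flatnonzero(mask) + 1).tolist()
    return ", ".join(map(str, rows[:20])) + ("..." if len(rows) > 20 else "")


def _check_positive(df, col, path):
    vals = df[col].to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals <= 0)
    if bad.any():
        raise ValueError(f"{path}: column {col!r} must be positive and finite; bad rows: {_offending_rows(bad)}")


def _check_nonnegative(df, col, path):
    vals = df[col].to_numpy(dtype=float)
    bad = ~np.isfinite(vals) | (vals < 0)
    if bad.any():
        raise ValueError(f"{path}: column {col!r} must be >= 0 and finite; bad rows: {_offending_rows(bad)}")


def curves_from_frame(df: pd.DataFrame, group_extra: tuple = ()) -> dict:
    """Group a validated dose_response frame into ConcentrationResponseCurve objects.

    Returns a dict keyed by (ligand, pathway) + values of any
    ``group_extra`` columns (e.g. ``("antagonist_conc_M",)`` or
    ``("depletion",)``), each holding one pooled curve.
    """
    keys = ["ligand", "pathway"] + list(group_extra)
    out = {}
    for key, grp in df.groupby(keys, sort=True):
        reps = tuple(grp["replicate"]) if "replicate" in grp.columns else ()
        out[key] = ConcentrationResponseCurve(
            ligand_id=str(key[0]),
            pathway_id=str(key[1]),
            concentrations=grp["conc_M"].to_numpy(dtype=float),
            responses=grp["response"].to_numpy(dtype=float),
            replicate_ids=reps,
        )
    return out


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a CSV with full-precision floats (roundtrips exactly through read)."""
    df.to_csv(path, index=False, float_format="%.17g")
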