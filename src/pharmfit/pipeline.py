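"""End-to-end analysis pipeline: raw CSVs + JSON config -> report bundle.

Runs, in order, whatever analyses the supplied data support: per-curve 4PL
fits, per-pathway operational fits and the bias table, Schild analysis of
interaction data, binding analyses, depletion analysis and the derived
exposure table, then writes one CSV per table plus a plain-text summary.
Every output embeds the config hash, seed and package version; stage
failures yield partial outputs plus a machine-readable error manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .antagonism import dose_ratio, schild_regression
from .binding import cheng_prusoff, fit_competition, fit_dissociation, fit_saturation
from .depletion import fit_depletion_batch
from .dose_response import fit_4pl
from .exposure import ExposureRecord
from .io import curves_from_frame, read_dataset, write_dataset
from .operational import bias_table_from_fits, fit_operational_global

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisConfig:
    reference_ligand: str = "ACh"
    pathways: tuple = ()
    bias_threshold: float = 1.0
    seed: int = 0
    radioligand_kd: float = 3e-10  # molar
    radioligand_conc: float = 3e-10  # molar
    specific_activity: float = 48.01  # Ci/mmol
    protein_mg: float = 0.005
    mol_weight: float = 365.5

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "pathways" in raw:
            raw["pathways"] = tuple(raw["pathways"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: AnalysisConfig, source: str) -> dict:
    return {
        "source": source,
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }


def run_pipeline(config: AnalysisConfig, data_paths: dict, out_dir, stages=None) -> dict:
    """Run every stage for which ``data_paths`` provides a CSV.

    ``data_paths`` keys (all optional): ``dose_response``, ``interaction``,
    ``saturation``, ``competition``, ``kinetics``, ``depletion``,
    ``exposure``.  ``stages`` optionally restricts which output tables are
    produced.  Returns {"tables": {name: path}, "errors": [...],
    "ok": bool}; on any stage failure the error manifest is written to
    errors.json and ok is False.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables, errors = {}, []

    def stage(name, fn, *args):
        if stages is not None and name not in stages:
            return
        try:
            df = fn(*args)
            if df is not None:
                path = out / f"{name}.csv"
                write_dataset(df, path)
                tables[name] = str(path)
        except Exception as exc:  # noqa: BLE001 - manifest, not silence
            log.error("stage %s failed: %s", name, exc)
            errors.append({"stage": name, "error": str(exc)})

    if "dose_response" in data_paths:
        stage("fits", _stage_fits, config, data_paths["dose_response"])
        stage("bias_table", _stage_bias, config, data_paths["dose_response"])
    if "interaction" in data_paths:
        stage("schild", _stage_schild, config, data_paths["interaction"])
    if "saturation" in data_paths:
        stage("saturation", _stage_saturation, config, data_paths["saturation"])
    if "competition" in data_paths:
        stage("competition", _stage_competition, config, data_paths["competition"])
    if "kinetics" in data_paths:
        stage("kinetics", _stage_kinetics, config, data_paths["kinetics"])
    if "depletion" in data_paths:
        stage("depletion", _stage_depletion, config, data_paths["depletion"])
    if "exposure" in data_paths:
        stage("pk_derived", _stage_exposure, config, data_paths["exposure"])

    summary = out / "summary.txt"
    lines = [
        "pharmfit analysis report",
        f"version: {__version__}  config: {config.digest()}  seed: {config.seed}",
        "",
        "tables written:",
    ]
    lines += [f"  {name}: {path}" for name, path in sorted(tables.items())]
    if errors:
        lines += ["", "stage failures:"] + [f"  {e['stage']}: {e['error']}" for e in errors]
    summary.write_text("\n".join(lines) + "\n")
    if errors:
        (out / "errors.json").write_text(json.dumps(errors, indent=2))
    return {"tables": tables, "summary": str(summary), "errors": errors, "ok": not errors}


def _stage_fits(config, path):
    df = read_dataset(path, "dose_response")
    if "antagonist_conc_M" in df.columns:
        df = df[df["antagonist_conc_M"] == 0].drop(columns=["antagonist_conc_M"])
    rows = []
    for (ligand, pathway), curve in curves_from_frame(df).items():
        f = fit_4pl(curve)
        rows.append(
            {
                "ligand": ligand, "pathway": pathway,
                "bottom": f.bottom, "top": f.top, "pEC50": f.pEC50, "hill": f.hill,
                "se_pEC50": f.se_pEC50, "ec50_M": f.ec50, "residual_sd": f.residual_sd,
                "n_points": f.n_points, "converged": f.converged, "flags": ";".join(f.flags),
                **_provenance(config, str(path)),
            }
        )
    return pd.DataFrame(rows)


def _stage_bias(config, path):
    df = read_dataset(path, "dose_response")
    if "antagonist_conc_M" in df.columns:
        df = df[df["antagonist_conc_M"] == 0]
    ligands = sorted(df["ligand"].unique())
    if config.reference_ligand not in ligands:
        raise ValueError(f"reference ligand {config.reference_ligand!r} absent from data")
    pathways = list(config.pathways) or sorted(df["pathway"].unique())
    if len(pathways) < 2 or len(ligands) < 2:
        return None  # bias needs >= 2 ligands and >= 2 pathways
    curves = curves_from_frame(df)
    fits = {}
    for pw in pathways:
        pw_curves = [c for (lig, p), c in curves.items() if p == pw]
        fits[pw] = fit_operational_global(pw_curves, config.reference_ligand)
    rows = []
    for lig in ligands:
        if lig == config.reference_ligand:
            continue
        table = bias_table_from_fits(fits, lig, config.reference_ligand, config.bias_threshold)
        for (pi, pj), entry in sorted(table.delta_delta.items()):
            if pi >= pj:
                continue  # report the upper triangle; antisymmetry implies the rest
            rows.append(
                {
                    "ligand": lig, "pathway_i": pi, "pathway_j": pj,
                    "dd_log_r": entry.value, "sem": entry.sem,
                    "bias_factor": 10.0 ** entry.value,
                    "unbiased": abs(entry.value) <= config.bias_threshold,
                    **_provenance(config, str(path)),
                }
            )
    return pd.DataFrame(rows)


def _stage_schild(config, path):
    df = read_dataset(path, "dose_response")
    if "antagonist_conc_M" not in df.columns:
        raise ValueError("interaction data needs an antagonist_conc_M column (0 = control)")
    curves = curves_from_frame(df, group_extra=("antagonist_conc_M",))
    by_b = {key[2]: c for key, c in curves.items()}
    if 0.0 not in by_b:
        raise ValueError("interaction data must include a control ([antagonist] = 0)")
    control = fit_4pl(by_b[0.0])
    pairs = [(b, dose_ratio(control, fit_4pl(c))) for b, c in sorted(by_b.items()) if b > 0]
    res = schild_regression(pairs)
    return pd.DataFrame(
        [
            {
                "slope": res.slope, "se_slope": res.se_slope, "pA2": res.pA2,
                "pKB_constrained": res.pKB_constrained, "r_squared": res.r_squared,
                "n_points": res.n_points,
                "excluded": ";".join(f"{b:g}" for b, _ in res.excluded),
                **_provenance(config, str(path)),
            }
        ]
    )


def _stage_saturation(config, path):
    df = read_dataset(path, "saturation")
    r = fit_saturation(df["conc_M"], df["total_dpm"], df["nsb_dpm"])
    return pd.DataFrame(
        [
            {
                "kd_M": r.kd, "bmax": r.bmax, "ns_slope": r.ns_slope,
                "se_kd": r.se_kd, "se_bmax": r.se_bmax,
                "converged": r.converged, "flags": ";".join(r.flags),
                **_provenance(config, str(path)),
            }
        ]
    )


def _stage_competition(config, path):
    df = read_dataset(path, "competition")
    r = fit_competition(np.log10(df["inhibitor_conc_M"]), df["bound_dpm"])
    row = {
        "pIC50": r.pIC50, "se_pIC50": r.se_pIC50, "no_binding": r.no_binding,
        **_provenance(config, str(path)),
    }
    if not r.no_binding:
        ki, pki = cheng_prusoff(r.ic50, config.radioligand_conc, config.radioligand_kd)
        row.update({"ki_M": ki, "pKi": pki})
    return pd.DataFrame([row])


def _stage_kinetics(config, path):
    df = read_dataset(path, "kinetics")
    rows = []
    for cond, grp in df.groupby("condition", sort=True):
        r = fit_dissociation(grp["time_min"], grp["bound_dpm"], str(cond))
        rows.append(
            {
                "condition": cond, "b0": r.b0, "koff_per_min": r.koff,
                "se_koff": r.se_koff, "half_life_min": r.half_life,
                **_provenance(config, str(path)),
            }
        )
    return pd.DataFrame(rows)


def _stage_depletion(config, path):
    df = read_dataset(path, "dose_response")
    if "depletion" not in df.columns:
        raise ValueError("depletion data needs a depletion column (control/depleted)")
    curves = curves_from_frame(df, group_extra=("depletion",))
    pairs = {}
    for (lig, pw, cond), c in curves.items():
        pairs.setdefault(lig, {})[cond] = c
    batch = {lig: (d["control"], d["depleted"]) for lig, d in pairs.items()
             if "control" in d and "depleted" in d}
    common = "batch" in df.columns and df["batch"].nunique() == 1
    results = fit_depletion_batch(batch, common_q=common)
    rows = []
    for lig, r in sorted(results.items()):
        rows.append(
            {
                "ligand": lig, "tau_pre": r.tau_pre, "tau_post": r.tau_post,
                "q": r.q, "se_log_q": r.se_log_q, "log_KA": r.log_KA,
                "partial_agonist": r.partial_agonist, "flags": ";".join(r.flags),
                **_provenance(config, str(path)),
            }
        )
    return pd.DataFrame(rows)


def _stage_exposure(config, path):
    df = read_dataset(path, "exposure")
    rows = []
    keys = ["species", "dose_mgkg", "route", "cmax_ngml", "fu", "mw"]
    for key, grp in df.groupby(keys, sort=True):
        species, dose, route, cmax, fu, mw = key
        ratios = {}
        if "ratio" in grp.columns:
            labels = grp["ratio_label"] if "ratio_label" in grp.columns else grp.index.astype(str)
            ratios = {str(l): float(r) for l, r in zip(labels, grp["ratio"]) if np.isfinite(r)}
        rec = ExposureRecord(
            species=str(species), dose_mgkg=float(dose), route=str(route),
            cmax_plasma_ng_ml=float(cmax), fu_plasma=float(fu), mol_weight=float(mw),
            csf_plasma_ratios=ratios,
        )
        rows.append(
            {
                "species": rec.species, "dose_mgkg": rec.dose_mgkg, "route": rec.route,
                "cmax_ngml": rec.cmax_plasma_ng_ml, "plasma_nM": rec.plasma_nM,
                "cu_plasma_nM": rec.cu_plasma_nM,
                "cu_brain_low_nM": rec.cu_brain_range_nM[0],
                "cu_brain_high_nM": rec.cu_brain_range_nM[1],
                **_provenance(config, str(path)),
            }
        )
    return pd.DataFrame(rows)
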