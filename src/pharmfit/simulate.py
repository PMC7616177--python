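"""Seeded synthetic-assay generators for every analysis in the package.

Each generator evaluates a closed-form truth model on a concentration (or
time) grid and adds Gaussian measurement noise with standard deviation
expressed as a fraction of the truth's response span - the dominant noise
mode of plate-read and filtration assays.  All randomness flows from a
single explicit integer seed through named substreams (one per replicate,
via ``numpy`` SeedSequence spawning), so the same (design, seed) pair is
byte-identical and adding replicates never perturbs existing ones.  Noise
never touches the truth: changing the seed changes realizations only.

Default designs mirror common practice: 8-point half-log concentration
grids, duplicate wells, 3-4 independent experiments per condition.
"""

from __future__ import annotations

import numpy as np

from .dose_response import ConcentrationResponseCurve
from .operational import operational_response

__all__ = [
    "half_log_grid",
    "gen_dose_response",
    "gen_antagonism_family",
    "gen_binding_assay",
    "gen_depletion_experiment",
]


def half_log_grid(top_molar: float, n: int = 8) -> np.ndarray:
    """Descending-from-top half-log (sqrt(10)) dilution series, returned ascending."""
    return top_molar / np.sqrt(10.0) ** np.arange(n)[::-1]


def _replicate_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _noisy_replicates(clean: np.ndarray, span: float, noise_sd: float, replicates: int, seed: int):
    """Stack `replicates` noisy copies of the clean signal; additive Gaussian."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rngs = _replicate_rngs(seed, replicates)
    return [clean + rng.normal(0.0, noise_sd * span, size=clean.shape) for rng in rngs]


def _truth_4pl(conc, truth):
    log_a = np.log10(np.asarray(conc, dtype=float))
    b, t = truth.get("bottom", 0.0), truth.get("top", 100.0)
    pec50, hill = truth["pEC50"], truth.get("hill", 1.0)
    return b + (t - b) / (1.0 + 10.0 ** ((-pec50 - log_a) * hill)), t - b


def _truth_operational(conc, truth):
    em, basal = truth.get("em", 100.0), truth.get("basal", 0.0)
    n = truth.get("n", 1.0)
    log_r, log_ka = truth["log_R"], truth["log_KA"]
    return operational_response(conc, em, basal, n, log_r, log_ka), em - basal


def gen_dose_response(
    truth: dict,
    concentrations,
    replicates: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    model: str = "4pl",
    ligand_id: str = "test",
    pathway_id: str = "assay",
) -> ConcentrationResponseCurve:
    """Simulate one ligand x pathway curve, replicate wells pooled into one curve.

    ``truth`` holds 4PL parameters (``bottom``, ``top``, ``pEC50``,
    ``hill``) for ``model="4pl"`` or operational parameters (``em``,
    ``basal``, ``n``, ``log_R``, ``log_KA``) for ``model="operational"``.
    ``noise_sd`` is a fraction of the truth's response span.
    """
    conc = np.asarray(concentrations, dtype=float)
    if model == "4pl":
        clean, span = _truth_4pl(conc, truth)
    elif model == "operational":
        clean, span = _truth_operational(conc, truth)
    else:
        raise ValueError(f"unknown model label: {model!r}")
    reps = _noisy_replicates(clean, span, noise_sd, replicates, seed)
    return ConcentrationResponseCurve(
        ligand_id=ligand_id,
        pathway_id=pathway_id,
        concentrations=np.tile(conc, replicates),
        responses=np.concatenate(reps),
        replicate_ids=tuple(np.repeat(np.arange(replicates), conc.size)),
    )


def gen_antagonism_family(
    agonist_truth: dict,
    pkb: float,
    antagonist_concs,
    concentrations,
    mode: str = "pure_competitive",
    tau_b: float = 0.0,
    replicates: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    ligand_id: str = "agonist",
    pathway_id: str = "assay",
) -> dict:
    """Family of agonist curves at increasing antagonist concentration [B].

    ``pure_competitive`` applies the Gaddum shift EC50' = EC50 * (1 +
    [B]/K_B) at unchanged top/bottom.  ``partial_agonist`` instead uses the
    two-ligand operational closed form, in which the interacting ligand
    contributes its own effect tau_b (raising the baseline at high [B]);
    ``agonist_truth`` must then be operational parameters plus the
    antagonist's ``log_KA`` given implicitly by pkb (K_B).  [B] = 0 (the
    control) must be included.
    """
    b_list = list(antagonist_concs)
    if 0.0 not in b_list:
        raise ValueError("antagonist concentration list must include 0 (control)")
    kb = 10.0 ** (-pkb)
    conc = np.asarray(concentrations, dtype=float)
    out = {}
    for i, b in enumerate(b_list):
        if mode == "pure_competitive":
            shifted = dict(agonist_truth)
            ec50 = 10.0 ** (-agonist_truth["pEC50"]) * (1.0 + b / kb)
            shifted["pEC50"] = -np.log10(ec50)
            clean, span = _truth_4pl(conc, shifted)
        elif mode == "partial_agonist":
            em = agonist_truth.get("em", 100.0)
            basal = agonist_truth.get("basal", 0.0)
            n = agonist_truth.get("n", 1.0)
            tau_a = 10.0 ** (agonist_truth["log_R"] + agonist_truth["log_KA"])
            ka = 10.0 ** agonist_truth["log_KA"]
            act = tau_a * conc / ka + tau_b * b / kb
            occ = 1.0 + conc / ka + b / kb
            clean = basal + (em - basal) * act ** n / (occ ** n + act ** n)
            span = em - basal
        else:
            raise ValueError(f"unknown antagonism mode: {mode!r}")
        reps = _noisy_replicates(clean, span, noise_sd, replicates, seed + 1000 * i)
        out[b] = ConcentrationResponseCurve(
            ligand_id=ligand_id,
            pathway_id=pathway_id,
            concentrations=np.tile(conc, replicates),
            responses=np.concatenate(reps),
            replicate_ids=tuple(np.repeat(np.arange(replicates), conc.size)),
        )
    return out


def gen_binding_assay(truth: dict, kind: str, grid, noise_sd: float = 0.05,
                      seed: int = 0, lognormal: bool = False) -> dict:
    """Simulate one radioligand binding experiment.

    kind="saturation": truth ``kd``, ``bmax``, ``ns_slope``; grid is L
    (molar).  Emits total and NSB channels (NSB = ns_slope * L).
    kind="competition": truth ``ki`` (or ``ic50``), ``radioligand_conc``,
    ``radioligand_kd``, ``top``, ``bottom``; grid is inhibitor molar.  The
    underlying IC50 follows the forward Cheng-Prusoff relation
    IC50 = K_i * (1 + L/K_D).
    kind="dissociation": truth ``b0``, ``koff``; grid is time (minutes).

    ``lognormal=True`` switches to multiplicative lognormal noise (an
    option for count data); the default is additive Gaussian on the span.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    def add_noise(clean, span):
        if noise_sd == 0:
            return clean.copy()
        if lognormal:
            return clean * rng.lognormal(0.0, noise_sd, size=clean.shape)
        return clean + rng.normal(0.0, noise_sd * span, size=clean.shape)

    g = np.asarray(grid, dtype=float)
    if kind == "saturation":
        kd, bmax = truth["kd"], truth["bmax"]
        ns = truth.get("ns_slope", 0.0)
        specific = bmax * g / (kd + g)
        nsb = ns * g
        return {
            "conc_M": g,
            "total_dpm": add_noise(specific + nsb, bmax),
            "nsb_dpm": add_noise(nsb, bmax),
        }
    if kind == "competition":
        if "ic50" in truth:
            ic50 = truth["ic50"]
        else:
            ic50 = truth["ki"] * (1.0 + truth["radioligand_conc"] / truth["radioligand_kd"])
        top, bottom = truth.get("top", 100.0), truth.get("bottom", 0.0)
        clean = bottom + (top - bottom) / (1.0 + g / ic50)
        return {"inhibitor_conc_M": g, "bound_dpm": add_noise(clean, top - bottom)}
    if kind == "dissociation":
        b0, koff = truth["b0"], truth["koff"]
        clean = b0 * np.exp(-koff * g)
        return {"time_min": g, "bound_dpm": add_noise(clean, b0)}
    raise ValueError(f"unknown binding assay kind: {kind!r}")


def gen_depletion_experiment(
    truths: dict,
    q: float,
    concentrations,
    em: float = 100.0,
    basal: float = 0.0,
    n: float = 1.0,
    replicates: int = 2,
    noise_sd: float = 0.05,
    seed: int = 0,
    pathway_id: str = "assay",
) -> dict:
    """Paired control/depleted curve sets; depletion scales every tau by common q.

    ``truths`` maps ligand_id -> dict with ``tau`` and ``ka`` (molar).
    Returns ligand_id -> (control_curve, depleted_curve).
    """
    if q < 0:
        raise ValueError("surviving fraction q must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    out = {}
    for i, (lig, tr) in enumerate(sorted(truths.items())):
        tau, ka = tr["tau"], tr["ka"]
        pair = []
        for j, tau_c in enumerate((tau, tau * q)):
            log_ka = np.log10(ka)
            log_r = np.log10(max(tau_c, 1e-300)) - log_ka
            clean = operational_response(conc, em, basal, n, log_r, log_ka)
            reps = _noisy_replicates(clean, em - basal, noise_sd, replicates, seed + 100 * i + j)
            pair.append(
                ConcentrationResponseCurve(
                    ligand_id=lig,
                    pathway_id=pathway_id,
                    concentrations=np.tile(conc, replicates),
                    responses=np.concatenate(reps),
                    replicate_ids=tuple(np.repeat(np.arange(replicates), conc.size)),
                )
            )
        out[lig] = tuple(pair)
    return out
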