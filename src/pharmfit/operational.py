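"""Operational (Black-Leff) model of agonism and ligand-bias quantification.

The operational model describes agonist response through a hyperbolic
transducer:

    E(A) = Basal + (Em - Basal) * (tau*A)^n / ((A + K_A)^n + (tau*A)^n)

where Em is the maximal system response, Basal the response at A = 0, n the
transducer slope, tau the operational efficacy (receptor density x coupling)
and K_A the functional dissociation constant.  The quantity interpreted per
ligand and pathway is the transduction coefficient log(tau/K_A): within a
pathway it is referenced to a standard agonist (Delta log(tau/K_A)) and the
between-pathway difference of those deltas (DeltaDelta log(tau/K_A)) is the
log bias factor.  |DeltaDelta| <= 1 log unit is the conventional window for
calling a ligand unbiased.

System parameters (Em, Basal, n) are shared across ligands within a pathway
- required for identifiability and standard transduction-coefficient
practice - while (log_R = log(tau/K_A), log_KA) are fitted per ligand.  For
full agonists (plateau within 2% of Em) K_A is poorly identified and only
log_R should be interpreted; such entries are flagged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dose_response import ConcentrationResponseCurve, _covariance_se, fit_4pl

__all__ = [
    "LigandTransduction",
    "OperationalFit",
    "BiasEntry",
    "BiasTable",
    "fit_operational_global",
    "delta_log_r",
    "delta_delta_log_r",
    "assess_bias",
    "operational_response",
]

N_BOUNDS = (0.3, 5.0)
LOGR_MARGIN = 3.0
LOGKA_MARGIN = 3.0
# plateau within this fraction of Em marks a full agonist (K_A unidentifiable)
FULL_AGONIST_TOL = 0.02


def operational_response(conc, em, basal, n, log_r, log_ka):
    """Closed-form operational response, computed in log space for stability."""
    a = np.asarray(conc, dtype=float)
    ka = 10.0 ** log_ka
    log_tau_a = (log_r + log_ka) + np.log10(a)
    exponent = n * (np.log10(a + ka) - log_tau_a)
    return basal + (em - basal) / (1.0 + 10.0 ** exponent)


@dataclass(frozen=True)
class LigandTransduction:
    """Per-ligand transduction parameters from one pathway's global fit."""

    ligand_id: str
    pathway_id: str
    log_R: float  # log10(tau/K_A), the transduction coefficient
    log_KA: float  # log10 K_A (molar)
    se_log_R: float
    se_log_KA: float
    ka_identifiable: bool = True

    @property
    def log_tau(self) -> float:
        return self.log_R + self.log_KA

    @property
    def tau(self) -> float:
        return 10.0 ** self.log_tau


@dataclass(frozen=True)
class OperationalFit:
    """Global operational fit of one pathway: shared system + per-ligand entries."""

    pathway_id: str
    em: float
    basal: float
    n: float
    se_em: float
    se_basal: float
    se_n: float
    ligands: dict  # ligand_id -> LigandTransduction
    reference_ligand: str
    converged: bool
    residual_sd: float

    def __getitem__(self, ligand_id: str) -> LigandTransduction:
        return self.ligands[ligand_id]


def fit_operational_global(
    curves: list[ConcentrationResponseCurve],
    reference_ligand: str,
    fix_basal: float | None = None,
) -> OperationalFit:
    """Globally fit the operational model to all ligands of one pathway.

    Em, Basal and n are shared; (log_R, log_KA) are free per ligand.  Basal
    is fitted unless the data are reference-normalized (all curves in
    percent_reference units), in which case it is fixed at 0; pass
    ``fix_basal`` to override either way.
    """
    if len(curves) < 2:
        raise ValueError("global operational fit needs >= 2 ligands (system parameters unidentifiable)")
    pathways = {c.pathway_id for c in curves}
    if len(pathways) > 1:
        raise ValueError(f"curves mix pathways: {sorted(pathways)}")
    ligand_ids = [c.ligand_id for c in curves]
    if len(set(ligand_ids)) != len(ligand_ids):
        raise ValueError("one curve per ligand expected (pool replicates into a single curve)")
    if reference_ligand not in ligand_ids:
        raise ValueError(f"reference ligand {reference_ligand!r} not among {ligand_ids}")
    # deterministic parameter layout independent of input order
    order = sorted(range(len(curves)), key=lambda i: ligand_ids[i])
    curves = [curves[i] for i in order]
    ligand_ids = [ligand_ids[i] for i in order]

    if fix_basal is None and all(c.response_units == "percent_reference" for c in curves):
        fix_basal = 0.0
    free_basal = fix_basal is None

    y_all = np.concatenate([c.responses for c in curves])
    ymax = float(y_all.max())
    ymin = float(y_all.min())
    span = ymax - ymin if ymax > ymin else 1.0
    all_log_a = np.concatenate([np.log10(c.concentrations) for c in curves])
    la_lo, la_hi = float(all_log_a.min()), float(all_log_a.max())

    # initialization from per-ligand 4PL fits (n = 1 identities)
    em0 = ymax * 1.02
    basal0 = fix_basal if fix_basal is not None else ymin
    per = []
    for c in curves:
        try:
            f = fit_4pl(c)
            plateau = min(max((f.top - basal0) / max(em0 - basal0, 1e-9), 0.05), 0.98)
            tau0 = plateau / (1.0 - plateau)
            ka0 = f.ec50 * (1.0 + tau0)
        except ValueError:
            tau0, ka0 = 1.0, 10.0 ** ((la_lo + la_hi) / 2.0)
        per.append((np.log10(tau0) - np.log10(ka0), np.log10(ka0)))

    # parameter vector: [em, (basal), n, log_R_1, log_KA_1, ...]
    x0 = [em0] + ([basal0] if free_basal else []) + [1.0]
    lo = [ymin + 0.5 * span] + ([ymin - span] if free_basal else []) + [N_BOUNDS[0]]
    hi = [ymax + 2.0 * span] + ([ymin + 0.5 * span] if free_basal else []) + [N_BOUNDS[1]]
    for log_r0, log_ka0 in per:
        x0 += [log_r0, log_ka0]
        lo += [-la_hi - LOGR_MARGIN, la_lo - LOGKA_MARGIN]
        hi += [-la_lo + LOGR_MARGIN + 3.0, la_hi + LOGKA_MARGIN]
    x0 = np.clip(np.asarray(x0, float), np.asarray(lo, float) + 1e-9, np.asarray(hi, float) - 1e-9)

    nsys = 3 if free_basal else 2

    def unpack(p):
        em = p[0]
        basal = p[1] if free_basal else fix_basal
        n = p[nsys - 1]
        return em, basal, n

    def residuals(p):
        em, basal, n = unpack(p)
        out = []
        for k, c in enumerate(curves):
            log_r, log_ka = p[nsys + 2 * k], p[nsys + 2 * k + 1]
            out.append(operational_response(c.concentrations, em, basal, n, log_r, log_ka) - c.responses)
        return np.concatenate(out)

    sol = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13
    )
    em, basal, n = unpack(sol.x)
    npts = y_all.size
    nparams = nsys + 2 * len(curves)
    dof = max(npts - nparams, 1)
    rss = float(2.0 * sol.cost)
    ses = _covariance_se(sol.jac, rss, dof)
    se_em = ses[0]
    se_basal = ses[1] if free_basal else 0.0
    se_n = ses[nsys - 1]

    ligands = {}
    for k, c in enumerate(curves):
        log_r, log_ka = float(sol.x[nsys + 2 * k]), float(sol.x[nsys + 2 * k + 1])
        tau = 10.0 ** (log_r + log_ka)
        plateau = basal + (em - basal) * tau ** n / (1.0 + tau ** n)
        identifiable = plateau < em - FULL_AGONIST_TOL * (em - basal)
        ligands[c.ligand_id] = LigandTransduction(
            ligand_id=c.ligand_id,
            pathway_id=c.pathway_id,
            log_R=log_r,
            log_KA=log_ka,
            se_log_R=ses[nsys + 2 * k],
            se_log_KA=ses[nsys + 2 * k + 1],
            ka_identifiable=bool(identifiable),
        )
    return OperationalFit(
        pathway_id=curves[0].pathway_id,
        em=float(em),
        basal=float(basal),
        n=float(n),
        se_em=se_em,
        se_basal=se_basal,
        se_n=se_n,
        ligands=ligands,
        reference_ligand=reference_ligand,
        converged=bool(sol.success),
        residual_sd=float(np.sqrt(rss / dof)),
    )


@dataclass(frozen=True)
class BiasEntry:
    value: float
    sem: float


@dataclass(frozen=True)
class BiasTable:
    """Delta and DeltaDelta log(tau/K_A) of one test ligand vs a reference."""

    ligand_id: str
    reference_ligand: str
    delta: dict  # pathway -> BiasEntry
    delta_delta: dict  # (pathway_i, pathway_j) -> BiasEntry
    bias_threshold: float = 1.0

    def bias_factor(self, pathway_i: str, pathway_j: str) -> float:
        return 10.0 ** self.delta_delta[(pathway_i, pathway_j)].value

    def unbiased(self, pathway_i: str, pathway_j: str) -> bool:
        return abs(self.delta_delta[(pathway_i, pathway_j)].value) <= self.bias_threshold


def delta_log_r(test: LigandTransduction, reference: LigandTransduction) -> BiasEntry:
    """Delta log(tau/K_A) = log_R_test - log_R_ref within one pathway; SEM by quadrature."""
    if test.pathway_id != reference.pathway_id:
        raise ValueError(
            f"cross-pathway subtraction: {test.pathway_id!r} vs {reference.pathway_id!r}"
        )
    return BiasEntry(
        value=test.log_R - reference.log_R,
        sem=float(np.sqrt(test.se_log_R ** 2 + reference.se_log_R ** 2)),
    )


def delta_delta_log_r(deltas: dict) -> dict:
    """All ordered pathway pairs of DeltaDelta = Delta_i - Delta_j, SEM by quadrature."""
    if len(deltas) < 2:
        raise ValueError("DeltaDelta requires deltas from >= 2 pathways")
    out = {}
    for pi, pj in itertools.permutations(sorted(deltas), 2):
        di, dj = deltas[pi], deltas[pj]
        out[(pi, pj)] = BiasEntry(
            value=di.value - dj.value, sem=float(np.sqrt(di.sem ** 2 + dj.sem ** 2))
        )
    return out


def assess_bias(table: BiasTable, threshold: float | None = None) -> dict:
    """Flag each pathway pair: unbiased iff |DeltaDelta| <= threshold (log units)."""
    thr = table.bias_threshold if threshold is None else threshold
    if not table.delta_delta:
        raise ValueError("bias table has no DeltaDelta entries")
    return {pair: abs(e.value) <= thr for pair, e in table.delta_delta.items()}


def bias_table_from_fits(
    fits: dict, ligand_id: str, reference_ligand: str, bias_threshold: float = 1.0
) -> BiasTable:
    """Assemble a BiasTable from per-pathway OperationalFits.

    ``fits`` maps pathway_id -> OperationalFit containing both ligands.
    """
    deltas = {}
    for pathway, fit in fits.items():
        deltas[pathway] = delta_log_r(fit[ligand_id], fit[reference_ligand])
    dd = delta_delta_log_r(deltas) if len(deltas) >= 2 else {}
    return BiasTable(
        ligand_id=ligand_id,
        reference_ligand=reference_ligand,
        delta=deltas,
        delta_delta=dd,
        bias_threshold=bias_threshold,
    )
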