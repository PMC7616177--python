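"""Intrinsic-efficacy estimation by irreversible receptor inactivation (Furchgott).

Alkylating agents such as phenoxybenzamine remove a fraction of the
receptor pool.  Under the operational model that is purely a scaling of the
operational efficacy tau by the surviving fraction q, at fixed K_A: the
control and depleted curves of one ligand are therefore fitted jointly with
shared K_A (and shared system Em, n) and free tau per condition, giving

    q = tau_post / tau_pre.

Because plateau = Em * tau^n / (1 + tau^n), the same q costs a partial
agonist (small tau) proportionally far more maximum than a full agonist -
the signature by which low-efficacy agonists are identified.  Relative
efficacy between two ligands in the same system is the ratio of their
pre-depletion tau values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dose_response import ConcentrationResponseCurve, _covariance_se, fit_4pl
from .operational import operational_response

__all__ = ["DepletionResult", "fit_depletion_pair", "fit_depletion_batch", "relative_efficacy"]

Q_UPPER_FLAG = 1.1  # q above this is flagged (depletion should not gain receptors)


@dataclass(frozen=True)
class DepletionResult:
    ligand_id: str
    tau_pre: float
    tau_post: float
    q: float  # surviving receptor fraction tau_post / tau_pre
    se_log_q: float
    log_KA: float
    se_log_KA: float
    em: float
    n: float
    converged: bool
    flags: tuple = ()

    @property
    def partial_agonist(self) -> bool:
        """Pre-depletion plateau below 95% of Em marks a partial agonist."""
        plateau = self.em * self.tau_pre ** self.n / (1.0 + self.tau_pre ** self.n)
        return plateau < 0.95 * self.em


def _log_tau_bounds(la_lo, la_hi):
    # tau/K_A spans the potency scale; generous box around the data decades
    return (-6.0, 6.0), (la_lo - 3.0, la_hi + 3.0)


def fit_depletion_pair(
    control: ConcentrationResponseCurve,
    depleted: ConcentrationResponseCurve,
    system: dict | None = None,
) -> DepletionResult:
    """Joint operational fit of a control/depleted curve pair for one ligand.

    Parameters
    ----------
    system
        Optional dict with any of ``em``, ``n``, ``basal`` to anchor the
        shared system parameters (e.g. Em from a pre-depletion full-agonist
        reference).  Unspecified parameters are co-fitted; a co-fitted Em is
        flagged ``em-cofitted``.
    """
    if control.ligand_id != depleted.ligand_id or control.pathway_id != depleted.pathway_id:
        raise ValueError("control and depleted curves must be the same ligand and pathway")
    batch = fit_depletion_batch({control.ligand_id: (control, depleted)}, common_q=False, system=system)
    return batch[control.ligand_id]


def fit_depletion_batch(
    pairs: dict,
    common_q: bool = True,
    system: dict | None = None,
) -> dict:
    """Joint fit of several ligands' control/depleted pairs from one treatment batch.

    With ``common_q=True`` (the default for curves sharing a treatment
    label) a single surviving fraction q is shared across ligands, since
    alkylation depletes the receptor pool, not the ligand.  Returns a dict
    ligand_id -> DepletionResult.
    """
    system = dict(system or {})
    ligands = sorted(pairs)
    curves = []
    for lig in ligands:
        c, d = pairs[lig]
        curves.extend([c, d])
    y_all = np.concatenate([c.responses for c in curves])
    all_log_a = np.concatenate([np.log10(c.concentrations) for c in curves])
    la_lo, la_hi = float(all_log_a.min()), float(all_log_a.max())
    ymax, ymin = float(y_all.max()), float(y_all.min())
    span = ymax - ymin if ymax > ymin else 1.0

    basal = float(system.get("basal", 0.0))
    em_fixed = "em" in system
    n_fixed = "n" in system
    flags_shared = [] if em_fixed else ["em-cofitted"]

    lt_bounds, lka_bounds = _log_tau_bounds(la_lo, la_hi)

    # layout: [em?][n?][log_q (common) or per-ligand][per ligand: log_tau_pre, log_KA, (log_q if not common)]
    x0, lo, hi = [], [], []
    if not em_fixed:
        x0 += [ymax * 1.05]
        lo += [ymin + 0.5 * span]
        hi += [ymax + 2.0 * span]
    if not n_fixed:
        x0 += [1.0]
        lo += [0.3]
        hi += [5.0]
    if common_q:
        x0 += [-0.3]
        lo += [-6.0]
        hi += [np.log10(1.5)]
    em0 = float(system.get("em", ymax * 1.05))
    for lig in ligands:
        c, d = pairs[lig]
        try:
            f = fit_4pl(c)
            p = min(max((f.top - basal) / max(em0 - basal, 1e-9), 0.05), 0.98)
            tau0 = p / (1.0 - p)
            ka0 = f.ec50 * (1.0 + tau0)
            lt0, lka0 = np.log10(tau0), np.log10(ka0)
        except ValueError:
            lt0, lka0 = 0.0, (la_lo + la_hi) / 2.0
        x0 += [lt0, lka0]
        lo += [lt_bounds[0], lka_bounds[0]]
        hi += [lt_bounds[1], lka_bounds[1]]
        if not common_q:
            x0 += [-0.3]
            lo += [-6.0]
            hi += [np.log10(1.5)]
    x0 = np.clip(np.asarray(x0, float), np.asarray(lo, float) + 1e-9, np.asarray(hi, float) - 1e-9)

    def unpack(p):
        i = 0
        em = float(system["em"]) if em_fixed else p[i]
        i += 0 if em_fixed else 1
        n = float(system["n"]) if n_fixed else p[i]
        i += 0 if n_fixed else 1
        lq_common = None
        if common_q:
            lq_common = p[i]
            i += 1
        per = {}
        for lig in ligands:
            lt, lka = p[i], p[i + 1]
            i += 2
            if common_q:
                lq = lq_common
            else:
                lq = p[i]
                i += 1
            per[lig] = (lt, lka, lq)
        return em, n, per

    def residuals(p):
        em, n, per = unpack(p)
        out = []
        for lig in ligands:
            c, d = pairs[lig]
            lt, lka, lq = per[lig]
            lr_pre = lt - lka
            out.append(operational_response(c.concentrations, em, basal, n, lr_pre, lka) - c.responses)
            out.append(operational_response(d.concentrations, em, basal, n, lr_pre + lq, lka) - d.responses)
        return np.concatenate(out)

    sol = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13
    )
    em, n, per = unpack(sol.x)
    npts = y_all.size
    dof = max(npts - sol.x.size, 1)
    rss = float(2.0 * sol.cost)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (rss / dof)
    except np.linalg.LinAlgError:
        cov = np.full((sol.x.size, sol.x.size), np.nan)
    ses = _covariance_se(sol.jac, rss, dof)

    # recover parameter indices for SEs
    idx = 0
    idx += 0 if em_fixed else 1
    idx += 0 if n_fixed else 1
    i_lq_common = idx if common_q else None
    idx += 1 if common_q else 0
    results = {}
    for lig in ligands:
        i_lt, i_lka = idx, idx + 1
        idx += 2
        i_lq = i_lq_common if common_q else idx
        idx += 0 if common_q else 1
        lt, lka, lq = per[lig]
        q = 10.0 ** lq
        flags = list(flags_shared)
        if q > Q_UPPER_FLAG:
            flags.append("q>1.1")
        c, d = pairs[lig]
        if np.ptp(d.responses) < 0.05 * span:
            flags.append("q-upper-bound")  # depleted response at basal: q only bounded
        results[lig] = DepletionResult(
            ligand_id=lig,
            tau_pre=float(10.0 ** lt),
            tau_post=float(10.0 ** (lt + lq)),
            q=float(q),
            se_log_q=ses[i_lq],
            log_KA=float(lka),
            se_log_KA=ses[i_lka],
            em=float(em),
            n=float(n),
            converged=bool(sol.success),
            flags=tuple(flags),
        )
    return results


def relative_efficacy(tau_test: float, se_log_tau_test: float,
                      tau_ref: float, se_log_tau_ref: float) -> tuple[float, float]:
    """tau_test / tau_ref with log-scale quadrature SE.

    Returns (ratio, se_log10_ratio).  Both ligands must come from the same
    pathway and system fit for the ratio to be meaningful.
    """
    if tau_ref <= 0:
        raise ValueError("reference tau must be positive")
    if tau_test < 0:
        raise ValueError("test tau must be non-negative")
    ratio = tau_test / tau_ref
    se = float(np.sqrt(se_log_tau_test ** 2 + se_log_tau_ref ** 2))
    return float(ratio), se
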