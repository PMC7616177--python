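"""Radioligand-binding analyses.

Covers the standard filtration-assay workflows: one-site saturation binding
(K_D, Bmax, with nonspecific binding modelled linearly through the origin),
one-site competition with the Cheng-Prusoff conversion of IC50 to K_i,
mono-exponential dissociation kinetics with a paired-condition koff ratio
test (the classic probe for allosteric modulation of ligand off-rate), and
the dpm -> fmol/mg unit conversion (1 Ci = 2.22e12 dpm).

All concentrations are molar, times in minutes, densities in fmol per mg
protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .dose_response import _covariance_se

__all__ = [
    "SaturationResult",
    "CompetitionResult",
    "KineticResult",
    "DissociationComparison",
    "fit_saturation",
    "fit_competition",
    "cheng_prusoff",
    "fit_dissociation",
    "compare_dissociation",
    "dpm_to_fmol_per_mg",
]

DPM_PER_CI = 2.22e12
# response span below this multiple of the noise scale means "no binding
# detected" rather than a fit failure
NO_BINDING_SPAN_FACTOR = 3.0


@dataclass(frozen=True)
class SaturationResult:
    kd: float  # molar
    bmax: float  # fmol/mg (or input units)
    ns_slope: float  # nonspecific binding per molar
    se_kd: float
    se_bmax: float
    converged: bool
    flags: tuple = ()

    def specific_at(self, conc) -> np.ndarray:
        L = np.asarray(conc, dtype=float)
        return self.bmax * L / (self.kd + L)


@dataclass(frozen=True)
class CompetitionResult:
    pIC50: float
    se_pIC50: float
    top: float
    bottom: float
    no_binding: bool = False
    converged: bool = True

    @property
    def ic50(self) -> float:
        return 10.0 ** (-self.pIC50)


@dataclass(frozen=True)
class KineticResult:
    b0: float
    koff: float  # per minute
    se_koff: float
    condition: str = ""
    converged: bool = True

    @property
    def half_life(self) -> float:
        """Minutes; ln(2)/koff."""
        return float(np.log(2.0) / self.koff)


@dataclass(frozen=True)
class DissociationComparison:
    koff_ratio: float  # test / control
    ci_low: float
    ci_high: float
    kinetics_altered: bool


def fit_saturation(L, total_dpm, nsb_dpm) -> SaturationResult:
    """One-site saturation fit: specific = Bmax*L/(K_D + L).

    Specific binding is total minus matched nonspecific wells; the
    nonspecific slope is a separate regression of NSB on L through the
    origin.  A fitted K_D above the highest tested concentration is
    flagged as extrapolated.
    """
    L = np.asarray(L, dtype=float)
    total = np.asarray(total_dpm, dtype=float)
    nsb = np.asarray(nsb_dpm, dtype=float)
    if L.size < 5:
        raise ValueError("saturation fit requires >= 5 concentrations")
    if L.shape != total.shape or L.shape != nsb.shape:
        raise ValueError("L, total and NSB arrays must align")
    specific = total - nsb
    ns_slope = float(np.sum(nsb * L) / np.sum(L * L))

    # fit log10 K_D: the molar scale is many orders below Bmax and would
    # otherwise wreck the optimizer's step scaling
    def residuals(p):
        log_kd, bmax = p
        return bmax * L / (10.0 ** log_kd + L) - specific

    bmax0 = float(specific.max())
    half = bmax0 / 2.0
    lkd0 = float(np.log10(L[np.argmin(np.abs(specific - half))]))
    sol = optimize.least_squares(
        residuals, [lkd0, bmax0],
        bounds=([np.log10(L.min()) - 4.0, 0.0], [np.log10(L.max()) + 4.0, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    kd, bmax = 10.0 ** sol.x[0], sol.x[1]
    dof = max(L.size - 2, 1)
    rss = float(2.0 * sol.cost)
    ses = _covariance_se(sol.jac, rss, dof)
    # delta method: se(K_D) from se(log10 K_D)
    ses = (kd * np.log(10.0) * ses[0], ses[1])
    flags = []
    if kd > L.max():
        flags.append("kd-extrapolated")
    return SaturationResult(
        kd=float(kd), bmax=float(bmax), ns_slope=ns_slope,
        se_kd=ses[0], se_bmax=ses[1], converged=bool(sol.success), flags=tuple(flags),
    )


def fit_competition(log_I, bound) -> CompetitionResult:
    """Descending one-site logistic with Hill slope fixed at -1.

        B = bottom + (top - bottom) / (1 + 10^(log[I] + pIC50))

    Returns a ``no_binding`` result (not an exception) when the fitted span
    is indistinguishable from the noise floor, mirroring assays where a test
    compound shows no detectable displacement.
    """
    log_i = np.asarray(log_I, dtype=float)
    y = np.asarray(bound, dtype=float)
    if log_i.size < 5:
        raise ValueError("competition fit requires >= 5 inhibitor concentrations")

    def model(p):
        bottom, top, pic50 = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** (log_i + pic50))

    bottom0, top0 = float(y.min()), float(y.max())
    half = (bottom0 + top0) / 2.0
    pic500 = -float(log_i[np.argmin(np.abs(y - half))])
    lo = [-np.inf, -np.inf, -log_i.max() - 3.0]
    hi = [np.inf, np.inf, -log_i.min() + 3.0]
    sol = optimize.least_squares(
        lambda p: model(p) - y, np.clip([bottom0, top0, pic500], np.asarray(lo) + 1e-9, np.asarray(hi) - 1e-9),
        bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
    )
    bottom, top, pic50 = sol.x
    dof = max(y.size - 3, 1)
    rss = float(2.0 * sol.cost)
    resid_sd = float(np.sqrt(rss / dof))
    span = abs(top - bottom)
    if span < NO_BINDING_SPAN_FACTOR * resid_sd:
        return CompetitionResult(
            pIC50=np.nan, se_pIC50=np.nan, top=float(top), bottom=float(bottom),
            no_binding=True, converged=bool(sol.success),
        )
    ses = _covariance_se(sol.jac, rss, dof)
    return CompetitionResult(
        pIC50=float(pic50), se_pIC50=ses[2], top=float(top), bottom=float(bottom),
        no_binding=False, converged=bool(sol.success),
    )


def cheng_prusoff(ic50: float, L: float, kd: float) -> tuple[float, float]:
    """K_i = IC50 / (1 + [L]/K_D); returns (K_i in molar, pK_i)."""
    if ic50 <= 0 or L < 0 or kd <= 0:
        raise ValueError("cheng_prusoff requires IC50 > 0, K_D > 0 and [L] >= 0")
    ki = ic50 / (1.0 + L / kd)
    return ki, float(-np.log10(ki))


def fit_dissociation(t, bound, condition: str = "") -> KineticResult:
    """Mono-exponential decay B(t) = B0 * exp(-koff * t).

    Requires >= 5 time points with t = 0 included or extrapolable.  A
    significantly increasing trend in bound counts over time is a protocol
    violation and raises.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(bound, dtype=float)
    if t.size < 5:
        raise ValueError("dissociation fit requires >= 5 time points")
    trend = stats.linregress(t, y)
    if trend.slope > 0 and trend.pvalue < 0.01:
        raise ValueError("bound counts increase over time beyond noise; not a dissociation curve")

    def residuals(p):
        b0, koff = p
        return b0 * np.exp(-koff * t) - y

    b0_0 = float(max(y.max(), 1e-12))
    pos = y > 0
    if pos.sum() >= 2:
        k0 = max(-stats.linregress(t[pos], np.log(y[pos])).slope, 1e-4)
    else:
        k0 = 0.1
    sol = optimize.least_squares(
        residuals, [b0_0, k0], bounds=([0.0, 1e-8], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14
    )
    b0, koff = sol.x
    dof = max(t.size - 2, 1)
    rss = float(2.0 * sol.cost)
    ses = _covariance_se(sol.jac, rss, dof)
    return KineticResult(
        b0=float(b0), koff=float(koff), se_koff=ses[1], condition=condition,
        converged=bool(sol.success),
    )


def compare_dissociation(
    t_control, bound_control, t_test, bound_test,
    n_boot: int = 200, seed: int = 0, ci: float = 0.95,
) -> DissociationComparison:
    """Seeded residual-bootstrap ratio test on fitted koff (test / control).

    The two conditions are fitted independently; residuals (inflated by
    sqrt(n/(n-p)) to undo the degrees-of-freedom shrinkage of fitted
    residuals) are resampled with replacement around each fitted curve and
    both curves refit per bootstrap draw.  The CI is a t-interval on the
    log koff ratio using the bootstrap standard error, which keeps close to
    its nominal coverage at the short time courses typical of these
    protocols.  The kinetics are called altered when the CI excludes 1 -
    the operational definition of an off-rate modulator in paired
    dissociation designs.
    """
    from scipy import stats as _stats

    rng = np.random.default_rng(seed)
    fit_c = fit_dissociation(t_control, bound_control, "control")
    fit_t = fit_dissociation(t_test, bound_test, "test")
    ratio = fit_t.koff / fit_c.koff

    def boot_one(t, y, fit):
        t = np.asarray(t, dtype=float)
        pred = fit.b0 * np.exp(-fit.koff * t)
        resid = np.asarray(y, dtype=float) - pred
        resid = resid * np.sqrt(resid.size / max(resid.size - 2, 1))
        draws = np.empty(n_boot)
        for i in range(n_boot):
            y_star = pred + rng.choice(resid, size=resid.size, replace=True)
            draws[i] = fit_dissociation(t, y_star, fit.condition).koff
        return draws

    kc = boot_one(t_control, bound_control, fit_c)
    kt = boot_one(t_test, bound_test, fit_t)
    se_log = float(np.sqrt(np.var(np.log(kt), ddof=1) + np.var(np.log(kc), ddof=1)))
    df = max(len(np.atleast_1d(t_control)) + len(np.atleast_1d(t_test)) - 4, 1)
    tcrit = _stats.t.ppf(0.5 + ci / 2.0, df)
    lo = float(np.exp(np.log(ratio) - tcrit * se_log))
    hi = float(np.exp(np.log(ratio) + tcrit * se_log))
    return DissociationComparison(
        koff_ratio=float(ratio), ci_low=lo, ci_high=hi,
        kinetics_altered=bool(lo > 1.0 or hi < 1.0),
    )


def dpm_to_fmol_per_mg(dpm: float, specific_activity: float, protein_mg: float) -> float:
    """Convert counted dpm to fmol per mg protein.

    ``specific_activity`` is in Ci/mmol; 1 Ci = 2.22e12 dpm, so the
    radioligand yields specific_activity * 2.22 dpm per fmol.
    """
    if specific_activity <= 0:
        raise ValueError("specific activity must be positive (Ci/mmol)")
    if protein_mg <= 0:
        raise ValueError("protein amount must be positive (mg)")
    if dpm < 0:
        raise ValueError("dpm must be non-negative")
    dpm_per_fmol = specific_activity * DPM_PER_CI * 1e-12
    return dpm / dpm_per_fmol / protein_mg
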