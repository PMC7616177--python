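"""Four-parameter logistic (4PL / Hill) analysis of agonist concentration-response data.

The workhorse model of functional pharmacology screens:

    E(A) = bottom + (top - bottom) / (1 + 10^((log10 EC50 - log10 A) * hill))

fitted in log10-concentration space with pEC50 = -log10(EC50 in molar) as a
free parameter, which conditions the problem well for the 3+ decade
concentration designs typical of plate-based assays.  Also provides
normalization to a reference full agonist, potency summaries across
independent experiments, and a descending-logistic thermal-melt fit for
receptor thermostability (Tm = temperature at which 50% ligand binding is
retained).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "ConcentrationResponseCurve",
    "Curve4PLFit",
    "PotencySummary",
    "FlatDataError",
    "fit_4pl",
    "normalize_to_reference",
    "potency_summary",
    "fit_thermal_melt",
]

# hill slope bounds: physiological Hill coefficients rarely leave [0.3, 5];
# tighter than this and truncated curves produce pathological fits
HILL_BOUNDS = (0.3, 5.0)
# pEC50 may wander this many log units beyond the tested concentration range
PEC50_MARGIN = 2.0
# fitted EC50 above max(conc)/TOP_EXTRAPOLATION_FACTOR means the upper
# plateau was never approached; the fit is returned but flagged
TOP_EXTRAPOLATION_FACTOR = 3.0


class FlatDataError(ValueError):
    """Raised when responses carry no concentration dependence (no fit possible).

    Distinct from optimizer non-convergence: flat data is an input condition,
    not a numerical failure.
    """


@dataclass(frozen=True)
class ConcentrationResponseCurve:
    """One ligand x pathway dose-response dataset.

    Concentrations are molar and strictly positive; responses are raw assay
    units or percent of a reference maximum (``response_units``).
    """

    ligand_id: str
    pathway_id: str
    concentrations: np.ndarray
    responses: np.ndarray
    replicate_ids: tuple = ()
    response_units: str = "raw"  # "raw" | "percent_reference"

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if conc.ndim != 1 or conc.shape != resp.shape or conc.size < 1:
            raise ValueError("concentrations and responses must be equal-length 1-D arrays (n >= 1)")
        if not np.all(np.isfinite(conc)) or np.any(conc <= 0):
            raise ValueError("all concentrations must be finite and strictly positive (molar)")
        if not np.all(np.isfinite(resp)):
            raise ValueError("all responses must be finite")
        if self.response_units not in ("raw", "percent_reference"):
            raise ValueError(f"unknown response_units: {self.response_units!r}")

    @property
    def n_distinct_concentrations(self) -> int:
        return np.unique(self.concentrations).size


@dataclass(frozen=True)
class Curve4PLFit:
    """Fitted 4PL parameters. ``pEC50`` is -log10(EC50 in molar); Emax = top."""

    bottom: float
    top: float
    pEC50: float
    hill: float
    se_bottom: float = np.nan
    se_top: float = np.nan
    se_pEC50: float = np.nan
    se_hill: float = np.nan
    converged: bool = True
    residual_sd: float = np.nan
    n_points: int = 0
    flags: tuple = ()
    ligand_id: str = ""
    pathway_id: str = ""

    @property
    def ec50(self) -> float:
        """EC50 in molar."""
        return 10.0 ** (-self.pEC50)

    @property
    def emax(self) -> float:
        return self.top

    def predict(self, concentrations) -> np.ndarray:
        a = np.asarray(concentrations, dtype=float)
        return _model_4pl(np.log10(a), self.bottom, self.top, self.pEC50, self.hill)


@dataclass(frozen=True)
class PotencySummary:
    mean_pEC50: float
    sem_pEC50: float
    n_experiments: int
    mean_Emax: float
    sem_Emax: float
    flags: tuple = ()


def _model_4pl(log_a: np.ndarray, bottom: float, top: float, pec50: float, hill: float) -> np.ndarray:
    # E = bottom + (top-bottom) / (1 + 10^((logEC50 - logA)*hill)); logEC50 = -pEC50
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((-pec50 - log_a) * hill))


def fit_4pl(curve: ConcentrationResponseCurve, constraints: dict | None = None) -> Curve4PLFit:
    """Least-squares 4PL fit of a concentration-response curve.

    Parameters
    ----------
    curve
        Must span >= 4 distinct concentrations.  Replicate points are pooled
        and weighted equally.
    constraints
        Optional per-parameter ``(lo, hi)`` bounds keyed by ``bottom``,
        ``top``, ``pEC50``, ``hill`` overriding the defaults.

    Raises
    ------
    ValueError
        Fewer than 4 distinct concentrations.
    FlatDataError
        Responses carry no detectable concentration dependence.
    """
    if curve.n_distinct_concentrations < 4:
        raise ValueError(
            f"4PL fit requires >= 4 distinct concentrations, got {curve.n_distinct_concentrations}"
        )
    log_a = np.log10(curve.concentrations)
    y = curve.responses
    span = float(np.ptp(y))
    if span == 0.0:
        raise FlatDataError("responses are identical at every concentration; no fit possible")
    # flat-data guard: with replication, require concentration to explain
    # variance beyond replicate scatter (one-way ANOVA across concentrations)
    if _replicate_sd(curve) is not None:
        _, inv = np.unique(curve.concentrations, return_inverse=True)
        groups = [y[inv == i] for i in range(inv.max() + 1)]
        fstat = _anova(groups)
        if fstat is not None and fstat[1] > 0.01:
            raise FlatDataError(
                f"no concentration dependence beyond replicate noise (ANOVA p = {fstat[1]:.2g})"
            )

    lo, hi = _bounds(log_a, y, constraints)
    x0 = _initial_guess(log_a, y, lo, hi)

    def residuals(p):
        return _model_4pl(log_a, *p) - y

    sol = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    bottom, top, pec50, hill = sol.x
    dof = max(y.size - 4, 1)
    rss = float(2.0 * sol.cost)
    residual_sd = float(np.sqrt(rss / dof))
    ses = _covariance_se(sol.jac, rss, dof)
    flags = []
    converged = bool(sol.success)
    if not converged:
        flags.append("non-converged")
    if 10.0 ** (-pec50) > curve.concentrations.max() / TOP_EXTRAPOLATION_FACTOR:
        flags.append("top-extrapolated")
    return Curve4PLFit(
        bottom=float(bottom),
        top=float(top),
        pEC50=float(pec50),
        hill=float(hill),
        se_bottom=ses[0],
        se_top=ses[1],
        se_pEC50=ses[2],
        se_hill=ses[3],
        converged=converged,
        residual_sd=residual_sd,
        n_points=int(y.size),
        flags=tuple(flags),
        ligand_id=curve.ligand_id,
        pathway_id=curve.pathway_id,
    )


def _anova(groups) -> tuple | None:
    """One-way ANOVA (F, p) across concentration groups, or None if degenerate."""
    from scipy import stats

    if len(groups) < 2 or all(g.size < 2 for g in groups):
        return None
    try:
        f, p = stats.f_oneway(*groups)
    except ValueError:
        return None
    if not np.isfinite(f):
        return None
    return float(f), float(p)


def _replicate_sd(curve: ConcentrationResponseCurve) -> float | None:
    """Pooled within-concentration SD, or None if no replication."""
    conc, inv = np.unique(curve.concentrations, return_inverse=True)
    ss, n = 0.0, 0
    for i in range(conc.size):
        grp = curve.responses[inv == i]
        if grp.size > 1:
            ss += float(np.sum((grp - grp.mean()) ** 2))
            n += grp.size - 1
    if n == 0:
        return None
    return float(np.sqrt(ss / n))


def _bounds(log_a, y, constraints):
    defaults = {
        "bottom": (-np.inf, np.inf),
        "top": (-np.inf, np.inf),
        "pEC50": (-log_a.max() - PEC50_MARGIN, -log_a.min() + PEC50_MARGIN),
        "hill": HILL_BOUNDS,
    }
    if constraints:
        defaults.update(constraints)
    order = ("bottom", "top", "pEC50", "hill")
    lo = np.array([defaults[k][0] for k in order], dtype=float)
    hi = np.array([defaults[k][1] for k in order], dtype=float)
    return lo, hi


def _initial_guess(log_a, y, lo, hi):
    """Deterministic start: extremes for plateaus, half-range crossing for pEC50."""
    bottom0, top0 = float(y.min()), float(y.max())
    half = (bottom0 + top0) / 2.0
    order = np.argsort(log_a)
    crossing = log_a[order][np.argmin(np.abs(y[order] - half))]
    x0 = np.array([bottom0, top0, -crossing, 1.0])
    return np.clip(x0, lo + 1e-9, hi - 1e-9)


def _covariance_se(jac, rss, dof):
    """Standard errors from the local curvature (J'J) at the optimum."""
    try:
        jtj = jac.T @ jac
        cov = np.linalg.inv(jtj) * (rss / dof)
        diag = np.diag(cov)
        return tuple(float(np.sqrt(d)) if d >= 0 else np.nan for d in diag)
    except np.linalg.LinAlgError:
        return (np.nan,) * 4


def normalize_to_reference(
    curve: ConcentrationResponseCurve, reference_fit: Curve4PLFit
) -> ConcentrationResponseCurve:
    """Rescale responses so the reference fit's bottom -> 0% and top -> 100%."""
    span = reference_fit.top - reference_fit.bottom
    if span <= 0:
        raise ValueError("degenerate reference fit: top must exceed bottom")
    scaled = (curve.responses - reference_fit.bottom) / span * 100.0
    return replace(curve, responses=scaled, response_units="percent_reference")


def potency_summary(fits: list[Curve4PLFit]) -> PotencySummary:
    """Mean +/- SEM of pEC50 (averaged on the log scale) and Emax across experiments.

    Averaging pEC50 rather than EC50 makes the summary a geometric mean on the
    concentration scale, the standard convention for potency tables.
    """
    if not fits:
        raise ValueError("potency_summary requires at least one fit")
    if not all(f.converged for f in fits):
        raise ValueError("all fits must be converged")
    keys = {(f.ligand_id, f.pathway_id) for f in fits}
    if len(keys) > 1:
        raise ValueError(f"fits mix ligand/pathway combinations: {sorted(keys)}")
    p = np.array([f.pEC50 for f in fits])
    e = np.array([f.top for f in fits])
    n = len(fits)
    flags = ("n=1",) if n == 1 else ()
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return PotencySummary(
        mean_pEC50=float(p.mean()),
        sem_pEC50=sem(p),
        n_experiments=n,
        mean_Emax=float(e.mean()),
        sem_Emax=sem(e),
        flags=flags,
    )


def fit_thermal_melt(temperatures, fraction_bound) -> dict:
    """Fit a descending logistic in temperature; Tm is the 50%-binding midpoint.

    Returns a dict with ``tm`` (deg C), ``slope``, ``top``, ``bottom``,
    ``se_tm`` and ``converged``.  Requires >= 4 temperatures spanning the
    transition (both plateaus represented).
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fraction_bound, dtype=float)
    if t.size < 4:
        raise ValueError("thermal melt fit requires >= 4 temperatures")
    if np.ptp(f) < 0.2:
        raise ValueError("no melting transition within the measured temperature range")

    def model(temp, bottom, top, tm, slope):
        return bottom + (top - bottom) / (1.0 + np.exp((temp - tm) * slope))

    x0 = [float(f.min()), float(f.max()), float(t[np.argmin(np.abs(f - (f.min() + f.max()) / 2))]), 0.5]
    lo = [-0.5, 0.0, t.min() - 10.0, 0.01]
    hi = [0.5, 1.5, t.max() + 10.0, 10.0]
    sol = optimize.least_squares(
        lambda p: model(t, *p) - f, np.clip(x0, np.array(lo) + 1e-9, np.array(hi) - 1e-9),
        bounds=(lo, hi), xtol=1e-12, ftol=1e-12,
    )
    bottom, top, tm, slope = sol.x
    dof = max(t.size - 4, 1)
    rss = float(2.0 * sol.cost)
    ses = _covariance_se(sol.jac, rss, dof)
    return {
        "tm": float(tm),
        "slope": float(slope),
        "top": float(top),
        "bottom": float(bottom),
        "se_tm": ses[2],
        "converged": bool(sol.success),
    }
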