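"""Schild analysis of surmountable (competitive) antagonism.

A competitive antagonist at concentration [B] shifts an agonist curve
rightward by the Gaddum dose ratio DR = 1 + [B]/K_B without depressing its
maximum.  The classical Schild regression plots log10(DR - 1) against
log10[B]: simple competition gives a line of slope 1 whose abscissa
intercept is pA2 = -log10 K_B.  Both the free-slope pA2 and the
slope-constrained pK_B (slope fixed at 1) are reported, since a slope near
unity is itself the diagnostic of simple competition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dose_response import Curve4PLFit

__all__ = ["SchildResult", "dose_ratio", "schild_regression"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SchildResult:
    antagonist_concentrations: tuple  # molar, points used
    dose_ratios: tuple
    slope: float
    se_slope: float
    pA2: float
    pKB_constrained: float
    r_squared: float
    n_points: int
    excluded: tuple = ()  # ([B], DR) pairs dropped because DR <= 1


def dose_ratio(control_fit: Curve4PLFit, treated_fit: Curve4PLFit) -> float:
    """DR = EC50(treated) / EC50(control), on the molar scale."""
    if not (control_fit.converged and treated_fit.converged):
        raise ValueError("dose ratio requires converged control and treated fits")
    return treated_fit.ec50 / control_fit.ec50


def schild_regression(pairs: list[tuple[float, float]]) -> SchildResult:
    """OLS of log10(DR - 1) on log10[B].

    ``pairs`` is a list of ([B] in molar, DR).  Points with DR <= 1 carry no
    information about surmountable antagonism (noise at low [B] commonly
    yields DR ~ 1) and are excluded with a logged warning.

    Returns both the free-slope pA2 (the negative of the abscissa intercept)
    and pK_B from the slope-1 refit (mean of log(DR-1) - log[B]).
    """
    usable = [(b, dr) for b, dr in pairs if dr > 1.0]
    excluded = tuple((b, dr) for b, dr in pairs if dr <= 1.0)
    for b, dr in excluded:
        log.warning("Schild point excluded (DR <= 1): [B]=%.3g M, DR=%.3g", b, dr)
    if not usable:
        raise ValueError("no antagonism detected: all dose ratios <= 1")
    if len(usable) < 2:
        raise ValueError(f"Schild regression requires >= 2 points with DR > 1, got {len(usable)}")
    log_b = np.log10([b for b, _ in usable])
    log_dr1 = np.log10([dr - 1.0 for _, dr in usable])
    res = stats.linregress(log_b, log_dr1)
    if res.slope == 0:
        raise ValueError("Schild regression degenerate: zero slope")
    # x-intercept of the regression line is log10 of the [B] giving DR = 2;
    # pA2 is its negative log, i.e. +intercept/slope
    pa2 = res.intercept / res.slope
    # slope fixed at 1: log(DR-1) = log[B] + pK_B
    pkb = float(np.mean(log_dr1 - log_b))
    ss_tot = float(np.sum((log_dr1 - log_dr1.mean()) ** 2))
    r2 = float(res.rvalue ** 2) if ss_tot > 0 else 1.0
    return SchildResult(
        antagonist_concentrations=tuple(b for b, _ in usable),
        dose_ratios=tuple(dr for _, dr in usable),
        slope=float(res.slope),
        se_slope=float(res.stderr) if res.stderr is not None else np.nan,
        pA2=float(pa2),
        pKB_constrained=pkb,
        r_squared=r2,
        n_points=len(usable),
        excluded=excluded,
    )
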