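"""Translational exposure arithmetic: from plasma Cmax to unbound brain estimates.

Pure-function conversions linking in-vitro potency to in-vivo dosing:
mass <-> molar concentration, unbound (free) concentration via the plasma
free fraction fu, CSF:plasma scaling of a plasma Cmax to an unbound-brain
concentration range (CSF concentration as the standard surrogate for
unbound brain drug), Kp,uu (unbound brain : unbound plasma partition
coefficient), and the apparent therapeutic index as the fold-margin between
an adverse-effect exposure and an efficacious exposure.

Every derived quantity here is deterministic arithmetic - same inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_MOL_WEIGHT",
    "ExposureRecord",
    "mass_to_molar",
    "molar_to_mass",
    "unbound_concentration",
    "brain_exposure_range",
    "kpuu",
    "therapeutic_index",
]

# free-base molecular weight (g/mol) of the default compound, consistent
# with its ESI-MS (M+H)+ of 366; configurable per compound in all functions
DEFAULT_MOL_WEIGHT = 365.5


def mass_to_molar(conc_ng_ml: float, mol_weight: float = DEFAULT_MOL_WEIGHT) -> float:
    """ng/mL -> nM:  nM = (ng/mL) / (g/mol) * 1000."""
    if mol_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if conc_ng_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ng_ml / mol_weight * 1000.0


def molar_to_mass(conc_nM: float, mol_weight: float = DEFAULT_MOL_WEIGHT) -> float:
    """nM -> ng/mL; exact inverse of :func:`mass_to_molar`."""
    if mol_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if conc_nM < 0:
        raise ValueError("concentration must be non-negative")
    return conc_nM * mol_weight / 1000.0


def unbound_concentration(total: float, fu: float) -> float:
    """Unbound concentration Cu = total * fu; fu must lie in (0, 1.5]."""
    if not 0.0 < fu <= 1.5:
        raise ValueError(f"fu out of range (0, 1.5]: {fu}")
    if total < 0:
        raise ValueError("total concentration must be non-negative")
    return total * fu


def brain_exposure_range(
    cmax_plasma_ng_ml: float,
    ratios,
    mol_weight: float = DEFAULT_MOL_WEIGHT,
) -> tuple[int, int]:
    """Unbound-brain range (nM) implied by a plasma Cmax and CSF:plasma ratios.

    Converts the plasma Cmax to nM and scales by the minimum and maximum
    ratio.  Returns the endpoints rounded to the nearest nM (the reporting
    convention); use :func:`mass_to_molar` directly for exact values.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("at least one CSF:plasma ratio is required")
    if any(not 0.0 < r <= 1.5 for r in ratios):
        raise ValueError("CSF:plasma ratios must lie in (0, 1.5]")
    plasma_nM = mass_to_molar(cmax_plasma_ng_ml, mol_weight)
    low = plasma_nM * min(ratios)
    high = plasma_nM * max(ratios)
    return int(round(low)), int(round(high))


def kpuu(cu_brain: float, cu_plasma: float) -> float:
    """Kp,uu = unbound brain / unbound plasma concentration (dimensionless)."""
    if cu_plasma <= 0:
        raise ValueError("unbound plasma concentration must be positive")
    if cu_brain < 0:
        raise ValueError("unbound brain concentration must be non-negative")
    return cu_brain / cu_plasma


def therapeutic_index(
    adverse_exposure: float,
    efficacy_exposure: float,
    units: str = "ng/mL",
    efficacy_units: str | None = None,
) -> float:
    """Apparent therapeutic index: adverse / efficacious exposure (fold).

    Both exposures must be supplied in the same declared unit (total plasma
    by convention; pass unbound values for an unbound-basis margin).  The
    exact quotient is returned; display rounding is the caller's business.
    """
    if efficacy_units is not None and efficacy_units != units:
        raise ValueError(f"unit mismatch: adverse in {units!r}, efficacy in {efficacy_units!r}")
    if efficacy_exposure <= 0:
        raise ValueError("efficacy exposure must be positive")
    if adverse_exposure < 0:
        raise ValueError("adverse exposure must be non-negative")
    return adverse_exposure / efficacy_exposure


@dataclass(frozen=True)
class ExposureRecord:
    """One species/dose exposure with all derived quantities computed on construction.

    ``csf_plasma_ratios`` maps a time label to a CSF:plasma concentration
    ratio; the derived unbound-brain range spans the min and max ratio.
    """

    species: str
    dose_mgkg: float
    route: str
    cmax_plasma_ng_ml: float
    fu_plasma: float
    mol_weight: float = DEFAULT_MOL_WEIGHT
    csf_plasma_ratios: dict = field(default_factory=dict)
    notes: str = ""
    plasma_nM: float = field(init=False)
    cu_plasma_nM: float = field(init=False)
    cu_brain_range_nM: tuple = field(init=False)

    def __post_init__(self):
        plasma_nM = mass_to_molar(self.cmax_plasma_ng_ml, self.mol_weight)
        cu_plasma = unbound_concentration(plasma_nM, self.fu_plasma)
        if self.csf_plasma_ratios:
            rng = brain_exposure_range(
                self.cmax_plasma_ng_ml, self.csf_plasma_ratios.values(), self.mol_weight
            )
        else:
            rng = (np.nan, np.nan)
        object.__setattr__(self, "plasma_nM", plasma_nM)
        object.__setattr__(self, "cu_plasma_nM", cu_plasma)
        object.__setattr__(self, "cu_brain_range_nM", rng)
        # dimensional self-audit
        if self.fu_plasma <= 1.0 and cu_plasma > plasma_nM * (1 + 1e-12):
            raise AssertionError("unbound plasma exceeds total plasma with fu <= 1")
        if self.csf_plasma_ratios and max(self.csf_plasma_ratios.values()) <= 1.0:
            if rng[1] > round(plasma_nM) + 1:
                raise AssertionError("brain range exceeds plasma molar with ratios <= 1")

    @property
    def kpuu_range(self) -> tuple:
        """Kp,uu implied by the ratio-scaled brain range (brain CSF surrogate / Cu plasma)."""
        if not self.csf_plasma_ratios:
            return (np.nan, np.nan)
        lo, hi = self.cu_brain_range_nM
        return kpuu(lo, self.cu_plasma_nM), kpuu(hi, self.cu_plasma_nM)
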