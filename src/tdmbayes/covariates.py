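"""Covariate engine: lean body weight, creatinine clearance, and the
mapping from prior parameters plus patient covariates to structural
clearance and volume.

All structural computation is done in L, h, mg, mg/L. Creatinine clearance
is carried both in mL/min (the clinical unit) and L/h (the unit the
clearance equations consume); the conversion factor is exactly 0.06.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .params import IndividualParams
from .priors import get_default_prior

__all__ = [
    "ML_MIN_TO_L_H",
    "PatientCovariates",
    "DerivedPK",
    "InvalidAnthropometryError",
    "lean_body_weight",
    "creatinine_clearance",
    "derive_structural_params",
]

ML_MIN_TO_L_H = 0.06

# CLnr is stored per kg lean body weight in drug-specific units; these
# factors convert the CLnr*LBW product to L/h.
_CLNR_TO_L_H = {
    "amikacin": 0.06,      # mL/min/kg
    "vancomycin": 0.06,    # mL/min/kg
    "theophylline": 0.001, # mL/h/kg
}


class InvalidAnthropometryError(ValueError):
    """Lean-body-weight formula produced a non-positive result."""


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics used by the covariate equations.

    weight: total body weight (kg); height: cm; age: years;
    sex: 'male' or 'female'; scr: serum creatinine (mg/dL).
    """

    weight: float
    height: float
    age: float
    sex: str
    scr: float

    def __post_init__(self):
        if self.weight <= 0 or self.height <= 0 or self.scr <= 0:
            raise ValueError("weight, height, scr must be positive")
        if not 0 <= self.age < 140:
            raise ValueError("age must be in [0, 140)")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")


@dataclass(frozen=True)
class DerivedPK:
    """Structural quantities derived from covariates and parameters."""

    lbw: float
    crcl_ml_min: float
    crcl_l_h: float
    cl: float | None  # L/h; None for phenytoin (concentration-dependent)
    v: float          # L


def lean_body_weight(cov: PatientCovariates) -> float:
    """Sex-specific lean body weight (kg) from total weight and height.

    male:   1.10*W - 128*(W/H)^2
    female: 1.07*W - 148*(W/H)^2      (W in kg, H in cm)
    """
    r2 = (cov.weight / cov.height) ** 2
    if cov.sex == "male":
        lbw = 1.10 * cov.weight - 128.0 * r2
    else:
        lbw = 1.07 * cov.weight - 148.0 * r2
    if lbw <= 0:
        raise InvalidAnthropometryError(
            f"lean body weight non-positive ({lbw:.2f} kg) for "
            f"weight={cov.weight}, height={cov.height}"
        )
    return lbw


def creatinine_clearance(cov: PatientCovariates, lbw: float | None = None) -> float:
    """Cockcroft-Gault creatinine clearance (mL/min) using lean body weight.

    (140 - age) * LBW / (72 * sCr), multiplied by 0.85 for females.
    """
    if cov.scr <= 0:
        raise ValueError("serum creatinine must be positive")
    if cov.age >= 140:
        raise ValueError("age must be < 140 for Cockcroft-Gault")
    if lbw is None:
        lbw = lean_body_weight(cov)
    crcl = (140.0 - cov.age) * lbw / (72.0 * cov.scr)
    if cov.sex == "female":
        crcl *= 0.85
    return crcl


def phenytoin_volume(vnr: float, tbw: float) -> float:
    """Phenytoin volume of distribution: allometric V = Vnr*70*(TBW/70)^0.6.

    Equals Vnr*TBW at 70 kg; isolated here so the allometry is swappable.
    """
    return vnr * 70.0 * (tbw / 70.0) ** 0.6


def derive_structural_params(drug: str, params: IndividualParams | Mapping[str, float],
                             cov: PatientCovariates) -> DerivedPK:
    """Map prior parameters + covariates to structural CL (L/h) and V (L).

    Linear drugs: CL = CLslope*CrCl(L/h) + CLnr*LBW*u and V = Vnr*LBW, with
    u converting CLnr's registry unit to L/h/kg. Phenytoin: returns V only
    (its concentration-dependent clearance lives in the forward model).
    """
    values = params.values if isinstance(params, IndividualParams) else params
    prior = get_default_prior(drug)
    lbw = lean_body_weight(cov)
    crcl = creatinine_clearance(cov, lbw=lbw)
    crcl_lh = crcl * ML_MIN_TO_L_H
    if prior.model_id == "mm_zero":
        v = phenytoin_volume(values["Vnr"], cov.weight)
        return DerivedPK(lbw=lbw, crcl_ml_min=crcl, crcl_l_h=crcl_lh, cl=None, v=v)
    u = _CLNR_TO_L_H[prior.drug]
    cl = values["CLslope"] * crcl_lh + values["CLnr"] * lbw * u if "CLslope" in values \
        else values["CLnr"] * lbw * u
    v = values["Vnr"] * lbw
    return DerivedPK(lbw=lbw, crcl_ml_min=crcl, crcl_l_h=crcl_lh, cl=cl, v=v)
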