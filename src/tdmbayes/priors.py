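"""Population PK prior registry for the four supported drugs.

The registry holds, for each drug, the typical values (lognormal medians),
coefficients of variation, truncation bounds used when simulating virtual
patients, fixed constants, and the assay error model

    sigma = cv_assay * C_pred + s_assay        (mg/L)

Between-subject variability is lognormal: ``P = mean * exp(eta)`` with
``eta ~ N(0, omega^2)`` and ``omega^2 = ln(CV^2 + 1)``, so ``mean`` is the
median of the natural-scale distribution, not its arithmetic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "DRUGS",
    "ParameterPrior",
    "ErrorModel",
    "PriorSpec",
    "UnsupportedDrugError",
    "get_default_prior",
    "cv_to_omega",
]

DRUGS = ("amikacin", "vancomycin", "theophylline", "phenytoin")


class UnsupportedDrugError(ValueError):
    """Raised for drug names outside the supported set."""

    def __init__(self, drug: str):
        super().__init__(
            f"unsupported drug {drug!r}; supported drugs are: {', '.join(DRUGS)}"
        )
        self.drug = drug


def cv_to_omega(cv: float) -> float:
    """Convert a coefficient of variation to the log-scale SD omega.

    omega = sqrt(ln(cv^2 + 1)); 0 for fixed parameters (cv = 0).
    """
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    return math.sqrt(math.log(cv * cv + 1.0))


@dataclass(frozen=True)
class ParameterPrior:
    """Prior for one PK parameter.

    ``mean`` is the typical value (lognormal median) in the unit given by
    ``unit``; ``cv`` the between-subject coefficient of variation (0 for
    fixed constants); ``lower``/``upper`` the truncation bounds applied when
    sampling virtual patients (None for fixed parameters).
    """

    name: str
    mean: float
    cv: float = 0.0
    lower: float | None = None
    upper: float | None = None
    unit: str = ""

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError(f"{self.name}: mean must be positive")
        if self.cv < 0:
            raise ValueError(f"{self.name}: cv must be non-negative")
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.mean <= self.upper):
                raise ValueError(f"{self.name}: mean outside [lower, upper]")

    @property
    def fixed(self) -> bool:
        return self.cv == 0.0

    @property
    def omega(self) -> float:
        return cv_to_omega(self.cv)


@dataclass(frozen=True)
class ErrorModel:
    """Heteroscedastic assay error: sigma = cv_assay * C_pred + s_assay."""

    cv_assay: float
    s_assay: float

    def __post_init__(self):
        if self.cv_assay <= 0 or self.s_assay <= 0:
            raise ValueError("cv_assay and s_assay must be positive")

    def sigma(self, conc):
        return self.cv_assay * conc + self.s_assay


@dataclass(frozen=True)
class PriorSpec:
    """Complete prior specification for one drug."""

    drug: str
    model_id: str
    parameters: tuple[ParameterPrior, ...]
    error: ErrorModel

    def __getitem__(self, name: str) -> ParameterPrior:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def estimated(self) -> tuple[ParameterPrior, ...]:
        """Parameters with between-subject variability, in registry order."""
        return tuple(p for p in self.parameters if not p.fixed)

    @property
    def estimated_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.estimated)

    @property
    def omegas(self):
        return tuple(p.omega for p in self.estimated)

    def to_dict(self) -> dict:
        """Human-readable mapping mirroring the registry columns."""
        return {
            "drug": self.drug,
            "model": self.model_id,
            "parameters": [
                {
                    "name": p.name,
                    "mean": p.mean,
                    "cv": p.cv,
                    "lower": p.lower,
                    "upper": p.upper,
                    "unit": p.unit,
                    "fixed": p.fixed,
                }
                for p in self.parameters
            ],
            "error": {"cv_assay": self.error.cv_assay, "s_assay": self.error.s_assay},
        }


def _P(name, mean, cv=0.0, lower=None, upper=None, unit=""):
    return ParameterPrior(name, mean, cv, lower, upper, unit)


# Registry. CLnr units differ between drugs (mL/min/kg for the IV drugs,
# mL/h/kg for theophylline); Vmax is a total maximum elimination rate in
# mg/day. The covariate engine owns the conversions to L, h, mg.
_REGISTRY: dict[str, PriorSpec] = {
    "amikacin": PriorSpec(
        drug="amikacin",
        model_id="1cmt_iv",
        parameters=(
            _P("CLslope", 0.815, 0.4, 0.3, 1.7),
            _P("CLnr", 0.0417, 0.25, 0.0001, 0.17, unit="mL/min/kg"),
            _P("Vnr", 0.27, 0.3, 0.15, 0.65, unit="L/kg"),
        ),
        error=ErrorModel(cv_assay=0.15, s_assay=0.25),
    ),
    "vancomycin": PriorSpec(
        drug="vancomycin",
        model_id="2cmt_iv",
        parameters=(
            _P("CLslope", 0.75, 0.33, 0.3, 1.7),
            _P("CLnr", 0.05, 0.2, 0.01, 0.2, unit="mL/min/kg"),
            _P("Vnr", 0.21, 0.2, 0.08, 0.4, unit="L/kg"),
            _P("k12", 1.12, 0.25, 0.6, 1.6, unit="1/h"),
            _P("k21", 0.48, 0.25, 0.2, 1.0, unit="1/h"),
        ),
        error=ErrorModel(cv_assay=0.15, s_assay=0.25),
    ),
    "theophylline": PriorSpec(
        drug="theophylline",
        model_id="1cmt_oral1",
        parameters=(
            _P("CLnr", 40.0, 0.5, 15.0, 90.0, unit="mL/h/kg"),
            _P("Vnr", 0.5, 0.2, 0.35, 0.65, unit="L/kg"),
            _P("ka", 0.27, unit="1/h"),
            _P("F", 1.0),
        ),
        error=ErrorModel(cv_assay=0.15, s_assay=0.25),
    ),
    "phenytoin": PriorSpec(
        drug="phenytoin",
        model_id="mm_zero",
        parameters=(
            _P("Vmax", 500.0, 0.3, 250.0, 2000.0, unit="mg/d"),
            _P("km", 5.0, 0.5, 2.0, 9.0, unit="mg/L"),
            _P("Vnr", 0.8, 0.2, 0.3, 1.4, unit="L/kg"),
            _P("CLslope", 0.01),
            _P("F", 0.92),
        ),
        error=ErrorModel(cv_assay=0.1, s_assay=1.0),
    ),
}


def get_default_prior(drug: str) -> PriorSpec:
    """Return the built-in prior specification for ``drug`` (case-insensitive)."""
    key = str(drug).strip().lower()
    if key not in _REGISTRY:
        raise UnsupportedDrugError(drug)
    return _REGISTRY[key]
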