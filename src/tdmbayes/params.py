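"""Individual PK parameter vectors on natural and log scales."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .priors import PriorSpec

__all__ = ["IndividualParams"]


@dataclass(frozen=True)
class IndividualParams:
    """Drug-specific parameter vector.

    ``values`` holds natural-scale parameters keyed by symbol; ``eta`` holds
    the log-scale deviations of the estimated (non-fixed) parameters, so that
    ``values[k] == prior_mean_k * exp(eta[k])`` whenever ``k in eta``.
    """

    drug: str
    values: Mapping[str, float]
    eta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.values.items():
            if not v > 0:
                raise ValueError(f"{self.drug}: parameter {k} must be positive, got {v}")

    @classmethod
    def from_prior(cls, prior: PriorSpec, eta: Mapping[str, float] | None = None
                   ) -> "IndividualParams":
        """Build a parameter vector from a prior and log-scale deviations.

        Missing eta entries default to 0 (the typical value); fixed parameters
        are copied as constants.
        """
        eta = dict(eta or {})
        unknown = set(eta) - set(p.name for p in prior.estimated)
        if unknown:
            raise ValueError(f"eta given for non-estimated parameters: {sorted(unknown)}")
        values = {}
        out_eta = {}
        for p in prior.parameters:
            if p.fixed:
                values[p.name] = p.mean
            else:
                e = eta.get(p.name, 0.0)
                values[p.name] = p.mean * math.exp(e)
                out_eta[p.name] = e
        return cls(prior.drug, values, out_eta)

    def __getitem__(self, name: str) -> float:
        return self.values[name]
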