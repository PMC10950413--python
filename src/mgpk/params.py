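"""Population PK parameters and covariate individualization for IV magnesium sulfate.

The central object is :class:`PKParameters`, the macro-constant parameterisation
of a two-compartment disposition model (clearance ``CL``, central volume ``V1``,
intercompartmental clearance ``Q``, peripheral volume ``V2``) together with two
magnesium-specific constants: the endogenous pre-treatment serum concentration
(``baseline``, mmol/L) and the conversion from labelled gram doses of the
sulfate salt to millimoles of elemental magnesium (``dose_to_amount``, mmol/g).

Typical (population) parameters are individualized to a subject via a
:class:`CovariateModel`: multiplicative power or linear functions of body
weight (kg) and serum creatinine (µmol/L), anchored at reference covariate
values where they evaluate to exactly 1.

The typical values shipped in :func:`default_parameters` are a documented
placeholder — transcribe the published population PK estimates into a config
file before any clinical-mimicking run.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "MGSO4_HEPTAHYDRATE_MMOL_PER_G",
    "PKParameters",
    "CovariateEffect",
    "CovariateModel",
    "individualize",
    "default_parameters",
    "default_covariate_model",
]

#: mmol elemental Mg per gram of labelled MgSO4·7H2O dose (MW 246.47 g/mol).
MGSO4_HEPTAHYDRATE_MMOL_PER_G = 4.06


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment disposition parameters for one subject.

    Parameters
    ----------
    CL : float
        Elimination clearance from the central compartment (L/h).
    V1 : float
        Central (sampled) volume of distribution (L).
    Q : float
        Intercompartmental clearance (L/h).
    V2 : float
        Peripheral volume of distribution (L).
    baseline : float
        Endogenous serum magnesium concentration (mmol/L), treated as an
        additive constant (no turnover of the endogenous pool).
    dose_to_amount : float
        mmol elemental Mg per gram of labelled dose.
    """

    CL: float
    V1: float
    Q: float
    V2: float
    baseline: float = 0.74
    dose_to_amount: float = MGSO4_HEPTAHYDRATE_MMOL_PER_G

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V1 > 0 and self.V2 > 0):
            raise ValueError("CL, V1 and V2 must be strictly positive")
        if self.Q < 0:
            raise ValueError("Q must be non-negative")
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if not self.dose_to_amount > 0:
            raise ValueError("dose_to_amount must be strictly positive")

    # micro rate constants (1/h)
    @property
    def k10(self) -> float:
        return self.CL / self.V1

    @property
    def k12(self) -> float:
        return self.Q / self.V1

    @property
    def k21(self) -> float:
        return self.Q / self.V2

    def to_dict(self) -> dict:
        return {
            "CL": self.CL,
            "V1": self.V1,
            "Q": self.Q,
            "V2": self.V2,
            "baseline": self.baseline,
            "dose_to_amount": self.dose_to_amount,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PKParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate function on one PK parameter.

    ``power``:  multiplier = (x / reference) ** value
    ``linear``: multiplier = 1 + value * (x - reference)

    Either form evaluates to exactly 1 at the reference covariate value.
    """

    parameter: Literal["CL", "V1", "Q", "V2"]
    covariate: Literal["weight", "creatinine"]
    form: Literal["power", "linear"]
    value: float

    def multiplier(self, x: float, reference: float) -> float:
        if self.form == "power":
            return (x / reference) ** self.value
        if self.form == "linear":
            return 1.0 + self.value * (x - reference)
        raise ValueError(f"unknown covariate form {self.form!r}")


@dataclass(frozen=True)
class CovariateModel:
    """Reference covariates plus the per-parameter effects applied around them."""

    reference_weight: float = 70.0
    reference_creatinine: float = 60.0
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        if not (self.reference_weight > 0 and self.reference_creatinine > 0):
            raise ValueError("reference covariates must be positive")

    def multipliers(self, weight: float, creatinine: float) -> dict[str, float]:
        refs = {"weight": self.reference_weight, "creatinine": self.reference_creatinine}
        cov = {"weight": weight, "creatinine": creatinine}
        mult = {"CL": 1.0, "V1": 1.0, "Q": 1.0, "V2": 1.0}
        for eff in self.effects:
            mult[eff.parameter] *= eff.multiplier(cov[eff.covariate], refs[eff.covariate])
        return mult

    def to_dict(self) -> dict:
        return {
            "reference_weight": self.reference_weight,
            "reference_creatinine": self.reference_creatinine,
            "effects": [
                {"parameter": e.parameter, "covariate": e.covariate, "form": e.form, "value": e.value}
                for e in self.effects
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateModel":
        return cls(
            reference_weight=float(d.get("reference_weight", 70.0)),
            reference_creatinine=float(d.get("reference_creatinine", 60.0)),
            effects=tuple(
                CovariateEffect(
                    parameter=e["parameter"],
                    covariate=e["covariate"],
                    form=e["form"],
                    value=float(e["value"]),
                )
                for e in d.get("effects", [])
            ),
        )


def individualize(
    typical: PKParameters,
    covmodel: CovariateModel,
    weight: float,
    creatinine: float,
) -> PKParameters:
    """Scale typical PK parameters to one subject's weight and creatinine.

    At the reference covariates the typical values are returned unchanged.
    """
    if not (weight > 0 and creatinine > 0):
        raise ValueError("weight and creatinine must be strictly positive")
    mult = covmodel.multipliers(weight, creatinine)
    for p, m in mult.items():
        if m <= 0:
            raise ValueError(f"covariate model yields non-positive multiplier for {p}")
    return replace(
        typical,
        CL=typical.CL * mult["CL"],
        V1=typical.V1 * mult["V1"],
        Q=typical.Q * mult["Q"],
        V2=typical.V2 * mult["V2"],
    )


def default_parameters() -> PKParameters:
    """Placeholder typical values — transcribe the published population PK
    estimates before any clinical-mimicking run."""
    return PKParameters(CL=4.0, V1=20.0, Q=2.0, V2=30.0)


def default_covariate_model() -> CovariateModel:
    """Placeholder covariate model: allometric body weight on CL/Q (exponent
    0.75) and volumes (exponent 1), inverse serum creatinine on CL.

    Renally eliminated magnesium: higher creatinine ⇒ lower glomerular
    filtration ⇒ lower clearance; heavier subjects carry larger distribution
    volumes and higher absolute clearance.
    """
    return CovariateModel(
        reference_weight=70.0,
        reference_creatinine=60.0,
        effects=(
            CovariateEffect("CL", "weight", "power", 0.75),
            CovariateEffect("CL", "creatinine", "power", -1.0),
            CovariateEffect("Q", "weight", "power", 0.75),
            CovariateEffect("V1", "weight", "power", 1.0),
            CovariateEffect("V2", "weight", "power", 1.0),
        ),
    )
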