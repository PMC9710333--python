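"""Kidney-function equations, their inversions, and body-surface-area scaling.

Implements the creatinine-based GFR estimators used for staging and chronic
disease assessment in adults:

* 4-parameter MDRD study equation (coefficient 186 for non-IDMS-traceable
  creatinine assays, 175 behind the ``idms_traceable`` flag), with the race
  coefficient removed by default,
* CKD-EPI 2009 (no race adjustment by default),
* the full-age-spectrum (FAS) equation,
* Cockcroft-Gault creatinine clearance (mL/min, not BSA-normalised),
* Du Bois body surface area.

Because patients presenting acutely rarely have a documented pre-illness
creatinine, each invertible equation can be run backwards: given an assumed
"healthy" GFR (conventionally 100 or 75 mL/min/1.73 m²) the equation is
solved for the serum creatinine that would produce it, yielding an estimated
baseline. MDRD and FAS invert in closed form; CKD-EPI is inverted by
bracketed root finding.

All creatinine values are mg/dL; all normalised GFRs are mL/min/1.73 m².
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .records import FEMALE, MALE, DomainError, PersonParams

MDRD4 = "MDRD4"
CKDEPI2009 = "CKDEPI2009"
FAS = "FAS"
COCKCROFT_GAULT = "COCKCROFT_GAULT"

EQUATION_NAMES = (MDRD4, CKDEPI2009, FAS, COCKCROFT_GAULT)

#: default equation constants; override via ``load_constants`` for audits
DEFAULT_CONSTANTS = {
    "mdrd_coefficient_non_idms": 186.0,
    "mdrd_coefficient_idms": 175.0,
    "mdrd_scr_exponent": -1.154,
    "mdrd_age_exponent": -0.203,
    "mdrd_female_factor": 0.742,
    "mdrd_race_factor": 1.212,
    "ckdepi_kappa_female": 0.7,
    "ckdepi_kappa_male": 0.9,
    "ckdepi_alpha_female": -0.329,
    "ckdepi_alpha_male": -0.411,
    "ckdepi_scr_exponent": -1.209,
    "ckdepi_age_base": 0.993,
    "ckdepi_female_factor": 1.018,
    "ckdepi_race_factor": 1.159,
    "fas_q_female": 0.70,
    "fas_q_male": 0.90,
    "fas_numerator": 107.3,
    "fas_age_base": 0.988,
    "cg_female_factor": 0.85,
    "bsa_coefficient": 0.007184,
    "bsa_weight_exponent": 0.425,
    "bsa_height_exponent": 0.725,
    "default_assumed_gfr": 100.0,
    "inversion_bracket_mgdl": (0.05, 25.0),
}


def load_constants(path) -> dict:
    """Read a YAML/JSON mapping of constant overrides merged over defaults."""
    import yaml

    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    unknown = set(overrides) - set(DEFAULT_CONSTANTS)
    if unknown:
        raise KeyError(f"unknown equation constants: {sorted(unknown)}")
    merged = dict(DEFAULT_CONSTANTS)
    merged.update(overrides)
    return merged


class InversionError(ArithmeticError):
    """No creatinine root found for the requested GFR within the bracket."""


@dataclass(frozen=True)
class EquationSpec:
    """Which eGFR equation, with which variant flags.

    ``race_adjust`` defaults to False (the race coefficient is excluded);
    ``idms_traceable`` defaults to False, selecting the MDRD-186 coefficient
    appropriate for non-IDMS-traceable assays.
    """

    name: str
    idms_traceable: bool = False
    race_adjust: bool = False
    bsa_normalised: bool = False

    def __post_init__(self):
        if self.name not in EQUATION_NAMES:
            raise DomainError(f"unknown equation {self.name!r}; expected one of {EQUATION_NAMES}")


@dataclass(frozen=True)
class GFRResult:
    """An estimated GFR (mL/min/1.73 m², or mL/min for Cockcroft-Gault)."""

    value: float
    equation: EquationSpec

    def __post_init__(self):
        if not (self.value > 0 and self.value < float("inf")):
            raise DomainError(f"GFR must be positive and finite, got {self.value}")


@dataclass(frozen=True)
class CombinedGFRResult(GFRResult):
    """Arithmetic mean of MDRD-4 and CKD-EPI estimates, with both components."""

    mdrd: float = 0.0
    ckdepi: float = 0.0


def _check_scr(scr: float) -> None:
    if scr is None or not scr > 0:
        raise DomainError(f"scr must be strictly positive, got {scr}")


def egfr_mdrd4(scr: float, person: PersonParams, spec: Optional[EquationSpec] = None,
               constants: dict = DEFAULT_CONSTANTS) -> GFRResult:
    """4-parameter MDRD study equation (mL/min/1.73 m²)."""
    spec = spec or EquationSpec(MDRD4)
    if spec.name != MDRD4:
        raise DomainError(f"spec.name must be {MDRD4}, got {spec.name}")
    _check_scr(scr)
    c = constants["mdrd_coefficient_idms"] if spec.idms_traceable else constants["mdrd_coefficient_non_idms"]
    v = c * scr ** constants["mdrd_scr_exponent"] * person.age ** constants["mdrd_age_exponent"]
    if person.sex == FEMALE:
        v *= constants["mdrd_female_factor"]
    if spec.race_adjust:
        v *= constants["mdrd_race_factor"]
    return GFRResult(v, spec)


def egfr_ckdepi2009(scr: float, person: PersonParams, spec: Optional[EquationSpec] = None,
                    constants: dict = DEFAULT_CONSTANTS) -> GFRResult:
    """CKD-EPI 2009 creatinine equation (mL/min/1.73 m²)."""
    spec = spec or EquationSpec(CKDEPI2009)
    if spec.name != CKDEPI2009:
        raise DomainError(f"spec.name must be {CKDEPI2009}, got {spec.name}")
    _check_scr(scr)
    female = person.sex == FEMALE
    kappa = constants["ckdepi_kappa_female"] if female else constants["ckdepi_kappa_male"]
    alpha = constants["ckdepi_alpha_female"] if female else constants["ckdepi_alpha_male"]
    r = scr / kappa
    v = (141.0
         * min(r, 1.0) ** alpha
         * max(r, 1.0) ** constants["ckdepi_scr_exponent"]
         * constants["ckdepi_age_base"] ** person.age)
    if female:
        v *= constants["ckdepi_female_factor"]
    if spec.race_adjust:
        v *= constants["ckdepi_race_factor"]
    return GFRResult(v, spec)


def _fas_age_factor(age: float, constants: dict = DEFAULT_CONSTANTS) -> float:
    return constants["fas_age_base"] ** (age - 40.0) if age > 40.0 else 1.0


def egfr_fas(scr: float, person: PersonParams,
             constants: dict = DEFAULT_CONSTANTS) -> GFRResult:
    """Full-age-spectrum equation for adults (mL/min/1.73 m²)."""
    _check_scr(scr)
    if person.age < 18:
        raise DomainError(f"FAS implemented for adults (age >= 18), got {person.age}")
    q = constants["fas_q_female"] if person.sex == FEMALE else constants["fas_q_male"]
    v = constants["fas_numerator"] / (scr / q) * _fas_age_factor(person.age, constants)
    return GFRResult(v, EquationSpec(FAS))


def crcl_cockcroft_gault(scr: float, person: PersonParams, spec: Optional[EquationSpec] = None,
                         constants: dict = DEFAULT_CONSTANTS) -> GFRResult:
    """Cockcroft-Gault creatinine clearance (mL/min; BSA-normalised on request)."""
    spec = spec or EquationSpec(COCKCROFT_GAULT)
    _check_scr(scr)
    if person.age >= 140:
        raise DomainError(f"Cockcroft-Gault undefined for age >= 140, got {person.age}")
    if person.weight is None:
        raise DomainError("Cockcroft-Gault requires body weight (kg); none provided")
    v = ((140.0 - person.age) * person.weight) / (72.0 * scr)
    if person.sex == FEMALE:
        v *= constants["cg_female_factor"]
    if spec.bsa_normalised:
        if person.height is None:
            raise DomainError("BSA normalisation requires height (cm)")
        v *= 1.73 / bsa_dubois(person.weight, person.height, constants)
    return GFRResult(v, spec)


def bsa_dubois(weight: float, height: float, constants: dict = DEFAULT_CONSTANTS) -> float:
    """Du Bois body surface area (m²) from weight (kg) and height (cm)."""
    if not (weight and weight > 0) or not (height and height > 0):
        raise DomainError(f"weight and height must be strictly positive, got {weight}, {height}")
    return (constants["bsa_coefficient"]
            * weight ** constants["bsa_weight_exponent"]
            * height ** constants["bsa_height_exponent"])


def backcalc_creatinine(assumed_gfr: float, person: PersonParams, spec: EquationSpec,
                        constants: dict = DEFAULT_CONSTANTS) -> float:
    """Serum creatinine (mg/dL) at which the forward equation yields ``assumed_gfr``.

    Closed-form inversion for MDRD4 and FAS; bracketed root finding for
    CKD-EPI 2009. The forward equation evaluated at the returned value agrees
    with ``assumed_gfr`` to within 1e-6.
    """
    if not assumed_gfr > 0:
        raise DomainError(f"assumed_gfr must be strictly positive, got {assumed_gfr}")
    if spec.name == MDRD4:
        c = constants["mdrd_coefficient_idms"] if spec.idms_traceable else constants["mdrd_coefficient_non_idms"]
        denom = c * person.age ** constants["mdrd_age_exponent"]
        if person.sex == FEMALE:
            denom *= constants["mdrd_female_factor"]
        if spec.race_adjust:
            denom *= constants["mdrd_race_factor"]
        return (assumed_gfr / denom) ** (1.0 / constants["mdrd_scr_exponent"])
    if spec.name == FAS:
        q = constants["fas_q_female"] if person.sex == FEMALE else constants["fas_q_male"]
        return q * constants["fas_numerator"] * _fas_age_factor(person.age, constants) / assumed_gfr
    if spec.name == CKDEPI2009:
        lo, hi = constants["inversion_bracket_mgdl"]

        def f(scr):
            return egfr_ckdepi2009(scr, person, spec, constants).value - assumed_gfr

        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise InversionError(
                f"no creatinine in [{lo}, {hi}] mg/dL yields GFR {assumed_gfr}; "
                f"f({lo})={flo:.3g}, f({hi})={fhi:.3g}"
            )
        return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    raise DomainError(f"equation {spec.name} is not invertible here")


def combined_egfr(scr: float, person: PersonParams,
                  constants: dict = DEFAULT_CONSTANTS) -> CombinedGFRResult:
    """Mean of MDRD-4 (non-IDMS, no race) and CKD-EPI 2009 (no race) estimates.

    The chronic-disease decision value is the arithmetic mean; both components
    are retained so callers can apply either equation alone.
    """
    m = egfr_mdrd4(scr, person, constants=constants).value
    c = egfr_ckdepi2009(scr, person, constants=constants).value
    spec = EquationSpec(MDRD4)  # tag: combined result, components carried alongside
    return CombinedGFRResult(value=0.5 * (m + c), equation=spec, mdrd=m, ckdepi=c)
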