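"""Estimated fetal weight (EFW) from ultrasound biometry.

Implements the regression formulas used by third-trimester growth screening:
the Hadlock log10-linear family (four-parameter BPD/HC/AC/FL version and the
three-parameter HC/AC/FL version) and the Stirnemann HC/AC formula used by the
INTERGROWTH-21st project. Coefficients live in versioned JSON parameter files
bundled under ``epwscreen/data/formulas`` and are transcribed from the source
publications named in each file's ``citation`` field.

Measurements enter the public API in millimetres; each formula declares its
own working units and the conversion happens internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

from .errors import (
    FormulaNotFoundError,
    FormulaRegistrationError,
    IncompleteBiometryError,
    ParameterError,
    ValidationError,
)

MEASUREMENTS = ("bpd", "hc", "ac", "fl")

#: supported functional forms
_FORMS = ("log10_linear", "stirnemann_hc_ac")


@dataclass(frozen=True)
class BiometrySet:
    """Ultrasound biometry at one scan, millimetres. Any subset may be present."""

    bpd_mm: float | None = None
    hc_mm: float | None = None
    ac_mm: float | None = None
    fl_mm: float | None = None
    ga_scan_days: int | None = None

    def __post_init__(self) -> None:
        for name in MEASUREMENTS:
            v = getattr(self, f"{name}_mm")
            if v is not None and not v > 0:
                raise ValidationError(f"{name}_mm must be strictly positive, got {v}")
        if self.hc_mm is not None and self.bpd_mm is not None and not self.hc_mm > self.bpd_mm:
            raise ValidationError(
                f"hc_mm ({self.hc_mm}) must exceed bpd_mm ({self.bpd_mm})"
            )

    def value_mm(self, name: str) -> float | None:
        return getattr(self, f"{name}_mm")


@dataclass(frozen=True)
class EfwFormula:
    """One EFW regression formula.

    ``form`` selects the functional family:

    * ``log10_linear`` — log10(weight g) = intercept + sum of terms, each term a
      coefficient times a product of measurements in the declared units.
    * ``stirnemann_hc_ac`` — ln(weight g) = c0 + c_ac3*(AC/100)^3
      + c_ac3_log*(AC/100)^3*ln(AC/100) + c_hc*(HC/100), AC/HC in cm.
    """

    formula_id: str
    form: str
    units: str  # units the coefficients expect ("cm" or "mm")
    required_measurements: frozenset[str]
    coefficients: Mapping[str, float]
    terms: Sequence[Mapping] = field(default_factory=tuple)  # log10_linear only
    citation: str = ""

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ParameterError(f"unknown formula form {self.form!r}")
        if self.units not in ("cm", "mm"):
            raise ParameterError(f"units must be 'cm' or 'mm', got {self.units!r}")
        if not self.required_measurements:
            raise ParameterError("required_measurements must be nonempty")
        unknown = self.required_measurements - set(MEASUREMENTS)
        if unknown:
            raise ParameterError(f"unknown measurements {sorted(unknown)}")
        if self.form == "stirnemann_hc_ac":
            need = {"c0", "c_ac3", "c_ac3_log", "c_hc"}
            missing = need - set(self.coefficients)
            if missing:
                raise ParameterError(f"stirnemann form missing coefficients {sorted(missing)}")
        else:
            if "intercept" not in self.coefficients:
                raise ParameterError("log10_linear form requires an 'intercept' coefficient")
            for t in self.terms:
                if "coef" not in t or "vars" not in t:
                    raise ParameterError("each log10_linear term needs 'coef' and 'vars'")


def _to_units(value_mm: float, units: str) -> float:
    return value_mm / 10.0 if units == "cm" else value_mm


def efw(formula: EfwFormula, biometry: BiometrySet, units: str = "mm") -> float:
    """Estimated fetal weight in grams.

    ``units`` declares the units of the *input* biometry ("mm" default; pass
    "cm" if the BiometrySet fields already hold centimetres).
    """
    if units not in ("mm", "cm"):
        raise ValidationError(f"units must be 'mm' or 'cm', got {units!r}")
    vals: dict[str, float] = {}
    for name in sorted(formula.required_measurements):
        v = biometry.value_mm(name)
        if v is None:
            raise IncompleteBiometryError(
                f"formula {formula.formula_id!r} requires measurement {name!r}"
            )
        v_mm = v * 10.0 if units == "cm" else v
        vals[name] = _to_units(v_mm, formula.units)
    return _evaluate(formula, vals)


def _evaluate(formula: EfwFormula, vals: Mapping[str, float]) -> float:
    if formula.form == "stirnemann_hc_ac":
        c = formula.coefficients
        ac = vals["ac"] / 100.0
        hc = vals["hc"] / 100.0
        ln_w = (
            c["c0"]
            + c["c_ac3"] * ac**3
            + c["c_ac3_log"] * ac**3 * math.log(ac)
            + c["c_hc"] * hc
        )
        return math.exp(ln_w)
    log10_w = formula.coefficients["intercept"]
    for term in formula.terms:
        prod = term["coef"]
        for var in term["vars"]:
            prod *= vals[var]
        log10_w += prod
    return 10.0**log10_w


def efw_array(formula: EfwFormula, bpd_mm, hc_mm, ac_mm, fl_mm):
    """Vectorized EFW in grams from biometry arrays in millimetres.

    Rows with a missing (NaN) required measurement yield NaN.
    """
    import numpy as np

    arrs = {
        "bpd": np.asarray(bpd_mm, dtype=float),
        "hc": np.asarray(hc_mm, dtype=float),
        "ac": np.asarray(ac_mm, dtype=float),
        "fl": np.asarray(fl_mm, dtype=float),
    }
    vals = {
        name: _to_units(arrs[name], formula.units) for name in formula.required_measurements
    }
    if formula.form == "stirnemann_hc_ac":
        c = formula.coefficients
        ac = vals["ac"] / 100.0
        hc = vals["hc"] / 100.0
        with np.errstate(invalid="ignore"):
            ln_w = (
                c["c0"]
                + c["c_ac3"] * ac**3
                + c["c_ac3_log"] * ac**3 * np.log(ac)
                + c["c_hc"] * hc
            )
        return np.exp(ln_w)
    log10_w = np.full_like(next(iter(vals.values())), formula.coefficients["intercept"])
    for term in formula.terms:
        prod = np.full_like(log10_w, term["coef"])
        for var in term["vars"]:
            prod = prod * vals[var]
        log10_w = log10_w + prod
    return 10.0**log10_w


# ---------------------------------------------------------------------------
# registry

_REGISTRY: dict[str, EfwFormula] = {}
_BUILTINS_LOADED = False
BUILTIN_FORMULA_IDS = ("hadlock4", "hadlock3", "stirnemann")


def formula_from_dict(d: Mapping) -> EfwFormula:
    try:
        return EfwFormula(
            formula_id=d["formula_id"],
            form=d["form"],
            units=d["units"],
            required_measurements=frozenset(d["required_measurements"]),
            coefficients=dict(d["coefficients"]),
            terms=tuple(d.get("terms", ())),
            citation=d.get("citation", ""),
        )
    except KeyError as e:
        raise ParameterError(f"formula file missing field {e.args[0]!r}") from None


def _load_builtins() -> None:
    global _BUILTINS_LOADED
    if _BUILTINS_LOADED:
        return
    _BUILTINS_LOADED = True
    root = resources.files("epwscreen").joinpath("data/formulas")
    for fid in BUILTIN_FORMULA_IDS:
        spec = json.loads(root.joinpath(f"{fid}.json").read_text())
        f = formula_from_dict(spec)
        _REGISTRY.setdefault(f.formula_id, f)


def register_formula(formula: EfwFormula) -> EfwFormula:
    """Add a formula to the registry; duplicate ids are rejected."""
    _load_builtins()
    if formula.formula_id in _REGISTRY:
        raise FormulaRegistrationError(f"formula id {formula.formula_id!r} already registered")
    _REGISTRY[formula.formula_id] = formula
    return formula


def get_formula(formula_id: str) -> EfwFormula:
    _load_builtins()
    try:
        return _REGISTRY[formula_id]
    except KeyError:
        raise FormulaNotFoundError(f"no formula registered under id {formula_id!r}") from None


def registered_formula_ids() -> tuple[str, ...]:
    _load_builtins()
    return tuple(sorted(_REGISTRY))
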