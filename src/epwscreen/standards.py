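"""Growth-standard engine: EFW -> estimated percentile weight (EPW).

Three parameterization families cover the six bundled standards:

* ``zscore_curve`` — a tabulated median-weight curve over scan GA plus a
  dispersion parameter under a declared transform (``normal``, ``log``, or the
  skewness-capable ``shifted_log``); percentile = 100*Phi(z).
* ``customized`` — Gardosi-style individualization: expected weight =
  (base term weight + additive covariate effects) * proportionality(GA),
  percentile from the z-score around that individualized center.
* ``quantile_grid`` — weights tabulated at the 5/10/25/50/75/90/95th
  percentiles on a weekly GA grid; percentile by linear GA interpolation then
  monotone interpolation of weight against the probit of the level.

Percentiles are reported on the 0-100 scale and clamped to [0.01, 99.99] so
probit transforms stay finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .biometry import efw_array, get_formula
from .errors import MissingCovariateError, ParameterError, RangeError, ValidationError

PCT_FLOOR, PCT_CEIL = 0.01, 99.99
FAMILIES = ("zscore_curve", "customized", "quantile_grid")
STANDARD_IDS = ("msuh_nc", "msuh_cust", "figueras", "intergrowth21", "who", "fmf")
GRID_LEVELS = (5, 10, 25, 50, 75, 90, 95)


def _clamp_pct(p):
    return np.clip(p, PCT_FLOOR, PCT_CEIL)


@dataclass(frozen=True)
class EPWResult:
    """Per-record, per-standard estimated fetal weight and percentile."""

    record_id: str
    standard_id: str
    efw_g: float
    percentile: float
    zscore: float | None = None


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class ZscoreCurveParams:
    ga_days: np.ndarray  # tabulated grid, integer days
    median_g: np.ndarray  # median weight per grid day
    sigma: float  # CV (normal transform) or SD of the transform
    transform: str = "log"  # normal | log | shifted_log
    shift_frac: float = 0.0  # shifted_log only; z = (ln(u+a)-ln(1+a))/sigma

    def __post_init__(self) -> None:
        ga = np.asarray(self.ga_days, dtype=float)
        med = np.asarray(self.median_g, dtype=float)
        object.__setattr__(self, "ga_days", ga)
        object.__setattr__(self, "median_g", med)
        if ga.ndim != 1 or ga.size < 2 or med.shape != ga.shape:
            raise ParameterError("median curve needs matching 1-D ga_days/median_g, length >= 2")
        if np.any(np.diff(ga) <= 0):
            raise ParameterError("ga_days must be strictly increasing")
        if np.any(med <= 0) or np.any(np.diff(med) < 0):
            raise ParameterError("median_g must be positive and nondecreasing in GA")
        if not self.sigma > 0:
            raise ParameterError("sigma (dispersion) must be positive")
        if self.transform not in ("normal", "log", "shifted_log"):
            raise ParameterError(f"unknown transform {self.transform!r}")
        if self.transform == "shifted_log" and not self.shift_frac > -1.0:
            raise ParameterError("shift_frac must exceed -1")

    def median_at(self, ga_days):
        ga = np.asarray(ga_days, dtype=float)
        if np.any(ga < self.ga_days[0]) or np.any(ga > self.ga_days[-1]):
            raise RangeError(
                f"scan GA outside the standard's envelope "
                f"[{self.ga_days[0]:.0f}, {self.ga_days[-1]:.0f}] days"
            )
        return np.interp(ga, self.ga_days, self.median_g)


@dataclass(frozen=True)
class CustomizationParams:
    base_term_weight: float  # g, reference profile at reference_ga_days
    reference_ga_days: int
    prop_rate_per_day: float  # proportionality(ga) = exp(rate*(ga-ref))
    covariate_effects: Mapping[str, Mapping]  # additive grams at term
    sigma: float
    transform: str = "log"
    shift_frac: float = 0.0
    ga_span: tuple = (238, 258)

    def __post_init__(self) -> None:
        if not self.base_term_weight > 0:
            raise ParameterError("base_term_weight must be positive")
        if self.prop_rate_per_day < 0:
            raise ParameterError("proportionality must be nondecreasing in GA")
        if not self.sigma > 0:
            raise ParameterError("sigma must be positive")
        if self.transform not in ("normal", "log", "shifted_log"):
            raise ParameterError(f"unknown transform {self.transform!r}")
        if not self.covariate_effects:
            raise ParameterError("customized standards must declare >= 1 covariate effect")
        for cov, eff in self.covariate_effects.items():
            if ("per_unit" in eff) == ("categories" in eff):
                raise ParameterError(
                    f"covariate {cov!r} must declare exactly one of per_unit/categories"
                )
            if "per_unit" in eff and "reference" not in eff:
                raise ParameterError(f"covariate {cov!r} needs a 'reference' value")

    def proportionality(self, ga_days):
        ga = np.asarray(ga_days, dtype=float)
        lo, hi = self.ga_span
        if np.any(ga < lo) or np.any(ga > hi):
            raise RangeError(f"scan GA outside the standard's envelope [{lo}, {hi}] days")
        return np.exp(self.prop_rate_per_day * (ga - self.reference_ga_days))

    def adjustment(self, profile: Mapping) -> float:
        """Total additive covariate adjustment (grams at term) for a profile."""
        total = 0.0
        for cov, eff in self.covariate_effects.items():
            val = profile.get(cov) if hasattr(profile, "get") else getattr(profile, cov, None)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise MissingCovariateError(f"profile is missing covariate {cov!r}")
            if "per_unit" in eff:
                total += eff["per_unit"] * (float(val) - eff["reference"])
            else:
                try:
                    total += eff["categories"][str(val)]
                except KeyError:
                    raise ValidationError(f"unknown category {val!r} for covariate {cov!r}") from None
        return total

    def expected_weight(self, ga_days, profile: Mapping):
        return (self.base_term_weight + self.adjustment(profile)) * self.proportionality(ga_days)


@dataclass(frozen=True)
class QuantileGrid:
    ga_days: np.ndarray  # weekly nodes
    levels: tuple = GRID_LEVELS
    weights_g: np.ndarray = None  # shape (len(ga_days), len(levels))

    def __post_init__(self) -> None:
        ga = np.asarray(self.ga_days, dtype=float)
        w = np.asarray(self.weights_g, dtype=float)
        object.__setattr__(self, "ga_days", ga)
        object.__setattr__(self, "weights_g", w)
        if ga.ndim != 1 or ga.size < 2 or np.any(np.diff(ga) <= 0):
            raise ParameterError("quantile grid needs >= 2 strictly increasing GA nodes")
        if tuple(self.levels) != GRID_LEVELS:
            raise ParameterError(f"quantile grid levels must be {GRID_LEVELS}")
        if w.shape != (ga.size, len(self.levels)):
            raise ParameterError("weights_g must have shape (n_ga, n_levels)")
        if np.any(np.diff(w, axis=1) <= 0):
            raise ParameterError("grid weights must be strictly increasing across levels")
        if np.any(np.diff(w, axis=0) < 0):
            raise ParameterError("grid weights must be nondecreasing in GA at each level")

    def weights_at(self, ga_days) -> np.ndarray:
        ga = np.asarray(ga_days, dtype=float)
        if np.any(ga < self.ga_days[0]) or np.any(ga > self.ga_days[-1]):
            raise RangeError(
                f"scan GA outside the grid span [{self.ga_days[0]:.0f}, {self.ga_days[-1]:.0f}]"
            )
        out = np.empty(np.shape(ga) + (len(self.levels),))
        for j in range(len(self.levels)):
            out[..., j] = np.interp(ga, self.ga_days, self.weights_g[:, j])
        return out


# ---------------------------------------------------------------------------
# family operations (vectorized over efw/ga)


def _z_from_ratio(u, transform: str, sigma: float, shift_frac: float = 0.0):
    u = np.asarray(u, dtype=float)
    if transform == "normal":
        return (u - 1.0) / sigma
    if transform == "log":
        with np.errstate(divide="ignore"):
            return np.log(u) / sigma
    a = shift_frac
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(u + a) - np.log1p(a)) / sigma
    return np.where(u + a <= 0, -np.inf, z)


def _ratio_from_z(z, transform: str, sigma: float, shift_frac: float = 0.0):
    z = np.asarray(z, dtype=float)
    if transform == "normal":
        return 1.0 + sigma * z
    if transform == "log":
        return np.exp(sigma * z)
    a = shift_frac
    return np.exp(sigma * z + np.log1p(a)) - a


def _check_efw(efw_g):
    if np.any(np.asarray(efw_g, dtype=float) <= 0):
        raise ValidationError("efw_g must be strictly positive")


def epw_zscore(efw_g, ga_days, params: ZscoreCurveParams):
    """(percentile, zscore) under a median-curve standard."""
    _check_efw(efw_g)
    u = np.asarray(efw_g, dtype=float) / params.median_at(ga_days)
    z = _z_from_ratio(u, params.transform, params.sigma, params.shift_frac)
    return _clamp_pct(100.0 * norm.cdf(z)), z


def epw_customized(efw_g, ga_days, profile: Mapping, params: CustomizationParams):
    """(percentile, zscore) around the profile-individualized expected weight."""
    _check_efw(efw_g)
    u = np.asarray(efw_g, dtype=float) / params.expected_weight(ga_days, profile)
    z = _z_from_ratio(u, params.transform, params.sigma, params.shift_frac)
    return _clamp_pct(100.0 * norm.cdf(z)), z


def epw_quantile_grid(efw_g, ga_days, grid: QuantileGrid):
    """Percentile by probit-scale interpolation between tabulated levels.

    Outside the P5-P95 span the outermost segment is extended on the probit
    scale; results are clamped to [0.01, 99.99].
    """
    _check_efw(efw_g)
    w = np.atleast_1d(np.asarray(efw_g, dtype=float))
    ga = np.broadcast_to(np.atleast_1d(np.asarray(ga_days, dtype=float)), w.shape)
    nodes = grid.weights_at(ga)  # (n, 7)
    probits = norm.ppf(np.asarray(grid.levels, dtype=float) / 100.0)
    n_lev = len(grid.levels)
    # bracketing segment per record (clipped to the outer segments)
    idx = np.sum(nodes < w[..., None], axis=-1)  # number of node weights below w
    seg = np.clip(idx - 1, 0, n_lev - 2)
    w_lo = np.take_along_axis(nodes, seg[..., None], axis=-1)[..., 0]
    w_hi = np.take_along_axis(nodes, (seg + 1)[..., None], axis=-1)[..., 0]
    frac = (w - w_lo) / (w_hi - w_lo)
    probit = probits[seg] + frac * (probits[seg + 1] - probits[seg])
    pct = _clamp_pct(100.0 * norm.cdf(probit))
    if np.isscalar(efw_g) or np.ndim(efw_g) == 0:
        return float(pct[0])
    return pct


# ---------------------------------------------------------------------------
# StandardSpec


@dataclass(frozen=True)
class StandardSpec:
    """A named growth standard: family + parameter block + EFW formula."""

    standard_id: str
    family: str
    efw_formula_id: str
    params: object  # family-specific block
    customization_covariates: frozenset = frozenset()
    citation: str = ""
    version: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        expected = {
            "zscore_curve": ZscoreCurveParams,
            "customized": CustomizationParams,
            "quantile_grid": QuantileGrid,
        }[self.family]
        if not isinstance(self.params, expected):
            raise ParameterError(
                f"family {self.family!r} requires a {expected.__name__} parameter block"
            )
        if self.family == "customized" and not self.customization_covariates:
            raise ParameterError("customized standards must declare covariates")
        get_formula(self.efw_formula_id)  # raises if unregistered

    # -- forward ------------------------------------------------------------
    def percentile(self, efw_g, ga_days, profile: Mapping | None = None):
        """(percentile, zscore-or-None) for EFW(s) at scan GA(s)."""
        if self.family == "zscore_curve":
            return epw_zscore(efw_g, ga_days, self.params)
        if self.family == "customized":
            if profile is None:
                raise MissingCovariateError(
                    f"standard {self.standard_id!r} needs a covariate profile"
                )
            return epw_customized(efw_g, ga_days, profile, self.params)
        return epw_quantile_grid(efw_g, ga_days, self.params), None

    # -- inverse ------------------------------------------------------------
    def weight_at_percentile(self, p, ga_days, profile: Mapping | None = None):
        """Weight (g) whose forward percentile is ``p``; mutual inverse to 0.1 pt."""
        p_arr = np.asarray(p, dtype=float)
        if np.any(p_arr <= 0) or np.any(p_arr >= 100):
            raise ValidationError("percentile must lie strictly inside (0, 100)")
        z = norm.ppf(p_arr / 100.0)
        if self.family == "zscore_curve":
            pr = self.params
            return pr.median_at(ga_days) * _ratio_from_z(z, pr.transform, pr.sigma, pr.shift_frac)
        if self.family == "customized":
            pr = self.params
            if profile is None:
                raise MissingCovariateError(
                    f"standard {self.standard_id!r} needs a covariate profile"
                )
            center = pr.expected_weight(ga_days, profile)
            return center * _ratio_from_z(z, pr.transform, pr.sigma, pr.shift_frac)
        grid: QuantileGrid = self.params
        nodes = grid.weights_at(ga_days)
        probits = norm.ppf(np.asarray(grid.levels, dtype=float) / 100.0)
        z1 = np.atleast_1d(z)
        nodes2 = np.broadcast_to(nodes, np.shape(z1) + (len(grid.levels),))
        seg = np.clip(np.searchsorted(probits, z1) - 1, 0, len(grid.levels) - 2)
        p_lo, p_hi = probits[seg], probits[seg + 1]
        w_lo = np.take_along_axis(nodes2, seg[..., None], axis=-1)[..., 0]
        w_hi = np.take_along_axis(nodes2, (seg + 1)[..., None], axis=-1)[..., 0]
        w = w_lo + (z1 - p_lo) / (p_hi - p_lo) * (w_hi - w_lo)
        return float(w[0]) if np.ndim(p) == 0 else w


# ---------------------------------------------------------------------------
# load / registry

_REQUIRED_TOP = ("standard_id", "family", "efw_formula_id", "parameters")


def standard_from_dict(d: Mapping) -> StandardSpec:
    for key in _REQUIRED_TOP:
        if key not in d:
            raise ParameterError(f"standard file missing field {key!r}")
    fam = d["family"]
    p = d["parameters"]
    try:
        if fam == "zscore_curve":
            params = ZscoreCurveParams(
                ga_days=np.asarray(p["median_curve"]["ga_days"]),
                median_g=np.asarray(p["median_curve"]["median_g"]),
                sigma=p["sigma"],
                transform=p.get("transform", "log"),
                shift_frac=p.get("shift_frac", 0.0),
            )
        elif fam == "customized":
            params = CustomizationParams(
                base_term_weight=p["base_term_weight"],
                reference_ga_days=p["reference_ga_days"],
                prop_rate_per_day=p["proportionality"]["rate_per_day"],
                covariate_effects=p["covariate_effects"],
                sigma=p["sigma"],
                transform=p.get("transform", "log"),
                shift_frac=p.get("shift_frac", 0.0),
                ga_span=tuple(p.get("ga_span", (238, 258))),
            )
        elif fam == "quantile_grid":
            params = QuantileGrid(
                ga_days=np.asarray(p["ga_days"]),
                levels=tuple(p.get("levels", GRID_LEVELS)),
                weights_g=np.asarray(p["weights_g"]),
            )
        else:
            raise ParameterError(f"unknown family {fam!r}")
    except KeyError as e:
        raise ParameterError(f"parameter block missing field {e.args[0]!r}") from None
    covs = frozenset(
        p["covariate_effects"].keys() if fam == "customized" else d.get("customization_covariates", ())
    )
    return StandardSpec(
        standard_id=d["standard_id"],
        family=fam,
        efw_formula_id=d["efw_formula_id"],
        params=params,
        customization_covariates=covs,
        citation=d.get("citation", ""),
        version=d.get("version", ""),
        provenance=d.get("provenance", ""),
    )


def load_standard(path) -> StandardSpec:
    with open(path) as fh:
        return standard_from_dict(json.load(fh))


def load_default_standards() -> dict[str, StandardSpec]:
    """The six bundled (synthetic-calibrated) standards, keyed by id."""
    root = resources.files("epwscreen").joinpath("data/standards")
    out = {}
    for sid in STANDARD_IDS:
        out[sid] = standard_from_dict(json.loads(root.joinpath(f"{sid}.json").read_text()))
    return out


# ---------------------------------------------------------------------------
# cohort-level dispatch

_COVARIATE_COLUMNS = (
    "maternal_age_yr",
    "maternal_bmi",
    "maternal_height_cm",
    "paternal_height_cm",
    "parity",
    "ethnicity",
    "fetal_sex",
)


def epw_all_standards(record, registry: Mapping[str, StandardSpec]) -> dict[str, EPWResult | None]:
    """EPW under every registered standard for one pregnancy record.

    Standards for which the record lacks a required measurement or covariate
    map to ``None`` (excluded for that standard only).
    """
    if not registry:
        raise ValidationError("standards registry must be nonempty")
    from .biometry import efw as _efw
    from .errors import IncompleteBiometryError

    out: dict[str, EPWResult | None] = {}
    bio = record.biometry()
    for sid, spec in registry.items():
        formula = get_formula(spec.efw_formula_id)
        try:
            w = _efw(formula, bio)
            profile = record if spec.family != "customized" else _record_profile(record)
            pct, z = spec.percentile(w, record.ga_scan_days, profile)
        except (MissingCovariateError, IncompleteBiometryError):
            out[sid] = None
            continue
        out[sid] = EPWResult(
            record_id=record.record_id,
            standard_id=sid,
            efw_g=float(w),
            percentile=float(pct),
            zscore=None if z is None else float(z),
        )
    return out


def _record_profile(record) -> dict:
    return {c: getattr(record, c, None) for c in _COVARIATE_COLUMNS}


def epw_table(frame: pd.DataFrame, registry: Mapping[str, StandardSpec]) -> pd.DataFrame:
    """Vectorized EPW for a whole cohort frame.

    Returns a frame indexed like ``frame`` with, per standard, columns
    ``efw_<id>`` (grams) and ``pct_<id>`` (percentile, NaN when the record is
    excluded for that standard).
    """
    if not registry:
        raise ValidationError("standards registry must be nonempty")
    out = pd.DataFrame({"record_id": frame["record_id"]})
    ga = frame["ga_scan_days"].to_numpy()
    for sid, spec in registry.items():
        formula = get_formula(spec.efw_formula_id)
        w = efw_array(
            formula,
            frame["bpd_mm"].to_numpy(dtype=float),
            frame["hc_mm"].to_numpy(dtype=float),
            frame["ac_mm"].to_numpy(dtype=float),
            frame["fl_mm"].to_numpy(dtype=float),
        )
        ok = np.isfinite(w)
        pct = np.full(len(frame), np.nan)
        if spec.family == "customized":
            for cov in spec.customization_covariates:
                col = frame[cov]
                ok = ok & col.notna().to_numpy()
            if ok.any():
                sub = frame.loc[ok]
                adj = _vector_adjustment(sub, spec.params)
                center = (spec.params.base_term_weight + adj) * spec.params.proportionality(ga[ok])
                u = w[ok] / center
                z = _z_from_ratio(u, spec.params.transform, spec.params.sigma, spec.params.shift_frac)
                pct[ok] = _clamp_pct(100.0 * norm.cdf(z))
        elif spec.family == "zscore_curve":
            if ok.any():
                pct[ok] = epw_zscore(w[ok], ga[ok], spec.params)[0]
        else:
            if ok.any():
                pct[ok] = epw_quantile_grid(w[ok], ga[ok], spec.params)
        out[f"efw_{sid}"] = w
        out[f"pct_{sid}"] = pct
    return out


def _vector_adjustment(frame: pd.DataFrame, params: CustomizationParams) -> np.ndarray:
    adj = np.zeros(len(frame))
    for cov, eff in params.covariate_effects.items():
        col = frame[cov]
        if "per_unit" in eff:
            adj += eff["per_unit"] * (col.to_numpy(dtype=float) - eff["reference"])
        else:
            adj += col.astype(str).map(eff["categories"]).to_numpy(dtype=float)
    return adj


def chart_frame(spec: StandardSpec, profile: Mapping | None = None) -> pd.DataFrame:
    """Chart export: weights at the seven reference levels across the scan
    envelope (238-258 days), one row per day."""
    ga = np.arange(238, 259)
    out = pd.DataFrame({"ga_days": ga})
    for level in GRID_LEVELS:
        out[f"p{level}_g"] = np.round(
            np.asarray(spec.weight_at_percentile(np.full(ga.size, float(level)), ga, profile)), 1
        )
    return out


def exclusion_tally(epw_frame: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Per-standard analyzed/excluded counts; they sum to the cohort size."""
    tally = {}
    n = len(epw_frame)
    for col in epw_frame.columns:
        if col.startswith("pct_"):
            sid = col[4:]
            analyzed = int(epw_frame[col].notna().sum())
            tally[sid] = {"analyzed": analyzed, "excluded": n - analyzed}
    return tally
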