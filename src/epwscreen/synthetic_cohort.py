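"""Synthetic perinatal cohort generator.

Emulates a hospital cohort of term singleton pregnancies with a universal
35-week growth scan: maternal covariates drawn from independent marginals,
fetal biometry consistent with a latent scan-weight percentile, birthweight
tied to the scan percentile through a probit-scale Gaussian copula whose
correlation decays with the scan-to-delivery interval, and adverse perinatal
outcome (APO) flags whose risk is elevated for fetuses below the 10th latent
birth percentile.

The defaults reproduce the marginal structure of a ~9600-pregnancy Spanish
single-centre cohort (median scan EFW 2495 g by Hadlock-4, birthweight median
3310 g, SGA rate 9.4%, per-component APO rates 0.2-2.8%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from . import population as pop
from .biometry import BiometrySet, efw, get_formula
from .errors import ConfigurationError, InfeasibleBiometryError, ParseError, ValidationError

_Z75 = norm.ppf(0.75)  # half-IQR in SD units

PARITY_LEVELS = ("0", "1", "2+")
ETHNICITY_LEVELS = ("Caucasian", "Asian", "African")
APO_COMPONENTS = ("apgar5_lt7", "instrumental_nrfs", "cesarean_nrfs", "ph_lt_710", "stillbirth")

#: default per-component APO rates among non-SGA pregnancies, chosen so the
#: cohort-wide marginals land on 0.44/1.7/2.8/2.6/0.2 % under the default
#: SGA risk ratios (marginal = base * (0.9 + 0.1 * RR) with 10% below P10)
_DEFAULT_APO_BASE = {
    "apgar5_lt7": 0.0034,
    "instrumental_nrfs": 0.0147,
    "cesarean_nrfs": 0.0222,
    "ph_lt_710": 0.0239,
    "stillbirth": 0.0016,
}
#: default relative risk of each APO component given latent birth percentile <10
_DEFAULT_APO_RR = {
    "apgar5_lt7": 3.9,
    "instrumental_nrfs": 2.4,
    "cesarean_nrfs": 3.5,
    "ph_lt_710": 2.1,
    "stillbirth": 3.4,
}


@dataclass
class CohortConfig:
    """All distributions, effect sizes, and noise parameters of the generator.

    Continuous covariates are given as (median, (IQR low, IQR high)). The
    latent percentile model is a probit-scale Gaussian copula: the correlation
    between scan and birth probits at interval ``d`` days is
    ``percentile_persistence_rho * exp(-interval_drift_per_week * d / 7)``.
    """

    n_records: int = 9585
    seed: int = 0
    maternal_age: tuple = (33.3, (30.1, 36.1))  # years
    maternal_bmi: tuple = (23.2, (21.1, 26.2))  # kg/m^2, log-normal
    maternal_height: tuple = (163.0, (159.0, 168.0))  # cm
    paternal_height: tuple = (176.0, (172.0, 181.0))  # cm
    parity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"0": 5077 / 9585, "1": 3724 / 9585, "2+": 784 / 9585}
    )
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Caucasian": 9243 / 9585, "Asian": 110 / 9585, "African": 232 / 9585}
    )
    smoking_prob: float = 1546 / 9585
    male_prob: float = 4933 / 9585
    scan_ga_range: tuple = pop.SCAN_GA_SPAN
    delivery_ga_range: tuple = pop.DELIVERY_GA_SPAN
    target_sga_rate: float = 0.094
    percentile_persistence_rho: float = 0.96
    interval_drift_per_week: float = 0.08
    apo_base_rates: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_APO_BASE))
    apo_sga_risk_ratio: Mapping[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_APO_RR)
    )
    #: "event": any-APO is the plain union of the five components (SGA itself
    #: is never an APO). "exclude_sga_records": reporting additionally drops
    #: SGA deliveries from the any-APO denominator.
    any_apo_convention: str = "event"
    # shape parameters of the GA distributions (days)
    scan_ga_median: int = 246
    scan_ga_concentration: float = 1.8  # Laplace scale of the discretized scan-GA law
    delivery_ga_median: float = 280.5
    delivery_ga_sd: float = 9.0
    #: log-scale SD of per-measurement biometry jitter around the reference shape
    efw_jitter_sd: float = 0.02

    def risk_ratio(self, component: str) -> float:
        if isinstance(self.apo_sga_risk_ratio, Mapping):
            return float(self.apo_sga_risk_ratio[component])
        return float(self.apo_sga_risk_ratio)

    def validate(self) -> "CohortConfig":
        if not isinstance(self.n_records, (int, np.integer)) or self.n_records < 0:
            raise ConfigurationError(f"n_records must be a nonnegative integer, got {self.n_records}")
        for name in ("maternal_age", "maternal_bmi", "maternal_height", "paternal_height"):
            med, (lo, hi) = getattr(self, name)
            if not (lo < med < hi):
                raise ConfigurationError(f"{name}: IQR ({lo}, {hi}) must bracket the median {med}")
        for name, probs, levels in (
            ("parity_probs", self.parity_probs, PARITY_LEVELS),
            ("ethnicity_probs", self.ethnicity_probs, ETHNICITY_LEVELS),
        ):
            if set(probs) != set(levels):
                raise ConfigurationError(f"{name} must have keys {levels}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1 within 1e-9")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} entries must be nonnegative")
        for name in ("smoking_prob", "male_prob", "target_sga_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("scan_ga_range", "delivery_ga_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} is empty: ({lo}, {hi})")
        if not self.scan_ga_range[1] < self.delivery_ga_range[0]:
            raise ConfigurationError("scan_ga_range must end before delivery_ga_range begins")
        if not 0.0 < self.percentile_persistence_rho < 1.0:
            raise ConfigurationError(
                f"percentile_persistence_rho must lie in (0, 1), got {self.percentile_persistence_rho}"
            )
        if self.interval_drift_per_week < 0:
            raise ConfigurationError("interval_drift_per_week must be nonnegative")
        if set(self.apo_base_rates) != set(APO_COMPONENTS):
            raise ConfigurationError(f"apo_base_rates must have keys {APO_COMPONENTS}")
        for k, v in self.apo_base_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"apo_base_rates[{k!r}] must lie in [0, 1], got {v}")
        for comp in APO_COMPONENTS:
            if self.risk_ratio(comp) < 0:
                raise ConfigurationError(f"apo_sga_risk_ratio[{comp!r}] must be nonnegative")
        if self.any_apo_convention not in ("event", "exclude_sga_records"):
            raise ConfigurationError(
                f"any_apo_convention must be 'event' or 'exclude_sga_records', "
                f"got {self.any_apo_convention!r}"
            )
        if self.efw_jitter_sd < 0:
            raise ConfigurationError("efw_jitter_sd must be nonnegative")
        return self

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


@dataclass
class PregnancyRecord:
    """One pregnancy: covariates, scan biometry, delivery data, outcome flags.

    ``latent_percentile_scan`` / ``latent_percentile_birth`` are the hidden
    simulation truths (0-100); they are excluded from analysis I/O unless a
    debug flag requests them.
    """

    record_id: str
    maternal_age_yr: float
    maternal_bmi: float
    maternal_height_cm: float
    paternal_height_cm: float
    parity: str
    ethnicity: str
    smoker: bool
    fetal_sex: str
    bpd_mm: float | None
    hc_mm: float | None
    ac_mm: float | None
    fl_mm: float | None
    ga_scan_days: int
    ga_delivery_days: int
    birthweight_g: float
    apgar5_lt7: bool
    instrumental_nrfs: bool
    cesarean_nrfs: bool
    ph_lt_710: bool
    stillbirth: bool
    latent_percentile_scan: float | None = None
    latent_percentile_birth: float | None = None

    def biometry(self) -> BiometrySet:
        return BiometrySet(
            bpd_mm=self.bpd_mm,
            hc_mm=self.hc_mm,
            ac_mm=self.ac_mm,
            fl_mm=self.fl_mm,
            ga_scan_days=self.ga_scan_days,
        )

    def interval_days(self) -> int:
        return self.ga_delivery_days - self.ga_scan_days


ANALYSIS_COLUMNS = [
    f.name for f in dc_fields(PregnancyRecord) if not f.name.startswith("latent_")
]
LATENT_COLUMNS = ["latent_percentile_scan", "latent_percentile_birth"]
_BOOL_COLUMNS = ("smoker",) + APO_COMPONENTS
_BIOMETRY_COLUMNS = ("bpd_mm", "hc_mm", "ac_mm", "fl_mm")


def validate_record(rec: PregnancyRecord, scan_span=pop.SCAN_GA_SPAN, delivery_span=pop.DELIVERY_GA_SPAN) -> None:
    rid = rec.record_id
    if not scan_span[0] <= rec.ga_scan_days <= scan_span[1]:
        raise ValidationError(
            f"record {rid}: ga_scan_days {rec.ga_scan_days} outside {list(scan_span)}"
        )
    if not delivery_span[0] <= rec.ga_delivery_days <= delivery_span[1]:
        raise ValidationError(
            f"record {rid}: ga_delivery_days {rec.ga_delivery_days} outside {list(delivery_span)}"
        )
    if not rec.ga_delivery_days > rec.ga_scan_days:
        raise ValidationError(f"record {rid}: delivery must postdate the scan")
    if not rec.birthweight_g > 0:
        raise ValidationError(f"record {rid}: birthweight_g must be positive")
    for col in _BIOMETRY_COLUMNS:
        v = getattr(rec, col)
        if v is not None and not v > 0:
            raise ValidationError(f"record {rid}: {col} must be positive when present")


# ---------------------------------------------------------------------------
# biometry synthesis


def _jittered_shape(ga_days, jitter: np.ndarray) -> dict:
    ref = pop.reference_biometry(ga_days)
    return {m: ref[m] * jitter[i] for i, m in enumerate(("bpd", "hc", "ac", "fl"))}


def synth_biometry(
    target_efw_g: float,
    ga_days: int,
    formula_id: str = "hadlock4",
    seed: int = 0,
    jitter_sd: float = 0.02,
) -> tuple[float, float, float, float]:
    """Biometry quadruple (bpd, hc, ac, fl in mm) whose EFW under ``formula_id``
    equals ``target_efw_g`` (relative error well below 0.5%).

    The reference biometry shape at ``ga_days`` receives seed-reproducible
    log-normal jitter on the measurement ratios, then a common scale factor is
    solved so the named formula reproduces the target exactly.
    """
    if not target_efw_g > 0:
        raise ValidationError(f"target_efw_g must be positive, got {target_efw_g}")
    formula = get_formula(formula_id)
    rng = np.random.default_rng(seed)
    jitter = np.exp(rng.normal(0.0, jitter_sd, size=4))
    shape = _jittered_shape(ga_days, jitter)

    def gap(s: float) -> float:
        b = BiometrySet(
            bpd_mm=shape["bpd"] * s,
            hc_mm=shape["hc"] * s,
            ac_mm=shape["ac"] * s,
            fl_mm=shape["fl"] * s,
        )
        return efw(formula, b) - target_efw_g

    lo, hi = pop.BIOMETRY_SCALE_BOUNDS
    if gap(lo) > 0 or gap(hi) < 0:
        raise InfeasibleBiometryError(
            f"target EFW {target_efw_g:.0f} g unattainable within physiologic "
            f"bounds at {ga_days} days for formula {formula_id!r}"
        )
    s = brentq(gap, lo, hi, xtol=1e-10)
    return tuple(float(shape[m] * s) for m in ("bpd", "hc", "ac", "fl"))


def _solve_hadlock4_scale(
    target_g: np.ndarray, bpd: np.ndarray, hc: np.ndarray, ac: np.ndarray, fl: np.ndarray
) -> np.ndarray:
    """Vectorized common-scale solve for the Hadlock-4 log10 form.

    With measurements in cm, log10(W) is quadratic in the scale factor s:
    L = intercept + s*(linear terms) + s^2*(product terms).
    """
    f = get_formula("hadlock4")
    c = {tuple(t["vars"]): t["coef"] for t in f.terms}
    bpd_c, hc_c, ac_c, fl_c = bpd / 10.0, hc / 10.0, ac / 10.0, fl / 10.0
    b_lin = c[("hc",)] * hc_c + c[("ac",)] * ac_c + c[("fl",)] * fl_c
    a_quad = c[("bpd", "ac")] * bpd_c * ac_c + c[("ac", "fl")] * ac_c * fl_c
    const = f.coefficients["intercept"] - np.log10(target_g)
    disc = b_lin**2 - 4.0 * a_quad * const
    if np.any(disc < 0):
        raise InfeasibleBiometryError("no real biometry scale for some target weights")
    s = (-b_lin + np.sqrt(disc)) / (2.0 * a_quad)
    lo, hi = pop.BIOMETRY_SCALE_BOUNDS
    if np.any((s < lo) | (s > hi)):
        bad = int(np.sum((s < lo) | (s > hi)))
        raise InfeasibleBiometryError(
            f"{bad} target weights fall outside the physiologic biometry envelope"
        )
    return s


# ---------------------------------------------------------------------------
# generation


def _iqr_to_sd(iqr: tuple[float, float]) -> float:
    return (iqr[1] - iqr[0]) / (2.0 * _Z75)


def _sample_scan_ga(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = cfg.scan_ga_range
    days = np.arange(lo, hi + 1)
    w = np.exp(-np.abs(days - cfg.scan_ga_median) / cfg.scan_ga_concentration)
    return rng.choice(days, size=n, p=w / w.sum())


def _sample_delivery_ga(cfg: CohortConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = cfg.delivery_ga_range
    a = (lo - cfg.delivery_ga_median) / cfg.delivery_ga_sd
    b = (hi - cfg.delivery_ga_median) / cfg.delivery_ga_sd
    u = rng.uniform(size=n)
    ga = truncnorm.ppf(u, a, b, loc=cfg.delivery_ga_median, scale=cfg.delivery_ga_sd)
    return np.clip(np.rint(ga).astype(int), lo, hi)


def generate_frame(config: CohortConfig) -> pd.DataFrame:
    """Vectorized generator core; returns a DataFrame incl. latent columns."""
    cfg = config.validate()
    n = cfg.n_records
    rng = np.random.default_rng(cfg.seed)
    cols: dict = {"record_id": [f"R{i:05d}" for i in range(n)]}

    cols["maternal_age_yr"] = np.round(
        rng.normal(cfg.maternal_age[0], _iqr_to_sd(cfg.maternal_age[1]), n), 1
    )
    med, iqr = cfg.maternal_bmi
    sd_log = (math.log(iqr[1]) - math.log(iqr[0])) / (2.0 * _Z75)
    cols["maternal_bmi"] = np.round(np.exp(rng.normal(math.log(med), sd_log, n)), 1)
    cols["maternal_height_cm"] = np.round(
        rng.normal(cfg.maternal_height[0], _iqr_to_sd(cfg.maternal_height[1]), n), 0
    )
    cols["paternal_height_cm"] = np.round(
        rng.normal(cfg.paternal_height[0], _iqr_to_sd(cfg.paternal_height[1]), n), 0
    )
    cols["parity"] = rng.choice(PARITY_LEVELS, size=n, p=[cfg.parity_probs[k] for k in PARITY_LEVELS])
    cols["ethnicity"] = rng.choice(
        ETHNICITY_LEVELS, size=n, p=[cfg.ethnicity_probs[k] for k in ETHNICITY_LEVELS]
    )
    cols["smoker"] = rng.uniform(size=n) < cfg.smoking_prob
    is_male = rng.uniform(size=n) < cfg.male_prob
    cols["fetal_sex"] = np.where(is_male, "male", "female")

    ga_scan = _sample_scan_ga(cfg, rng, n)
    ga_del = _sample_delivery_ga(cfg, rng, n)
    cols["ga_scan_days"] = ga_scan
    cols["ga_delivery_days"] = ga_del

    # latent copula: scan probit -> birth probit with interval-decaying corr
    interval = ga_del - ga_scan
    rho_d = cfg.percentile_persistence_rho * np.exp(
        -cfg.interval_drift_per_week * interval / 7.0
    )
    z_scan = rng.normal(size=n)
    z_birth = rho_d * z_scan + np.sqrt(1.0 - rho_d**2) * rng.normal(size=n)
    cols["latent_percentile_scan"] = 100.0 * norm.cdf(z_scan)
    cols["latent_percentile_birth"] = 100.0 * norm.cdf(z_birth)

    sex_off = pop.sex_log_offset(is_male)
    w_scan = np.asarray(pop.scan_median_efw(ga_scan)) * np.exp(sex_off + pop.SCAN_LOG_SD * z_scan)

    jitter = np.exp(rng.normal(0.0, cfg.efw_jitter_sd, size=(n, 4)))
    ref = pop.reference_biometry(ga_scan)
    bpd0 = ref["bpd"] * jitter[:, 0]
    hc0 = ref["hc"] * jitter[:, 1]
    ac0 = ref["ac"] * jitter[:, 2]
    fl0 = ref["fl"] * jitter[:, 3]
    s = _solve_hadlock4_scale(w_scan, bpd0, hc0, ac0, fl0)
    cols["bpd_mm"] = np.round(bpd0 * s, 1)
    cols["hc_mm"] = np.round(hc0 * s, 1)
    cols["ac_mm"] = np.round(ac0 * s, 1)
    cols["fl_mm"] = np.round(fl0 * s, 1)

    w_birth = np.asarray(pop.birth_median_weight(ga_del)) * np.exp(
        sex_off + pop.BIRTH_LOG_SD * z_birth
    )
    cols["birthweight_g"] = np.rint(w_birth).astype(float)

    below_p10 = z_birth < norm.ppf(0.10)
    for comp in APO_COMPONENTS:
        p = cfg.apo_base_rates[comp] * np.where(below_p10, cfg.risk_ratio(comp), 1.0)
        cols[comp] = rng.uniform(size=n) < np.clip(p, 0.0, 1.0)

    frame = pd.DataFrame(cols)
    return frame[ANALYSIS_COLUMNS + LATENT_COLUMNS]


def frame_to_records(frame: pd.DataFrame) -> list[PregnancyRecord]:
    records = []
    has_latent = all(c in frame.columns for c in LATENT_COLUMNS)
    for row in frame.itertuples(index=False):
        d = row._asdict()
        for col in _BIOMETRY_COLUMNS:
            v = d.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                d[col] = None
        for col in _BOOL_COLUMNS:
            d[col] = bool(d[col])
        d["ga_scan_days"] = int(d["ga_scan_days"])
        d["ga_delivery_days"] = int(d["ga_delivery_days"])
        if not has_latent:
            d.setdefault("latent_percentile_scan", None)
            d.setdefault("latent_percentile_birth", None)
        records.append(PregnancyRecord(**d))
    return records


def cohort_to_frame(records: list[PregnancyRecord], include_latent: bool = False) -> pd.DataFrame:
    cols = ANALYSIS_COLUMNS + (LATENT_COLUMNS if include_latent else [])
    data = {c: [getattr(r, c) for r in records] for c in cols}
    return pd.DataFrame(data)


def generate_cohort(config: CohortConfig) -> list[PregnancyRecord]:
    """Generate ``config.n_records`` pregnancies; bit-reproducible given the seed."""
    if config.validate().n_records == 0:
        return []
    return frame_to_records(generate_frame(config))


# ---------------------------------------------------------------------------
# CSV I/O


def write_cohort(records: list[PregnancyRecord], path, include_latent: bool = False) -> None:
    """Write the cohort as UTF-8 CSV. Latent columns only with the debug flag."""
    cohort_to_frame(records, include_latent=include_latent).to_csv(path, index=False)


def read_cohort(path, validate: bool = True) -> list[PregnancyRecord]:
    """Read a cohort CSV; validates GA windows and positivity per record.

    Missing biometry cells are kept as ``None`` (the record stays in the
    cohort and is excluded only from standards whose formula needs the
    missing measurement).
    """
    try:
        frame = pd.read_csv(path, dtype={"record_id": str, "parity": str})
    except pd.errors.ParserError as e:
        raise ParseError(f"malformed cohort CSV {path}: {e}") from e
    missing = [c for c in ANALYSIS_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"cohort CSV {path} lacks required columns {missing}")
    records = frame_to_records(frame)
    if validate:
        for rec in records:
            validate_record(rec)
    return records
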