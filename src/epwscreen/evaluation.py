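"""Screening-performance statistics for EPW-based SGA prediction.

The percentile score convention throughout: a *lower* estimated percentile
weight is more SGA-like, so scores are negated internally and every reported
AUC is above 0.5 for an informative standard. Screen-positive means EPW
strictly below the threshold percentile, matching the strict "<10th
percentile" SGA definition.

Implements tie-aware (midrank) AUC with DeLong structural-component variance
and the paired DeLong test, sensitivity at fixed false-positive rates with
the realized threshold percentile, pooled two-proportion z-tests, logistic
odds ratios per 1% of EPW, APO detection by EPW<10, and the
ultrasound-delivery interval stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import AlignmentError, DegenerateClassesError, SeparationError, ValidationError

DEFAULT_FPRS = (5.0, 10.0, 15.0, 20.0)
INTERVAL_BUCKETS = {1: (8, 14), 2: (15, 21), 3: (22, 28), 4: (29, 35), 5: (36, 42), 6: (43, 49)}
APO_COLUMNS = ("apgar5_lt7", "instrumental_nrfs", "cesarean_nrfs", "ph_lt_710", "stillbirth", "any_apo")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding used for table percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise DegenerateClassesError("both outcome classes must be present")


def _as_arrays(percentiles, labels):
    s = np.asarray(percentiles, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise AlignmentError("percentiles and labels must be equal-length 1-D vectors")
    if np.isnan(s).any():
        raise ValidationError("percentile scores contain NaN")
    return s, y


# ---------------------------------------------------------------------------
# DeLong machinery


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank AUC and DeLong structural components.

    ``scores`` follow the higher-is-more-positive convention. Returns
    (auc, v10 per positive, v01 per negative).
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def _var_term(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if v.size > 1 else 0.0


def auc_delong(percentiles, labels) -> tuple[float, float, float]:
    """AUC of low-EPW for the positive label, with a DeLong 95% Wald CI."""
    s, y = _as_arrays(percentiles, labels)
    _check_classes(y)
    auc, v10, v01 = _structural_components(-s, y)
    var = _var_term(v10) / v10.size + _var_term(v01) / v01.size
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    return float(auc), float(max(auc - half, 0.0)), float(min(auc + half, 1.0))


def delong_paired_test(percentiles_a, percentiles_b, labels) -> float:
    """Two-sided p-value for equality of two correlated AUCs on the same records."""
    a, y = _as_arrays(percentiles_a, labels)
    b, y2 = _as_arrays(percentiles_b, labels)
    if a.shape != b.shape:
        raise AlignmentError("paired score vectors must have equal length")
    _check_classes(y)
    auc_a, v10a, v01a = _structural_components(-a, y)
    auc_b, v10b, v01b = _structural_components(-b, y)
    var = _var_term(v10a - v10b) / v10a.size + _var_term(v01a - v01b) / v01a.size
    diff = auc_a - auc_b
    if var <= 1e-300:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# sensitivity at fixed FPR


def sensitivity_at_fpr(
    percentiles, labels, target_fpr: float, ci_method: str = "wilson"
) -> tuple[float, tuple[float, float], float, float]:
    """(sensitivity %, (ci lo, ci hi), threshold percentile, achieved FPR %).

    The threshold is the largest candidate EPW cut ``t`` whose realized FPR
    (# negatives with EPW < t over all negatives) does not exceed the target;
    a sentinel above every observation makes the 100% target attainable.
    """
    s, y = _as_arrays(percentiles, labels)
    _check_classes(y)
    if not 0.0 < target_fpr <= 100.0:
        raise ValidationError(f"target_fpr must lie in (0, 100], got {target_fpr}")
    neg = np.sort(s[~y])
    pos = np.sort(s[y])
    candidates = np.unique(np.concatenate([[0.0], s, [100.0]]))
    fpr = np.searchsorted(neg, candidates, side="left") / neg.size
    ok = fpr <= target_fpr / 100.0 + 1e-12
    t = candidates[ok][-1]
    k = int(np.searchsorted(pos, t, side="left"))
    sens = 100.0 * k / pos.size
    lo, hi = proportion_confint(k, pos.size, alpha=0.05, method=ci_method)
    achieved = 100.0 * np.searchsorted(neg, t, side="left") / neg.size
    return float(sens), (100.0 * lo, 100.0 * hi), float(t), float(achieved)


# ---------------------------------------------------------------------------
# proportion and logistic tests


def two_proportion_test(k1: int, n1: int, k2: int, n2: int, continuity: bool = False) -> float:
    """Two-sided pooled-variance z-test for equality of two proportions."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValidationError(f"invalid counts: {k}/{n}")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 1.0
    diff = abs(p1 - p2)
    if continuity:
        diff = max(diff - 0.5 * (1.0 / n1 + 1.0 / n2), 0.0)
    return float(2.0 * norm.sf(diff / se))


def logistic_or_per_percent(percentiles, labels) -> tuple[float, float, float]:
    """Odds ratio (with Wald 95% CI) per +1 percentile point of EPW."""
    s, y = _as_arrays(percentiles, labels)
    _check_classes(y)
    x = sm.add_constant(s)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is re-raised as an error below
            fit = sm.Logit(y.astype(float), x).fit(
                method="newton", tol=1e-8, maxiter=100, disp=0
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise SeparationError(f"logistic fit failed: complete separation ({e})") from e
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (separation suspected)")
    slope = fit.params[1]
    se = fit.bse[1]
    if not np.isfinite(slope) or not np.isfinite(se):
        raise SeparationError("logistic fit produced non-finite estimates")
    z = 1.959963984540054
    return float(np.exp(slope)), float(np.exp(slope - z * se)), float(np.exp(slope + z * se))


# ---------------------------------------------------------------------------
# ScreenEval assembly


@dataclass(frozen=True)
class FprEntry:
    target_fpr: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    threshold_percentile: float
    achieved_fpr: float


@dataclass(frozen=True)
class ScreenEval:
    """AUC with CI plus sensitivity/threshold at each target FPR."""

    standard_id: str
    n_pos: int
    n_neg: int
    auc: float
    auc_ci: tuple[float, float]
    by_fpr: tuple[FprEntry, ...]

    def to_dict(self) -> dict:
        return {
            "standard_id": self.standard_id,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "by_fpr": [
                {
                    "target_fpr": e.target_fpr,
                    "sensitivity": e.sensitivity,
                    "sensitivity_ci": list(e.sensitivity_ci),
                    "threshold_percentile": e.threshold_percentile,
                    "achieved_fpr": e.achieved_fpr,
                }
                for e in self.by_fpr
            ],
        }


def screen_eval(
    percentiles, labels, standard_id: str = "", fprs=DEFAULT_FPRS, ci_method: str = "wilson"
) -> ScreenEval:
    s, y = _as_arrays(percentiles, labels)
    auc, lo, hi = auc_delong(s, y)
    entries = []
    for f in fprs:
        sens, ci, thr, ach = sensitivity_at_fpr(s, y, f, ci_method=ci_method)
        entries.append(FprEntry(f, sens, ci, thr, ach))
    return ScreenEval(
        standard_id=standard_id,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        auc=auc,
        auc_ci=(lo, hi),
        by_fpr=tuple(entries),
    )


# ---------------------------------------------------------------------------
# pairwise standard comparison (Table-4 style)


@dataclass(frozen=True)
class PairwiseComparison:
    standard_a: str
    standard_b: str
    auc_p: float
    sens_p: float
    apo_p: float


def pairwise_comparisons(
    epw_frame: pd.DataFrame,
    sga_labels,
    apo_labels,
    standard_ids,
    sens_fpr: float = 10.0,
) -> list[PairwiseComparison]:
    """All unordered pairs: DeLong AUC p, sensitivity-at-90%-specificity
    proportion p, and EPW<10 any-APO detection proportion p."""
    y = np.asarray(sga_labels, dtype=bool)
    apo = np.asarray(apo_labels, dtype=bool)
    n_apo = int(apo.sum())
    out = []
    for i, a in enumerate(standard_ids):
        for b in standard_ids[i + 1 :]:
            sa = epw_frame[f"pct_{a}"].to_numpy()
            sb = epw_frame[f"pct_{b}"].to_numpy()
            keep = ~(np.isnan(sa) | np.isnan(sb))
            auc_p = delong_paired_test(sa[keep], sb[keep], y[keep])
            ka = _sens_count(sa[keep], y[keep], sens_fpr)
            kb = _sens_count(sb[keep], y[keep], sens_fpr)
            npos = int(y[keep].sum())
            sens_p = two_proportion_test(ka, npos, kb, npos)
            det_a = int(((sa < 10.0) & apo)[keep].sum())
            det_b = int(((sb < 10.0) & apo)[keep].sum())
            apo_p = two_proportion_test(det_a, n_apo, det_b, n_apo) if n_apo else float("nan")
            out.append(PairwiseComparison(a, b, auc_p, sens_p, apo_p))
    return out


def _sens_count(percentiles, labels, target_fpr: float) -> int:
    sens, _, _, _ = sensitivity_at_fpr(percentiles, labels, target_fpr)
    return int(round(sens / 100.0 * labels.sum()))


# ---------------------------------------------------------------------------
# APO detection by EPW < 10


def apo_detection_by_epw10(
    epw_frame: pd.DataFrame, outcome_frame: pd.DataFrame, standard_ids
) -> pd.DataFrame:
    """Counts (and %) of APO cases detected by EPW<10 per standard.

    Rows: total cohort counts, the SGA-at-birth row, then one row per
    standard. Percentages use each APO component's total-cohort count as the
    denominator, rounded half-up to one decimal.
    """
    rows = {}
    totals = {c: int(outcome_frame[c].sum()) for c in APO_COLUMNS}
    rows["total_cohort"] = {c: (totals[c], 100.0) for c in APO_COLUMNS}
    sga = outcome_frame["sga"].to_numpy(dtype=bool)
    rows["sga_birth"] = _detection_row(sga, outcome_frame, totals)
    for sid in standard_ids:
        flag = epw_frame[f"pct_{sid}"].to_numpy() < 10.0
        rows[sid] = _detection_row(flag, outcome_frame, totals)
    table = pd.DataFrame(
        {
            c: {rid: row[c][0] for rid, row in rows.items()}
            for c in APO_COLUMNS
        }
    )
    pct = pd.DataFrame(
        {
            c: {rid: row[c][1] for rid, row in rows.items()}
            for c in APO_COLUMNS
        }
    )
    return table.join(pct, lsuffix="_n", rsuffix="_pct")


def _detection_row(flag: np.ndarray, outcome_frame: pd.DataFrame, totals) -> dict:
    out = {}
    for c in APO_COLUMNS:
        k = int((outcome_frame[c].to_numpy(dtype=bool) & flag).sum())
        pct = round_half_up(100.0 * k / totals[c], 1) if totals[c] else float("nan")
        out[c] = (k, pct)
    return out


# ---------------------------------------------------------------------------
# ultrasound-delivery interval strata


@dataclass
class IntervalStratum:
    """One week-bucket of the scan-to-delivery interval."""

    label: int
    day_range: tuple[int, int]
    n: int
    evals: dict = field(default_factory=dict)  # standard_id -> ScreenEval | None
    odds_ratios: dict = field(default_factory=dict)  # standard_id -> (or, lo, hi) | None
    not_evaluable_reason: str | None = None


def stratify_by_interval(
    cohort_frame: pd.DataFrame,
    epw_frame: pd.DataFrame,
    sga_labels,
    standard_ids,
    fprs=DEFAULT_FPRS,
) -> list[IntervalStratum]:
    """Per-week-bucket screening evaluation (intervals of 8-49 days).

    Records outside the declared buckets are excluded; a stratum with a
    single outcome class is reported as not-evaluable rather than erroring.
    """
    interval = (
        cohort_frame["ga_delivery_days"] - cohort_frame["ga_scan_days"]
    ).to_numpy()
    y = np.asarray(sga_labels, dtype=bool)
    out = []
    for label, (lo, hi) in INTERVAL_BUCKETS.items():
        mask = (interval >= lo) & (interval <= hi)
        stratum = IntervalStratum(label=label, day_range=(lo, hi), n=int(mask.sum()))
        ys = y[mask]
        if stratum.n == 0 or ys.all() or not ys.any():
            stratum.not_evaluable_reason = "degenerate outcome classes in stratum"
            out.append(stratum)
            continue
        for sid in standard_ids:
            s = epw_frame[f"pct_{sid}"].to_numpy()[mask]
            keep = ~np.isnan(s)
            if ys[keep].all() or not ys[keep].any():
                stratum.evals[sid] = None
                stratum.odds_ratios[sid] = None
                continue
            stratum.evals[sid] = screen_eval(s[keep], ys[keep], standard_id=sid, fprs=fprs)
            try:
                stratum.odds_ratios[sid] = logistic_or_per_percent(s[keep], ys[keep])
            except SeparationError:
                stratum.odds_ratios[sid] = None
        out.append(stratum)
    return out
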