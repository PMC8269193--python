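"""End-to-end pipeline: simulate/load -> EPW -> outcomes -> evaluate -> tables.

One :func:`run_pipeline` call produces a reproducible artifact set: the
cohort snapshot, the per-standard EPW table, a results JSON, CSV analogues of
the five report tables (descriptives, APO detection, AUC/sensitivity,
pairwise p-values, interval strata), and a manifest with the seed, parameter
file hashes, and exclusion tallies. Re-running with the same configuration
reproduces every numeric artifact byte-for-byte.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evaluation import (
    APO_COLUMNS,
    DEFAULT_FPRS,
    apo_detection_by_epw10,
    pairwise_comparisons,
    logistic_or_per_percent,
    round_half_up,
    screen_eval,
    stratify_by_interval,
)
from .outcomes import load_reference, outcome_frame
from .standards import epw_table, exclusion_tally, load_default_standards, load_standard
from .synthetic_cohort import (
    APO_COMPONENTS,
    CohortConfig,
    cohort_to_frame,
    generate_frame,
    read_cohort,
)

log = logging.getLogger("epwscreen")


def stage_seed(seed: int, stage: str) -> int:
    """Named substream seed below 2^31, stable across runs."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    out_dir: str
    seed: int = 0
    cohort_csv: str | None = None  # if None, simulate with cohort_config
    cohort_config: CohortConfig = field(default_factory=CohortConfig)
    standards_dir: str | None = None  # if None, bundled six standards
    reference_path: str | None = None  # if None, bundled synthetic reference
    fprs: tuple = DEFAULT_FPRS
    interval_analysis: bool = True
    log_level: str = "INFO"
    include_latent: bool = False

    def validate(self) -> "RunConfig":
        fprs = tuple(self.fprs)
        if len(set(fprs)) != len(fprs) or any(not 0 < f < 100 for f in fprs):
            raise ConfigurationError("fprs must be unique values in (0, 100)")
        if tuple(sorted(fprs)) != fprs:
            raise ConfigurationError("fprs must be sorted ascending")
        for name in ("cohort_csv", "standards_dir", "reference_path"):
            p = getattr(self, name)
            if p is not None and not os.path.exists(p):
                raise ConfigurationError(f"{name} path does not exist: {p}")
        return self


def _load_registry(cfg: RunConfig) -> dict:
    if cfg.standards_dir is None:
        return load_default_standards()
    paths = sorted(glob.glob(os.path.join(cfg.standards_dir, "*.json")))
    if not paths:
        raise ConfigurationError(f"no standard files found in {cfg.standards_dir}")
    registry = {}
    for p in paths:
        spec = load_standard(p)
        registry[spec.standard_id] = spec
    return registry


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    cfg = config.validate()
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- cohort -------------------------------------------------------------
    if cfg.cohort_csv is not None:
        records = read_cohort(cfg.cohort_csv)
        frame = cohort_to_frame(records, include_latent=False)
        log.info("loaded cohort: %d records from %s", len(frame), cfg.cohort_csv)
    else:
        sim_cfg = cfg.cohort_config.replace(seed=stage_seed(cfg.seed, "simulate"))
        frame = generate_frame(sim_cfg)
        log.info("simulated cohort: %d records (seed %d)", len(frame), sim_cfg.seed)
    cohort_path = out / "cohort.csv"
    cols = [c for c in frame.columns if cfg.include_latent or not c.startswith("latent_")]
    frame[cols].to_csv(cohort_path, index=False)

    # --- EPW ----------------------------------------------------------------
    registry = _load_registry(cfg)
    standard_ids = list(registry)
    epw = epw_table(frame, registry)
    epw_path = out / "epw.csv"
    epw.to_csv(epw_path, index=False)
    tally = exclusion_tally(epw)
    for sid, t in tally.items():
        log.info("standard %s: %d analyzed, %d excluded", sid, t["analyzed"], t["excluded"])

    # --- outcomes -----------------------------------------------------------
    reference = load_reference(cfg.reference_path)
    outcomes = outcome_frame(frame, reference)
    sga = outcomes["sga"].to_numpy(dtype=bool)
    log.info("SGA at birth: %d (%.1f%%)", sga.sum(), 100 * sga.mean())

    # --- evaluation ---------------------------------------------------------
    evals, odds = {}, {}
    for sid in standard_ids:
        s = epw[f"pct_{sid}"].to_numpy()
        keep = ~np.isnan(s)
        evals[sid] = screen_eval(s[keep], sga[keep], standard_id=sid, fprs=cfg.fprs)
        odds[sid] = logistic_or_per_percent(s[keep], sga[keep])
    pairs = pairwise_comparisons(epw, sga, outcomes["any_apo"], standard_ids)
    detection = apo_detection_by_epw10(epw, outcomes, standard_ids)
    strata = (
        stratify_by_interval(frame, epw, sga, standard_ids, fprs=cfg.fprs)
        if cfg.interval_analysis
        else []
    )

    results = {
        "n_records": int(len(frame)),
        "sga_rate_pct": round_half_up(100 * float(np.mean(sga)), 1),
        "screen_evals": {sid: ev.to_dict() for sid, ev in evals.items()},
        "odds_ratio_per_percent": {sid: list(o) for sid, o in odds.items()},
        "pairwise": [
            {
                "standard_a": p.standard_a,
                "standard_b": p.standard_b,
                "auc_p": p.auc_p,
                "sens_p": p.sens_p,
                "apo_p": p.apo_p,
            }
            for p in pairs
        ],
        "apo_detection": {
            str(rid): {c: row[c] for c in detection.columns} for rid, row in detection.iterrows()
        },
        "interval_strata": [
            {
                "label": st.label,
                "day_range": list(st.day_range),
                "n": st.n,
                "not_evaluable_reason": st.not_evaluable_reason,
                "evals": {
                    sid: (ev.to_dict() if ev is not None else None)
                    for sid, ev in st.evals.items()
                },
                "odds_ratios": {
                    sid: (list(o) if o is not None else None) for sid, o in st.odds_ratios.items()
                },
            }
            for st in strata
        ],
        "exclusions": tally,
    }
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results, indent=1, sort_keys=True) + "\n")

    # --- table analogues ----------------------------------------------------
    tables = {
        "table1_descriptives.csv": _table1(frame, epw, outcomes, standard_ids, cfg),
        "table2_apo_detection.csv": detection.reset_index(names="row"),
        "table3_auc_sensitivity.csv": _table3(evals),
        "table4_pairwise_p.csv": pd.DataFrame(results["pairwise"]),
        "table5_interval.csv": _table5(strata),
    }
    table_paths = {}
    for name, tbl in tables.items():
        p = out / name
        tbl.to_csv(p, index=False)
        table_paths[name] = str(p)

    manifest = {
        "seed": cfg.seed,
        "n_records": int(len(frame)),
        "standards": standard_ids,
        "exclusions": tally,
        "artifacts": {
            str(p.name): _sha256(p)
            for p in [cohort_path, epw_path, results_path] + [Path(v) for v in table_paths.values()]
        },
        "stage_seeds": {"simulate": stage_seed(cfg.seed, "simulate")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _fmt_median_iqr(x: pd.Series, nd: int = 1) -> str:
    q = np.percentile(x.dropna(), [50, 25, 75])
    return f"{round_half_up(q[0], nd)} ({round_half_up(q[1], nd)}-{round_half_up(q[2], nd)})"


def _count_pct(k: int, n: int) -> str:
    return f"{k} ({round_half_up(100 * k / n, 1)}%)"


def _table1(frame, epw, outcomes, standard_ids, cfg: RunConfig) -> pd.DataFrame:
    n = len(frame)
    rows = [("pregnancies_n", str(n))]
    rows.append(("maternal_age_yr", _fmt_median_iqr(frame["maternal_age_yr"])))
    rows.append(("maternal_bmi", _fmt_median_iqr(frame["maternal_bmi"])))
    rows.append(("maternal_height_cm", _fmt_median_iqr(frame["maternal_height_cm"], 0)))
    rows.append(("paternal_height_cm", _fmt_median_iqr(frame["paternal_height_cm"], 0)))
    for lvl in ("0", "1", "2+"):
        rows.append((f"parity_{lvl}", _count_pct(int((frame["parity"] == lvl).sum()), n)))
    for lvl in ("Caucasian", "Asian", "African"):
        rows.append((f"ethnicity_{lvl}", _count_pct(int((frame["ethnicity"] == lvl).sum()), n)))
    rows.append(("smoking", _count_pct(int(frame["smoker"].sum()), n)))
    rows.append(
        ("ga_scan_weeks", _fmt_median_iqr(frame["ga_scan_days"] / 7.0))
    )
    for col, label in (("efw_msuh_nc", "efw_hadlock_g"), ("efw_intergrowth21", "efw_stirnemann_g")):
        if col in epw.columns:
            rows.append((label, _fmt_median_iqr(epw[col], 0)))
    for sid in standard_ids:
        p = epw[f"pct_{sid}"].dropna()
        q = np.percentile(p, [50, 10, 90])
        rows.append(
            (
                f"percentile_{sid}_p50_p10_p90",
                f"{round_half_up(q[0], 1)} ({round_half_up(q[1], 1)}-{round_half_up(q[2], 1)})",
            )
        )
    rows.append(("ga_delivery_weeks", _fmt_median_iqr(frame["ga_delivery_days"] / 7.0)))
    rows.append(("birthweight_g", _fmt_median_iqr(frame["birthweight_g"], 0)))
    rows.append(("sga_lt_p10", _count_pct(int(outcomes["sga"].sum()), n)))
    for c in APO_COMPONENTS:
        rows.append((c, _count_pct(int(outcomes[c].sum()), n)))
    if cfg.cohort_config.any_apo_convention == "exclude_sga_records":
        mask = ~outcomes["sga"]
        rows.append(
            ("any_apo_excl_sga", _count_pct(int(outcomes.loc[mask, "any_apo"].sum()), int(mask.sum())))
        )
    else:
        rows.append(("any_apo", _count_pct(int(outcomes["any_apo"].sum()), n)))
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def _table3(evals) -> pd.DataFrame:
    rows = []
    for sid, ev in evals.items():
        row = {
            "standard_id": sid,
            "auc": round(ev.auc, 3),
            "auc_ci_low": round(ev.auc_ci[0], 3),
            "auc_ci_high": round(ev.auc_ci[1], 3),
        }
        for e in ev.by_fpr:
            tag = f"fpr{int(e.target_fpr)}"
            row[f"sens_{tag}"] = round_half_up(e.sensitivity, 1)
            row[f"sens_{tag}_ci_low"] = round_half_up(e.sensitivity_ci[0], 1)
            row[f"sens_{tag}_ci_high"] = round_half_up(e.sensitivity_ci[1], 1)
            row[f"thr_{tag}"] = round_half_up(e.threshold_percentile, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def _table5(strata) -> pd.DataFrame:
    rows = []
    for st in strata:
        for sid, ev in st.evals.items():
            if ev is None:
                continue
            row = {
                "standard_id": sid,
                "interval_weeks": st.label,
                "day_lo": st.day_range[0],
                "day_hi": st.day_range[1],
                "n": st.n,
                "auc": round(ev.auc, 3),
            }
            for e in ev.by_fpr:
                row[f"sens_fpr{int(e.target_fpr)}"] = round_half_up(e.sensitivity, 1)
            orr = st.odds_ratios.get(sid)
            if orr is not None:
                row["or_per_percent"] = round(orr[0], 4)
            rows.append(row)
    return pd.DataFrame(rows)
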