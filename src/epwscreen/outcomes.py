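"""SGA classification against a birthweight reference and APO composites.

Small-for-gestational-age (SGA) at birth is the analysis gold standard: a
birthweight strictly below the reference's 10th percentile for the delivery
GA (and newborn sex, when the reference is sex-specific). The adverse
perinatal outcome (APO) composite is the union of five component events;
SGA itself is never counted as an APO.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ParameterError, RangeError
from .synthetic_cohort import APO_COMPONENTS, PregnancyRecord

_REFERENCE_RESOURCE = "data/reference/synthetic_birthweight_reference.csv"


@dataclass(frozen=True)
class BirthweightReference:
    """10th-percentile birthweight grid over the delivery GA span.

    ``p10`` maps sex -> (ga_days array, weight array); use the key "pooled"
    for a sex-pooled reference.
    """

    p10: dict

    def __post_init__(self) -> None:
        if not self.p10:
            raise ParameterError("reference grid is empty")
        for sex, (ga, w) in self.p10.items():
            ga = np.asarray(ga, dtype=float)
            w = np.asarray(w, dtype=float)
            if ga.size < 2 or np.any(np.diff(ga) <= 0):
                raise ParameterError(f"reference grid for {sex!r} needs increasing GA nodes")
            if np.any(np.diff(w) <= 0):
                raise ParameterError(f"P10 weights for {sex!r} must increase with GA")
            self.p10[sex] = (ga, w)

    @property
    def sex_specific(self) -> bool:
        return "pooled" not in self.p10

    def span(self, sex: str) -> tuple[float, float]:
        ga, _ = self.p10[self._key(sex)]
        return float(ga[0]), float(ga[-1])

    def _key(self, sex: str) -> str:
        return sex if self.sex_specific else "pooled"

    def p10_at(self, ga_days, sex) -> np.ndarray:
        """Linearly GA-interpolated 10th-percentile weight (g)."""
        ga = np.asarray(ga_days, dtype=float)
        sexes = np.broadcast_to(np.asarray(sex), ga.shape) if ga.ndim else np.asarray(sex)
        out = np.empty_like(ga, dtype=float)
        if ga.ndim == 0:
            ga = ga[None]
            sexes = np.asarray([sexes])
            out = out[None]
        for key in np.unique(sexes):
            grid_ga, grid_w = self.p10[self._key(str(key))]
            if np.any((ga < grid_ga[0]) | (ga > grid_ga[-1])):
                raise RangeError(
                    f"delivery GA outside reference span [{grid_ga[0]:.0f}, {grid_ga[-1]:.0f}]"
                )
            m = sexes == key
            out[m] = np.interp(ga[m], grid_ga, grid_w)
        return out if out.size > 1 else float(out[0])


def reference_from_frame(frame: pd.DataFrame) -> BirthweightReference:
    need = {"ga_days", "sex", "level", "weight_g"}
    missing = need - set(frame.columns)
    if missing:
        raise ParameterError(f"reference grid missing columns {sorted(missing)}")
    p10_rows = frame[frame["level"] == 10]
    if p10_rows.empty:
        raise ParameterError("reference grid has no level-10 rows")
    p10 = {}
    for sex, grp in p10_rows.groupby("sex"):
        grp = grp.sort_values("ga_days")
        p10[str(sex)] = (grp["ga_days"].to_numpy(float), grp["weight_g"].to_numpy(float))
    return BirthweightReference(p10=p10)


def load_reference(path=None) -> BirthweightReference:
    """Load a reference grid CSV; defaults to the bundled synthetic grid."""
    if path is None:
        with resources.files("epwscreen").joinpath(_REFERENCE_RESOURCE).open() as fh:
            return reference_from_frame(pd.read_csv(fh))
    return reference_from_frame(pd.read_csv(path))


def classify_sga(birthweight_g, ga_delivery_days, sex, reference: BirthweightReference):
    """True iff birthweight is strictly below the interpolated P10 (equality
    is *not* SGA)."""
    cut = reference.p10_at(ga_delivery_days, sex)
    return np.asarray(birthweight_g, dtype=float) < cut


@dataclass(frozen=True)
class OutcomeFlags:
    sga: bool
    apgar5_lt7: bool
    instrumental_nrfs: bool
    cesarean_nrfs: bool
    ph_lt_710: bool
    stillbirth: bool
    any_apo: bool


def derive_outcomes(record: PregnancyRecord, reference: BirthweightReference) -> OutcomeFlags:
    comps = {c: bool(getattr(record, c)) for c in APO_COMPONENTS}
    return OutcomeFlags(
        sga=bool(
            classify_sga(record.birthweight_g, record.ga_delivery_days, record.fetal_sex, reference)
        ),
        any_apo=any(comps.values()),
        **comps,
    )


def outcome_frame(cohort_frame: pd.DataFrame, reference: BirthweightReference) -> pd.DataFrame:
    """Vectorized outcome flags for a whole cohort frame."""
    sga = classify_sga(
        cohort_frame["birthweight_g"].to_numpy(float),
        cohort_frame["ga_delivery_days"].to_numpy(float),
        cohort_frame["fetal_sex"].to_numpy(),
        reference,
    )
    out = pd.DataFrame({"record_id": cohort_frame["record_id"], "sga": np.asarray(sga, dtype=bool)})
    any_apo = np.zeros(len(cohort_frame), dtype=bool)
    for c in APO_COMPONENTS:
        flags = cohort_frame[c].to_numpy(dtype=bool)
        out[c] = flags
        any_apo |= flags
    out["any_apo"] = any_apo
    return out
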