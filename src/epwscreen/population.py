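"""Reference population model shared by the cohort generator and calibration.

This module pins down the internal "truth" the synthetic cohort is drawn from:
log-normal fetal-weight distributions at the 35-week scan and at delivery, a
small multiplicative sex effect, and reference biometry shapes that tie a
target Hadlock-4 weight back to a plausible BPD/HC/AC/FL quadruple.

All gestational ages are integer days internally (weeks appear only at I/O).
"""

from __future__ import annotations

import numpy as np

# --- scan-weight distribution (EFW scale, grams) ---------------------------
SCAN_ANCHOR_GA_DAYS = 246  # ~35+1
SCAN_MEDIAN_EFW_G = 2495.0  # pooled median Hadlock-4 EFW at the anchor GA
SCAN_GROWTH_RATE_PER_DAY = 0.0100  # d ln(weight)/d day near 35 weeks
SCAN_LOG_SD = 0.109  # SD of ln(EFW) at fixed GA and sex

# --- birthweight distribution (grams) ---------------------------------------
BIRTH_ANCHOR_GA_DAYS = 280
BIRTH_MEDIAN_G = 3310.0
_BIRTH_B = 17.904762  # g/day at the anchor
_BIRTH_C = -0.054421  # curvature (growth decelerates toward 42 weeks)
BIRTH_LOG_SD = 0.117  # SD of ln(birthweight) at fixed GA and sex

#: ln multiplier applied with sign +1 for males, -1 for females, both scales
SEX_LOG_EFFECT = 0.018

SCAN_GA_SPAN = (238, 258)  # 34+0 .. 36+6
DELIVERY_GA_SPAN = (259, 294)  # 37+0 .. 42+0

# --- reference biometry shape at the scan (mm) -------------------------------
# values at SCAN_ANCHOR_GA_DAYS and linear growth per day around it
REF_BIOMETRY_MM = {"bpd": 87.0, "hc": 318.0, "ac": 310.0, "fl": 67.0}
REF_BIOMETRY_SLOPE_MM_PER_DAY = {"bpd": 0.25, "hc": 0.80, "ac": 1.15, "fl": 0.22}

#: physiologic scaling envelope around the reference shape
BIOMETRY_SCALE_BOUNDS = (0.55, 1.60)


def scan_median_efw(ga_days):
    """Median Hadlock-4 EFW (g) at scan GA, pooled over sex."""
    ga = np.asarray(ga_days, dtype=float)
    return SCAN_MEDIAN_EFW_G * np.exp(SCAN_GROWTH_RATE_PER_DAY * (ga - SCAN_ANCHOR_GA_DAYS))


def birth_median_weight(ga_days):
    """Median birthweight (g) at delivery GA, pooled over sex."""
    ga = np.asarray(ga_days, dtype=float)
    x = ga - BIRTH_ANCHOR_GA_DAYS
    return BIRTH_MEDIAN_G + _BIRTH_B * x + _BIRTH_C * x**2


def sex_log_offset(is_male):
    """ln-scale weight offset: +SEX_LOG_EFFECT for males, - for females."""
    return np.where(np.asarray(is_male, dtype=bool), SEX_LOG_EFFECT, -SEX_LOG_EFFECT)


def reference_biometry(ga_days):
    """Reference biometry quadruple(s) in mm at the given scan GA(s).

    Returns a dict of arrays (or scalars) keyed bpd/hc/ac/fl.
    """
    ga = np.asarray(ga_days, dtype=float)
    return {
        m: REF_BIOMETRY_MM[m] + REF_BIOMETRY_SLOPE_MM_PER_DAY[m] * (ga - SCAN_ANCHOR_GA_DAYS)
        for m in ("bpd", "hc", "ac", "fl")
    }
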