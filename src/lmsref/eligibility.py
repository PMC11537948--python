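"""Inclusion/exclusion screening for the metabolically-healthy analysis sample.

A subject is retained only when every configured rule passes.  Thresholds
use the comparators exactly as published for this reference population:

* fasting glucose >= 100 mg/dL                       -> excluded
* total cholesterol >= 200 mg/dL                     -> excluded
* HDL cholesterol < 40 mg/dL (< 45 for post-pubertal girls, Tanner >= 4)
* triglycerides >= 100 mg/dL under age 10, >= 130 mg/dL from age 10
* blood pressure >= the 90th percentile for sex/age/height (rule applied
  only when an external percentile reference is injected)
* HOMA-IR (glucose*insulin/405, Matthews) > 3.5
* BMI z-score at or beyond +/-3

Missing required data is itself a violation (``incomplete_data``), never an
exception.  A separate robust within-band screen flags gross anthropometric
outliers for height, weight and BMI.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "CRITERIA",
    "homa_ir",
    "classify_eligibility",
    "anthropometric_outlier_filter",
]

log = logging.getLogger(__name__)

#: violation columns, in report order
CRITERIA = [
    "glucose", "total_chol", "hdl", "triglycerides",
    "blood_pressure", "homa_ir", "bmi_z",
    "incomplete_data", "anthropometric_outlier",
]

HOMA_IR_LIMIT = 3.5
GLUCOSE_LIMIT = 100.0
TOTAL_CHOL_LIMIT = 200.0
HDL_LIMIT = 40.0
HDL_LIMIT_POSTPUBERTAL_GIRLS = 45.0
TG_LIMIT_UNDER_10 = 100.0
TG_LIMIT_10_PLUS = 130.0
BMI_Z_LIMIT = 3.0
POSTPUBERTAL_TANNER = 4  # Tanner stage IV/V treated as post-pubertal

_MAD_CONSISTENCY = 1.4826   # MAD -> SD for normal data
ROBUST_Z_LIMIT = 4.0
_MIN_BAND_SIZE = 8


def homa_ir(glucose_mg_dl, insulin_uu_ml):
    """Homeostatic model assessment of insulin resistance.

    Matthews formula: fasting glucose (mg/dL) x fasting insulin (uU/mL) / 405.
    """
    g = np.asarray(glucose_mg_dl, float)
    i = np.asarray(insulin_uu_ml, float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("glucose and insulin must be > 0")
    out = g * i / 405.0
    return out if out.ndim else float(out)


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x)


def classify_eligibility(cohort: pd.DataFrame,
                         bp_reference: Callable | None = None
                         ) -> pd.DataFrame:
    """Evaluate every exclusion rule for each subject.

    Parameters
    ----------
    cohort : DataFrame
        One row per subject with the cohort column schema
        (:data:`lmsref.anthro.COHORT_COLUMNS`).
    bp_reference : callable, optional
        ``bp_reference(sex, age, height) -> (sbp_p90, dbp_p90)`` giving the
        90th blood-pressure percentiles.  When absent the blood-pressure
        rule is skipped (and logged), mirroring its plug-in status.

    Returns
    -------
    DataFrame indexed like ``cohort`` with one boolean column per criterion
    in :data:`CRITERIA` (except ``anthropometric_outlier``, handled by
    :func:`anthropometric_outlier_filter`) plus an ``eligible`` column that
    is True iff no violation fired.
    """
    if bp_reference is None:
        log.info("no blood-pressure percentile reference injected: "
                 "BP >= P90 rule skipped")
    required = ["glucose", "insulin", "total_chol", "hdl", "triglycerides",
                "bmi_z", "tanner", "age", "sex"]
    if bp_reference is not None:
        required += ["sbp", "dbp", "height"]

    out = []
    for _, r in cohort.iterrows():
        v = {c: False for c in CRITERIA if c != "anthropometric_outlier"}
        v["incomplete_data"] = any(_missing(r.get(c, np.nan)) for c in required)

        if not _missing(r.get("glucose")):
            v["glucose"] = r["glucose"] >= GLUCOSE_LIMIT
        if not _missing(r.get("total_chol")):
            v["total_chol"] = r["total_chol"] >= TOTAL_CHOL_LIMIT
        if not _missing(r.get("hdl")):
            postpub_girl = (str(r.get("sex")) == "female"
                            and not _missing(r.get("tanner"))
                            and r["tanner"] >= POSTPUBERTAL_TANNER)
            limit = HDL_LIMIT_POSTPUBERTAL_GIRLS if postpub_girl else HDL_LIMIT
            v["hdl"] = r["hdl"] < limit
        if not _missing(r.get("triglycerides")) and not _missing(r.get("age")):
            limit = TG_LIMIT_UNDER_10 if r["age"] < 10 else TG_LIMIT_10_PLUS
            v["triglycerides"] = r["triglycerides"] >= limit
        if (bp_reference is not None
                and not _missing(r.get("sbp")) and not _missing(r.get("dbp"))):
            sbp90, dbp90 = bp_reference(r.get("sex"), r.get("age"),
                                        r.get("height"))
            v["blood_pressure"] = (r["sbp"] >= sbp90) or (r["dbp"] >= dbp90)
        if not _missing(r.get("glucose")) and not _missing(r.get("insulin")):
            v["homa_ir"] = homa_ir(r["glucose"], r["insulin"]) > HOMA_IR_LIMIT
        if not _missing(r.get("bmi_z")):
            v["bmi_z"] = abs(r["bmi_z"]) >= BMI_Z_LIMIT

        v["eligible"] = not any(v.values())
        out.append(v)
    return pd.DataFrame(out, index=cohort.index)


def anthropometric_outlier_filter(cohort: pd.DataFrame) -> pd.Series:
    """Flag gross outliers for height, weight and BMI.

    Within each sex x 1-year age band, a subject is flagged when the robust
    z-score (median/MAD with the 1.4826 normal-consistency constant) of
    height, weight or BMI exceeds |4|.  Bands with fewer than 8 subjects
    are skipped with a warning (no flags).  Order-independent: flags depend
    only on band membership.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    flags = pd.Series(False, index=cohort.index)
    bmi = cohort["weight"] / (cohort["height"] / 100.0) ** 2
    band = cohort["age"].astype(float).apply(np.floor)
    for (sex, b), idx in cohort.groupby([cohort["sex"], band]).groups.items():
        if len(idx) < _MIN_BAND_SIZE:
            log.warning("band sex=%s age=%g has %d subjects (<%d): outlier "
                        "screen skipped", sex, b, len(idx), _MIN_BAND_SIZE)
            continue
        for values in (cohort.loc[idx, "height"], cohort.loc[idx, "weight"],
                       bmi.loc[idx]):
            med = values.median()
            mad = (values - med).abs().median() * _MAD_CONSISTENCY
            if mad == 0:
                # constant band: any deviation from the shared value is gross
                flagged = values != med
            else:
                flagged = (values - med).abs() / mad > ROBUST_Z_LIMIT
            flags.loc[idx] |= flagged
    return flags
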