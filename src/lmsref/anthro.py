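"""Body-composition quantities from raw anthropometry and device outputs.

Internal units are fixed throughout the package: mass in kg, height and
circumferences in cm, skinfolds in mm, age in decimal years.  Indices
(FMI, FFMI) divide a component mass in kg by height in metres squared.

Cohorts are plain pandas DataFrames, one row per subject, with the column
schema in :data:`COHORT_COLUMNS`; missing values are NaN (empty fields in
CSV).  :func:`derive_body_composition` turns such a cohort into a long
table of per-subject, per-method body-composition rows.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "slaughter_fm_percent",
    "fat_mass_kg",
    "fat_free_mass_kg",
    "mass_index",
    "average_bia",
    "smm_lee_poortmans",
    "derive_body_composition",
]

#: Cohort CSV column schema.  ``bia{k}_fm_kg`` / ``bia{k}_ffm_kg`` hold the
#: k-th MF-BIA device's estimates (k = 1..3; NaN where a device was not
#: used).  ``dxa_*`` columns are optional.
COHORT_COLUMNS = [
    "id", "sex", "age", "weight", "height",
    "triceps_sf", "calf_sf", "thigh_sf",
    "waist", "hip", "arm_circ", "thigh_circ", "calf_circ",
    "bia1_fm_kg", "bia1_ffm_kg", "bia2_fm_kg", "bia2_ffm_kg",
    "bia3_fm_kg", "bia3_ffm_kg",
    "dxa_fm_kg", "dxa_lm_kg", "dxa_bmc_kg",
    "glucose", "total_chol", "hdl", "ldl", "triglycerides", "insulin",
    "sbp", "dbp", "tanner", "bmi_z",
]

# Slaughter two-site (triceps + calf) coefficients: slope, intercept
_SLAUGHTER = {"male": (0.735, 1.0), "female": (0.610, 5.1)}


def slaughter_fm_percent(sex, triceps_mm, calf_mm):
    """Percent body fat from the Slaughter triceps+calf skinfold equation.

    males:   %fat = 0.735*(triceps + calf) + 1.0
    females: %fat = 0.610*(triceps + calf) + 5.1
    """
    triceps = np.asarray(triceps_mm, float)
    calf = np.asarray(calf_mm, float)
    if np.any(triceps < 0) or np.any(calf < 0):
        raise ValueError("skinfolds must be >= 0 mm")
    sex_arr = np.asarray(sex)
    if sex_arr.ndim == 0:
        slope, intercept = _slaughter_coeffs(str(sex))
    else:
        slope = np.array([_slaughter_coeffs(s)[0] for s in sex_arr])
        intercept = np.array([_slaughter_coeffs(s)[1] for s in sex_arr])
    pct = slope * (triceps + calf) + intercept
    if np.any(pct >= 100):
        raise ValueError("estimated fat fraction >= 100%: implausible skinfolds")
    return pct if pct.ndim else float(pct)


def _slaughter_coeffs(sex: str):
    try:
        return _SLAUGHTER[sex.lower()]
    except KeyError:
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}") from None


def fat_mass_kg(fm_pct, weight_kg):
    """Total fat mass: fraction of fat times body weight."""
    fm_pct = np.asarray(fm_pct, float)
    weight = np.asarray(weight_kg, float)
    if np.any((fm_pct < 0) | (fm_pct >= 100)):
        raise ValueError("fm_pct must lie in [0, 100)")
    if np.any(weight <= 0):
        raise ValueError("weight must be > 0 kg")
    out = fm_pct / 100.0 * weight
    return out if out.ndim else float(out)


def fat_free_mass_kg(weight_kg, fm_kg):
    """Fat-free mass: body weight minus fat mass."""
    weight = np.asarray(weight_kg, float)
    fm = np.asarray(fm_kg, float)
    if np.any((fm < 0) | (fm > weight)):
        raise ValueError("fat mass must lie in [0, weight]")
    out = weight - fm
    return out if out.ndim else float(out)


def mass_index(mass_kg, height_cm):
    """Component mass (kg) divided by height (m) squared."""
    mass = np.asarray(mass_kg, float)
    height = np.asarray(height_cm, float)
    if np.any(height <= 0):
        raise ValueError("height must be > 0 cm")
    out = mass / (height / 100.0) ** 2
    return out if out.ndim else float(out)


def average_bia(estimates: Sequence[float]):
    """Arithmetic mean of the available MF-BIA device estimates (1-3)."""
    vals = np.asarray([v for v in estimates if np.isfinite(v)], float)
    if vals.size == 0:
        raise ValueError("no MF-BIA device estimates available")
    if vals.size > 3:
        raise ValueError("at most 3 MF-BIA devices are supported")
    return float(vals.mean())


def smm_lee_poortmans(record: Mapping, coeffs: Mapping[str, float] | None = None):
    """Skeletal muscle mass from an injected linear coefficient set.

    The coefficient values come from the literature reference that defines
    the equation and are deliberately not bundled; ``coeffs`` maps field
    names of ``record`` to linear coefficients, plus an optional
    ``"intercept"``.  Returns None when no coefficient set is configured.
    """
    if coeffs is None:
        return None
    total = float(coeffs.get("intercept", 0.0))
    for field, beta in coeffs.items():
        if field == "intercept":
            continue
        value = record.get(field) if hasattr(record, "get") else record[field]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"field {field!r} required by the SMM coefficient "
                             "set is missing")
        total += float(beta) * float(value)
    return total


def _row_bia_mean(row: pd.Series, what: str) -> float:
    cols = [f"bia{k}_{what}" for k in (1, 2, 3)]
    vals = [row[c] for c in cols if c in row.index and np.isfinite(row[c])]
    return float(np.mean(vals)) if vals else np.nan


def derive_body_composition(cohort: pd.DataFrame,
                            smm_coeffs: Mapping[str, float] | None = None
                            ) -> pd.DataFrame:
    """Per-subject, per-method body-composition table.

    Produces one row per subject and available method (SF, MFBIA, DXA) with
    columns ``id, sex, age, method, fm_pct, fm_kg, ffm_kg, fmi, ffmi``
    (plus ``smm_kg`` when an SMM coefficient set is injected).

    For SF and MFBIA, fat-free mass is weight minus fat mass, so the two
    components close on body weight exactly.  For DXA, fat-free mass is
    lean mass plus bone mineral content; DXA components are measured, not
    derived from weight, so closure is not enforced.
    """
    rows = []
    for _, r in cohort.iterrows():
        base = {"id": r["id"], "sex": r["sex"], "age": r["age"]}
        w, h = r["weight"], r["height"]
        # skinfolds
        if np.isfinite(r.get("triceps_sf", np.nan)) and np.isfinite(r.get("calf_sf", np.nan)):
            pct = slaughter_fm_percent(r["sex"], r["triceps_sf"], r["calf_sf"])
            fm = fat_mass_kg(pct, w)
            ffm = fat_free_mass_kg(w, fm)
            row = dict(base, method="SF", fm_pct=pct, fm_kg=fm, ffm_kg=ffm,
                       fmi=mass_index(fm, h), ffmi=mass_index(ffm, h))
            if smm_coeffs is not None:
                row["smm_kg"] = smm_lee_poortmans(r, smm_coeffs)
            rows.append(row)
        # MF-BIA: mean over available devices, FFM closed on weight
        fm_bia = _row_bia_mean(r, "fm_kg")
        if np.isfinite(fm_bia):
            ffm_bia = fat_free_mass_kg(w, fm_bia)
            rows.append(dict(base, method="MFBIA", fm_pct=100.0 * fm_bia / w,
                             fm_kg=fm_bia, ffm_kg=ffm_bia,
                             fmi=mass_index(fm_bia, h),
                             ffmi=mass_index(ffm_bia, h)))
        # DXA: FFM = lean + bone mineral content
        if np.isfinite(r.get("dxa_fm_kg", np.nan)) and np.isfinite(r.get("dxa_lm_kg", np.nan)):
            fm_dxa = r["dxa_fm_kg"]
            bmc = r.get("dxa_bmc_kg", 0.0)
            bmc = bmc if np.isfinite(bmc) else 0.0
            ffm_dxa = r["dxa_lm_kg"] + bmc
            rows.append(dict(base, method="DXA", fm_pct=100.0 * fm_dxa / w,
                             fm_kg=fm_dxa, ffm_kg=ffm_dxa,
                             fmi=mass_index(fm_dxa, h),
                             ffmi=mass_index(ffm_dxa, h)))
    return pd.DataFrame(rows)
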