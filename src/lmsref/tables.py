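"""Centile tables: generation from fitted curves, reading/writing published
LMS tables, scoring individuals against them, and internal consistency
checks.

Table format is delimited text with header ``age,L,M,S[,P1,P3,...]``:
one row per tabulated age, L/M/S the BCCG parameters at that age, optional
centile columns named ``P<level>``.  Packaged reference tables (pediatric
fat-mass index and fat-free-mass index by skinfolds, MF-BIA and DXA, per
sex, ages 5-18 in half-year steps) are available through
:func:`load_reference_table`.

Scoring interpolates L, M and S linearly between bracketing table ages —
the convention used with published growth references — then applies the
LMS z-score transform; no extrapolation outside the tabulated range.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from . import bccg

__all__ = [
    "DEFAULT_LEVELS",
    "make_centile_table",
    "read_lms_table",
    "write_lms_table",
    "load_reference_table",
    "list_reference_tables",
    "interpolate_lms",
    "zscore_against_table",
    "check_table_consistency",
]

#: centile levels published for this reference (percent)
DEFAULT_LEVELS = (1, 3, 5, 15, 25, 50, 75, 85, 95, 97, 99)

#: default tabulation ages: 5 to 18 years in half-year steps
DEFAULT_AGES = tuple(np.arange(5.0, 18.0 + 1e-9, 0.5))

_REQUIRED = ["age", "L", "M", "S"]


def make_centile_table(curve, ages=DEFAULT_AGES, levels=DEFAULT_LEVELS,
                       step=None) -> pd.DataFrame:
    """Centile table from a fitted LMS curve (an ``LMSRegressor``).

    ``cell(age, p) = value_from_z(Phi^-1(p/100), (L,M,S)(age))``.  The P50
    column equals M by construction.  ``step`` overrides the age grid with
    ``arange(min(ages), max(ages), step)`` (the reference supports both
    0.5- and 0.25-year steps).
    """
    ages = np.asarray(ages, float)
    if step is not None:
        ages = np.arange(ages.min(), ages.max() + 1e-9, step)
    L, M, S = curve.predict_params(ages)
    out = pd.DataFrame({"age": ages, "L": L, "M": M, "S": S})
    for p in levels:
        z = stats.norm.ppf(p / 100.0)
        out[f"P{p}"] = bccg.value_from_z(z, (L, M, S)) if p != 50 else M
    return out


def read_lms_table(path_or_buf) -> pd.DataFrame:
    """Read an LMS table CSV (``age,L,M,S[,P...]``), validating its shape.

    Unicode minus signs are normalized to ASCII.  Raises ``ValueError``
    naming the offending row/column for missing columns or non-increasing
    ages.
    """
    df = pd.read_csv(path_or_buf, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"LMS table missing required column(s): {missing}")
    for c in df.columns:
        df[c] = pd.to_numeric(df[c].str.replace("−", "-", regex=False))
    ages = df["age"].to_numpy()
    bad = np.flatnonzero(np.diff(ages) <= 0)
    if bad.size:
        # +3: header line, 0-based index, and the second row of the pair
        raise ValueError(f"ages must be strictly increasing; violated at row "
                         f"{bad[0] + 3} (age {ages[bad[0] + 1]:g})")
    if (df["M"] <= 0).any() or (df["S"] <= 0).any():
        row = int(np.flatnonzero((df["M"] <= 0) | (df["S"] <= 0))[0]) + 2
        raise ValueError(f"M and S must be > 0; violated at row {row}")
    return df


def write_lms_table(table: pd.DataFrame, path) -> None:
    """Write an LMS table to CSV (lossless round-trip with read)."""
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"LMS table missing required column(s): {missing}")
    table.to_csv(path, index=False)


def list_reference_tables() -> list[str]:
    """Names of the packaged reference tables."""
    pkg = resources.files("lmsref") / "data"
    return sorted(p.name[:-4] for p in pkg.iterdir() if p.name.endswith(".csv"))


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a packaged reference table by name, e.g. ``fmi_dxa_female``.

    Names follow ``{variable}_{method}_{sex}`` with variable in
    {fmi, ffmi}, method in {sf, mfbia, dxa}, sex in {female, male}.
    """
    path = resources.files("lmsref") / "data" / f"{name}.csv"
    if not path.is_file():
        raise KeyError(f"no packaged table {name!r}; available: "
                       f"{list_reference_tables()}")
    with path.open() as fh:
        return read_lms_table(fh)


def interpolate_lms(table: pd.DataFrame, age) -> bccg.BCCGParams:
    """L, M, S at ``age``, linearly interpolated between bracketing rows.

    At a tabulated age the tabulated values are returned exactly.  Refuses
    ages outside the table with a hint to the nearest tabulated age.
    """
    ages = table["age"].to_numpy(float)
    a = np.asarray(age, float)
    if np.any((a < ages[0]) | (a > ages[-1])):
        nearest = ages[np.argmin(np.abs(ages - float(np.atleast_1d(a)[0])))]
        raise ValueError(
            f"age outside the table range [{ages[0]:g}, {ages[-1]:g}] "
            f"(nearest tabulated age: {nearest:g}); no extrapolation")
    L = np.interp(a, ages, table["L"].to_numpy(float))
    M = np.interp(a, ages, table["M"].to_numpy(float))
    S = np.interp(a, ages, table["S"].to_numpy(float))
    if np.ndim(a) == 0:
        return bccg.BCCGParams(float(L), float(M), float(S))
    return bccg.BCCGParams(L, M, S)


def zscore_against_table(value, age, table: pd.DataFrame) -> dict:
    """z-score and centile of a measurement against a published LMS table.

    Returns ``{"z": ..., "centile": ...}`` with centile = 100*Phi(z).
    """
    value = np.asarray(value, float)
    if np.any(value <= 0):
        raise ValueError("measurement must be > 0")
    params = interpolate_lms(table, age)
    z = bccg.z_from_value(value, params)
    centile = 100.0 * stats.norm.cdf(z)
    if np.ndim(z) == 0:
        return {"z": float(z), "centile": float(centile)}
    return {"z": z, "centile": centile}


def check_table_consistency(table: pd.DataFrame) -> dict:
    """Recompute every centile cell from its row's L/M/S and report deviations.

    For each centile column ``P<p>`` the signed deviation
    ``printed - recomputed`` is reported per cell, along with the maximum
    absolute deviation per row and over the whole table.  Printed tables
    round centiles to 2 decimals from 3-decimal parameters, so internally
    consistent rows deviate by at most ~0.02; larger deviations indicate
    the printed centiles and printed parameters disagree.  The checker
    reports, it does not repair.

    Returns ``{"deviation": DataFrame, "row_max": Series, "max_abs": float}``.
    """
    levels = [int(c[1:]) for c in table.columns if c.startswith("P")]
    if not levels:
        raise ValueError("table has no centile columns to check")
    dev = pd.DataFrame(index=table.index)
    L = table["L"].to_numpy(float)
    M = table["M"].to_numpy(float)
    S = table["S"].to_numpy(float)
    for p in levels:
        z = stats.norm.ppf(p / 100.0)
        recomputed = bccg.value_from_z(z, (L, M, S))
        dev[f"P{p}"] = table[f"P{p}"].to_numpy(float) - recomputed
    row_max = dev.abs().max(axis=1)
    return {"deviation": dev, "row_max": row_max,
            "max_abs": float(row_max.max())}
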