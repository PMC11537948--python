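"""End-to-end orchestration: derive body composition, screen the sample,
fit LMS curves per sex/variable/method, and tabulate centiles, with a
reproducibility manifest.

Everything in and out is plain text: cohorts and tables as CSV, curves and
the manifest as JSON.  Re-running with identical inputs, config and seed
reproduces identical outputs byte for byte (the manifest records no wall
clock by default for exactly that reason; pass ``include_timestamp=True``
to add one).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anthro import derive_body_composition
from .eligibility import (CRITERIA, anthropometric_outlier_filter,
                          classify_eligibility)
from .fitting import FitConfig, fit_lms
from .tables import DEFAULT_AGES, DEFAULT_LEVELS, make_centile_table

__all__ = ["run_pipeline", "compare_curves", "PipelineError"]

log = logging.getLogger(__name__)

#: variables the pipeline fits, as columns of the derived BC table
VARIABLES = ("fmi", "ffmi")
METHODS = ("SF", "MFBIA", "DXA")
_MIN_FIT_N = 50


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cohort, outdir, config: FitConfig | None = None,
                 bp_reference=None, seed: int = 0,
                 ages=DEFAULT_AGES, levels=DEFAULT_LEVELS,
                 variables=VARIABLES, methods=METHODS,
                 include_timestamp: bool = False) -> dict:
    """Derive -> filter -> fit -> tabulate, writing all outputs to ``outdir``.

    Parameters
    ----------
    cohort : DataFrame or path to a cohort CSV.
    outdir : output directory (created if needed).
    config : FitConfig for every fit (default: GCV-selected smoothing).
    bp_reference : optional blood-pressure percentile plug-in.
    seed : recorded in the manifest (the pipeline itself is deterministic).

    Returns the manifest dict; writes per-stratum ``curve_*.json`` and
    ``table_*.csv``, ``eligible.csv``, ``violations.csv`` and
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or FitConfig()

    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "thresholds": {
            "glucose": ">= 100 mg/dL", "total_chol": ">= 200 mg/dL",
            "hdl": "< 40 mg/dL (< 45 post-pubertal girls)",
            "triglycerides": ">= 100 mg/dL under 10 y, >= 130 mg/dL 10-19 y",
            "blood_pressure": ">= P90 (skipped unless reference injected)",
            "homa_ir": "> 3.5", "bmi_z": "|z| >= 3",
        },
        "counts": {},
    }
    if include_timestamp:
        import datetime
        manifest["timestamp"] = datetime.datetime.now().isoformat()

    # ---- load ------------------------------------------------------------
    if isinstance(cohort, (str, Path)):
        manifest["input"] = {"path": str(cohort), "sha256": _sha256(cohort)}
        cohort = pd.read_csv(cohort)
    else:
        manifest["input"] = {"path": None, "sha256": None}
    n_input = len(cohort)
    manifest["counts"]["input"] = n_input
    log.info("pipeline: %d input subjects", n_input)

    # ---- derive ----------------------------------------------------------
    try:
        bc = derive_body_composition(cohort)
    except Exception as err:
        raise PipelineError(f"derive stage failed: {err}") from err

    # ---- eligibility + outlier screens ----------------------------------
    try:
        verdict = classify_eligibility(cohort, bp_reference)
        outliers = anthropometric_outlier_filter(cohort)
    except Exception as err:
        raise PipelineError(f"filter stage failed: {err}") from err
    verdict["anthropometric_outlier"] = outliers
    verdict["eligible"] &= ~outliers
    n_incomplete = int(verdict["incomplete_data"].sum())
    n_outlier = int((outliers & ~verdict["incomplete_data"]).sum())
    n_eligible = int(verdict["eligible"].sum())
    n_excluded = n_input - n_eligible - n_outlier - n_incomplete
    manifest["counts"].update(eligible=n_eligible, excluded=n_excluded,
                              outliers=n_outlier, incomplete=n_incomplete)
    for crit in CRITERIA:
        if crit in verdict:
            manifest["counts"][f"violations_{crit}"] = int(verdict[crit].sum())
    log.info("filter: %d eligible / %d excluded / %d outliers / %d incomplete",
             n_eligible, n_excluded, n_outlier, n_incomplete)

    report = pd.concat([cohort[["id"]], verdict], axis=1)
    report.to_csv(outdir / "violations.csv", index=False)
    eligible_ids = cohort.loc[verdict["eligible"], "id"]
    cohort.loc[verdict["eligible"]].to_csv(outdir / "eligible.csv", index=False)
    bc = bc[bc["id"].isin(set(eligible_ids))]

    # ---- fit + tabulate per sex/variable/method --------------------------
    manifest["strata"] = {}
    for sex in ("female", "male"):
        for method in methods:
            for var in variables:
                sub = bc[(bc["sex"] == sex) & (bc["method"] == method)]
                name = f"{var}_{method.lower()}_{sex}"
                if len(sub) < _MIN_FIT_N:
                    raise PipelineError(
                        f"fit stage: insufficient eligible subjects for "
                        f"{name} (n={len(sub)} < {_MIN_FIT_N})")
                try:
                    est = fit_lms(sub["age"].to_numpy(),
                                  sub[var].to_numpy(), config)
                except Exception as err:
                    raise PipelineError(f"fit stage failed for {name}: {err}"
                                        ) from err
                est.save(outdir / f"curve_{name}.json",
                         sex=sex, variable=var.upper(), method=method)
                lo, hi = est.age_range_
                grid = np.asarray([a for a in ages if lo <= a <= hi], float)
                table = make_centile_table(est, grid, levels)
                table.to_csv(outdir / f"table_{name}.csv", index=False,
                             float_format="%.6g")
                manifest["strata"][name] = {
                    "n": int(len(sub)), "edf": est.edf_,
                    "deviance": est.deviance_, "lambda": est.lambda_,
                    "table_rows": int(len(table)),
                }
                log.info("fitted %s: n=%d deviance=%.1f", name, len(sub),
                         est.deviance_)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def compare_curves(table_a: pd.DataFrame, table_b: pd.DataFrame
                   ) -> pd.DataFrame:
    """Per-age differences between two centile tables on shared ages.

    Returns a frame with the median (M) difference and ratio per shared
    age, plus differences for every centile level both tables share.
    Refuses disjoint age ranges.
    """
    shared = sorted(set(table_a["age"]).intersection(table_b["age"]))
    if not shared:
        raise ValueError("tables have disjoint age grids: nothing to compare")
    a = table_a.set_index("age").loc[shared]
    b = table_b.set_index("age").loc[shared]
    out = pd.DataFrame(index=pd.Index(shared, name="age"))
    out["median_diff"] = a["M"] - b["M"]
    out["median_ratio"] = a["M"] / b["M"]
    for col in a.columns:
        if col.startswith("P") and col in b.columns:
            out[f"{col}_diff"] = a[col] - b[col]
    return out.reset_index()
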