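"""Synthetic cross-sectional cohorts with the statistical structure the
reference-construction pipeline assumes.

The generator emulates a school-age body-composition survey: ages uniform
over 4-20.9 years (the recruitment design aimed at a flat ~62 subjects per
year of age and sex), DXA fat-mass index and fat-free-mass index drawn from
BCCG distributions whose age-varying L/M/S truth curves linearly
interpolate the packaged female DXA reference tables, body weight closed on
the DXA components, skinfolds back-derived from the Slaughter equation,
up to three MF-BIA devices with multiplicative noise around the DXA fat
mass, and fasting biochemistry drawn healthy by construction except where a
violation is deliberately planted.  Every record carries generator-truth
violation labels, so the eligibility filter can be checked against them
exactly: healthy draws are clipped strictly inside every threshold and
planted draws strictly beyond it.

Violations are planted independently per criterion; the default marginal
rate is calibrated so that about 21% of subjects carry at least one
exclusion criterion, matching the exclusion fraction such surveys observe.

All randomness flows from one ``numpy`` Generator seeded by the spec, with
draws in a fixed documented order, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d

from . import bccg, tables
from .anthro import _SLAUGHTER, mass_index
from .eligibility import (CRITERIA, classify_eligibility,
                          anthropometric_outlier_filter,
                          HDL_LIMIT, HDL_LIMIT_POSTPUBERTAL_GIRLS,
                          POSTPUBERTAL_TANNER, TG_LIMIT_10_PLUS,
                          TG_LIMIT_UNDER_10)

__all__ = ["TruthCurves", "SyntheticCohortSpec", "SyntheticCohort",
           "synthetic_bp_reference", "generate_cohort", "recovery_experiment"]

#: criteria the generator can plant (biochemical/clinical rules)
PLANTABLE = ["glucose", "total_chol", "hdl", "triglycerides",
             "blood_pressure", "homa_ir", "bmi_z"]

# marginal per-criterion rate giving P(any of 7) ~= 0.21
_DEFAULT_RATE = 1.0 - (1.0 - 0.21) ** (1.0 / len(PLANTABLE))


class TruthCurves:
    """Age-varying truth (L, M, S), linear interpolation of a reference table.

    Outside the tabulated age span the end segments are extended linearly
    (the cohort covers 4-20.9 y while published rows span 5-18 y); M and S
    are floored at small positive values to stay in the BCCG domain.
    """

    def __init__(self, table: pd.DataFrame):
        ages = table["age"].to_numpy(float)
        self._f = {
            k: interp1d(ages, table[k].to_numpy(float), kind="linear",
                        fill_value="extrapolate", assume_sorted=True)
            for k in ("L", "M", "S")
        }
        self.age_span = (float(ages[0]), float(ages[-1]))

    def params(self, age) -> bccg.BCCGParams:
        age = np.asarray(age, float)
        L = self._f["L"](age)
        M = np.maximum(self._f["M"](age), 1e-3)
        S = np.maximum(self._f["S"](age), 1e-3)
        return bccg.BCCGParams(L, M, S)

    def raw(self, age):
        """Interpolated (L, M, S) without the positivity floor (validation)."""
        age = np.asarray(age, float)
        return self._f["L"](age), self._f["M"](age), self._f["S"](age)


def synthetic_bp_reference(sex, age, height=None):
    """Synthetic 90th-percentile blood-pressure reference (plug-in stand-in).

    A deliberately simple linear-in-age rule used by the generator and the
    tests; it is *not* the Expert Panel reference, which users inject from
    external tables.  Returns ``(sbp_p90, dbp_p90)`` in mmHg.
    """
    age = np.asarray(age, float)
    sbp90 = 104.0 + 1.1 * (age - 4.0)
    dbp90 = 68.0 + 0.55 * (age - 4.0)
    if np.ndim(age) == 0:
        return float(sbp90), float(dbp90)
    return sbp90, dbp90


def _default_rates() -> dict:
    return {c: _DEFAULT_RATE for c in PLANTABLE}


@dataclass
class SyntheticCohortSpec:
    """Full generative description of a synthetic cohort.

    ``fmi_truth`` / ``ffmi_truth`` name packaged reference tables (or pass
    DataFrames) whose L/M/S columns become the truth curves.  Violation
    rates are marginal per-criterion planting probabilities; the defaults
    give an overall ~21% exclusion fraction.  ``device_cv`` is the
    multiplicative coefficient of variation of each MF-BIA device around
    the DXA fat mass (default 2%); ``skinfold_cv`` the relative noise on
    the skinfold-derived fat percentage.
    """

    n: int = 2000
    sex_ratio: float = 0.5              # fraction female
    age_range: tuple = (4.0, 20.9)
    fmi_truth: object = "fmi_dxa_female"
    ffmi_truth: object = "ffmi_dxa_female"
    violation_rates: dict = field(default_factory=_default_rates)
    incomplete_rate: float = 0.0
    outlier_rate: float = 0.0
    device_cv: float = 0.02
    n_devices: int = 3
    skinfold_cv: float = 0.08
    height_cv: float = 0.035
    seed: int = 0

    def __post_init__(self):
        for c, r in self.violation_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"violation rate for {c!r} outside [0, 1]")
        if not 1 <= self.n_devices <= 3:
            raise ValueError("n_devices must be 1-3")

    def truth(self, which: str) -> TruthCurves:
        src = self.fmi_truth if which == "fmi" else self.ffmi_truth
        table = tables.load_reference_table(src) if isinstance(src, str) else src
        tc = TruthCurves(table)
        lo, hi = self.age_range
        _, M, S = tc.raw(np.linspace(lo, hi, 50))
        if np.any(M <= 0) or np.any(S <= 0):
            raise ValueError("truth curves not positive over the age range")
        return tc


@dataclass
class SyntheticCohort:
    """Generated records plus the generator's truth."""

    records: pd.DataFrame
    truth_labels: pd.DataFrame      # per-subject planted violation flags
    fmi_truth: TruthCurves
    ffmi_truth: TruthCurves
    spec: SyntheticCohortSpec

    @property
    def bp_reference(self):
        return synthetic_bp_reference


def _mean_height(age, is_female):
    """Smooth reference height (cm) by age/sex for the covariate layer."""
    knots_f = [(4, 102), (8, 127), (12, 150), (15, 160), (18, 162), (21, 163)]
    knots_m = [(4, 103), (8, 128), (12, 149), (15, 168), (18, 174), (21, 175)]
    hf = np.interp(age, *zip(*knots_f))
    hm = np.interp(age, *zip(*knots_m))
    return np.where(is_female, hf, hm)


def generate_cohort(spec: SyntheticCohortSpec | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort per ``spec`` (deterministic under a fixed seed).

    ``seed`` overrides ``spec.seed``.  Draw order is fixed: demographics,
    pubertal stage, height, FMI and FFMI outcomes, device and skinfold
    noise, violation masks, biochemistry.
    """
    spec = spec or SyntheticCohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    fmi_truth = spec.truth("fmi")
    ffmi_truth = spec.truth("ffmi")

    # --- demographics -----------------------------------------------------
    is_female = rng.random(n) < spec.sex_ratio
    sex = np.where(is_female, "female", "male")
    age = rng.uniform(*spec.age_range, n)
    bmi_z = np.clip(rng.normal(0.1, 1.0, n), -2.8, 2.8)
    # pubertal stage: ordered age thresholds with individual jitter
    thr = np.array([10.0, 11.5, 13.0, 14.5])
    jitter = rng.normal(0.0, 0.8, (n, 4))
    tanner = 1 + np.sum(age[:, None] > (thr[None, :] + jitter), axis=1)

    # --- anthropometry and outcomes --------------------------------------
    height = _mean_height(age, is_female) * np.exp(rng.normal(0, spec.height_cv, n))
    fmi = bccg.sample(fmi_truth.params(age), rng=rng)
    ffmi = bccg.sample(ffmi_truth.params(age), rng=rng)
    hm2 = (height / 100.0) ** 2
    dxa_fm = fmi * hm2
    dxa_ffm = ffmi * hm2
    weight = dxa_fm + dxa_ffm          # DXA components close on weight
    dxa_bmc = 0.07 * dxa_ffm
    dxa_lm = dxa_ffm - dxa_bmc

    # skinfolds: invert the Slaughter equation from a noisy fat percentage
    slope = np.where(is_female, _SLAUGHTER["female"][0], _SLAUGHTER["male"][0])
    intercept = np.where(is_female, _SLAUGHTER["female"][1], _SLAUGHTER["male"][1])
    sf_pct = 100.0 * dxa_fm / weight * np.exp(rng.normal(0, spec.skinfold_cv, n))
    sf_pct = np.clip(sf_pct, intercept + 0.5, 60.0)
    sum_sf = (sf_pct - intercept) / slope
    triceps = 0.55 * sum_sf
    calf = 0.45 * sum_sf
    thigh_sf = 1.1 * triceps

    # MF-BIA devices: multiplicative noise around the DXA fat mass
    bia = {}
    for k in range(1, 4):
        if k <= spec.n_devices:
            fm_k = np.maximum(dxa_fm * np.exp(rng.normal(0, spec.device_cv, n)),
                              0.05)
            bia[f"bia{k}_fm_kg"] = fm_k
            bia[f"bia{k}_ffm_kg"] = weight - fm_k
        else:
            bia[f"bia{k}_fm_kg"] = np.full(n, np.nan)
            bia[f"bia{k}_ffm_kg"] = np.full(n, np.nan)

    # --- violation plan ---------------------------------------------------
    plant = {c: rng.random(n) < spec.violation_rates.get(c, 0.0)
             for c in PLANTABLE}
    incomplete = rng.random(n) < spec.incomplete_rate
    outlier = rng.random(n) < spec.outlier_rate
    for c in PLANTABLE:                # incomplete records plant nothing else
        plant[c] &= ~incomplete

    # --- biochemistry: healthy inside thresholds, planted beyond ----------
    glucose = np.clip(rng.normal(85, 7, n), 60.0, 99.0)
    glucose = np.where(plant["glucose"], rng.uniform(100.0, 126.0, n), glucose)

    # insulin keeps HOMA-IR <= 3.45 unless a HOMA violation is planted
    ins_cap = np.minimum(15.0, 3.45 * 405.0 / glucose)
    insulin = np.clip(rng.normal(8, 3, n), 1.0, ins_cap)
    homa_target = rng.uniform(3.6, 8.0, n)
    insulin = np.where(plant["homa_ir"], homa_target * 405.0 / glucose, insulin)

    total_chol = np.clip(rng.normal(150, 20, n), 100.0, 199.0)
    total_chol = np.where(plant["total_chol"], rng.uniform(200.0, 260.0, n),
                          total_chol)

    hdl_limit = np.where(is_female & (tanner >= POSTPUBERTAL_TANNER),
                         HDL_LIMIT_POSTPUBERTAL_GIRLS, HDL_LIMIT)
    hdl = np.clip(rng.normal(55, 8, n), 46.0, 95.0)
    hdl = np.where(plant["hdl"],
                   np.maximum(hdl_limit - rng.uniform(1.0, 15.0, n), 20.0), hdl)

    tg_limit = np.where(age < 10.0, TG_LIMIT_UNDER_10, TG_LIMIT_10_PLUS)
    tg = np.clip(rng.normal(75, 15, n), 30.0, tg_limit - 2.0)
    tg = np.where(plant["triglycerides"], tg_limit + rng.uniform(0.0, 40.0, n),
                  tg)
    ldl = np.clip(total_chol - hdl - tg / 5.0, 30.0, None)

    sbp90, dbp90 = synthetic_bp_reference(sex, age, height)
    sbp = sbp90 - rng.uniform(5.0, 20.0, n)
    dbp = dbp90 - rng.uniform(5.0, 20.0, n)
    sbp = np.where(plant["blood_pressure"], sbp90 + rng.uniform(0.0, 15.0, n),
                   sbp)

    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    bmi_z = np.where(plant["bmi_z"],
                     sign * (3.0 + np.abs(rng.normal(0, 0.5, n))), bmi_z)

    # --- assembly ---------------------------------------------------------
    records = pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(n)],
        "sex": sex, "age": age, "weight": weight, "height": height,
        "triceps_sf": triceps, "calf_sf": calf, "thigh_sf": thigh_sf,
        "waist": 50.0 + 1.6 * (age - 4.0),
        "hip": 55.0 + 2.0 * (age - 4.0),
        "arm_circ": 16.0 + 0.55 * age,
        "thigh_circ": 30.0 + 1.1 * age,
        "calf_circ": 24.0 + 0.75 * age,
        **bia,
        "dxa_fm_kg": dxa_fm, "dxa_lm_kg": dxa_lm, "dxa_bmc_kg": dxa_bmc,
        "glucose": glucose, "total_chol": total_chol, "hdl": hdl,
        "ldl": ldl, "triglycerides": tg, "insulin": insulin,
        "sbp": sbp, "dbp": dbp, "tanner": tanner, "bmi_z": bmi_z,
    })
    if incomplete.any():
        records.loc[incomplete, "glucose"] = np.nan
    if outlier.any():
        records.loc[outlier, "weight"] = records.loc[outlier, "weight"] * 5.0

    labels = pd.DataFrame({c: plant[c] for c in PLANTABLE})
    labels["incomplete_data"] = incomplete
    labels["anthropometric_outlier"] = outlier
    labels["eligible"] = ~labels.any(axis=1)
    return SyntheticCohort(records, labels, fmi_truth, ffmi_truth, spec)


def filter_cohort(cohort: SyntheticCohort):
    """Apply the eligibility and outlier screens; return the eligible records."""
    verdict = classify_eligibility(cohort.records, cohort.bp_reference)
    out_flags = anthropometric_outlier_filter(cohort.records)
    keep = verdict["eligible"] & ~out_flags
    return cohort.records.loc[keep], verdict, out_flags


def recovery_experiment(spec: SyntheticCohortSpec | None = None,
                        fit_config=None, n_seeds: int = 10,
                        base_seed: int = 0,
                        eval_ages=None,
                        m_rel_tol: float = 0.03, s_rel_tol: float = 0.10,
                        l_abs_tol: float = 0.30) -> pd.DataFrame:
    """Parameter-recovery study: generate -> filter -> fit -> compare to truth.

    For each seed, a cohort is generated from ``spec``, screened with the
    eligibility and outlier filters, the DXA fat-mass index is derived from
    the records, LMS curves are fitted, and the fitted L/M/S are compared
    with the generator truth on ``eval_ages`` (default 6-17 y, half-year
    grid).  Returns one row per seed with the maximum relative error of M
    and S, the maximum absolute error of L, and a ``pass`` flag against the
    given tolerances.  Fit non-convergence propagates with the seed id.
    """
    from .fitting import FitConfig, fit_lms, ConvergenceError

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    spec = spec or SyntheticCohortSpec()
    fit_config = fit_config or FitConfig()
    if eval_ages is None:
        eval_ages = np.arange(6.0, 17.0 + 1e-9, 0.5)
    eval_ages = np.asarray(eval_ages, float)

    rows = []
    for i in range(n_seeds):
        seed = (base_seed + 7919 * i) % (2 ** 31)
        cohort = generate_cohort(spec, seed=seed)
        # recovery screens on the metabolic criteria only: the gross-error
        # outlier screen has nothing planted to catch here, and because
        # synthetic weight is built from the outcome itself it would clip
        # the outcome's genuine heavy tail and bias the recovered L and S
        verdict = classify_eligibility(cohort.records, cohort.bp_reference)
        eligible = cohort.records.loc[verdict["eligible"]]
        y = mass_index(eligible["dxa_fm_kg"].to_numpy(),
                       eligible["height"].to_numpy())
        try:
            est = fit_lms(eligible["age"].to_numpy(), y, fit_config)
        except ConvergenceError as err:
            raise ConvergenceError(f"seed {seed}: {err}",
                                   estimator=err.estimator) from err
        Lf, Mf, Sf = est.predict_params(eval_ages)
        Lt, Mt, St = cohort.fmi_truth.params(eval_ages)
        m_err = float(np.max(np.abs(Mf - Mt) / Mt))
        s_err = float(np.max(np.abs(Sf - St) / St))
        l_err = float(np.max(np.abs(Lf - Lt)))
        rows.append({
            "seed": seed, "n_eligible": len(eligible),
            "m_max_rel_err": m_err, "s_max_rel_err": s_err,
            "l_max_abs_err": l_err,
            "pass": (m_err <= m_rel_tol and s_err <= s_rel_tol
                     and l_err <= l_abs_tol),
        })
    return pd.DataFrame(rows)
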