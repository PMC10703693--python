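"""Study exclusions and the association-statistics layer.

Implements the cohort hygiene and statistics surrounding the barcode
caller: exclusion of participants with prior or peri-draw hematological
disease or grossly abnormal hematology; Fisher's exact tests for individual
somatic variants; covariate-adjusted logistic associations of CH with
case-control phenotypes; a smoking dose-response model; and the
inverse-variance-weighted (IVW) effect-on-effect regression used for
Mendelian-randomization-style analyses.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "BONFERRONI_ALPHA",
    "HEME_ICD10_BLOCKS",
    "apply_exclusions",
    "fisher_variant_test",
    "logistic_assoc",
    "smoking_dose_model",
    "ivw_regression",
    "AssocResult",
    "IVWResult",
]

# conservative study-wide Bonferroni level for ~10,000 disease phenotypes
BONFERRONI_ALPHA = 5.00e-6

# hematological-disorder ICD10 blocks: C81-C96 and D45-D47, with subcode
# inheritance (C91 matches C91.1)
HEME_ICD10_BLOCKS = (("C", 81, 96), ("D", 45, 47))

_ICD_RE = re.compile(r"^([A-Z])(\d{2})")


def _matches_heme_block(code: str) -> bool:
    m = _ICD_RE.match(str(code).replace(".", "").upper().strip())
    if not m:
        return False
    letter, block = m.group(1), int(m.group(2))
    return any(letter == l and lo <= block <= hi for l, lo, hi in HEME_ICD10_BLOCKS)


def apply_exclusions(manifest: pd.DataFrame, diagnoses: pd.DataFrame,
                     window_days: int = 183):
    """Apply the study exclusion criteria; returns ``(eligible, exclusion_log)``.

    Excluded are participants with (a) a hematological-disorder diagnosis
    (ICD10 C81-C96, D45-D47) any time before, or within ``window_days``
    (~6 months) after, blood draw; (b) WBC < 1.5 or > 35 x 10^9/l;
    (c) HGB < 8 g/dl; (d) PLT < 50 x 10^9/l.  Missing hematology never
    excludes on that measure.  Malformed ICD10 codes are logged and treated
    as non-matching.  The log records every reason that applies to a sample,
    so the operation is order-independent over its criteria and idempotent.
    """
    reasons = []

    if len(diagnoses):
        bad_codes = [c for c in diagnoses["icd10"].unique()
                     if not _ICD_RE.match(str(c).replace(".", "").upper().strip())]
        if bad_codes:
            log.warning("ignoring %d malformed ICD10 codes: %s",
                        len(bad_codes), bad_codes[:5])
        heme = diagnoses[
            diagnoses["icd10"].map(_matches_heme_block)
            & (diagnoses["date_offset_days"] <= window_days)]
        for sid in heme["sample_id"].unique():
            reasons.append((sid, "hematological_diagnosis"))

    def flag(mask, reason):
        for sid in manifest.loc[mask.fillna(False), "sample_id"]:
            reasons.append((sid, reason))

    if "wbc" in manifest:
        flag(manifest["wbc"] < 1.5, "wbc_low")
        flag(manifest["wbc"] > 35, "wbc_high")
    if "hgb" in manifest:
        flag(manifest["hgb"] < 8, "hgb_low")
    if "plt" in manifest:
        flag(manifest["plt"] < 50, "plt_low")

    exclusion_log = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    excluded = set(exclusion_log["sample_id"])
    eligible = manifest[~manifest["sample_id"].isin(excluded)].copy()
    return eligible, exclusion_log


def fisher_variant_test(a: int, b: int, c: int, d: int):
    """Fisher's exact test for one variant's 2x2 carrier table.

    ``a``=carriers among CH cases, ``b``=non-carriers among cases,
    ``c``=carriers among controls, ``d``=non-carriers among controls.
    Returns ``(odds_ratio, p_value)`` with the sample odds ratio ad/bc
    (``inf``/0 for degenerate-but-informative tables) and the exact
    two-sided p summing hypergeometric tables no more probable than the
    observed one.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be >= 0")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds_ratio = np.float64(a * d) / np.float64(b * c)  # inf/0/nan as they fall
    return float(odds_ratio), float(res.pvalue)


@dataclass
class AssocResult:
    phenotype: str
    n_cases: int
    n_controls: int
    odds_ratio: float
    p_value: float
    beta: float
    se: float
    covariates: str
    model: str = "logistic"
    converged: bool = True
    note: str = ""

    def __post_init__(self):
        if np.isfinite(self.odds_ratio) and self.odds_ratio <= 0:
            raise ValueError("finite odds ratio must be > 0")
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def _design(frame: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = frame[list(cols)].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add")


def _covariate_frame(covariates: pd.DataFrame, adjust: str) -> pd.DataFrame:
    out = pd.DataFrame(index=covariates.index)
    out["age"] = covariates["age"].astype(float)
    out["age_sq"] = out["age"] ** 2
    sex = covariates["sex"]
    out["sex"] = (sex == "F").astype(float) if sex.dtype == object else sex.astype(float)
    if adjust == "smoking":
        status = covariates["smoking_status"].astype(str)
        out["smoking_current"] = (status == "current").astype(float)
        out["smoking_previous"] = (status == "previous").astype(float)
        out["pack_years"] = covariates["pack_years"].astype(float)
        out["years_quit"] = covariates["years_quit"].astype(float)
    elif adjust != "basic":
        raise ValueError("adjust must be 'basic' or 'smoking'")
    return out


def logistic_assoc(ch: Sequence[bool], phenotype: Sequence[bool],
                   covariates: pd.DataFrame, adjust: str = "basic",
                   phenotype_label: str = "phenotype") -> AssocResult:
    """Covariate-adjusted logistic association of a phenotype with CH status.

    The phenotype is regressed on the CH indicator plus age, age squared
    and sex ('basic'), optionally adding smoking status, pack years and
    years since quitting ('smoking').  Complete-case over all covariates.
    The reported OR is exp(CH coefficient) with its Wald p-value; complete
    or quasi-complete separation is detected and flagged rather than
    reported silently.
    """
    ch = np.asarray(ch, dtype=bool)
    phen = np.asarray(phenotype, dtype=bool)
    cov = _covariate_frame(covariates.reset_index(drop=True), adjust)
    frame = cov.assign(ch=ch.astype(float), phen=phen.astype(float)).dropna()
    y = frame["phen"].to_numpy()
    # zero-variance covariates (e.g. no previous smokers) would make the
    # design singular; drop them rather than fail
    usable = [c for c in cov.columns if frame[c].nunique() > 1]
    X = _design(frame, ["ch"] + usable)
    n_cases, n_controls = int(y.sum()), int(len(y) - y.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("phenotype needs at least one case and one control")

    note, converged = "", True
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        beta, se = float(fit.params[1]), float(fit.bse[1])
        pval = float(fit.pvalues[1])
        if not np.isfinite(se) or abs(beta) > 15:
            converged, note = False, "separation suspected: unstable CH coefficient"
    except Exception as err:  # PerfectSeparationError and kin
        converged = False
        beta, se, pval = np.nan, np.nan, np.nan
        note = f"fit failed: {type(err).__name__}"
    if not converged and not note:
        note = "maximum-likelihood fit did not converge"

    return AssocResult(
        phenotype=phenotype_label, n_cases=n_cases, n_controls=n_controls,
        odds_ratio=float(np.exp(beta)) if np.isfinite(beta) else np.nan,
        p_value=pval, beta=beta, se=se,
        covariates="age+age^2+sex" + ("+smoking" if adjust == "smoking" else ""),
        converged=converged, note=note)


def smoking_dose_model(manifest: pd.DataFrame, ch: Sequence[bool]) -> list[AssocResult]:
    """Dose-response model of CH on smoking behaviour.

    Logistic fit of CH status on smoking status indicators, pack years and
    years since quitting, adjusted for age, age squared and sex; returns one
    AssocResult per smoking covariate.  Degenerate designs (for example a
    cohort of never-smokers) drop the constant columns with a warning.
    """
    ch = np.asarray(ch, dtype=float)
    cov = _covariate_frame(manifest.reset_index(drop=True), "smoking")
    frame = cov.assign(ch=ch).dropna()
    smoking_cols = ["smoking_current", "smoking_previous", "pack_years", "years_quit"]
    usable = [c for c in smoking_cols if frame[c].nunique() > 1]
    dropped = sorted(set(smoking_cols) - set(usable))
    if dropped:
        log.warning("smoking covariates with no variation dropped: %s", dropped)
    if not usable:
        return []
    cols = usable + ["age", "age_sq", "sex"]
    y = frame["ch"].to_numpy()
    X = _design(frame, cols)
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:  # singular design / separation on tiny cohorts
        log.warning("smoking dose model could not be fitted: %s", err)
        return []
    results = []
    for i, name in enumerate(usable, start=1):
        beta, se = float(fit.params[i]), float(fit.bse[i])
        results.append(AssocResult(
            phenotype=name, n_cases=int(y.sum()), n_controls=int(len(y) - y.sum()),
            odds_ratio=float(np.exp(beta)), p_value=float(fit.pvalues[i]),
            beta=beta, se=se, covariates="age+age^2+sex+smoking",
            model="logistic (CH ~ smoking)",
            converged=bool(fit.mle_retvals.get("converged", True))))
    return results


@dataclass
class IVWResult:
    slope: float
    se: float
    p_value: float
    n_instruments: int


def ivw_regression(beta_exposure: Sequence[float], se_exposure: Sequence[float],
                   beta_outcome: Sequence[float], se_outcome: Sequence[float]) -> IVWResult:
    """Inverse-variance-weighted effect-on-effect regression without intercept.

    slope = sum(w bx by) / sum(w bx^2) with w = 1/se_y^2 — the closed-form
    weighted-least-squares solution of by ~ bx through the origin, weighted
    by the precision of the outcome associations.  The exposure standard
    errors are accepted for interface symmetry but do not enter the
    estimator.  Wald p from the normal approximation.
    """
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    sy = np.asarray(se_outcome, dtype=float)
    if not (len(bx) == len(by) == len(sy)):
        raise ValueError("effect lists must have equal length")
    if len(bx) == 0:
        raise ValueError("no instruments supplied")
    if (sy <= 0).any():
        raise ValueError("outcome standard errors must be > 0")
    if np.all(bx == 0):
        raise ValueError("all exposure effects are zero; slope undefined")
    w = 1.0 / sy**2
    denom = np.sum(w * bx * bx)
    slope = np.sum(w * bx * by) / denom
    se = np.sqrt(1.0 / denom)
    z = slope / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return IVWResult(float(slope), float(se), p, len(bx))
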