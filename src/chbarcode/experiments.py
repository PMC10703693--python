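"""Calibration and recovery experiments exercising the pipeline end to end.

Each function builds a synthetic cohort under stated study conditions, runs
the relevant pipeline stage, and returns the measured quantities together
with the problem size.  They are the single source of truth for the
analysis drivers, the acceptance checks and the reproduction script, so the
numbers those report are always recomputed from scratch.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import fisher_variant_test, ivw_regression, logistic_assoc
from .caller import ThresholdConfig, call_from_tables, fit_germline_ratio
from .config import CenterConfig, Constant, SimulationConfig
from .drivers import binomial_germline_test
from .simulate import simulate_cohort
from .variants import build_profiles

__all__ = [
    "exact_window_ratio",
    "flat_threshold",
    "null_calibration_experiment",
    "ratio_oracle_experiment",
    "spike_recovery_experiment",
    "fisher_oracle_scan",
    "binomial_oracle_scan",
    "logistic_recovery_experiment",
    "confounding_experiment",
    "ivw_experiment",
    "prevalence_anchor_experiment",
]


def flat_threshold(base: float = 20.0) -> ThresholdConfig:
    """Threshold config with no center/platform adjustment (T = base everywhere)."""
    return ThresholdConfig(base_threshold=base, center_adjustments={},
                           platform_thresholds={}, default_adjustment=0.0)


def exact_window_ratio(depth: int, p: float = 0.5) -> float:
    """Exact HIGH/MID window-probability ratio under Binomial(depth, p).

    Window membership uses the same closed rational bounds as the pipeline,
    evaluated in exact arithmetic.
    """
    def wprob(lo, hi):
        ks = [k for k in range(depth + 1)
              if Fraction(lo[0], lo[1]) <= Fraction(k, depth) <= Fraction(hi[0], hi[1])]
        return float(stats.binom.pmf(ks, depth, p).sum())
    return wprob((3, 4), (9, 10)) / wprob((7, 20), (13, 20))


def _germline_only_config(seed: int, n_samples: int, n_het: float,
                          mean_depth: float, dispersion: float = 1.0,
                          prevalence: float = 0.0, **overrides) -> SimulationConfig:
    base = dict(
        n_samples=n_samples, seed=seed, n_germline_het=n_het,
        error_bump_rate=0.0, shared_pool_size=0,
        clone_prevalence_fn=lambda age: prevalence,
        driver_spike_prob=0.0, candidate_germline_leak_sites=0,
        gq_fail_rate=0.0, low_qd_rate=0.0, filter_fail_rate=0.0,
        heme_dx_rate=0.0, abnormal_hematology_rate=0.0,
        centers=(CenterConfig("Vanguard", "UKB WGS", 0.5, mean_depth, dispersion),
                 CenterConfig("Sanger", "UKB WGS", 0.5, mean_depth, dispersion)),
    )
    base.update(overrides)
    return SimulationConfig(**base)


def null_calibration_experiment(seed: int, n_samples: int = 500,
                                n_het: float = 30_000.0,
                                mean_depth: float = 35.0,
                                threshold: float = 20.0) -> dict:
    """False-positive behaviour on a cohort with no clones and no error bump.

    The estimated somatic count should be centred on zero and almost never
    reach the calling threshold.
    """
    cfg = _germline_only_config(seed, n_samples, n_het, mean_depth)
    cohort = simulate_cohort(cfg)
    calls, _, _ = call_from_tables(cohort.variants, cohort.manifest,
                                   threshold_cfg=flat_threshold(threshold))
    s = calls["estimated_somatic"].to_numpy()
    return {
        "n_samples": n_samples,
        "mean_estimated_somatic": float(s.mean()),
        "se_mean": float(s.std(ddof=1) / np.sqrt(len(s))),
        "ch_positive_fraction": float((s >= threshold).mean()),
    }


def ratio_oracle_experiment(seed: int, depths=(25, 35, 50), n_samples: int = 10,
                            n_het: float = 100_000.0) -> dict:
    """Fitted germline ratio r(d) at fixed depths vs the exact binomial ratio.

    Depth is held constant per run (dispersion 0) so r(d) has a closed-form
    target; ``mc_rel_se`` is the Monte-Carlo relative standard error implied
    by the realised HIGH-window count.
    """
    out = {}
    for i, d in enumerate(depths):
        cfg = _germline_only_config(seed + i, n_samples, n_het, float(d),
                                    dispersion=0.0)
        cohort = simulate_cohort(cfg)
        profiles, _ = build_profiles(cohort.variants, cohort.manifest)
        model = fit_germline_ratio(profiles)
        pooled = model.table[model.table["depth"] == d]
        n_high = float(pooled["n_high"].sum())
        fitted = n_high / float(pooled["n_mid"].sum())
        exact = exact_window_ratio(d)
        out[d] = {
            "fitted": fitted,
            "exact": exact,
            "rel_err": abs(fitted - exact) / exact,
            "mc_rel_se": 1.0 / np.sqrt(max(n_high, 1.0)),
            "n_sites": int(n_samples * n_het),
        }
    return out


def spike_recovery_experiment(seed: int, n_samples: int = 400,
                              n_het: float = 30_000.0, depth: int = 35,
                              clone_fraction: float = 0.35,
                              target_in_window: int = 40,
                              threshold: float = 20.0) -> dict:
    """Sensitivity and bias for clones contributing ~``target_in_window``
    somatic singletons to the indicator window.

    Depth is fixed so the per-site in-window probability q under
    Binomial(depth, f/2) is exact, and the clone founder-mutation count is
    set to target_in_window / q.  Half the cohort carries a clone; quality
    failures are off because the truth counts pre-filter sites.
    """
    ks = np.arange(depth + 1)
    in_win = (ks * 10 >= depth) & (ks * 4 <= depth)  # closed [0.10, 0.25]
    q = float(stats.binom.pmf(ks[in_win], depth, clone_fraction / 2.0).sum())
    n_clone_mut = int(round(target_in_window / q))

    cfg = _germline_only_config(
        seed, n_samples, n_het, float(depth), dispersion=0.0, prevalence=0.5,
        clone_fraction_dist=Constant(clone_fraction),
        n_clone_mutations_dist=Constant(n_clone_mut))
    cohort = simulate_cohort(cfg)
    calls, _, _ = call_from_tables(cohort.variants, cohort.manifest,
                                   threshold_cfg=flat_threshold(threshold))
    merged = calls.merge(cohort.truth, on="sample_id")
    clones = merged[merged["has_clone"]]
    diff = (clones["estimated_somatic"]
            - clones["true_somatic_singletons_in_window"]).to_numpy()
    return {
        "n_clones": int(len(clones)),
        "mean_true_in_window": float(clones["true_somatic_singletons_in_window"].mean()),
        "sensitivity": float((clones["estimated_somatic"] >= threshold).mean()),
        "paired_bias": float(diff.mean()),
        "paired_se": float(diff.std(ddof=1) / np.sqrt(len(diff))),
        "false_positive_fraction": float(
            (merged.loc[~merged["has_clone"], "estimated_somatic"] >= threshold).mean()),
    }


def _enumerated_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit hypergeometric enumeration (oracle)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
    obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


def fisher_oracle_scan(max_total: int = 30) -> dict:
    """Compare fisher_variant_test with enumeration on every non-degenerate
    2x2 table whose grand total is at most ``max_total``."""
    worst, n_tables = 0.0, 0
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                        continue
                    n_tables += 1
                    _, p = fisher_variant_test(a, b, c, d)
                    worst = max(worst, abs(p - _enumerated_fisher_p(a, b, c, d)))
    return {"max_abs_p_diff": worst, "n_tables": n_tables}


def binomial_oracle_scan(max_depth: int = 40) -> dict:
    """Compare the exact binomial germline test with a pmf-enumeration oracle
    over every (alt_reads, depth) with depth <= ``max_depth``."""
    worst, n_points = 0.0, 0
    for n in range(1, max_depth + 1):
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
        for k in range(n + 1):
            oracle = float(pmf[pmf <= pmf[k] * (1 + 1e-9)].sum())
            p, _ = binomial_germline_test(k, n)
            worst = max(worst, abs(p - oracle))
            n_points += 1
    return {"max_abs_p_diff": worst, "n_points": n_points}


def _covariate_frame(rng: np.random.Generator, n: int,
                     smokers: np.ndarray | None = None) -> pd.DataFrame:
    frame = pd.DataFrame({
        "age": rng.uniform(40, 85, n),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "smoking_status": "never", "pack_years": 0.0, "years_quit": 0.0,
    })
    if smokers is not None:
        frame.loc[smokers, "smoking_status"] = "current"
        frame.loc[smokers, "pack_years"] = rng.gamma(2.0, 10.0, int(smokers.sum()))
    return frame


def logistic_recovery_experiment(seed: int, n: int = 20_000,
                                 log_or: float = float(np.log(2.0))) -> dict:
    """Plant a known CH -> phenotype log-odds effect and recover it."""
    rng = np.random.default_rng(seed)
    cov = _covariate_frame(rng, n)
    ch = rng.random(n) < 0.10
    lin = -2.0 + log_or * ch + 0.01 * (cov["age"] - 60)
    phen = rng.random(n) < 1 / (1 + np.exp(-lin))
    res = logistic_assoc(ch, phen, cov, adjust="basic")
    return {"n": n, "true_or": float(np.exp(log_or)), "or": res.odds_ratio,
            "beta": res.beta, "se": res.se, "p": res.p_value,
            "covered": abs(res.beta - log_or) <= 2 * res.se}


def confounding_experiment(seed: int, n: int = 20_000) -> dict:
    """Smoking drives both CH and a phenotype; CH itself has no effect.

    The unadjusted CH odds ratio is inflated by the shared cause and must
    attenuate toward 1 when smoking enters the model.
    """
    rng = np.random.default_rng(seed)
    smokers = rng.random(n) < 0.3
    cov = _covariate_frame(rng, n, smokers)
    ch = rng.random(n) < 1 / (1 + np.exp(-(-2.5 + 1.2 * smokers)))
    phen = rng.random(n) < 1 / (1 + np.exp(-(-2.0 + 1.0 * smokers)))
    unadj = logistic_assoc(ch, phen, cov, adjust="basic")
    adj = logistic_assoc(ch, phen, cov, adjust="smoking")
    return {"n": n, "or_unadjusted": unadj.odds_ratio,
            "or_adjusted": adj.odds_ratio,
            "attenuated": abs(np.log(adj.odds_ratio)) < abs(np.log(unadj.odds_ratio))}


def ivw_experiment(seed: int, n_instruments: int = 50,
                   true_slope: float = 0.3) -> dict:
    """Simulated instruments with a known causal slope, plus the closed-form
    weighted-least-squares cross-check on the same inputs."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.1, 0.03, n_instruments)
    se_x = np.full(n_instruments, 0.01)
    se_y = rng.uniform(0.01, 0.05, n_instruments)
    by = true_slope * bx + rng.normal(0.0, se_y)
    res = ivw_regression(bx, se_x, by, se_y)
    w = 1.0 / se_y**2
    wls = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
    return {"n_instruments": n_instruments, "true_slope": true_slope,
            "slope": res.slope, "se": res.se, "p": res.p_value,
            "wls_closed_form": wls, "wls_abs_diff": abs(res.slope - wls),
            "covered": abs(res.slope - true_slope) <= 2 * res.se}


def prevalence_anchor_experiment(seed: int, n_per_age: int = 4000) -> dict:
    """Empirical clone prevalence at the two anchor ages of the age curve.

    Smoking and germline modifiers are switched off so the age curve is
    isolated; samples carry no variant sites (only clone presence is drawn),
    making the check cheap at cohort scale.
    """
    out = {}
    for i, age in enumerate((40.0, 80.0)):
        cfg = SimulationConfig(
            n_samples=n_per_age, seed=seed + i, n_germline_het=0.0,
            error_bump_rate=0.0, shared_pool_size=0, driver_spike_prob=0.0,
            candidate_germline_leak_sites=0, age_dist=Constant(age),
            current_smoker_rate=0.0, previous_smoker_rate=0.0, tert_maf=0.0,
            n_clone_mutations_dist=Constant(1), heme_dx_rate=0.0,
            abnormal_hematology_rate=0.0)
        cohort = simulate_cohort(cfg)
        p = float(cohort.truth["has_clone"].mean())
        expected = cfg.clone_prevalence_fn(age)
        out[int(age)] = {
            "prevalence": p, "expected": expected, "n": n_per_age,
            "binomial_se": float(np.sqrt(expected * (1 - expected) / n_per_age)),
        }
    return out
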