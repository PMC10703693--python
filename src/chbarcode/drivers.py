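"""CPLD and CHIP driver-mutation filter cascades and CH subtype classification.

Candidates arrive as the table a somatic caller plus annotator would export
(sample_id, chrom, pos, ref, alt, depth, alt_reads, gene, hgvsp, impact,
filter).  Two cascades are implemented:

* the CPLD (candidate preleukemic driver) cascade: basic call-quality
  bounds, an exact binomial test of VAF against 0.5 to mark potential
  germline calls, removal of recurrent mostly-germline variant keys, and an
  impact rule keeping high-impact variants (outside four genes whose drivers
  are specific missense hotspots) or variants on a published driver list;

* the adapted CHIP cascade over a 73-gene panel (U2AF1 excluded): depth and
  alternate-read bounds, a recurrence filter that drops variants whose
  carrier frequency associates with neither age nor rs7705526 dosage, and a
  pooled-read binomial germline test with three exempt TET2 hotspots.

Every removal is attributed to exactly one step in the attrition log.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

log = logging.getLogger(__name__)

__all__ = [
    "binomial_germline_test",
    "binomial_germline_pvalues",
    "cpld_filter_cascade",
    "chip_filter_cascade",
    "classify_subtypes",
    "load_published_cpld_list",
    "load_chip_gene_panel",
    "CPLD_EXCLUDED_HIGH_IMPACT_GENES",
    "CHIP_EXEMPT_SITES",
]

CPLD_EXCLUDED_HIGH_IMPACT_GENES = frozenset({"GNAS", "JAK2", "SRSF2", "SF3B1"})
# TET2 sites that bypass the CHIP pooled binomial removal despite
# germline-like pooled VAF
CHIP_EXEMPT_SITES = frozenset({("TET2", "H1904R"), ("TET2", "I1873T"),
                               ("TET2", "T1884A")})
_KEY = ["chrom", "pos", "ref", "alt"]


def load_published_cpld_list() -> pd.DataFrame:
    """Bundled (gene, hgvsp) driver list.

    Synthetic stand-in for the published CPLD variant list, which is an
    access-restricted journal supplement; gene symbols are real CH drivers
    but membership is constructed for testing.
    """
    ref = importlib_resources.files("chbarcode.resources") / "cpld_list_synthetic.tsv"
    with importlib_resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_chip_gene_panel() -> list[str]:
    """Bundled 73-gene CHIP panel (synthetic stand-in, real gene symbols)."""
    ref = importlib_resources.files("chbarcode.resources") / "chip_gene_panel_synthetic.tsv"
    with importlib_resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str)["gene"].tolist()


def binomial_germline_test(alt_reads: int, depth: int, alpha: float = 0.05):
    """Exact two-sided binomial test of alt_reads ~ Binomial(depth, 0.5).

    Returns ``(p_value, is_potential_germline)`` with the germline flag set
    on strict inequality p > alpha: a call whose VAF is statistically
    compatible with a heterozygous germline genotype.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= alt_reads <= depth:
        raise ValueError("alt_reads must be in [0, depth]")
    p = stats.binomtest(int(alt_reads), int(depth), 0.5).pvalue
    return float(p), bool(p > alpha)


def binomial_germline_pvalues(alt_reads, depth) -> np.ndarray:
    """Vectorized exact two-sided p-values for the p=0.5 binomial test.

    For a symmetric binomial the minimum-likelihood two-sided p equals
    2*P(X <= min(k, n-k)), capped at 1 (the cap bites only at k = n/2).
    """
    alt_reads = np.asarray(alt_reads, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    if (depth < 1).any():
        raise ValueError("depth must be >= 1")
    m = np.minimum(alt_reads, depth - alt_reads)
    return np.minimum(2.0 * stats.binom.cdf(m, depth, 0.5), 1.0)


@dataclass
class CascadeAttrition:
    """Removal counts per cascade step; sums to input minus output."""

    n_input: int
    steps: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": list(self.steps), "removed": list(self.steps.values())})

    def check(self, n_output: int) -> None:
        if self.n_input - sum(self.steps.values()) != n_output:
            raise AssertionError("cascade attrition does not reconcile")


def _require_columns(candidates: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = set(cols) - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")


def cpld_filter_cascade(candidates: pd.DataFrame,
                        published_list: Optional[pd.DataFrame] = None,
                        excluded_high_impact_genes: frozenset = CPLD_EXCLUDED_HIGH_IMPACT_GENES,
                        alpha: float = 0.05,
                        max_occurrences: int = 5,
                        germline_fraction_threshold: float = 0.75):
    """CPLD candidate filter cascade; returns ``(retained, attrition)``.

    Steps, in fixed order:
      0. drop candidates with no impact annotation (logged);
      1. depth > 10 (strict), FILTER == PASS, 0.01 <= VAF <= 0.99;
      2. binomial germline classification per candidate; per variant key,
         cohort_occurrences and the potential-germline fraction are computed
         across all step-1 survivors, before any removal;
      3. remove keys with > ``max_occurrences`` carriers AND potential-
         germline fraction > ``germline_fraction_threshold``;
      4. keep HIGH impact with gene outside ``excluded_high_impact_genes``,
         OR membership of the published list (any impact).
    """
    _require_columns(candidates, _KEY + ["sample_id", "depth", "alt_reads",
                                         "impact", "filter", "gene", "hgvsp"])
    if published_list is None:
        published_list = load_published_cpld_list()
    steps = {}
    tab = candidates.copy()

    no_impact = tab["impact"].isna() | (tab["impact"].astype(str) == "")
    steps["missing_impact"] = int(no_impact.sum())
    if steps["missing_impact"]:
        log.warning("dropping %d candidates without impact annotation",
                    steps["missing_impact"])
    tab = tab.loc[~no_impact].copy()

    depth = tab["depth"].to_numpy(dtype=np.int64)
    alt = tab["alt_reads"].to_numpy(dtype=np.int64)
    # VAF bounds as exact integer comparisons: 0.01 <= alt/depth <= 0.99
    ok = ((depth > 10) & (tab["filter"].astype(str).to_numpy() == "PASS")
          & (alt * 100 >= depth) & (alt * 100 <= 99 * depth))
    steps["call_quality"] = int((~ok).sum())
    tab = tab.loc[ok].copy()

    if len(tab):
        tab["p_germline"] = binomial_germline_pvalues(tab["alt_reads"], tab["depth"])
        tab["is_potential_germline"] = tab["p_germline"] > alpha
        grp = tab.groupby(_KEY, sort=False)
        tab["cohort_occurrences"] = grp["sample_id"].transform("size")
        tab["potential_germline_fraction"] = grp["is_potential_germline"].transform("mean")
        recurrent_germline = ((tab["cohort_occurrences"] > max_occurrences)
                              & (tab["potential_germline_fraction"]
                                 > germline_fraction_threshold))
    else:
        recurrent_germline = np.zeros(0, dtype=bool)
    steps["recurrent_germline"] = int(np.asarray(recurrent_germline).sum())
    tab = tab.loc[~recurrent_germline].copy()

    if len(tab):
        pub = set(zip(published_list["gene"], published_list["hgvsp"]))
        in_pub = np.fromiter(
            ((g, h) in pub for g, h in zip(tab["gene"], tab["hgvsp"])),
            dtype=bool, count=len(tab))
        tab["in_published_list"] = in_pub
        high_kept = ((tab["impact"].astype(str) == "HIGH")
                     & ~tab["gene"].isin(excluded_high_impact_genes))
        keep = high_kept.to_numpy() | in_pub
    else:
        tab["in_published_list"] = pd.Series(dtype=bool)
        keep = np.zeros(0, dtype=bool)
    steps["impact_rule"] = int((~keep).sum())
    retained = tab.loc[keep].copy()

    att = CascadeAttrition(len(candidates), steps)
    att.check(len(retained))
    return retained, att


def _recurrence_association(carrier: np.ndarray, covariates: pd.DataFrame):
    """Binomial GLM of carrier status on age and rs7705526 dosage.

    Returns ((beta_age, p_age), (beta_dosage, p_dosage)) from Wald z-tests
    on the jointly fitted model; (0, 1) per covariate on fit failure, which
    can only make the filter drop the variant.
    """
    X = sm.add_constant(covariates[["age", "rs7705526_dosage"]].to_numpy(dtype=float))
    try:
        fit = sm.GLM(carrier.astype(float), X,
                     family=sm.families.Binomial()).fit(maxiter=50)
        return ((float(fit.params[1]), float(fit.pvalues[1])),
                (float(fit.params[2]), float(fit.pvalues[2])))
    except Exception:  # separation / singular design on degenerate keys
        return ((0.0, 1.0), (0.0, 1.0))


def chip_filter_cascade(candidates: pd.DataFrame,
                        covariates: pd.DataFrame,
                        gene_panel: Optional[Iterable[str]] = None,
                        exempt_sites: frozenset = CHIP_EXEMPT_SITES,
                        min_depth: int = 20,
                        min_alt_reads: int = 3,
                        recurrence_min_carriers: int = 15,
                        recurrence_alpha: float = 0.1,
                        germline_alpha: float = 0.01):
    """Adapted CHIP filter cascade; returns ``(retained, attrition)``.

    ``covariates`` must carry one row per cohort sample with columns
    sample_id, age, rs7705526_dosage.  Steps, in fixed order:
      0. restrict to the gene panel, always excluding U2AF1;
      1. depth >= 20 and alternate reads (minAD) >= 3;
      2. for variant keys with >= 15 carriers, test carrier status against
         age and rs7705526 dosage; remove keys for which BOTH covariates
         have p > 0.1 or estimate < 0 (keys below 15 carriers skip this);
      3. pooled binomial test of total alternate reads against half of all
         reads at the site; remove keys with p > 0.01 unless exempt.
    """
    _require_columns(candidates, _KEY + ["sample_id", "depth", "alt_reads",
                                         "gene", "hgvsp"])
    _require_columns(covariates, ["sample_id", "age", "rs7705526_dosage"])
    if gene_panel is None:
        gene_panel = load_chip_gene_panel()
    panel = set(gene_panel) - {"U2AF1"}
    steps = {}
    tab = candidates.copy()

    in_panel = tab["gene"].isin(panel)
    steps["outside_panel"] = int((~in_panel).sum())
    tab = tab.loc[in_panel].copy()

    ok = (tab["depth"].to_numpy() >= min_depth) & \
         (tab["alt_reads"].to_numpy() >= min_alt_reads)
    steps["depth_minad"] = int((~ok).sum())
    tab = tab.loc[ok].copy()

    removed_keys = []
    if len(tab):
        carrier_counts = tab.groupby(_KEY, sort=False)["sample_id"].nunique()
        cov = covariates.drop_duplicates("sample_id").reset_index(drop=True)
        all_samples = cov["sample_id"]
        for key, n_carriers in carrier_counts.items():
            if n_carriers < recurrence_min_carriers:
                continue
            carriers = set(tab.loc[(tab[_KEY] == pd.Series(key, index=_KEY)).all(axis=1),
                                   "sample_id"])
            y = all_samples.isin(carriers).to_numpy()
            (b_age, p_age), (b_dos, p_dos) = _recurrence_association(y, cov)
            age_fails = p_age > recurrence_alpha or b_age < 0
            dos_fails = p_dos > recurrence_alpha or b_dos < 0
            if age_fails and dos_fails:
                removed_keys.append(key)
    if removed_keys:
        drop = pd.MultiIndex.from_frame(tab[_KEY]).isin(removed_keys)
    else:
        drop = np.zeros(len(tab), dtype=bool)
    steps["recurrence_regression"] = int(np.asarray(drop).sum())
    tab = tab.loc[~drop].copy()

    if len(tab):
        pooled = tab.groupby(_KEY, sort=False).agg(
            alt_total=("alt_reads", "sum"), depth_total=("depth", "sum"),
            gene=("gene", "first"), hgvsp=("hgvsp", "first"))
        pvals = binomial_germline_pvalues(pooled["alt_total"], pooled["depth_total"])
        exempt = np.fromiter(((g, h) in exempt_sites
                              for g, h in zip(pooled["gene"], pooled["hgvsp"])),
                             dtype=bool, count=len(pooled))
        germline_keys = pooled.index[(pvals > germline_alpha) & ~exempt]
        drop = pd.MultiIndex.from_frame(tab[_KEY]).isin(germline_keys)
    else:
        drop = np.zeros(0, dtype=bool)
    steps["pooled_germline"] = int(np.asarray(drop).sum())
    retained = tab.loc[~drop].copy()

    att = CascadeAttrition(len(candidates), steps)
    att.check(len(retained))
    return retained, att


def classify_subtypes(ch_calls: pd.DataFrame, retained_drivers: pd.DataFrame,
                      evaluated_samples: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Assign CH subtypes given barcode calls and retained drivers per sample.

    Subtypes: CPLD-CH (barcode-positive with a retained driver), CPLDneg-CH
    (barcode-positive without), CPLD-only (driver without a barcode — seen
    particularly in younger carriers whose clone is still small), none.
    Samples outside ``evaluated_samples`` (default: all) could not be
    assessed for drivers: they are marked unevaluable and get no
    CPLDneg-CH label.
    """
    if ch_calls["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in CH call table")
    driver_map = (retained_drivers.groupby("sample_id")["gene"]
                  .agg(lambda g: ",".join(sorted(set(g))))
                  if len(retained_drivers) else pd.Series(dtype=str))
    out = ch_calls[["sample_id", "is_ch"]].rename(columns={"is_ch": "barcode_ch"}).copy()
    out["driver_genes"] = out["sample_id"].map(driver_map).fillna("")
    out["cpld_ch"] = out["driver_genes"] != ""
    if evaluated_samples is None:
        out["evaluable"] = True
    else:
        out["evaluable"] = out["sample_id"].isin(set(evaluated_samples))

    def label(row):
        if not row["evaluable"]:
            return "unevaluable"
        if row["cpld_ch"] and row["barcode_ch"]:
            return "CPLD-CH"
        if row["cpld_ch"]:
            return "CPLD-only"
        if row["barcode_ch"]:
            return "CPLDneg-CH"
        return "none"

    out["subtype"] = out.apply(label, axis=1)
    return out
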