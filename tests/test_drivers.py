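"""CPLD/CHIP filter cascades, the binomial germline test and subtype calls."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chbarcode import (CHIP_EXEMPT_SITES, binomial_germline_test,
                       chip_filter_cascade, classify_subtypes,
                       cpld_filter_cascade, load_chip_gene_panel,
                       load_published_cpld_list)
from chbarcode.drivers import binomial_germline_pvalues

CAND_COLS = ["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_reads",
             "gene", "hgvsp", "impact", "filter"]


def cand(sample, pos, depth, alt, gene="TET2", hgvsp="Q1084*", impact="HIGH",
         filt="PASS", chrom="chr4"):
    return (sample, chrom, pos, "G", "T", depth, alt, gene, hgvsp, impact, filt)


def table(rows):
    return pd.DataFrame(rows, columns=CAND_COLS)


def covariates(n=200, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"sample_id": [f"S{i:04d}" for i in range(n)],
                         "age": rng.uniform(40, 85, n),
                         "rs7705526_dosage": rng.binomial(2, 0.33, n)})


class TestBinomialGermlineTest:
    def test_symmetric_center_is_germline(self):
        p, germ = binomial_germline_test(20, 40)
        assert p == 1.0 and germ is True

    def test_low_vaf_rejects_germline(self):
        p, germ = binomial_germline_test(3, 30)
        # 2 * sum_{k<=3} C(30,k) / 2^30, computed exactly
        assert p == pytest.approx(9052 / 2**30, rel=1e-12)
        assert germ is False

    def test_degenerate_depth_one(self):
        p, germ = binomial_germline_test(0, 1)
        assert p == 1.0 and germ is True

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            binomial_germline_test(0, 0)

    def test_strict_inequality_at_alpha(self):
        # germline iff p > alpha, strictly
        p, germ = binomial_germline_test(10, 20, alpha=1.0)
        assert p == 1.0 and germ is False

    def test_vectorized_matches_scalar_and_is_symmetric(self):
        for n in range(1, 35):
            ks = np.arange(n + 1)
            vec = binomial_germline_pvalues(ks, np.full(n + 1, n))
            for k in ks:
                assert vec[k] == pytest.approx(
                    binomial_germline_test(int(k), n)[0], rel=1e-12)
            assert np.allclose(vec, vec[::-1])  # p(k) == p(n-k)


class TestCpldCascade:
    def test_call_quality_bounds(self):
        rows = [
            cand("S1", 1, 10, 5),            # depth 10: strict > 10 removes
            cand("S2", 2, 11, 5),            # kept to later steps
            cand("S3", 3, 100, 0),           # VAF 0 < 0.01
            cand("S4", 4, 100, 1),           # VAF exactly 0.01: kept
            cand("S5", 5, 100, 100),         # VAF 1.0 > 0.99 (also germline-like)
            cand("S6", 6, 30, 10, filt="LowQual"),
        ]
        retained, att = cpld_filter_cascade(table(rows))
        assert att.steps["call_quality"] == 4
        assert set(retained["sample_id"]) <= {"S2", "S4"}

    def test_recurrent_germline_removal(self):
        # one variant key carried by 6 samples, 5 with germline-like VAF:
        # fraction 5/6 > 0.75 and occurrences 6 > 5 -> whole key removed
        rows = [cand(f"S{i}", 100, 40, 20) for i in range(5)]
        rows.append(cand("S5", 100, 40, 8))       # somatic-like carrier
        rows.append(cand("S9", 200, 40, 8))       # unrelated somatic singleton
        retained, att = cpld_filter_cascade(table(rows))
        assert att.steps["recurrent_germline"] == 6
        assert set(retained["pos"]) == {200}

    def test_five_carriers_not_removed(self):
        rows = [cand(f"S{i}", 100, 40, 20) for i in range(5)]  # exactly 5 obs
        retained, _ = cpld_filter_cascade(table(rows))
        assert len(retained) == 5  # kept: > 5 observations required

    def test_impact_rule_enumeration(self):
        published = load_published_cpld_list()
        rows = [
            cand("S1", 1, 40, 8, gene="JAK2", hgvsp="E543*", impact="HIGH"),
            cand("S2", 2, 40, 8, gene="TET2", hgvsp="Q1084*", impact="HIGH"),
            cand("S3", 3, 40, 8, gene="JAK2", hgvsp="V617F", impact="MODERATE"),
            cand("S4", 4, 40, 8, gene="TET2", hgvsp="A999V", impact="MODERATE"),
            cand("S5", 5, 40, 8, gene="GNAS", hgvsp="Q227*", impact="HIGH"),
        ]
        retained, _ = cpld_filter_cascade(table(rows), published)
        # HIGH outside {GNAS,JAK2,SRSF2,SF3B1} or on the published list
        assert set(retained["sample_id"]) == {"S2", "S3"}

    def test_missing_impact_dropped_with_count(self):
        rows = [cand("S1", 1, 40, 8), cand("S2", 2, 40, 8, impact=None)]
        retained, att = cpld_filter_cascade(table(rows))
        assert att.steps["missing_impact"] == 1
        assert list(retained["sample_id"]) == ["S1"]

    def test_attrition_reconciles(self):
        rows = [cand(f"S{i}", i, 40, 8) for i in range(10)]
        rows += [cand(f"T{i}", 500, 9, 4) for i in range(3)]
        retained, att = cpld_filter_cascade(table(rows))
        assert att.n_input - sum(att.steps.values()) == len(retained)

    def test_step_order_is_load_bearing(self):
        # A recurrent mostly-germline key whose single somatic-looking carrier
        # is HIGH impact: the stated order (recurrence removal before the
        # impact rule) removes the whole key.  Were the impact rule applied
        # first, the surviving HIGH candidate would be a singleton key and
        # pass.  This pins the order.
        rows = [cand(f"S{i}", 100, 40, 20, impact="MODERATE", hgvsp="X1Y")
                for i in range(6)]
        high = cand("S7", 100, 40, 8, impact="HIGH")
        retained, _ = cpld_filter_cascade(table(rows + [high]))
        assert retained.empty
        # the same HIGH candidate alone survives the full cascade
        alone, _ = cpld_filter_cascade(table([high]))
        assert len(alone) == 1


class TestChipCascade:
    def test_depth_and_minad_bounds(self):
        cov = covariates()
        rows = [cand("S0001", 1, 19, 8),   # depth >= 20 fails
                cand("S0002", 2, 20, 3),   # boundary: depth 20, minAD 3 kept
                cand("S0003", 3, 40, 2)]   # minAD >= 3 fails
        retained, att = chip_filter_cascade(table(rows), cov)
        assert att.steps["depth_minad"] == 2
        assert list(retained["sample_id"]) == ["S0002"]

    def test_u2af1_always_excluded(self):
        cov = covariates()
        rows = [cand("S0001", 1, 40, 8, gene="U2AF1", hgvsp="S34F")]
        retained, att = chip_filter_cascade(table(rows), cov)
        assert retained.empty and att.steps["outside_panel"] == 1

    def test_panel_has_73_genes(self):
        assert len(load_chip_gene_panel()) == 73

    def test_fourteen_carriers_skip_recurrence_regression(self):
        cov = covariates()
        rng = np.random.default_rng(3)
        carriers = rng.choice(cov["sample_id"], 14, replace=False)
        rows = [cand(s, 100, 40, 8) for s in carriers]
        retained, att = chip_filter_cascade(table(rows), cov)
        assert att.steps["recurrence_regression"] == 0
        assert len(retained) == 14

    def test_recurrent_variant_unlinked_to_age_or_dosage_removed(self):
        cov = covariates(n=400, seed=1)
        rng = np.random.default_rng(4)
        carriers = rng.choice(cov["sample_id"], 60, replace=False)
        rows = [cand(s, 100, 40, 8) for s in carriers]
        retained, att = chip_filter_cascade(table(rows), cov)
        assert att.steps["recurrence_regression"] == 60
        assert retained.empty

    def test_age_linked_recurrent_variant_kept(self):
        cov = covariates(n=400, seed=1)
        rng = np.random.default_rng(5)
        p_carrier = 1 / (1 + np.exp(-(-8.0 + 0.1 * cov["age"])))
        carriers = cov.loc[rng.random(400) < p_carrier, "sample_id"]
        assert len(carriers) >= 15
        rows = [cand(s, 100, 40, 8) for s in carriers]
        retained, att = chip_filter_cascade(table(rows), cov)
        assert att.steps["recurrence_regression"] == 0
        assert len(retained) == len(carriers)

    def test_pooled_germline_removed_unless_exempt(self):
        cov = covariates()
        germline_like = [cand("S0001", 100, 40, 20, gene="TET2", hgvsp="A1B"),
                         cand("S0002", 100, 40, 21, gene="TET2", hgvsp="A1B")]
        exempt = [cand("S0003", 200, 40, 20, gene="TET2", hgvsp="H1904R"),
                  cand("S0004", 200, 40, 19, gene="TET2", hgvsp="H1904R")]
        somatic = [cand("S0005", 300, 40, 7, gene="TET2", hgvsp="C2D")]
        retained, att = chip_filter_cascade(
            table(germline_like + exempt + somatic), cov)
        assert att.steps["pooled_germline"] == 2
        assert set(retained["pos"]) == {200, 300}

    def test_exemption_set_is_closed(self):
        assert CHIP_EXEMPT_SITES == frozenset(
            {("TET2", "H1904R"), ("TET2", "I1873T"), ("TET2", "T1884A")})


class TestGermlineMisclassificationOracle:
    def test_rate_matches_exact_binomial_acceptance(self, rng):
        # spiked somatic drivers at fraction 0.6, depth 40: the chance the
        # exact test calls them potential germline equals the acceptance
        # probability sum_k P(p(k) > 0.05) under Binomial(40, 0.3)
        depth, frac, n_sim = 40, 0.6, 4000
        ks = np.arange(depth + 1)
        accept = binomial_germline_pvalues(ks, np.full(depth + 1, depth)) > 0.05
        p_accept = float(stats.binom.pmf(ks[accept], depth, frac / 2).sum())
        draws = rng.binomial(depth, frac / 2, n_sim)
        observed = float(np.mean(
            binomial_germline_pvalues(draws, np.full(n_sim, depth)) > 0.05))
        se = np.sqrt(p_accept * (1 - p_accept) / n_sim)
        assert abs(observed - p_accept) < 4 * max(se, 1e-4)


class TestClassifySubtypes:
    def calls(self):
        return pd.DataFrame({"sample_id": ["A", "B", "C", "D", "E"],
                             "is_ch": [True, True, False, False, True]})

    def drivers(self):
        return pd.DataFrame({"sample_id": ["A", "C", "C"],
                             "gene": ["DNMT3A", "JAK2", "TET2"]})

    def test_all_labels(self):
        out = classify_subtypes(self.calls(), self.drivers())
        labels = dict(zip(out["sample_id"], out["subtype"]))
        assert labels == {"A": "CPLD-CH", "B": "CPLDneg-CH", "C": "CPLD-only",
                          "D": "none", "E": "CPLDneg-CH"}
        genes = dict(zip(out["sample_id"], out["driver_genes"]))
        assert genes["C"] == "JAK2,TET2"

    def test_invariants(self):
        out = classify_subtypes(self.calls(), self.drivers())
        neg = out[out["subtype"] == "CPLDneg-CH"]
        assert neg["barcode_ch"].all() and not neg["cpld_ch"].any()
        only = out[out["subtype"] == "CPLD-only"]
        assert only["cpld_ch"].all() and not only["barcode_ch"].any()

    def test_unevaluable_samples_not_cpldneg(self):
        out = classify_subtypes(self.calls(), self.drivers(),
                                evaluated_samples={"A", "C", "D"})
        labels = dict(zip(out["sample_id"], out["subtype"]))
        assert labels["B"] == "unevaluable" and labels["E"] == "unevaluable"

    def test_duplicate_sample_hard_error(self):
        dup = pd.DataFrame({"sample_id": ["A", "A"], "is_ch": [True, False]})
        with pytest.raises(ValueError, match="duplicated"):
            classify_subtypes(dup, self.drivers())


class TestEndToEndDrivers:
    def test_simulated_driver_candidates_flow_through_cpld(self, small_cohort):
        retained, att = cpld_filter_cascade(small_cohort.drivers)
        assert att.n_input == len(small_cohort.drivers)
        # the recurrent germline leak-through sites must not survive
        leak = retained[retained["pos"].between(25_000_000, 25_000_010)]
        assert leak.empty
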