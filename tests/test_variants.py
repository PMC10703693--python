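"""Singleton extraction, indicator filters, VAF windows and barcode profiles."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chbarcode import (FilterConfig, build_profiles, find_singletons,
                       indicator_filter, indicator_filter_mask,
                       profile_cohort, profile_sample, window_codes)
from chbarcode.io import read_cohort, read_sample_vcf, write_sample_vcf
from chbarcode.variants import WINDOW_LABELS, in_vaf_window


def toy_variant_table(rows):
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_reads",
            "gq", "filter"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# VCF round trip and decomposition
# ---------------------------------------------------------------------------

class TestVcfIO:
    def test_round_trip(self, small_cohort, tmp_path):
        sid = small_cohort.variants["sample_id"].iloc[0]
        sample = small_cohort.variants[small_cohort.variants["sample_id"] == sid]
        path = write_sample_vcf(sample, str(sid), tmp_path / "s.vcf")
        back = read_sample_vcf(path)
        assert len(back) == len(sample)
        orig = sample.sort_values(["chrom", "pos"]).reset_index()
        for col in ("pos", "depth", "alt_reads"):
            assert (back[col].to_numpy() == orig[col].to_numpy()).all()
        assert (back["gq"].to_numpy() == orig["gq"].to_numpy()).all()
        assert not back["flagged"].any()

    def test_empty_vcf(self, tmp_path):
        empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "depth",
                                      "alt_reads", "gq", "filter"])
        path = write_sample_vcf(empty, "S0", tmp_path / "e.vcf")
        assert read_sample_vcf(path).empty

    def test_ad_dp_arithmetic_and_multiallelic(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tG\tA\t.\tPASS\t.\tGT:AD:DP:GQ\t0/1:25,15:40:99\n"
            "chr1\t200\t.\tC\tA,T\t.\tPASS\t.\tGT:AD:DP:GQ\t1/2:20,12,8:40:95\n"
            "chr1\t300\t.\tT\tG\t.\tPASS\t.\tGT:DP\t0/1:30\n")
        path = tmp_path / "m.vcf"
        path.write_text(text)
        tab = read_sample_vcf(path)
        biall = tab[tab["pos"] == 100].iloc[0]
        assert biall["alt_reads"] == 15 and biall["depth"] == 40
        assert biall["alt_reads"] / biall["depth"] == pytest.approx(0.375)
        multi = tab[tab["pos"] == 200]
        assert len(multi) == 2  # one row per ALT allele
        assert sorted(multi["alt"]) == ["A", "T"]
        assert sorted(multi["alt_reads"]) == [8, 12]
        flagged = tab[tab["pos"] == 300]
        assert flagged["flagged"].all()  # missing AD/GQ

    def test_sample_missing_from_manifest_is_hard_error(self, tmp_path):
        tab = toy_variant_table(
            [("GHOST", "chr1", 1, "A", "T", 30, 10, 99, "PASS")])
        path = write_sample_vcf(tab, "GHOST", tmp_path / "g.vcf")
        manifest = pd.DataFrame({"sample_id": ["S1"], "center": ["Vanguard"],
                                 "platform": ["UKB WGS"]})
        with pytest.raises(ValueError, match="absent from manifest"):
            read_cohort([path], manifest)


# ---------------------------------------------------------------------------
# Cohort singletons
# ---------------------------------------------------------------------------

def brute_force_singletons(table, key_cols):
    counts = Counter(tuple(row) for row in table[key_cols].itertuples(index=False))
    keep = [counts[tuple(row)] == 1
            for row in table[key_cols].itertuples(index=False)]
    return table.loc[keep]


class TestFindSingletons:
    def toy(self):
        return toy_variant_table([
            ("S1", "chr1", 100, "A", "T", 30, 10, 99, "PASS"),  # shared with S2
            ("S2", "chr1", 100, "A", "T", 30, 11, 99, "PASS"),
            ("S1", "chr1", 200, "A", "T", 30, 10, 99, "PASS"),  # singleton
            ("S2", "chr1", 300, "C", "G", 30, 10, 99, "PASS"),  # same pos, diff alt
            ("S3", "chr1", 300, "C", "A", 30, 10, 99, "PASS"),
        ])

    def test_matches_brute_force_enumeration(self):
        table = self.toy()
        got = find_singletons(table)
        expect = brute_force_singletons(table, ["chrom", "pos", "alt"])
        pd.testing.assert_frame_equal(got, expect)
        assert set(got["pos"]) == {200, 300}  # allele-level keys both kept

    def test_position_level_keying(self):
        got = find_singletons(self.toy(), key="position")
        assert set(got["pos"]) == {200}

    def test_ref_never_in_key(self):
        table = toy_variant_table([
            ("S1", "chr1", 50, "A", "T", 30, 10, 99, "PASS"),
            ("S2", "chr1", 50, "G", "T", 30, 10, 99, "PASS")])
        assert find_singletons(table).empty

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(1, 6),
                              st.sampled_from("ACGT")), max_size=25))
    def test_idempotent(self, rows):
        table = toy_variant_table([
            (f"S{s}", "chr1", pos, "A", alt, 30, 10, 99, "PASS")
            for s, pos, alt in rows])
        once = find_singletons(table)
        twice = find_singletons(once)
        pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# Indicator quality filter
# ---------------------------------------------------------------------------

class TestIndicatorFilter:
    @pytest.mark.parametrize("depth,alt,gq,filt,expect", [
        (40, 10, 90, "PASS", True),
        (40, 10, 89, "PASS", False),        # GQ bound is >= 90
        (15, 3, 90, "PASS", True),          # all boundaries inclusive
        (60, 3, 90, "Low_QD", True),        # Low_QD admitted
        (61, 3, 90, "PASS", False),
        (14, 3, 90, "PASS", False),
        (40, 2, 99, "PASS", False),         # alt reads >= 3
        (40, 3, 99, "LowQual", False),
    ])
    def test_boundaries(self, depth, alt, gq, filt, expect):
        assert indicator_filter(depth, alt, gq, filt) is expect

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_relaxing_any_threshold_is_monotone(self, data):
        rows = data.draw(st.lists(st.tuples(
            st.integers(1, 80), st.integers(0, 80), st.integers(0, 120),
            st.sampled_from(["PASS", "Low_QD", "LowQual"])), min_size=1,
            max_size=40))
        table = toy_variant_table([
            ("S1", "chr1", i + 1, "A", "T", d, min(a, d), q, f)
            for i, (d, a, q, f) in enumerate(rows)])
        strict = FilterConfig()
        base = set(np.flatnonzero(indicator_filter_mask(table, strict)))
        relaxations = [
            FilterConfig(min_gq=80), FilterConfig(min_depth=10),
            FilterConfig(max_depth=70), FilterConfig(min_alt_reads=1),
            FilterConfig(allowed_filters=frozenset({"PASS", "Low_QD", "LowQual"}))]
        for cfg in relaxations:
            relaxed = set(np.flatnonzero(indicator_filter_mask(table, cfg)))
            assert base <= relaxed


# ---------------------------------------------------------------------------
# VAF windows and profiles
# ---------------------------------------------------------------------------

class TestWindows:
    @pytest.mark.parametrize("alt,depth,label", [
        (10, 40, "LOW"),    # VAF exactly 0.25: upper bound inclusive
        (11, 40, None),     # 0.275: outside all windows
        (4, 40, "LOW"),     # 0.10 boundary
        (3, 30, "LOW"),     # 3/30 = 0.10 exactly: float-hazard case
        (2, 20, "LOW"),
        (7, 20, "MID"),     # 0.35 boundary
        (13, 20, "MID"),    # 0.65 boundary
        (15, 20, "HIGH"),   # 0.75 boundary
        (18, 20, "HIGH"),   # 0.90 boundary
        (19, 20, None),
        (27, 30, "HIGH"),   # 0.90 exactly via 27/30
    ])
    def test_closed_rational_bounds(self, alt, depth, label):
        code = window_codes([alt], [depth])[0]
        got = None if code < 0 else WINDOW_LABELS[code]
        assert got == label

    def test_windows_are_disjoint(self, rng):
        depth = rng.integers(1, 80, 3000)
        alt = rng.integers(0, 81, 3000) % (depth + 1)
        hits = sum(in_vaf_window(alt, depth, lo, hi).astype(int)
                   for _, lo, hi in
                   [("LOW", (1, 10), (1, 4)), ("MID", (7, 20), (13, 20)),
                    ("HIGH", (3, 4), (9, 10))])
        assert hits.max() <= 1


class TestProfiles:
    def test_uniform_mid_example(self):
        table = toy_variant_table([
            ("S1", "chr1", i + 1, "A", "T", 30, 15, 99, "PASS")
            for i in range(100)])
        prof = profile_sample(table)
        assert len(prof) == 1
        row = prof.iloc[0]
        assert (row["depth"], row["window"], row["count"]) == (30, "MID", 100)

    def test_rejects_multiple_samples(self):
        table = toy_variant_table([
            ("S1", "chr1", 1, "A", "T", 30, 15, 99, "PASS"),
            ("S2", "chr1", 2, "A", "T", 30, 15, 99, "PASS")])
        with pytest.raises(ValueError, match="single sample"):
            profile_sample(table)

    def test_counts_match_brute_force_recount(self, small_cohort):
        v = small_cohort.variants
        prof = profile_cohort(v)
        # independent recount with explicit float-free membership checks
        recount = Counter()
        for sid, depth, alt in zip(v["sample_id"], v["depth"], v["alt_reads"]):
            for label, (ln, ld), (hn, hd) in (
                    ("LOW", (1, 10), (1, 4)), ("MID", (7, 20), (13, 20)),
                    ("HIGH", (3, 4), (9, 10))):
                if alt * ld >= depth * ln and alt * hd <= depth * hn:
                    recount[(sid, depth, label)] += 1
        got = {(r.sample_id, r.depth, r.window): r.count
               for r in prof.itertuples()}
        assert got == dict(recount)

    def test_profile_total_equals_in_window_filtered_singletons(self, small_cohort):
        profiles, att = build_profiles(small_cohort.variants,
                                       small_cohort.manifest)
        assert profiles["count"].sum() <= att.n_retained
        att.check()  # step removals sum to input - retained
        assert att.n_input == len(small_cohort.variants)
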