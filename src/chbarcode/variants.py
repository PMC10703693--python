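"""Cohort singleton extraction, indicator-mutation filters and barcode profiles.

A "variant table" throughout this package is a pandas DataFrame with one row
per called ALT allele per sample, carrying at least the columns
``sample_id, chrom, pos, ref, alt, depth, alt_reads, gq, filter``.

VAF-window membership is decided with exact integer arithmetic
(``alt * den >= depth * num``), so boundary sites such as alt=3 at depth=30
(VAF exactly 0.10) land on the correct side of the closed bounds regardless
of floating-point representation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .config import FilterConfig

__all__ = [
    "WINDOWS",
    "WINDOW_LABELS",
    "window_codes",
    "in_vaf_window",
    "find_singletons",
    "indicator_filter",
    "indicator_filter_mask",
    "profile_sample",
    "profile_cohort",
    "build_profiles",
]

# (label, (lo_num, lo_den), (hi_num, hi_den)) — closed rational VAF bounds.
WINDOWS = (
    ("LOW", (1, 10), (1, 4)),     # 0.10 <= VAF <= 0.25: indicator window
    ("MID", (7, 20), (13, 20)),   # 0.35 <= VAF <= 0.65: germline heterozygote core
    ("HIGH", (3, 4), (9, 10)),    # 0.75 <= VAF <= 0.90: germline symmetry window
)
WINDOW_LABELS = tuple(w[0] for w in WINDOWS)


def in_vaf_window(alt_reads, depth, lo=(1, 10), hi=(1, 4)):
    """Vectorized closed-interval test lo <= alt/depth <= hi with rational bounds."""
    alt_reads = np.asarray(alt_reads, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    (ln, ld), (hn, hd) = lo, hi
    return (alt_reads * ld >= depth * ln) & (alt_reads * hd <= depth * hn)


def window_codes(alt_reads, depth):
    """Window index per variant: 0=LOW, 1=MID, 2=HIGH, -1=outside all windows.

    Windows are disjoint, so a variant lands in at most one.
    """
    alt_reads = np.asarray(alt_reads, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    out = np.full(alt_reads.shape, -1, dtype=np.int8)
    for idx, (_, lo, hi) in enumerate(WINDOWS):
        out[in_vaf_window(alt_reads, depth, lo, hi)] = idx
    return out


def _site_keys(table: pd.DataFrame, key: str) -> np.ndarray:
    """Composite int64 site key: fast path packs (chrom, pos[, alt]) into one
    integer; falls back to MultiIndex factorization if packing could overflow.
    """
    cols = ["chrom", "pos", "alt"] if key == "allele" else ["chrom", "pos"]
    chrom_codes, n_chrom = pd.factorize(table["chrom"], use_na_sentinel=False)[0], None
    n_chrom = int(chrom_codes.max()) + 1 if len(chrom_codes) else 1
    pos = table["pos"].to_numpy(dtype=np.int64)
    max_pos = int(pos.max()) + 1 if len(pos) else 1
    if key == "allele":
        alt_codes = pd.factorize(table["alt"], use_na_sentinel=False)[0]
        n_alt = int(alt_codes.max()) + 1 if len(alt_codes) else 1
    else:
        alt_codes, n_alt = 0, 1
    if float(max_pos) * n_chrom * n_alt < 2**62:
        return (pos * n_chrom + chrom_codes) * n_alt + alt_codes
    return pd.MultiIndex.from_frame(table[cols]).factorize()[0]


def singleton_mask(table: pd.DataFrame, key: str = "allele") -> np.ndarray:
    """Boolean mask of rows whose site key occurs exactly once cohort-wide."""
    if table.empty:
        return np.zeros(0, dtype=bool)
    keys = _site_keys(table, key)
    codes, _ = pd.factorize(keys, use_na_sentinel=False)
    counts = np.bincount(codes)
    return counts[codes] == 1


def find_singletons(table: pd.DataFrame, key: str = "allele") -> pd.DataFrame:
    """Retain variants whose site key is carried by exactly one sample cohort-wide.

    The key is (chrom, pos, alt) by default — barcode mutations are allele
    events — or (chrom, pos) with ``key='position'``.  REF and sample never
    enter the key.  Idempotent: singletons of singletons are themselves.
    """
    if table.empty:
        return table
    return table.loc[singleton_mask(table, key)]


def _is_snv(table: pd.DataFrame) -> np.ndarray:
    ref = table["ref"].astype(str).str.len().to_numpy()
    alt = table["alt"].astype(str).str.len().to_numpy()
    return (ref == 1) & (alt == 1)


def indicator_filter_mask(table: pd.DataFrame, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Boolean mask of records passing every indicator-mutation quality filter."""
    gq_ok = table["gq"].to_numpy() >= cfg.min_gq
    filt_ok = table["filter"].isin(cfg.allowed_filters).to_numpy()
    depth = table["depth"].to_numpy()
    depth_ok = (depth >= cfg.min_depth) & (depth <= cfg.max_depth)
    alt_ok = table["alt_reads"].to_numpy() >= cfg.min_alt_reads
    return gq_ok & filt_ok & depth_ok & alt_ok


def indicator_filter(depth: int, alt_reads: int, gq: float, filter_status: str,
                     cfg: FilterConfig = FilterConfig()) -> bool:
    """Scalar form of the quality filter (all four bounds inclusive as printed)."""
    return bool(
        gq >= cfg.min_gq
        and filter_status in cfg.allowed_filters
        and cfg.min_depth <= depth <= cfg.max_depth
        and alt_reads >= cfg.min_alt_reads
    )


def _counts_frame(table: pd.DataFrame) -> pd.DataFrame:
    """(sample_id, depth, window) -> count over in-window rows of ``table``.

    Implemented as one bincount over a packed (sample, depth, window) index;
    this is the hot path for cohort-scale tables.
    """
    win = window_codes(table["alt_reads"], table["depth"])
    keep = win >= 0
    sid_codes, sid_levels = pd.factorize(table["sample_id"], use_na_sentinel=False)
    sid = sid_codes[keep].astype(np.int64)
    depth = table["depth"].to_numpy(dtype=np.int64)[keep]
    w = win[keep].astype(np.int64)
    n_depth = int(depth.max()) + 1 if len(depth) else 1
    packed = (sid * n_depth + depth) * 3 + w
    counts = np.bincount(packed)
    nz = np.flatnonzero(counts)
    out = pd.DataFrame({
        "sample_id": np.asarray(sid_levels)[nz // (3 * n_depth)],
        "depth": (nz // 3) % n_depth,
        "window": np.asarray(WINDOW_LABELS)[nz % 3],
        "count": counts[nz],
    })
    return out.sort_values(["sample_id", "depth", "window"],
                           kind="mergesort", ignore_index=True)


def profile_sample(sample_table: pd.DataFrame) -> pd.DataFrame:
    """Barcode profile of one sample: counts by exact integer depth and VAF window.

    Input rows must all belong to one sample and should already be filtered
    cohort singletons.  Variants outside all three windows are counted
    nowhere.
    """
    if sample_table.empty:
        return pd.DataFrame(columns=["sample_id", "depth", "window", "count"])
    if sample_table["sample_id"].nunique() > 1:
        raise ValueError("profile_sample expects records from a single sample")
    return _counts_frame(sample_table)


def profile_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Barcode profiles for every sample in a filtered-singleton variant table."""
    if table.empty:
        return pd.DataFrame(columns=["sample_id", "depth", "window", "count"])
    return _counts_frame(table)


@dataclass
class FilterAttrition:
    """Per-step removal counts; each record is removed by exactly one step."""

    n_input: int = 0
    n_missing_fields: int = 0
    n_non_snv: int = 0
    n_non_singleton: int = 0
    n_fail_gq: int = 0
    n_fail_filter_status: int = 0
    n_fail_depth: int = 0
    n_fail_alt_reads: int = 0
    n_retained: int = 0

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))

    def check(self) -> None:
        removed = (self.n_missing_fields + self.n_non_snv + self.n_non_singleton
                   + self.n_fail_gq + self.n_fail_filter_status
                   + self.n_fail_depth + self.n_fail_alt_reads)
        if removed + self.n_retained != self.n_input:
            raise AssertionError("attrition counts do not sum to input size")


def build_profiles(variants: pd.DataFrame, manifest: pd.DataFrame,
                   cfg: FilterConfig = FilterConfig()):
    """Full filter chain: singletons -> quality filters -> per-sample profiles.

    Singleton determination happens before the per-variant quality filters
    (singletons are extracted from the raw cohort, then filtered), after the
    SNV restriction when ``cfg.snv_only``.  Returns ``(profiles, attrition)``
    where profiles carry center/platform merged from the manifest.
    """
    att = FilterAttrition(n_input=len(variants))
    table = variants

    # cumulative boolean masks: no intermediate table copies on cohort-scale
    # input; each removal is attributed to the first step that rejects it
    alive = np.ones(len(table), dtype=bool)

    if "flagged" in table.columns:
        bad = table["flagged"].to_numpy().astype(bool)
        att.n_missing_fields = int((alive & bad).sum())
        alive &= ~bad

    if cfg.snv_only and len(table):
        snv = _is_snv(table)
        att.n_non_snv = int((alive & ~snv).sum())
        alive &= snv

    if len(table):
        # singleton status is judged on the cohort that reaches this step
        single = np.zeros(len(table), dtype=bool)
        key_cols = ["chrom", "pos"] + (["alt"] if cfg.singleton_key == "allele" else [])
        single[alive] = singleton_mask(table.loc[alive, key_cols], cfg.singleton_key)
        att.n_non_singleton = int((alive & ~single).sum())
        alive &= single

        gq_ok = table["gq"].to_numpy() >= cfg.min_gq
        att.n_fail_gq = int((alive & ~gq_ok).sum())
        alive &= gq_ok

        f_ok = table["filter"].isin(cfg.allowed_filters).to_numpy()
        att.n_fail_filter_status = int((alive & ~f_ok).sum())
        alive &= f_ok

        depth = table["depth"].to_numpy()
        d_ok = (depth >= cfg.min_depth) & (depth <= cfg.max_depth)
        att.n_fail_depth = int((alive & ~d_ok).sum())
        alive &= d_ok

        a_ok = table["alt_reads"].to_numpy() >= cfg.min_alt_reads
        att.n_fail_alt_reads = int((alive & ~a_ok).sum())
        alive &= a_ok

    att.n_retained = int(alive.sum())
    att.check()

    retained = table.loc[alive, ["sample_id", "depth", "alt_reads"]]
    profiles = profile_cohort(retained)
    meta = manifest[["sample_id", "center", "platform"]]
    profiles = profiles.merge(meta, on="sample_id", how="left")
    return profiles, att
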