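"""Germline-contamination ratio model and the mutational-barcode CH caller.

The somatic-count estimator rests on three assumptions about germline
heterozygotes: (i) the expected counts in the VAF windows 0.10-0.25 and
0.75-0.90 are equal (the binomial read-sampling distribution is symmetric
about 0.5); (ii) essentially everything in 0.35-0.65 and 0.75-0.90 is
germline; (iii) the ratio HIGH/MID is constant across participants given
read depth and sequencing center.  The cohort-fitted ratio r(center, depth)
therefore converts a sample's observed MID counts into its expected germline
contamination of the LOW (indicator) window:

    E = sum_d r(center, d) * MID(d),        d >= 21
    S = sum_d LOW(d) - E                    (may be negative; never clamped)

A sample is called CH when S meets the center/platform-adjusted threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .config import FilterConfig, ThresholdConfig
from .variants import build_profiles

__all__ = [
    "GermlineRatioModel",
    "CHCall",
    "fit_germline_ratio",
    "expected_germline",
    "estimate_somatic",
    "call_ch",
    "score_cohort",
    "call_cohort",
    "run_barcode_pipeline",
    "call_from_tables",
]

NEIGHBOR_POOL = 2  # +/- depth window for the zero-denominator fallback


@dataclass
class GermlineRatioModel:
    """Fitted ratio r(center, depth) = HIGH/MID over cohort totals.

    Fallback chain for a (center, depth) cell with no MID counts: ratio
    pooled over depth +/- ``NEIGHBOR_POOL`` within the center, then the
    center-wide pooled ratio, then the cohort-wide pooled ratio, then 0.
    Depths outside [min_depth, max_depth] are never stored or scored.
    """

    table: pd.DataFrame            # columns: center, depth, ratio, n_mid, n_high
    min_depth: int = 21
    max_depth: int = 60
    center_pooled: Mapping[str, float] = field(default_factory=dict)
    global_pooled: float = 0.0

    def __post_init__(self):
        r = self.table["ratio"].to_numpy()
        if len(r) and (not np.all(np.isfinite(r)) or (r < 0).any()):
            raise ValueError("fitted ratios must be finite and >= 0")
        if len(self.table) and int(self.table["depth"].min()) < self.min_depth:
            raise ValueError("model contains depths below min_depth")

    def ratio(self, center: str, depth: int) -> float:
        if not self.min_depth <= depth <= self.max_depth:
            return 0.0
        hit = self.table[(self.table["center"] == center)
                         & (self.table["depth"] == depth)]
        if len(hit):
            return float(hit["ratio"].iloc[0])
        if center in self.center_pooled:
            return float(self.center_pooled[center])
        return float(self.global_pooled)

    def to_yaml(self, path) -> None:
        out = {"min_depth": int(self.min_depth), "max_depth": int(self.max_depth),
               "global_pooled": float(self.global_pooled),
               "center_pooled": {k: float(v) for k, v in self.center_pooled.items()},
               "ratios": {}}
        for center, grp in self.table.groupby("center", observed=True):
            out["ratios"][str(center)] = {
                int(d): float(r) for d, r in zip(grp["depth"], grp["ratio"])}
        Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


@dataclass
class CHCall:
    sample_id: str
    observed_low: int
    expected_germline: float
    estimated_somatic: float
    effective_threshold: float
    is_ch: bool
    center: str
    platform: str

    def __post_init__(self):
        if self.expected_germline < 0:
            raise ValueError("expected_germline must be >= 0")
        if self.is_ch != (self.estimated_somatic >= self.effective_threshold):
            raise ValueError("is_ch inconsistent with threshold rule")


def fit_germline_ratio(profiles: pd.DataFrame, min_depth: int = 21,
                       max_depth: int = 60) -> GermlineRatioModel:
    """Fit r(center, depth) from cohort barcode profiles.

    ``profiles`` has columns sample_id, center, depth, window, count.  Totals
    are summed over samples per (center, depth); only depths in
    [min_depth, max_depth] enter the model.
    """
    if profiles is None or profiles.empty:
        raise ValueError("cannot fit a germline ratio model on an empty cohort")
    sub = profiles[(profiles["depth"] >= min_depth)
                   & (profiles["depth"] <= max_depth)
                   & profiles["window"].isin(["MID", "HIGH"])]
    pivot = (sub.groupby(["center", "depth", "window"], observed=True)["count"]
                .sum().unstack("window", fill_value=0)
                .reindex(columns=["MID", "HIGH"], fill_value=0)
                .reset_index())

    glob_mid = float(pivot["MID"].sum())
    glob_high = float(pivot["HIGH"].sum())
    global_pooled = glob_high / glob_mid if glob_mid > 0 else 0.0

    rows = []
    center_pooled = {}
    for center, grp in pivot.groupby("center", observed=True):
        grp = grp.set_index("depth")
        c_mid, c_high = float(grp["MID"].sum()), float(grp["HIGH"].sum())
        c_pool = c_high / c_mid if c_mid > 0 else global_pooled
        center_pooled[center] = c_pool
        for d in grp.index:
            mid = float(grp.at[d, "MID"])
            high = float(grp.at[d, "HIGH"])
            if mid > 0:
                r = high / mid
            else:
                lo, hi = d - NEIGHBOR_POOL, d + NEIGHBOR_POOL
                near = grp.loc[(grp.index >= lo) & (grp.index <= hi)]
                n_mid = float(near["MID"].sum())
                r = float(near["HIGH"].sum()) / n_mid if n_mid > 0 else c_pool
            rows.append({"center": center, "depth": int(d), "ratio": r,
                         "n_mid": mid, "n_high": high})
    table = pd.DataFrame(rows, columns=["center", "depth", "ratio", "n_mid", "n_high"])
    return GermlineRatioModel(table, min_depth, max_depth, center_pooled, global_pooled)


def _sample_window_counts(profile: pd.DataFrame, model: GermlineRatioModel):
    """Per-depth LOW and MID counts of one sample within the model's depth range."""
    sub = profile[(profile["depth"] >= model.min_depth)
                  & (profile["depth"] <= model.max_depth)]
    low = sub[sub["window"] == "LOW"].set_index("depth")["count"]
    mid = sub[sub["window"] == "MID"].set_index("depth")["count"]
    return low, mid


def expected_germline(profile: pd.DataFrame, model: GermlineRatioModel,
                      center: Optional[str] = None) -> float:
    """Expected germline contamination E of the indicator window for one sample."""
    if profile.empty:
        return 0.0
    if center is None:
        center = profile["center"].iloc[0] if "center" in profile else ""
    _, mid = _sample_window_counts(profile, model)
    return float(sum(model.ratio(center, int(d)) * c for d, c in mid.items()))


def estimate_somatic(profile: pd.DataFrame, model: GermlineRatioModel,
                     center: Optional[str] = None) -> float:
    """Estimated somatic singleton count S = observed LOW - E (not clamped)."""
    if profile.empty:
        return 0.0
    low, _ = _sample_window_counts(profile, model)
    return float(low.sum()) - expected_germline(profile, model, center)


def call_ch(estimated_somatic: float, center: str, platform: str,
            cfg: ThresholdConfig = ThresholdConfig(), *,
            sample_id: str = "", observed_low: int = 0,
            expected: float = 0.0) -> CHCall:
    """Threshold decision: is_ch = (S >= T), no rounding of S or T."""
    t = cfg.resolve(center, platform)
    return CHCall(sample_id, observed_low, expected, float(estimated_somatic),
                  t, bool(estimated_somatic >= t), center, platform)


def score_cohort(profiles: pd.DataFrame, manifest: pd.DataFrame,
                 model: GermlineRatioModel) -> pd.DataFrame:
    """Vectorized per-sample observed/expected/estimated somatic counts.

    Every manifest sample gets a row; samples with no in-window variants
    score observed_low = 0, E = 0, S = 0.
    """
    base = manifest[["sample_id", "center", "platform"]].copy()
    if profiles.empty:
        base["observed_low"] = 0
        base["expected_germline"] = 0.0
        base["estimated_somatic"] = 0.0
        return base

    sub = profiles[(profiles["depth"] >= model.min_depth)
                   & (profiles["depth"] <= model.max_depth)].copy()
    low = (sub[sub["window"] == "LOW"].groupby("sample_id", observed=True)["count"]
           .sum().rename("observed_low"))
    mid = sub[sub["window"] == "MID"][["sample_id", "center", "depth", "count"]].copy()
    mid = mid.merge(model.table[["center", "depth", "ratio"]],
                    on=["center", "depth"], how="left")
    if mid["ratio"].isna().any():  # unseen (center, depth) cells: fallback chain
        miss = mid["ratio"].isna()
        mid.loc[miss, "ratio"] = [
            model.ratio(c, int(d))
            for c, d in zip(mid.loc[miss, "center"], mid.loc[miss, "depth"])]
    exp = ((mid["ratio"] * mid["count"]).groupby(mid["sample_id"], observed=True)
           .sum().rename("expected_germline"))

    out = base.merge(low, on="sample_id", how="left").merge(
        exp, on="sample_id", how="left")
    out["observed_low"] = out["observed_low"].fillna(0).astype(int)
    out["expected_germline"] = out["expected_germline"].fillna(0.0)
    out["estimated_somatic"] = out["observed_low"] - out["expected_germline"]
    return out


def call_cohort(scores: pd.DataFrame,
                cfg: ThresholdConfig = ThresholdConfig()) -> pd.DataFrame:
    """Apply the threshold rule to a cohort score table."""
    out = scores.copy()
    pairs = out[["center", "platform"]].drop_duplicates()
    tmap = {(c, p): cfg.resolve(c, p) for c, p in pairs.itertuples(index=False)}
    out["threshold"] = [tmap[(c, p)] for c, p in zip(out["center"], out["platform"])]
    out["is_ch"] = out["estimated_somatic"] >= out["threshold"]
    return out


def call_from_tables(variants: pd.DataFrame, manifest: pd.DataFrame,
                     filter_cfg: FilterConfig = FilterConfig(),
                     threshold_cfg: ThresholdConfig = ThresholdConfig(),
                     min_depth: int = 21):
    """Filter -> profile -> fit -> score -> call, all in memory.

    Returns ``(ch_calls, model, attrition)``.  Deterministic given inputs.
    """
    profiles, attrition = build_profiles(variants, manifest, filter_cfg)
    if profiles.empty:
        calls = manifest[["sample_id", "center", "platform"]].copy()
        calls["observed_low"] = 0
        calls["expected_germline"] = 0.0
        calls["estimated_somatic"] = 0.0
        calls = call_cohort(calls, threshold_cfg)
        return calls, None, attrition
    model = fit_germline_ratio(profiles, min_depth=min_depth,
                               max_depth=filter_cfg.max_depth)
    scores = score_cohort(profiles, manifest, model)
    calls = call_cohort(scores, threshold_cfg)
    return calls, model, attrition


def run_barcode_pipeline(vcf_dir, manifest_path, out_dir=None,
                         filter_cfg: FilterConfig = FilterConfig(),
                         threshold_cfg: ThresholdConfig = ThresholdConfig(),
                         min_depth: int = 21):
    """File-level pipeline: read per-sample VCFs + manifest, emit CH calls.

    Writes ``ch_calls.tsv``, ``germline_ratio_model.yaml`` and
    ``attrition.tsv`` under ``out_dir`` when given.
    """
    from .io import read_cohort, read_manifest

    manifest = read_manifest(manifest_path)
    paths = sorted(Path(vcf_dir).glob("*.vcf"))
    variants = read_cohort(paths, manifest)
    calls, model, attrition = call_from_tables(
        variants, manifest, filter_cfg, threshold_cfg, min_depth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out / "ch_calls.tsv", sep="\t", index=False)
        attrition.to_series().to_csv(out / "attrition.tsv", sep="\t", header=False)
        if model is not None:
            model.to_yaml(out / "germline_ratio_model.yaml")
    return calls, model, attrition
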