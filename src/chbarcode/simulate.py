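"""Synthetic WGS cohort generator with known clonal-hematopoiesis ground truth.

Each simulated sample is a table of called variants built from four origins:

* ``germline``  — private heterozygous sites, alt reads ~ Binomial(depth, 0.5),
  so the VAF distribution is symmetric about 0.5 by construction and the
  expected counts in the 0.10–0.25 and 0.75–0.90 windows are equal;
* ``shared``    — cohort-shared germline heterozygotes drawn from a common
  pool, hence never cohort singletons;
* ``clone``     — present only when the sample carries a clone of cell
  fraction f: private somatic sites at Binomial(depth, f/2) (heterozygous
  mutation in a diploid clone);
* ``artifact``  — a sequencing-error bump of records with exactly 1–2
  alternate reads, which the alt-reads >= 3 filter is designed to remove.

Clone presence follows an age-logistic prevalence curve with odds
multipliers for smoking (status, pack years, years since quitting) and
germline rs7705526 (TERT) dosage, so the downstream association layer has
real signal to recover.  Site coordinates are 1-based and globally unique
per private site, which makes every private site a cohort singleton exactly.

All randomness flows through one ``numpy.random.Generator``; identical seeds
give byte-identical tables.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig, CenterConfig
from .variants import in_vaf_window

__all__ = [
    "TruthRecord",
    "SimulatedCohort",
    "PositionAllocator",
    "simulate_sample",
    "simulate_cohort",
    "spike_driver",
    "DRIVER_CATALOG",
]

_BASES = np.array(["A", "C", "G", "T"])
_CHROMS = [f"chr{i}" for i in range(1, 23)]
_FILTER_LEVELS = ["PASS", "Low_QD", "LowQual"]

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt",
                   "depth", "alt_reads", "gq", "filter", "origin"]

# Known driver mutations the simulator can spike into a clone:
# (gene, protein change, VEP-style impact, present in the published CPLD list)
DRIVER_CATALOG = (
    ("DNMT3A", "R882H", "MODERATE", True),
    ("JAK2", "V617F", "MODERATE", True),
    ("TET2", "Q1084*", "HIGH", False),
    ("ASXL1", "G646Wfs*12", "HIGH", False),
    ("TP53", "R175H", "MODERATE", True),
    ("SF3B1", "K700E", "MODERATE", True),
    ("SRSF2", "P95H", "MODERATE", True),
    ("PPM1D", "R552*", "HIGH", False),
    ("GNB1", "K57E", "MODERATE", True),
    ("CALR", "L367fs*46", "HIGH", False),
)
_CATALOG_BY_GENE = {g: (p, imp, pub) for g, p, imp, pub in DRIVER_CATALOG}


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample.

    ``true_somatic_singletons_in_window`` counts emitted clone-origin sites
    whose realized VAF lies in the closed indicator window [0.10, 0.25],
    before any quality filtering.
    """

    sample_id: str
    has_clone: bool
    clone_fraction: float
    true_somatic_singletons_in_window: int
    driver_gene: Optional[str] = None

    def __post_init__(self):
        if not self.has_clone and self.true_somatic_singletons_in_window != 0:
            raise ValueError("no clone implies zero true somatic singletons")


@dataclass
class SimulatedCohort:
    variants: pd.DataFrame
    manifest: pd.DataFrame
    truth: pd.DataFrame
    diagnoses: pd.DataFrame
    drivers: pd.DataFrame
    config: SimulationConfig = None


class PositionAllocator:
    """Hands out globally unique 1-based positions across the cohort.

    Private sites of different samples must never collide (they are the
    cohort singletons), so positions come from a single increasing counter,
    striped across chr1..chr22.
    """

    def __init__(self, start: int = 1_000_000):
        self._next = start

    def take(self, n: int):
        pos = np.arange(self._next, self._next + n, dtype=np.int64)
        self._next += n
        chrom_idx = (pos % 22).astype(np.int64)
        return pos, chrom_idx


def _draw_depths(center: CenterConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-variant read depth: Poisson / negative-binomial / constant, >= 1."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    disp = center.depth_dispersion
    if disp == 0:
        d = np.full(n, int(round(center.mean_depth)), dtype=np.int64)
    elif disp <= 1.0:
        d = rng.poisson(center.mean_depth, size=n).astype(np.int64)
    else:
        r = center.mean_depth / (disp - 1.0)
        d = rng.negative_binomial(r, 1.0 / disp, size=n).astype(np.int64)
    return np.maximum(d, 1)


def _draw_alleles(n: int, rng: np.random.Generator):
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _draw_qc(n: int, cfg: SimulationConfig, rng: np.random.Generator):
    gq = np.where(rng.random(n) < cfg.gq_fail_rate,
                  rng.integers(40, 90, size=n), 99).astype(np.int64)
    u = rng.random(n)
    filt = np.zeros(n, dtype=np.int8)                      # PASS
    filt[u < cfg.filter_fail_rate + cfg.low_qd_rate] = 1   # Low_QD
    filt[u < cfg.filter_fail_rate] = 2                     # LowQual
    return gq, filt


def _block(sample_id, chrom_idx, pos, ref, alt, depth, alt_reads, gq, filt, origin):
    keep = alt_reads >= 1  # a caller emits no record without alternate reads
    return {
        "sample_id": sample_id,
        "chrom_idx": chrom_idx[keep],
        "pos": pos[keep],
        "ref": ref[keep],
        "alt": alt[keep],
        "depth": depth[keep],
        "alt_reads": alt_reads[keep],
        "gq": gq[keep],
        "filter": filt[keep],
        "origin": origin,
    }


def _assemble(blocks, sample_ids=None) -> pd.DataFrame:
    """Concatenate origin blocks into a variant DataFrame with compact dtypes."""
    if not blocks:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    parts = {}
    for col in ("chrom_idx", "pos", "ref", "alt", "depth", "alt_reads", "gq", "filter"):
        parts[col] = np.concatenate([b[col] for b in blocks])
    n_each = [len(b["pos"]) for b in blocks]
    sid = np.concatenate([np.repeat(b["sample_id"], k) for b, k in zip(blocks, n_each)])
    origin = np.concatenate([np.repeat(b["origin"], k) for b, k in zip(blocks, n_each)])
    df = pd.DataFrame({
        "sample_id": pd.Categorical(sid, categories=sample_ids),
        "chrom": pd.Categorical.from_codes(parts["chrom_idx"].astype(np.int8)
                                           if parts["chrom_idx"].size else
                                           np.zeros(0, np.int8), categories=_CHROMS),
        "pos": parts["pos"],
        "ref": pd.Categorical(parts["ref"], categories=list(_BASES)),
        "alt": pd.Categorical(parts["alt"], categories=list(_BASES)),
        "depth": parts["depth"].astype(np.int32),
        "alt_reads": parts["alt_reads"].astype(np.int32),
        "gq": parts["gq"].astype(np.int16),
        "filter": pd.Categorical.from_codes(parts["filter"], categories=_FILTER_LEVELS),
        "origin": pd.Categorical(origin, categories=["germline", "shared", "clone", "artifact"]),
    })
    return df


def _clone_probability(config: SimulationConfig, age: float, smoking_status: str,
                       pack_years: float, years_quit: float, tert_dosage: int) -> float:
    p = config.clone_prevalence_fn(age)
    p = min(max(p, 1e-12), 1 - 1e-12)
    log_odds = np.log(p / (1 - p))
    if smoking_status == "current":
        log_odds += np.log(config.smoking_or_current) + config.pack_years_log_or * pack_years
    elif smoking_status == "previous":
        log_odds += (np.log(config.smoking_or_previous)
                     + config.pack_years_log_or * pack_years
                     + config.years_quit_log_or * years_quit)
    log_odds += config.tert_log_or * tert_dosage
    return float(1.0 / (1.0 + np.exp(-log_odds)))


def simulate_sample(config: SimulationConfig, age: float, center: CenterConfig,
                    rng: np.random.Generator, *, sample_id: str = "S0",
                    allocator: Optional[PositionAllocator] = None,
                    smoking_status: str = "never", pack_years: float = 0.0,
                    years_quit: float = 0.0, tert_dosage: int = 0,
                    force_clone: Optional[bool] = None, _as_blocks: bool = False):
    """Simulate one sample's private variant calls.

    Returns ``(variants, truth)``.  Cohort-shared sites are added by
    :func:`simulate_cohort`; a standalone call yields only private sites.
    Passing an ``allocator`` keeps positions disjoint across manual calls.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    alloc = allocator or PositionAllocator()
    blocks = []

    # private germline heterozygotes
    n_g = int(rng.poisson(config.n_germline_het))
    pos, cidx = alloc.take(n_g)
    depth = _draw_depths(center, n_g, rng)
    alt_reads = rng.binomial(depth, 0.5)
    ref, alt = _draw_alleles(n_g, rng)
    gq, filt = _draw_qc(n_g, config, rng)
    blocks.append(_block(sample_id, cidx, pos, ref, alt, depth, alt_reads,
                         gq, filt, "germline"))

    # clone
    if force_clone is None:
        p_clone = _clone_probability(config, age, smoking_status, pack_years,
                                     years_quit, tert_dosage)
        has_clone = bool(rng.random() < p_clone)
    else:
        has_clone = bool(force_clone)
    clone_fraction = 0.0
    true_in_window = 0
    if has_clone:
        clone_fraction = float(config.clone_fraction_dist.sample(rng))
        n_c = int(config.n_clone_mutations_dist.sample(rng))
        pos, cidx = alloc.take(n_c)
        depth = _draw_depths(center, n_c, rng)
        alt_reads = rng.binomial(depth, clone_fraction / 2.0)
        ref, alt = _draw_alleles(n_c, rng)
        gq, filt = _draw_qc(n_c, config, rng)
        b = _block(sample_id, cidx, pos, ref, alt, depth, alt_reads, gq, filt, "clone")
        true_in_window = int(in_vaf_window(b["alt_reads"], b["depth"]).sum())
        blocks.append(b)

    # sequencing-error bump: exactly 1-2 alternate reads
    n_e = int(rng.poisson(config.error_bump_rate))
    pos, cidx = alloc.take(n_e)
    depth = _draw_depths(center, n_e, rng)
    alt_reads = np.minimum(rng.integers(1, 3, size=n_e), depth)
    ref, alt = _draw_alleles(n_e, rng)
    gq, filt = _draw_qc(n_e, config, rng)
    blocks.append(_block(sample_id, cidx, pos, ref, alt, depth, alt_reads,
                         gq, filt, "artifact"))

    variants = blocks if _as_blocks else _assemble(blocks, sample_ids=[sample_id])
    truth = TruthRecord(sample_id, has_clone, clone_fraction, true_in_window)
    return variants, truth


def spike_driver(variants: pd.DataFrame, gene: str, protein_change: str,
                 clone_fraction: float, rng: np.random.Generator, *,
                 depth: Optional[int] = None, mean_depth: float = 35.0,
                 chrom: str = "chr9", pos: int = 5_073_770):
    """Append one driver-mutation record at alt reads ~ Binomial(depth, f/2).

    Returns ``(amended variant table, candidate row dict)``; the candidate row
    carries the annotation fields (gene, HGVS-p, impact) a somatic caller plus
    annotator would export.  A zero-depth site is never emitted (the table is
    returned unchanged with a ``None`` candidate).  An unknown gene raises a
    warning but the record is still emitted, with MODERATE impact.
    """
    if not 0 < clone_fraction <= 1:
        raise ValueError("clone_fraction must be in (0, 1]")
    if gene in _CATALOG_BY_GENE:
        _, impact, _ = _CATALOG_BY_GENE[gene]
    else:
        warnings.warn(f"unknown driver gene {gene!r}; emitting with MODERATE impact")
        impact = "MODERATE"
    d = int(depth) if depth is not None else int(rng.poisson(mean_depth))
    if d == 0:
        return variants, None
    alt_reads = int(rng.binomial(d, clone_fraction / 2.0))
    sample_id = variants["sample_id"].iloc[0] if len(variants) else "S0"
    row = pd.DataFrame({
        "sample_id": [sample_id], "chrom": [chrom], "pos": [pos],
        "ref": ["G"], "alt": ["T"], "depth": [d], "alt_reads": [alt_reads],
        "gq": [99], "filter": ["PASS"], "origin": ["clone"],
    })
    amended = pd.concat([variants, row], ignore_index=True) if len(variants) else row
    candidate = {
        "sample_id": sample_id, "chrom": chrom, "pos": pos, "ref": "G", "alt": "T",
        "depth": d, "alt_reads": alt_reads, "gene": gene, "hgvsp": protein_change,
        "impact": impact, "filter": "PASS",
    }
    return amended, candidate


# fixed loci for the driver-candidate table, one per catalog gene
_DRIVER_LOCI = {g: ("chr%d" % ((i % 22) + 1), 5_000_000 + 977 * i)
                for i, (g, _, _, _) in enumerate(DRIVER_CATALOG)}


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort: variants, manifest, truth, diagnoses and a
    somatic driver-candidate table, fully reproducible from ``config.seed``.
    """
    if config.n_samples < 2:
        raise ValueError("a cohort needs n_samples >= 2")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]
    alloc = PositionAllocator()

    # --- manifest covariates -------------------------------------------------
    ages = np.asarray(config.age_dist.sample(rng, n), dtype=float)
    sexes = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    u = rng.random(n)
    smoking = np.full(n, "never", dtype=object)
    smoking[u < config.current_smoker_rate + config.previous_smoker_rate] = "previous"
    smoking[u < config.current_smoker_rate] = "current"
    pack_years = np.where(smoking != "never",
                          config.pack_years_dist.sample(rng, n), 0.0)
    years_quit = np.where(smoking == "previous",
                          config.years_quit_dist.sample(rng, n), 0.0)
    tert_dosage = rng.binomial(2, config.tert_maf, size=n)
    wbc = np.clip(rng.normal(7.0, 1.8, n), 0.3, None)
    hgb = np.clip(rng.normal(14.0, 1.2, n), 4.0, None)
    plt = np.clip(rng.normal(250.0, 60.0, n), 10.0, None)
    # plant occasional grossly abnormal hematology to exercise exclusions
    for arr, low, high in ((wbc, 0.5, 1.4), (hgb, 5.0, 7.9), (plt, 15.0, 49.0)):
        mask = rng.random(n) < config.abnormal_hematology_rate
        arr[mask] = rng.uniform(low, high, mask.sum())
    mask = rng.random(n) < config.abnormal_hematology_rate
    wbc[mask] = rng.uniform(36.0, 60.0, mask.sum())

    # center assignment by configured fractions
    fracs = np.array([c.fraction for c in config.centers])
    center_idx = rng.choice(len(config.centers), size=n, p=fracs / fracs.sum())

    # --- shared germline pool ------------------------------------------------
    shared_blocks = []
    if config.shared_pool_size > 0:
        pool_pos, pool_cidx = alloc.take(config.shared_pool_size)
        pool_ref, pool_alt = _draw_alleles(config.shared_pool_size, rng)
        pool_freq = np.asarray(config.shared_carrier_freq.sample(
            rng, config.shared_pool_size), dtype=float)

    # --- per-sample private variants -----------------------------------------
    all_blocks = []
    truths = []
    driver_rows = []
    for i, sid in enumerate(sample_ids):
        center = config.centers[center_idx[i]]
        blocks, truth = simulate_sample(
            config, float(ages[i]), center, rng, sample_id=sid, allocator=alloc,
            smoking_status=str(smoking[i]), pack_years=float(pack_years[i]),
            years_quit=float(years_quit[i]), tert_dosage=int(tert_dosage[i]),
            _as_blocks=True)
        all_blocks.extend(blocks)

        if config.shared_pool_size > 0:
            carry = rng.random(config.shared_pool_size) < pool_freq
            k = int(carry.sum())
            depth = _draw_depths(center, k, rng)
            alt_reads = rng.binomial(depth, 0.5)
            gq, filt = _draw_qc(k, config, rng)
            all_blocks.append(_block(sid, pool_cidx[carry], pool_pos[carry],
                                     pool_ref[carry], pool_alt[carry],
                                     depth, alt_reads, gq, filt, "shared"))

        if truth.has_clone and rng.random() < config.driver_spike_prob:
            gene, hgvsp, impact, _ = DRIVER_CATALOG[rng.integers(len(DRIVER_CATALOG))]
            chrom, posn = _DRIVER_LOCI[gene]
            d = int(_draw_depths(center, 1, rng)[0])
            alt_reads = int(rng.binomial(d, truth.clone_fraction / 2.0))
            if alt_reads >= 1:
                driver_rows.append({
                    "sample_id": sid, "chrom": chrom, "pos": posn, "ref": "G",
                    "alt": "T", "depth": d, "alt_reads": alt_reads, "gene": gene,
                    "hgvsp": hgvsp, "impact": impact, "filter": "PASS"})
                truth.driver_gene = gene
        truths.append(truth)

    # recurrent germline leak-through sites in the candidate table: many
    # carriers, VAF ~ 0.5 — what the >5 obs / >75% germline rule removes
    for j in range(config.candidate_germline_leak_sites):
        carriers = np.flatnonzero(rng.random(n) < config.candidate_germline_leak_freq)
        for i in carriers:
            center = config.centers[center_idx[i]]
            d = int(_draw_depths(center, 1, rng)[0])
            alt_reads = int(rng.binomial(d, 0.5))
            if alt_reads >= 1:
                driver_rows.append({
                    "sample_id": sample_ids[i], "chrom": "chr2",
                    "pos": 25_000_000 + j, "ref": "C", "alt": "A", "depth": d,
                    "alt_reads": alt_reads, "gene": "DNMT3A",
                    "hgvsp": f"P{700 + j}L", "impact": "MODERATE", "filter": "PASS"})

    variants = _assemble(all_blocks, sample_ids=sample_ids)
    manifest = pd.DataFrame({
        "sample_id": sample_ids,
        "center": [config.centers[j].label for j in center_idx],
        "platform": [config.centers[j].platform for j in center_idx],
        "age": np.round(ages, 2), "sex": sexes, "smoking_status": smoking,
        "pack_years": np.round(pack_years, 2), "years_quit": np.round(years_quit, 2),
        "wbc": np.round(wbc, 2), "hgb": np.round(hgb, 2), "plt": np.round(plt, 1),
        "rs7705526_dosage": tert_dosage,
    })
    truth = pd.DataFrame([vars(t) for t in truths])

    dx_rows = []
    heme_codes = ["C911", "D45", "C920", "D473", "C831"]
    for i, sid in enumerate(sample_ids):
        if rng.random() < config.heme_dx_rate:
            dx_rows.append({"sample_id": sid,
                            "icd10": heme_codes[rng.integers(len(heme_codes))],
                            "date_offset_days": int(rng.integers(-2000, 400))})
    diagnoses = pd.DataFrame(dx_rows, columns=["sample_id", "icd10", "date_offset_days"])

    drivers = pd.DataFrame(driver_rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_reads",
        "gene", "hgvsp", "impact", "filter"])
    return SimulatedCohort(variants, manifest, truth, diagnoses, drivers, config)
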