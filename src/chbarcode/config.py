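"""Configuration objects for the simulator, the indicator-mutation filters and the caller.

All printed method constants live here as dataclass defaults so that every
decision boundary of the pipeline (filter bounds, VAF windows, thresholds,
center adjustments) is visible and overridable in one place.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "Constant",
    "Uniform",
    "Poisson",
    "Gamma",
    "logistic_prevalence",
    "CenterConfig",
    "FilterConfig",
    "ThresholdConfig",
    "SimulationConfig",
]


# ---------------------------------------------------------------------------
# Small distribution objects: picklable, reproducible, YAML-representable.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constant:
    """Degenerate distribution returning a fixed value."""

    value: float

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not self.low <= self.high:
            raise ValueError(f"Uniform requires low <= high, got ({self.low}, {self.high})")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class Poisson:
    mean: float

    def __post_init__(self):
        if self.mean < 0:
            raise ValueError(f"Poisson mean must be >= 0, got {self.mean}")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.poisson(self.mean, size=size)


@dataclass(frozen=True)
class Gamma:
    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Gamma shape and scale must be positive")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)


def logistic_prevalence(p1: float = 0.01, age1: float = 40.0,
                        p2: float = 0.50, age2: float = 80.0) -> Callable[[float], float]:
    """Age -> clone probability curve through two (age, prevalence) anchors.

    The curve is linear on the logit scale, which reproduces the observed
    age dependence of clonal hematopoiesis: rare in the young, approaching
    one in two among the elderly.  Defaults anchor ~1% at age 40 and 50%
    at age 80.
    """
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValueError("prevalence anchors must lie strictly in (0, 1)")
    if age1 == age2:
        raise ValueError("anchor ages must differ")
    l1 = math.log(p1 / (1 - p1))
    l2 = math.log(p2 / (1 - p2))
    slope = (l2 - l1) / (age2 - age1)
    intercept = l1 - slope * age1

    def prevalence(age: float) -> float:
        z = intercept + slope * age
        return 1.0 / (1.0 + math.exp(-z))

    return prevalence


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CenterConfig:
    """One sequencing center/platform stratum of a cohort.

    ``depth_dispersion`` is the variance-to-mean ratio of per-variant read
    depth: 1 gives Poisson depth, > 1 negative binomial, and 0 a constant
    depth equal to ``round(mean_depth)`` (useful for fixed-depth experiments).
    """

    label: str
    platform: str
    fraction: float
    mean_depth: float
    depth_dispersion: float = 1.0

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"center fraction must be in [0,1], got {self.fraction}")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")


@dataclass(frozen=True)
class FilterConfig:
    """Indicator-mutation quality filters applied to cohort singletons.

    Defaults are the method's printed bounds: genotype quality >= 90,
    FILTER in {PASS, Low_QD}, 15 <= depth <= 60, alternate reads >= 3
    (which removes the spurious 1-2 read low-VAF error bump).  All bounds
    are inclusive.  ``singleton_key`` selects whether cohort uniqueness is
    judged per allele (chrom, pos, alt) or per position (chrom, pos).
    """

    min_gq: float = 90.0
    allowed_filters: frozenset = frozenset({"PASS", "Low_QD"})
    min_depth: int = 15
    max_depth: int = 60
    min_alt_reads: int = 3
    snv_only: bool = True
    singleton_key: str = "allele"  # or "position"

    def __post_init__(self):
        if self.singleton_key not in ("allele", "position"):
            raise ValueError("singleton_key must be 'allele' or 'position'")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")


@dataclass(frozen=True)
class ThresholdConfig:
    """Effective CH-calling thresholds on the estimated somatic count.

    The base threshold (20 somatic singleton indicator mutations) is
    adjusted additively per sequencing center (+1 Vanguard, -2.2 Sanger).
    Platform-specific absolute thresholds (46 for WGS NoPCR Nova, 32 for
    NEB WGS) override base+adjustment entirely where present, reflecting
    pipelines run without base-quality recalibration.
    """

    base_threshold: float = 20.0
    center_adjustments: Mapping[str, float] = field(
        default_factory=lambda: {"Vanguard": 1.0, "Sanger": -2.2})
    platform_thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"WGS NoPCR Nova": 46.0, "NEB WGS": 32.0})
    default_adjustment: float | None = None

    def resolve(self, center: str, platform: str) -> float:
        """Effective threshold for a (center, platform) pair.

        Raises ``KeyError`` for a center with no configured adjustment when
        no ``default_adjustment`` is set, listing the known centers.
        """
        if platform in self.platform_thresholds:
            return float(self.platform_thresholds[platform])
        if center in self.center_adjustments:
            return float(self.base_threshold + self.center_adjustments[center])
        if self.default_adjustment is not None:
            return float(self.base_threshold + self.default_adjustment)
        raise KeyError(
            f"no threshold adjustment configured for center {center!r}; "
            f"known centers: {sorted(self.center_adjustments)}")


def _default_centers():
    return (
        CenterConfig("Vanguard", "UKB WGS", 0.5, 33.0),
        CenterConfig("Sanger", "UKB WGS", 0.5, 33.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort generator.

    The generator emulates the statistical structure the barcode method
    assumes: private germline heterozygotes with alt reads ~ Binomial(depth,
    0.5); clone-private somatic sites at Binomial(depth, f/2) for clone cell
    fraction f; a low-VAF artifact bump of 1-2 alt-read records; a pool of
    cohort-shared germline sites (never cohort singletons); per-center depth
    laws; and clone prevalence rising with age (and smoking, and rs7705526
    dosage) on the odds scale.
    """

    n_samples: int = 100
    seed: int = 0
    centers: tuple = field(default_factory=_default_centers)
    n_germline_het: float = 30_000.0            # expected private het sites / sample
    shared_pool_size: int = 5_000               # cohort-shared germline sites
    shared_carrier_freq: Uniform = Uniform(0.05, 0.5)
    clone_prevalence_fn: Callable[[float], float] = field(
        default_factory=logistic_prevalence)
    clone_fraction_dist: object = Uniform(0.1, 0.6)      # clone cell fraction; VAF = f/2
    n_clone_mutations_dist: object = Poisson(120.0)      # founder barcode mutations
    error_bump_rate: float = 500.0              # expected 1-2 alt-read artifacts / sample
    driver_spike_prob: float = 0.3              # P(clone carries a named driver)
    age_dist: object = Uniform(40.0, 85.0)
    sex_ratio: float = 0.5                      # fraction female
    # smoking model: status frequencies and odds multipliers on clone prevalence
    current_smoker_rate: float = 0.10
    previous_smoker_rate: float = 0.35
    smoking_or_current: float = 2.0
    smoking_or_previous: float = 1.4
    pack_years_dist: object = Gamma(2.0, 10.0)
    pack_years_log_or: float = 0.02             # per pack-year, on clone odds
    years_quit_dist: object = Uniform(1.0, 30.0)
    years_quit_log_or: float = -0.03            # per year since quitting
    # rs7705526 (TERT) germline dosage effect on clone odds (reported OR 1.28)
    tert_maf: float = 0.33
    tert_log_or: float = math.log(1.28)
    # simulated QC: fraction of records failing GQ, carrying Low_QD, failing FILTER
    gq_fail_rate: float = 0.02
    low_qd_rate: float = 0.01
    filter_fail_rate: float = 0.02
    # manifest extras
    abnormal_hematology_rate: float = 0.005     # per abnormal-hematology mode
    heme_dx_rate: float = 0.005                 # prior/peri-draw hematological ICD10 dx
    # somatic driver-candidate table: recurrent germline leak-through sites
    candidate_germline_leak_sites: int = 3
    candidate_germline_leak_freq: float = 0.05

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        fracs = [c.fraction for c in self.centers]
        if not self.centers or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"center sample fractions must sum to 1, got {sum(fracs):.6f}")
        for name in ("driver_spike_prob", "sex_ratio", "current_smoker_rate",
                     "previous_smoker_rate", "gq_fail_rate", "low_qd_rate",
                     "filter_fail_rate", "abnormal_hematology_rate",
                     "heme_dx_rate", "candidate_germline_leak_freq", "tert_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.current_smoker_rate + self.previous_smoker_rate > 1:
            raise ValueError("smoker rates sum above 1")
        if self.n_germline_het < 0 or self.error_bump_rate < 0:
            raise ValueError("expected counts must be >= 0")
        if self.shared_pool_size < 0 or self.candidate_germline_leak_sites < 0:
            raise ValueError("pool sizes must be >= 0")
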