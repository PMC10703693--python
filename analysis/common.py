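"""Shared study-cohort definition for the numbered analysis drivers.

One mixed demonstration cohort is used across scripts 01-03 so their outputs
line up; it is regenerated deterministically from its seed, so each script
runs standalone.  Site counts are scaled down from the calibration
experiments (which use 30k het sites per sample) to keep the drivers quick;
the clone-to-background contrast the caller relies on is unchanged.
"""
from pathlib import Path

from chbarcode import CenterConfig, SimulationConfig, simulate_cohort

SEED = 20230
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def demo_config() -> SimulationConfig:
    return SimulationConfig(
        n_samples=250, seed=SEED, n_germline_het=4000, error_bump_rate=200,
        shared_pool_size=1000, driver_spike_prob=0.5,
        centers=(CenterConfig("Vanguard", "UKB WGS", 0.55, 33.0),
                 CenterConfig("Sanger", "UKB WGS", 0.45, 33.0)))


def demo_cohort():
    return simulate_cohort(demo_config())
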