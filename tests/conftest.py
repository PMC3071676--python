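import numpy as np
import pytest

from discbind.intervals import Peak, PeakSet
from discbind.motifscan import PWM
from discbind.synthdata import TruthConfig, make_genome, plant_sites


def make_peaks(label, centers, chrom="chr1", half=250):
    return PeakSet(
        label,
        [Peak(chrom, max(0, c - half), c + half, c) for c in centers],
    )


@pytest.fixture(scope="session")
def small_cfg():
    return TruthConfig(
        seed=7,
        n_chromosomes=1,
        chrom_length_bp=400_000,
        n_genes=30,
        n_sites={
            ("haltere", "Ubx"): 20,
            ("leg", "Ubx"): 20,
            ("haltere", "Hth"): 10,
            ("leg", "Hth"): 10,
        },
        tissue_shared_fraction=0.5,
        factor_cobound_fraction=0.2,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    genome = make_genome(small_cfg)
    truth = plant_sites(small_cfg, genome)
    return small_cfg, genome, truth


@pytest.fixture
def sharp_pwm():
    """An 8-position PWM with a strongly preferred base per column."""
    rng = np.random.default_rng(11)
    counts = np.full((8, 4), 5.0)
    for i, b in enumerate(rng.integers(0, 4, size=8)):
        counts[i, b] = 85.0
    return PWM.from_counts("sharp", counts)
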