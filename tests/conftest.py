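import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

import capxcise as cx


@pytest.fixture(scope="session")
def small_genome_config():
    """A compact diploid fixture: 60 kb target chromosome with a 1/6-copy
    minisatellite heterozygote, one 40 kb decoy carrying a 90% paralog."""
    from capxcise._dna import random_dna
    rng = np.random.default_rng(4242)   # distinct stream from the genome seed
    return cx.SyntheticGenomeConfig(
        seed=42,
        decoy_chromosomes=[cx.DecoySpec("tchr", 60_000, 0.4),
                           cx.DecoySpec("dchr", 40_000, 0.4)],
        target_locus=cx.TargetLocusSpec(
            chrom="tchr", insert_pos=30_000, flank=1_500,
            repeat_unit=random_dna(rng, 23, 0.5),
            copies_hap_a=1, copies_hap_b=6),
        paralog=cx.ParalogSpec(chrom="dchr", position=20_000, identity=0.90),
    )


@pytest.fixture(scope="session")
def small_genome(small_genome_config):
    return cx.make_genome(small_genome_config)


@pytest.fixture(scope="session")
def calibrated_outcome():
    """One full calibrated 7,000-read run, shared across tests."""
    return cx.calibrated_percentage(1)
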