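import pytest

import iclipkit as ik
from iclipkit.crosslinks import demultiplex


def run_sim_pipeline(config: ik.SimConfig):
    """Simulate, demultiplex, place and extract: the shared test pipeline."""
    genome, annotation, truth = ik.simulate_genome(config)
    reads, truth = ik.simulate_iclip_reads(genome, annotation, truth, config)
    demux = demultiplex(reads, list(config.barcode_sample_codes))
    trimmed = [r for c in config.barcode_sample_codes for r in demux.by_sample[c]]
    placed = ik.place_reads_exact(trimmed, genome, barcode_len=0)
    table = ik.extract_crosslinks(placed.records, annotation.chrom_lengths)
    return genome, annotation, truth, reads, placed, table


@pytest.fixture(scope="session")
def default_config():
    return ik.SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_run(default_config):
    """Full default-condition simulation shared across test modules."""
    return run_sim_pipeline(default_config)


@pytest.fixture(scope="session")
def aa_run():
    return run_sim_pipeline(ik.SimConfig(seed=1, affinity_mode="AA"))
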