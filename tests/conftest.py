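import pytest
from hypothesis import settings

import tagcapture as tc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config() -> tc.SimConfig:
    """A small, fast simulation: 200 kb genome, ~1 % accessible, 20 cells."""
    return tc.SimConfig(seed=7, contigs=(("chr1", 200_000),), n_cells=20)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return tc.generate_landscape(tiny_config)


@pytest.fixture(scope="session")
def tiny_events(tiny_model, tiny_config):
    return tc.simulate_insertions(tiny_model, tiny_config)


@pytest.fixture(scope="session")
def ths_library(tiny_model, tiny_config, tiny_events):
    """Unique THS alignments of the tiny simulation."""
    params = tc.CaptureParams(assay="THS", amp_factor=3)
    reads = tc.ths_capture(tiny_events, params, tiny_model)
    return tc.remove_clonal(tc.reads_to_alignments(reads))


def make_peakset(intervals, name="S"):
    """PeakSet from (contig, start, end) tuples."""
    from tagcapture.peak_calling import Peak, PeakSet
    return PeakSet([Peak(*iv) for iv in intervals], name=name)


@pytest.fixture
def peakset_factory():
    return make_peakset
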