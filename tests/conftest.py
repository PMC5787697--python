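import pytest

import clipshift as cs


@pytest.fixture(scope="session")
def toy_genome():
    return cs.make_genome(seed=101)


@pytest.fixture(scope="session")
def clip_data(toy_genome):
    """Reads + planted sites with boundary-weighted, GC-biased placement."""
    genome = cs.make_genome(seed=101)
    model = cs.BindingModel(
        region_weights={"exon_boundary": 3.0, "intron": 1.0, "intergenic": 1.0},
        gc_bias_exponent=1.0,
        conversion_probability=0.8,
        background_rate=0.1,
        n_sites=200,
    )
    reads, sites = cs.simulate_clip_reads(genome, model, n_reads=20_000, seed=102)
    return genome, model, reads, sites


@pytest.fixture(scope="session")
def called_peaks(clip_data):
    _genome, _model, reads, _sites = clip_data
    return cs.call_peaks(reads)
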