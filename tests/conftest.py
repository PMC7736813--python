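import pytest

from asmduet.synthetic_data import SimulationConfig, simulate, write_fixtures


@pytest.fixture(scope="session")
def small_truth():
    """A 2 x 1 Mb simulated truth with one tandem array and one dispersed pair."""
    config = SimulationConfig(
        seed=11,
        n_chromosomes=2,
        chromosome_len_bp=1_000_000,
        tandem_repeat_lengths=(23_000,),
        dispersed_dup_lengths=(48_000,),
        gene_density=30.0,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def fixture_dir(small_truth, tmp_path_factory):
    """The small truth written out as files, for I/O and pipeline tests."""
    outdir = tmp_path_factory.mktemp("fixtures")
    write_fixtures(small_truth, outdir)
    return outdir
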