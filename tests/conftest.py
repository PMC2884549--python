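import pytest

from tema import SimulationConfig, bin_peaks, build_matrix, emulate_td, identify_ancestral_loci, run_experiment


@pytest.fixture(scope="session")
def small_config():
    """A quiet little cohort: segregation only, no excision/gain/somatic noise."""
    return SimulationConfig(
        n_sexual=8,
        n_asexual=8,
        generations_mean=6,
        n_ancestral_loci=10,
        fraction_heterozygous=0.3,
        excision_rate=0.0,
        germline_transposition_rate=0.0,
        somatic_rate=0.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return run_experiment(small_config)


def score_cohort(lines, config, **kwargs):
    """Run the TD emulation + scoring stages and return the presence matrix."""
    tables = emulate_td(lines, config)
    counts = bin_peaks(tables, **kwargs)
    ancestral = identify_ancestral_loci(counts, n_lineages=len(lines))
    treatments = {ln.lineage_id: ln.treatment for ln in lines}
    return build_matrix(counts, ancestral, treatments)
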