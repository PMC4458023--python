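import pytest

from pinepop.pipeline import PipelineConfig, run_pipeline
from pinepop.simulate import SimulationConfig, simulate_complex, study_like_config


@pytest.fixture(scope="session")
def small_result():
    """A small four-taxon simulation without admixture, shared across tests."""
    cfg = SimulationConfig(
        n_contigs=40,
        contig_length_mean=600,
        contig_length_min=200,
        samples_per_species=(3, 3, 3, 3),
        admixed_sample=None,
        seed=11,
    )
    return simulate_complex(cfg)


@pytest.fixture(scope="session")
def study_result():
    """The 17-sample study-scale simulation with the admixed outlier."""
    return simulate_complex(study_like_config(seed=5))


@pytest.fixture(scope="session")
def study_pipeline(tmp_path_factory):
    """One full pipeline run on the study-scale configuration."""
    out = tmp_path_factory.mktemp("study_pipeline")
    cfg = PipelineConfig(
        simulation=study_like_config(seed=2),
        out_dir=str(out),
        n_permutations=200,
        seed=2,
        exclude_samples=["UN3"],
    )
    return run_pipeline(cfg)
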