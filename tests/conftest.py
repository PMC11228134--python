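import pytest
from hypothesis import HealthCheck, settings

from esourceflow.crf_model import canonical_dictionary, canonical_mapping_rules
from esourceflow.pipeline import PipelineConfig, run_pipeline
from esourceflow.synthetic_ehr import StudyConfig, generate_study, pilot_study_config

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dictionary():
    return canonical_dictionary()


@pytest.fixture(scope="session")
def mapping_rules(dictionary):
    return canonical_mapping_rules(dictionary)


@pytest.fixture(scope="session")
def pilot_config():
    return pilot_study_config(seed=1)


@pytest.fixture(scope="session")
def pilot_study(pilot_config):
    """(EHRStore, EDCTruth) for the pilot design; generated once per session."""
    return generate_study(pilot_config)


@pytest.fixture(scope="session")
def pilot_result(pilot_config, tmp_path_factory):
    """Full pipeline run on the pilot design (generate → ... → evaluate)."""
    out = tmp_path_factory.mktemp("pilot_run")
    return run_pipeline(PipelineConfig(study=pilot_config, output_dir=out))


@pytest.fixture(scope="session")
def noisy_result(tmp_path_factory):
    """Pipeline run with 10% transcription corruption over ~10k electronic points."""
    study = StudyConfig(
        n_patients=4,
        blood_tests_total=2000,
        blood_nonnull_points=10000,
        vitals_points_required=90,
        vitals_points_captured=90,
        urine_points_required=40,
        urine_points_captured=40,
        conmed_pages=10,
        conmed_pages_electronic=10,
        corruption_rate=0.1,
        seed=11,
    )
    out = tmp_path_factory.mktemp("noisy_run")
    return run_pipeline(PipelineConfig(study=study, output_dir=out))
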