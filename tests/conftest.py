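import pytest

from lncduplex import config_for_dataset, run_pipeline
from lncduplex.genomic_model import ScoringParams
from lncduplex.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def params():
    return ScoringParams()


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic dataset (seed 1) with its ground truth."""
    d = tmp_path_factory.mktemp("synth") / "ds"
    truth = generate_dataset(str(d), seed=1, validate="planted")
    return str(d), truth


@pytest.fixture(scope="session")
def pipeline_report(dataset, tmp_path_factory):
    """Full pipeline run on the default synthetic dataset."""
    d, _ = dataset
    out = tmp_path_factory.mktemp("run") / "out"
    return run_pipeline(config_for_dataset(d, str(out)))
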