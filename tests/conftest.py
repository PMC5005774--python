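import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quatstack.features import encode_features
from quatstack.stack import StackConfig, train_stack
from quatstack.synthetic import GeneratorSpec, generate_all

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small 3-class fixture set for cheap encoder/db tests."""
    spec = GeneratorSpec(
        n_blocks=6,
        n_domains=6,
        classes=("monomer", "homo:2", "hetero:2"),
        records_per_class=10,
        seed=11,
    )
    block_db, domain_db, records, truth = generate_all(spec)
    return spec, block_db, domain_db, records, truth


@pytest.fixture(scope="session")
def four_class_data():
    """4-class dataset at generator defaults (60 records/class, seed 7)."""
    spec = GeneratorSpec(
        classes=("monomer", "homo:2", "homo:3", "hetero:2"), seed=7
    )
    block_db, domain_db, records, truth = generate_all(spec)
    feats = encode_features(records, block_db=block_db, domain_db=domain_db)
    labels = [str(r.label) for r in records]
    return spec, block_db, domain_db, records, truth, feats, labels


@pytest.fixture(scope="session")
def four_class_model(four_class_data):
    _, _, _, _, _, feats, labels = four_class_data
    config = StackConfig(seed=7)
    return train_stack(feats, labels, config), config


@pytest.fixture(scope="session")
def default_six_class():
    """The full default study conditions: 6 classes x 60, embed 0.9, seed 7."""
    spec = GeneratorSpec()
    block_db, domain_db, records, truth = generate_all(spec)
    feats = encode_features(records, block_db=block_db, domain_db=domain_db)
    labels = [str(r.label) for r in records]
    return spec, block_db, domain_db, records, truth, feats, labels
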