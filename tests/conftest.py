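import pytest

from fermwatch import align_offline_online, fit_gam, make_study_set, split_batches

MODEL_VARS = ["T", "DO", "OUR", "CER"]


@pytest.fixture(scope="session")
def study_batches():
    return make_study_set(5, [], base_seed=11)


@pytest.fixture(scope="session")
def train_test(study_batches):
    return split_batches(study_batches)


@pytest.fixture(scope="session")
def training_table(train_test):
    train, _ = train_test
    return align_offline_online(train)


@pytest.fixture(scope="session")
def gam_fit(training_table):
    return fit_gam(training_table, MODEL_VARS)
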