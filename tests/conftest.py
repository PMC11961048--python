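import warnings

import pytest

import fairskin as fs
from fairskin.fixtures import CLASS_SUPPORTS, CONFUSION_MATRICES


@pytest.fixture(scope="session")
def chatgpt_cm():
    """Published chat-model confusion matrix scored against declared supports."""
    return fs.confusion_from_counts(
        CONFUSION_MATRICES["chatgpt4-web"], stratum="chatgpt4-web", support=CLASS_SUPPORTS
    )


@pytest.fixture(scope="session")
def all_fixture_cms():
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # three printed matrices are inconsistent
        for name, rows in CONFUSION_MATRICES.items():
            out[name] = fs.confusion_from_counts(rows, stratum=name, support=CLASS_SUPPORTS)
    return out


@pytest.fixture(scope="session")
def test_cohort():
    """Synthetic 972-record cohort with the published margins."""
    return fs.generate_cohort(fs.ham10000_test_cohort(), seed=20240101)


@pytest.fixture(scope="session")
def replayed_records(test_cohort):
    """Cohort with predictions simulated from the chat-model profile."""
    profile = fs.load_fixture_profile("chatgpt4-web")
    return fs.simulate_predictions(test_cohort, profile, seed=7)
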