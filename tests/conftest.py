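import warnings

import pytest

from ricelai.extraction import extract_observations, observation_table
from ricelai.synthetic import generate_campaign
from ricelai.validation import add_vi_columns

#: Seed of the reference synthetic study used by the campaign-level tests.
CAMPAIGN_SEED = 11


@pytest.fixture(scope="session")
def campaign():
    """The full study design: 48 cultivars x 13 flight dates, first flight
    contaminated by water specular pixels in 24 plots."""
    return generate_campaign(seed=CAMPAIGN_SEED)


@pytest.fixture(scope="session")
def observations(campaign):
    obs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # specular pixels exceed rho=1
        for scene in campaign.scenes:
            obs.extend(extract_observations(
                scene, campaign.true_calibration, campaign.cultivars,
                campaign.sampling,
            ))
    return obs


@pytest.fixture(scope="session")
def vi_table(observations):
    """Observation table with the eight index columns attached."""
    return add_vi_columns(observation_table(observations))
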