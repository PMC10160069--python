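import sys
from pathlib import Path

import pytest

# make the test-local synthetic reference oracle importable
sys.path.insert(0, str(Path(__file__).parent))

from buscarb import synthetic


@pytest.fixture(scope="session")
def small_survey():
    """A compact single-region survey used by several gridding tests."""
    cfg = synthetic.SurveyConfig(
        coastline=((14.0, -22.0), (14.0, -30.0)),
        lat_range=(-29.5, -22.5),
        offshore_max_km=250.0,
        n_tracks=12,
        points_per_track=60,
        seasonal_amplitude=0.0,
        seed=7,
    )
    return cfg, synthetic.generate_underway_survey(cfg)


@pytest.fixture(scope="session")
def default_bottles():
    cfg = synthetic.ProfileConfig(seed=11)
    return cfg, synthetic.generate_ctd_profiles(cfg)
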