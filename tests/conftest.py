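import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from mobispect.config import CohortConfig
from mobispect import synthetic as syn
from mobispect import inference as inf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_hc=2, n_bp=2, n_mdd=2, n_days=28, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return syn.generate_cohort(small_config)


def simulate_person_day_table(cfg: CohortConfig):
    """Cohort-wide person-day rows from the day-level feature emulator."""
    cohort = syn.generate_cohort(cfg)
    moods, feats = [], []
    for p in cohort:
        m = syn.simulate_mood_series(p, cfg)
        moods.append(m)
        feats.append(syn.simulate_day_features(p, m, cfg))
    moods = pd.concat(moods, ignore_index=True)
    feats = pd.concat(feats, ignore_index=True)
    cov = pd.DataFrame(
        [
            {
                "participant_id": p.id,
                "group": p.group,
                "age": p.age,
                "sex": p.sex,
                "employment": p.employment,
                "antidepressant": p.antidepressant,
            }
            for p in cohort
        ]
    )
    return inf.build_person_day_rows(feats.drop(columns=["weekday"]), moods, cov)


@pytest.fixture(scope="session")
def random_walk_bins():
    """A fully valid random-walk day of 10-s bins for feature oracles."""

    def make(seed: int, n: int = 360, step_sd: float = 8.0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        x = np.cumsum(rng.normal(0, step_sd, size=n))
        y = np.cumsum(rng.normal(0, step_sd, size=n))
        return pd.DataFrame(
            {"t": 10.0 * np.arange(n), "x": x, "y": y, "valid": True}
        )

    return make
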