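import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tempohmax.decision import RateSeries, Trial, accumulate
from tempohmax.frontend import SpikeEncoder
from tempohmax.pipeline import TemporalHMAX
from tempohmax.synthetic import FixtureSpec, generate_images

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# small fixture shared across the expensive end-to-end tests
FIXTURE_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8)
FIXTURE_SIZE = (64, 96)
FIXTURE_N = 8


@pytest.fixture(scope="session")
def small_fixture():
    return generate_images(
        FixtureSpec(
            image_size=FIXTURE_SIZE,
            n_per_category=FIXTURE_N,
            noise_levels=FIXTURE_LEVELS,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def encoder():
    return SpikeEncoder().fit()


@pytest.fixture(scope="session")
def fixture_trains(small_fixture, encoder):
    """Latency spike trains of the clean fixture images."""
    return encoder.transform(small_fixture.originals)


@pytest.fixture(scope="session")
def trained_clf(small_fixture):
    clf = TemporalHMAX(random_state=0)
    clf.fit(small_fixture.originals, [im.label for im in small_fixture.originals])
    return clf


def poisson_race_trials(
    seed: int,
    levels=(0.1, 0.3, 0.5, 0.7),
    n_per_level: int = 50,
    base_rate: float = 9.0,
    rate_span: float = 5.0,
    distractor_rate: float = 5.0,
    bin_width: float = 0.05,
    n_bins: int = 2000,
) -> list[Trial]:
    """Two-population Poisson evidence trials for decision-layer tests.

    The matched population's rate falls with noise level while the
    distractor rate is constant, so harder levels yield slower and less
    reliable decisions.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for lvl in levels:
        r_sig = base_rate - rate_span * lvl
        for cat in ("face", "house"):
            for _ in range(n_per_level // 2):
                rf = r_sig if cat == "face" else distractor_rate
                rh = r_sig if cat == "house" else distractor_rate
                cf = rng.poisson(rf * bin_width, n_bins).astype(float)
                ch = rng.poisson(rh * bin_width, n_bins).astype(float)
                trace = accumulate(
                    RateSeries(bin_width, cf, "face"),
                    RateSeries(bin_width, ch, "house"),
                )
                trials.append(Trial(trace, lvl, cat))
    return trials
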