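import numpy as np
import pytest

from triplematch import (
    COVARIATES,
    ScenarioConfig,
    estimate_multinomial_ps,
    generate_dataset,
    logit_transform,
)


@pytest.fixture(scope="session")
def big_table():
    """One large cohort for law-of-large-numbers checks (shared, read-only)."""
    cfg = ScenarioConfig.from_scenario("2:3:5", n_total=100_000, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_cohort():
    """A default 1:2:7 cohort with fitted logit scores (shared, read-only)."""
    cfg = ScenarioConfig.from_scenario("1:2:7", seed=11)
    table = generate_dataset(cfg)
    probs = estimate_multinomial_ps(table, list(COVARIATES))
    logits = logit_transform(probs)
    groups = table["group"].to_numpy()
    return table, probs, logits, groups


def random_logit_instance(rng, max_per_group=5, n_components=3, n_groups=3):
    """Small random matching instance for brute-force comparisons."""
    sizes = rng.integers(1, max_per_group + 1, size=n_groups)
    groups = np.repeat(np.arange(1, n_groups + 1), sizes)
    scores = rng.normal(scale=1.5, size=(sizes.sum(), n_components))
    return scores, groups
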