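import pytest

from wmhh.synthetic_cohort import (
    BiologySpec,
    RaterProfile,
    SiteSpec,
    generate_cohort,
    generate_subject,
)


@pytest.fixture(scope="session")
def default_site():
    return SiteSpec("S1", bias_amplitude=0.3, bias_smoothness=8.0, noise_sd=2.0,
                    age_mean=69.0, age_sd=5.0, age_min=60.0, age_max=85.0)


@pytest.fixture(scope="session")
def biology():
    return BiologySpec()


@pytest.fixture(scope="session")
def subject(default_site, biology):
    """One default synthetic subject on a small grid."""
    return generate_subject(default_site, biology, 70.0, seed=42, shape=(32, 32, 32))


@pytest.fixture(scope="session")
def clean_subject(biology):
    """Zero-noise, zero-bias subject: image equals the pure tissue-mean map."""
    site = SiteSpec("clean", bias_amplitude=0.0, noise_sd=0.0)
    return generate_subject(site, biology, 70.0, seed=7, shape=(32, 32, 32))


@pytest.fixture(scope="session")
def small_cohort(biology):
    """Single-site labelled cohort used by the segmentation tests."""
    site = SiteSpec("S1", bias_amplitude=0.15, bias_smoothness=8.0, noise_sd=3.0,
                    age_mean=69.0, age_sd=5.0, age_min=60.0, age_max=85.0,
                    n_subjects=14)
    rater = RaterProfile("R", boundary_jitter_sd=0.3, miss_prob_small=0.2,
                         size_threshold=6, dilation_bias=0.0)
    return generate_cohort([site], biology, [rater], seed=11, shape=(32, 32, 32),
                           labelled_per_site=13)


def random_mask_pair(rng, shape=(14, 14, 14), p=0.12):
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    return a, b
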