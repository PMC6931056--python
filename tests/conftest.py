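import numpy as np
import pytest

from gaitbeep import GaitProfile, extract_sagittal, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One deterministic 2-minute session with the default profile."""
    profile = GaitProfile(seed=12345)
    series, truth = simulate_session(profile)
    return profile, series, truth


@pytest.fixture(scope="session")
def default_trace(default_session):
    _, series, _ = default_session
    return extract_sagittal(series)


@pytest.fixture
def random_profile_factory():
    """Profiles drawn over realistic ranges from an externally seeded RNG."""

    def make(rng: np.random.Generator, *, walk: float = 60.0,
             noise_sd: float | None = None) -> GaitProfile:
        return GaitProfile(
            cadence=float(rng.uniform(60.0, 125.0)),
            av_mean=float(rng.uniform(-250.0, -115.0)),
            av_sd=float(rng.uniform(10.0, 40.0)),
            p_good=float(rng.uniform(0.0, 1.0)),
            noise_sd=float(rng.uniform(0.0, 10.0)) if noise_sd is None else noise_sd,
            bout_plan=[(walk, 0.0)],
            seed=int(rng.integers(2**31)),
        )

    return make
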