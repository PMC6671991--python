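import pytest
from hypothesis import settings

from concord7 import synthetic_data as sd

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_records():
    """300 consultations under the study-regime defaults (seed 11)."""
    cfg = sd.default_config(n_consultations=300, seed=11)
    return sd.generate_consultations(cfg)


@pytest.fixture(scope="session")
def medium_records():
    """2000 consultations under the study-regime defaults (seed 5)."""
    cfg = sd.default_config(n_consultations=2000, seed=5)
    return sd.generate_consultations(cfg)


@pytest.fixture()
def perfect_agreement_config():
    """noise = 0, all biases 0, no direct jeopardy proposals: score 0 everywhere."""
    cfg = sd.default_config(n_consultations=500, seed=1)
    import dataclasses

    return dataclasses.replace(
        cfg,
        noise=0.0,
        p_proposed_jeopardy=0.0,
        agency_pool=[(a, w, 0.0) for a, w, _ in cfg.agency_pool],
    )
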