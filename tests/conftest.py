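import dataclasses

import numpy as np
import pytest

from fdgmismatch.polarmap import N_SEGMENTS, SegmentProfile
from fdgmismatch.synthetic import CohortConfig, NucleiConfig, simulate_cohort


def random_profile(rng: np.random.Generator, animal_id: str = "A1",
                   timepoint: str = "day3") -> SegmentProfile:
    """A structurally valid profile with uniformly random segment values."""
    return SegmentProfile(
        animal_id=animal_id,
        timepoint=timepoint,
        transmurality=rng.uniform(0, 100, N_SEGMENTS),
        uptake_raw=rng.uniform(0.1, 10, N_SEGMENTS),
        contractility=rng.uniform(-20, 60, N_SEGMENTS),
        mvo_extent=float(rng.uniform(0, 20)),
    )


def zero_sd_config(n_match: int = 22, n_mismatch: int = 8) -> CohortConfig:
    """Degenerate cohort config: every distribution collapsed to its mean."""
    cfg = CohortConfig(n_match=n_match, n_mismatch=n_mismatch)
    updates = {}
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        if isinstance(val, tuple) and len(val) == 2 and all(
            isinstance(v, float) for v in val
        ):
            updates[f.name] = (val[0], 0.0)
        elif isinstance(val, dict) and all(
            isinstance(v, tuple) and len(v) == 2 for v in val.values()
        ):
            updates[f.name] = {k: (v[0], 0.0) for k, v in val.items()}
    updates["contractility_month1_noise_sd"] = 0.0
    updates["ct_sample_shift_sd"] = 0.0
    updates["timi2_rate"] = {"Match": 0.0, "Mismatch": 0.0}
    updates["blush2_rate"] = {"Match": 0.0, "Mismatch": 0.0}
    return dataclasses.replace(cfg, **updates)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(), seed=1)


@pytest.fixture(scope="session")
def nuclei_config():
    return NucleiConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
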