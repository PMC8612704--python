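import dataclasses

import numpy as np
import pytest

from axocascade import CascadeParams


@pytest.fixture
def params() -> CascadeParams:
    return CascadeParams()


@pytest.fixture
def quiet_params() -> CascadeParams:
    """Deterministic cascade: all sds zero, no frame noise, crisis at 4 h."""
    return dataclasses.replace(
        CascadeParams(),
        crisis_time=(4.0, 0.0, 3.5, 10.0),
        offset_mito_stop_to_ca=(0.42, 0.0),
        offset_tmrm_to_ca=(7.85 / 60.0, 0.0),
        offset_ca_to_ps=(0.51, 0.0),
        offset_ca_to_degeneration=(100.0 / 60.0, 0.0),
        offset_degeneration_to_frag=(0.25, 0.0),
        atp_decline_rate=(1.2, 0.0),
        ca_plateau_fold=(3.5, 0.0, 2.5),
        frame_noise_cv=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
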