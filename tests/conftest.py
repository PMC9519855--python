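import numpy as np
import pytest

from rhythmcomp.cohort import SEGMENT_LABELS, TraitProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trait(
    cv_paced=0.04,
    cv_unpaced=0.05,
    lapse=0.0,
    false_alarm=0.1,
    comp=None,
    **latents,
):
    """Handmade trait profile for driving the simulators directly."""
    comp = dict.fromkeys(SEGMENT_LABELS, 0.0) | (comp or {})
    return TraitProfile(
        participant_id="TEST",
        acuity_general=latents.get("acuity_general", 0.0),
        acuity_bat=latents.get("acuity_bat", 0.0),
        motor_var_paced=cv_paced,
        motor_var_unpaced=cv_unpaced,
        lapse_rate=lapse,
        false_alarm_rate=false_alarm,
        compensation_true=comp,
        latent_z={
            "acuity_general": latents.get("acuity_general", 0.0),
            "acuity_bat": latents.get("acuity_bat", 0.0),
            "motor_var_paced": 0.0,
            "motor_var_unpaced": 0.0,
        },
    )


@pytest.fixture
def trait_factory():
    return make_trait
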