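import numpy as np
import pytest

from pkpdkit import IndirectResponseParameters, OralPKParameters, oral_concentration


@pytest.fixture
def em_pk() -> OralPKParameters:
    """Extensive-metabolizer-like oral PK parameter set."""
    return OralPKParameters(v_over_f=1.12, k01=1.5, k10=0.277, tlag=0.25)


@pytest.fixture
def em_conc_fn(em_pk):
    """Noise-free oral concentration curve at 2 mg/kg."""
    return lambda t: float(oral_concentration(em_pk, 2.0, [t])[0])


# EM-group turnover parameter sets, one per modeled endpoint
PD_SETS = {
    "body_temperature": IndirectResponseParameters(
        kin=41.30, kout=1.04, effect_cap=0.04, c50=193.2, n=5.09
    ),
    "creeping_speed": IndirectResponseParameters(
        kin=0.90, kout=0.95, effect_cap=0.71, c50=239.4, n=4.74
    ),
    "lameness_score": IndirectResponseParameters(
        kin=5.34, kout=1.08, effect_cap=1.0, c50=284.3, n=4.25
    ),
    "vertical_force": IndirectResponseParameters(
        kin=0.09, kout=7.40, effect_cap=0.98, c50=160.8, n=6.13
    ),
}


@pytest.fixture
def pd_sets():
    return PD_SETS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
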