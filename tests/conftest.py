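import pytest

from ecovir.model import (
    DEFAULT_PARAMS,
    EcoParams,
    PreferredHost,
    SpecialismCase,
    SpecialismSpec,
)


@pytest.fixture(scope="session")
def params() -> EcoParams:
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def generalist() -> SpecialismSpec:
    return SpecialismSpec()


def spec_for(case: SpecialismCase, strength: float = 0.3,
             ph: PreferredHost = PreferredHost.HOST1) -> SpecialismSpec:
    if case is SpecialismCase.GENERALIST:
        return SpecialismSpec(case, 0.0, ph)
    return SpecialismSpec(case, strength, ph)


FOUR_CASES = (
    SpecialismCase.CASE1_SUSCEPTIBILITY,
    SpecialismCase.CASE2_GROWTH,
    SpecialismCase.CASE3_TRANSMISSION,
    SpecialismCase.CASE4_TOLERANCE,
)

ALL_CASES = (SpecialismCase.GENERALIST,) + FOUR_CASES


def closed_form_generalist_optimum(params: EcoParams) -> float:
    """Independent closed form: argmax of c*eps^eta / (d + gamma + eps).

    Setting the log-derivative eta/eps - 1/(d+gamma+eps) to zero gives
    eps* = eta*(d+gamma)/(1-eta).
    """
    return params.eta * (params.d + params.gamma_rec) / (1.0 - params.eta)
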