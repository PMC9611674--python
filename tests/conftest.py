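import pytest

from cooltwin import (
    DEFAULT_BANANA_CONFIG,
    InMemoryBroker,
    ScenarioSpec,
    TwinRuntime,
    load_config,
)

#: The printed configuration example for the ripening model (cargo Bananas).
BOX1_SNIPPET = """\
Bananas:
  RipeningModel:
    Topic_In: Transports_Shipment_#ID_CoolPara
    Topic_Out: Transports_Shipment_#ID_RipePara
    LifeCycleTranslate:
      Start_Transport: Start_Collect
      Arrive_Transport: Stop_Collect
      Start_Ripening: Start_Model
"""


@pytest.fixture
def broker():
    return InMemoryBroker()


@pytest.fixture
def banana_cfg():
    return load_config(DEFAULT_BANANA_CONFIG)


@pytest.fixture
def box1_text():
    return BOX1_SNIPPET


def noiseless_spec(**overrides) -> ScenarioSpec:
    """Reference scenario with all noise switched off."""
    kwargs = dict(supply_noise=0.0, box_noise=0.0)
    kwargs.update(overrides)
    return ScenarioSpec(**kwargs)


@pytest.fixture
def short_spec():
    """Compressed chain (3-day transport) for fast end-to-end tests."""
    return noiseless_spec(
        packing_start=0.0, transport_start=2.0, harbor_start=74.0,
        ripening_start=80.0, end=104.0,
    )


def run_pipeline(spec: ScenarioSpec):
    rt = TwinRuntime(load_config(DEFAULT_BANANA_CONFIG))
    report = rt.run_scenario(spec)
    return rt, report
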