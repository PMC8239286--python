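import dataclasses

import pytest

import oligocea as oc


@pytest.fixture(scope="session")
def ref_inputs() -> oc.ModelInputs:
    """The bundled published input set (72-month horizon, 3% discount)."""
    return oc.reference_inputs()


@pytest.fixture(scope="session")
def base_results(ref_inputs):
    """Base-case arm results keyed by arm name."""
    return oc.run_model(ref_inputs)


@pytest.fixture(scope="session")
def base_comparison(ref_inputs, base_results):
    return oc.compare(
        base_results["SABR"], base_results["SC"], ref_inputs.settings.wtp
    )


@pytest.fixture()
def undiscounted_inputs(ref_inputs):
    return dataclasses.replace(
        ref_inputs,
        settings=dataclasses.replace(ref_inputs.settings, annual_discount_rate=0.0),
    )
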