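"""Shared solved cases for the acceptance suite.

The bench cases used by several acceptance checks are solved once per
session at the desk-scale mesh and reused.  Everything is deterministic, so
fixture reuse cannot leak state between tests.
"""

import pytest

from stentflow.workbench import CaseConfig, run_case


@pytest.fixture(scope="session")
def base_flow_result():
    """Unstented bench geometry; base-flow validation case."""
    return run_case(CaseConfig(DSH=None, h_global=2.0, h_sh=0.5))


@pytest.fixture(scope="session")
def case_ds1_dsh11():
    return run_case(CaseConfig(DSH=1.1, Ds=1.0), keep_field=True)


@pytest.fixture(scope="session")
def case_ds1_dsh04():
    return run_case(CaseConfig(DSH=0.4, Ds=1.0), keep_field=True)


@pytest.fixture(scope="session")
def case_ds08_dsh04():
    return run_case(CaseConfig(DSH=0.4, Ds=0.8), keep_field=False)


@pytest.fixture(scope="session")
def case_ds08_dsh10():
    return run_case(CaseConfig(DSH=1.0, Ds=0.8), keep_field=False)
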