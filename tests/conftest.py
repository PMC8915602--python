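"""Shared fixtures: the demonstration runs used across the suite.

All runs use the published study conditions (0.001-min RK4 step, 720-min
window unless the check needs otherwise); they are session-scoped because
each takes on the order of a second.
"""

import numpy as np
import pytest

import mmplug
from mmplug import IntegratorConfig, PKParameters, Scenario, preset, simulate
from mmplug.scenarios import REFERENCE_DRUG, REFERENCE_PK, build_plug

FULL = dict(step_size=0.001, duration=720.0, output_interval=0.5)


@pytest.fixture(scope="session")
def fig2_result():
    return simulate(preset("figure2"), IntegratorConfig(**FULL))


@pytest.fixture(scope="session")
def fig3_result():
    return simulate(preset("figure3"), IntegratorConfig(**FULL))


@pytest.fixture(scope="session")
def fig4_result():
    return simulate(preset("figure4"), IntegratorConfig(**FULL))


@pytest.fixture(scope="session")
def single_result():
    return simulate(preset("figure5_single"), IntegratorConfig(**FULL))


@pytest.fixture(scope="session")
def seven_result():
    return simulate(preset("figure6_seven"), IntegratorConfig(**FULL))


@pytest.fixture(scope="session")
def fig2_step_mode_result():
    return simulate(
        preset("figure2"), IntegratorConfig(transition_mode="step", **FULL)
    )


@pytest.fixture(scope="session")
def fig2_half_step_result():
    return simulate(
        preset("figure2"),
        IntegratorConfig(step_size=0.0005, duration=720.0, output_interval=0.5),
    )


@pytest.fixture(scope="session")
def pk_one_compartment():
    return PKParameters(cl=4.0, vd=600.0, mb=70.0, k12=0.0, k21=0.0)


@pytest.fixture(scope="session")
def bateman_result(pk_one_compartment):
    """Pre-dissolved single plug, constant ka, no tissue compartment."""
    plug = build_plug(1, volume=240.0, dose=2.4, onset=None, predissolved=True)
    scenario = Scenario(
        drug=REFERENCE_DRUG, pk=pk_one_compartment, plugs=[plug], label="bateman"
    )
    return simulate(
        scenario, IntegratorConfig(step_size=0.001, duration=3000.0, output_interval=0.5)
    )


@pytest.fixture(scope="session")
def two_compartment_result():
    """Pre-dissolved single plug, constant ka, full k12/k21 exchange."""
    plug = build_plug(1, volume=240.0, dose=2.4, onset=None, predissolved=True)
    scenario = Scenario(
        drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=[plug], label="two-compartment"
    )
    return simulate(scenario, IntegratorConfig(**FULL))


def sink_dissolution_result(radius_cm: float, duration: float):
    """Monodisperse fraction dissolving under forced sink, no absorption."""
    plug = build_plug(1, volume=80.0, dose=0.8, onset=None, ka_si=0.0, radius=radius_cm)
    scenario = Scenario(drug=REFERENCE_DRUG, pk=REFERENCE_PK, plugs=[plug], label="sink")
    return simulate(
        scenario,
        IntegratorConfig(
            step_size=0.001, duration=duration, output_interval=0.01, sink=True
        ),
    )


@pytest.fixture(scope="session")
def sink_1um_result():
    return sink_dissolution_result(1e-4, 5.0)


@pytest.fixture(scope="session")
def sink_10um_result():
    return sink_dissolution_result(10e-4, 260.0)
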