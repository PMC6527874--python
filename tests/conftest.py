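"""Shared fixtures.

The heavyweight simulation runs (tens of seconds each) are session-scoped
and shared between the integration-level property tests and the acceptance
tests, so each protocol is simulated exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import mossyfiber as mf
from mossyfiber import experiments
from mossyfiber.protocols import tune_resting_potential


@pytest.fixture(scope="session")
def chain():
    """Default pearl-chain model."""
    return mf.build_mossy_fiber_model()


@pytest.fixture(scope="session")
def tuned_chain(chain):
    """Default model with the leak reversal tuned for a −80 mV rest."""
    return tune_resting_potential(chain, -80.0)


@pytest.fixture(scope="session")
def passive_chain():
    """Full morphology with all active densities zero (leak only), tuned."""
    ch = mf.build_mossy_fiber_model(gna_axon=0.0, gna_soma=0.0, gk=0.0)
    return tune_resting_potential(ch, -80.0)


@pytest.fixture(scope="session")
def passive_exp(chain):
    """Distal-knockout passive propagation experiment (spatial decay)."""
    return experiments.passive_propagation_experiment(chain)


@pytest.fixture(scope="session")
def steady_exp(chain):
    """Steady-state length-constant experiment (4 pA, 500 ms at bouton 10)."""
    return experiments.steady_state_lambda_experiment(chain)


@pytest.fixture(scope="session")
def steps_exp(chain):
    """Step family at bouton 10 with superimposed propagated AP."""
    return experiments.step_family_experiment(chain=chain)


@pytest.fixture(scope="session")
def voltage_exp(chain):
    """Propagation at −80/−90/−100 mV resting potential."""
    return experiments.voltage_dependency_experiment(chain=chain)


@pytest.fixture(scope="session")
def decomp_exp(chain):
    """Control / gK-removed / gNa+gK-removed decomposition at −80 mV."""
    return experiments.decomposition_experiment(chain=chain)


@pytest.fixture(scope="session")
def ek10_exp(chain):
    """E_K10 sweep with passive companion runs."""
    return experiments.ek10_sweep_experiment(chain=chain)


@pytest.fixture(scope="session")
def cm_exp(chain):
    """Cm sweep of the passive propagating component."""
    return experiments.cm_sweep_experiment(chain=chain)


@pytest.fixture(scope="session")
def icap_propagated(chain):
    return experiments.icap_onset_experiment("propagated", chain=chain)


@pytest.fixture(scope="session")
def icap_direct(chain):
    return experiments.icap_onset_experiment("direct", chain=chain)


@pytest.fixture(scope="session")
def control_prop(tuned_chain):
    """Control propagation with full current recording at every bouton."""
    sites = ("soma",) + tuple(f"bouton{k}" for k in range(1, 11))
    settings = mf.SimulationSettings(duration=30.0, record_sites=sites)
    return mf.integrate(
        tuned_chain, settings, [mf.StimulusEvent("soma", 0.2, 10.0, 2.0)]
    )


@pytest.fixture(scope="session")
def convergence_report(tuned_chain):
    """dt vs dt/2 self-convergence on the spiking model."""
    settings = mf.SimulationSettings(
        duration=25.0, record_sites=("soma", "bouton5", "bouton10")
    )
    return mf.check_convergence(
        tuned_chain, settings, [mf.StimulusEvent("soma", 0.2, 10.0, 2.0)]
    )


def peak_time(time: np.ndarray, vm: np.ndarray) -> float:
    return float(time[int(np.argmax(vm))])
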