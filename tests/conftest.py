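import numpy as np
import pytest

from fsikir.calibrate import CalibrationTargets, calibrate_full
from fsikir.engine import EngineConfig
from fsikir.mechanisms import KirSpec, LeakSpec, Mechanisms
from fsikir.model import CellModel
from fsikir.morphology import Morphology, Section, discretize


@pytest.fixture(scope="session")
def targets():
    return CalibrationTargets()


@pytest.fixture(scope="session")
def calibrated(targets):
    """Full calibration pipeline, shared by the protocol/acceptance tests."""
    return calibrate_full(targets=targets)


@pytest.fixture(scope="session")
def syn_kwargs(calibrated):
    return {"tau_rise": calibrated.synapse_tau_rise,
            "tau_decay": calibrated.synapse_tau_decay,
            "weight": calibrated.synapse_weight}


def make_single_compartment(g_k=1.5e-4, g_na=0.45e-4, g_kir=0.0,
                            kir_v_half=-85.0, soma=15.0):
    """Isopotential cell: one cylindrical compartment."""
    morph = Morphology((Section(0, -1, "soma", soma, soma),))
    tree = discretize(morph, max_compartment_length=1e4)
    mech = Mechanisms(leak=LeakSpec(g_k_density=g_k, g_na_density=g_na),
                      kir=KirSpec(g_density=g_kir, v_half=kir_v_half))
    return CellModel(tree=tree, mech=mech, config=EngineConfig())


@pytest.fixture
def single_compartment():
    return make_single_compartment()


@pytest.fixture
def soma_dendrite():
    """Soma plus one 200 µm dendrite, passive K leak only (rest at e_K)."""
    morph = Morphology((Section(0, -1, "soma", 15, 15),
                        Section(1, 0, "dendrite", 200, 1.5)))
    tree = discretize(morph, max_compartment_length=5.0)
    mech = Mechanisms(leak=LeakSpec(g_k_density=2e-4, g_na_density=0.0),
                      kir=KirSpec(g_density=0.0))
    return CellModel(tree=tree, mech=mech, config=EngineConfig())
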