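import numpy as np
import pytest

from notchcrypt.circuits import CircuitParams, ModelForm
from notchcrypt.fixtures import li_default, model2_default, pfli_default
from notchcrypt.lattice import NeighborGraph, Topology, build_lattice


@pytest.fixture(scope="session")
def li_params() -> CircuitParams:
    return li_default()


@pytest.fixture(scope="session")
def pfli_params() -> CircuitParams:
    return pfli_default()


@pytest.fixture(scope="session")
def model2_params() -> CircuitParams:
    return model2_default()


@pytest.fixture(scope="session")
def pair_graph() -> NeighborGraph:
    return NeighborGraph.pair()


@pytest.fixture(scope="session")
def hex_4x4() -> NeighborGraph:
    return build_lattice(4, 4, Topology.HEX_PERIODIC)


@pytest.fixture(scope="session")
def hex_6x6() -> NeighborGraph:
    return build_lattice(6, 6, Topology.HEX_PERIODIC)


def random_model3_params(rng: np.random.Generator, s_pf: float | None = None) -> CircuitParams:
    """Random MODEL3 parameter draw around the default scales."""
    return CircuitParams(
        model_form=ModelForm.MODEL3,
        beta_N=float(rng.uniform(1.0, 10.0)),
        beta_D=float(rng.uniform(2.0, 20.0)),
        alpha_n=float(rng.uniform(0.5, 2.0)),
        alpha_D=float(rng.uniform(0.5, 2.0)),
        alpha_R=float(rng.uniform(0.5, 2.0)),
        k_p=float(rng.uniform(0.5, 2.0)),
        k_d=float(rng.uniform(0.2, 1.0)),
        p=float(rng.integers(1, 4)),
        h=float(rng.integers(1, 5)),
        S_PF=float(rng.uniform(0.0, 1.0)) if s_pf is None else s_pf,
        S_LI=1.0,
    )
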