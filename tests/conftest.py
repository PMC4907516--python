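import numpy as np
import pytest

from retsim import SimConfig, assign_boundary_conditions, generate_hexagonal
from retsim.network import (
    BTYPE_ARTERIAL,
    BTYPE_VENOUS,
    VascularNetwork,
)


def make_line_network(n_segments=1, diameter=5.0, seg_len=100.0, p_in=40.0, p_out=20.0):
    """A straight pipe of n identical segments with Dirichlet ends."""
    n = n_segments + 1
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * seg_len
    pos[:, 2] = 25.0
    btype = np.zeros(n, dtype=np.int8)
    btype[0] = BTYPE_ARTERIAL
    btype[-1] = BTYPE_VENOUS
    pressure = np.full(n, np.nan)
    pressure[0], pressure[-1] = p_in, p_out
    oxygen = np.full(n, np.nan)
    seg_nodes = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    d = np.full(n_segments, diameter, dtype=float)
    return VascularNetwork(
        node_pos=pos,
        node_is_boundary=btype != 0,
        node_btype=btype,
        node_pressure=pressure,
        node_oxygen=oxygen,
        seg_nodes=seg_nodes,
        seg_diameter=d,
        seg_ref_diameter=d.copy(),
        seg_state=np.zeros(n_segments, dtype=np.int8),
        seg_is_trunk=np.zeros(n_segments, dtype=bool),
        domain=np.array([[pos[:, 0].min() - 20, pos[:, 0].max() + 20],
                         [-30.0, 30.0], [0.0, 50.0]]),
    )


def make_y_network(diameter=5.0, leg=100.0, p_in=40.0, p_out=20.0):
    """Symmetric Y: one parent splitting into two identical daughters."""
    pos = np.array(
        [[0.0, 0.0, 25.0], [leg, 0.0, 25.0],
         [2 * leg, 60.0, 25.0], [2 * leg, -60.0, 25.0]]
    )
    btype = np.array([BTYPE_ARTERIAL, 0, BTYPE_VENOUS, BTYPE_VENOUS], dtype=np.int8)
    pressure = np.array([p_in, np.nan, p_out, p_out])
    seg_nodes = np.array([[0, 1], [1, 2], [1, 3]])
    d = np.full(3, diameter, dtype=float)
    return VascularNetwork(
        node_pos=pos,
        node_is_boundary=btype != 0,
        node_btype=btype,
        node_pressure=pressure,
        node_oxygen=np.full(4, np.nan),
        seg_nodes=seg_nodes,
        seg_diameter=d,
        seg_ref_diameter=d.copy(),
        seg_state=np.zeros(3, dtype=np.int8),
        seg_is_trunk=np.zeros(3, dtype=bool),
        domain=np.array([[-20.0, 2 * leg + 20], [-90.0, 90.0], [0.0, 50.0]]),
    )


@pytest.fixture
def config():
    return SimConfig()


@pytest.fixture
def line_net():
    return make_line_network()


@pytest.fixture
def y_net():
    return make_y_network()


@pytest.fixture(scope="session")
def hex_net():
    net = generate_hexagonal(65.0, 4, 4, 0.0, seed=0)
    assign_boundary_conditions(net, SimConfig())
    return net
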