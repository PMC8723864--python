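import numpy as np
import pytest

import pbcsync as pb


@pytest.fixture(scope="session")
def params():
    return pb.ModelParams.table1()


@pytest.fixture(scope="session")
def burst_trace(params):
    """Reference period-3 bursting run (I_exc = 8.5), post-transient part."""
    tr = pb.run_single(params, 8.5, 6e4)
    return tr.discard_transient()


@pytest.fixture(scope="session")
def sync_pair_trace(params):
    """Identical pair in the complete-synchronization band, no delay."""
    net = pb.NetworkConfig(g_c=-0.4, I_exc1=8.5, I_exc2=8.5)
    return pb.run_pair(params, net, 6e4).discard_transient()


@pytest.fixture(scope="session")
def hopf_point(params):
    h = pb.locate_hopf(params, (8.0, 13.0))
    return pb.normal_form_coeffs(h, params)
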