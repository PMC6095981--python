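import pytest

from bcrnet import SimConfig, make_germline_set, simulate_repertoire


@pytest.fixture(scope="session")
def germline():
    return make_germline_set(n_v=5, n_d=3, n_j=2, seed=1)


@pytest.fixture(scope="session")
def small_repertoire(germline):
    cfg = SimConfig(n_clones=60, clone_size_law="geometric",
                    clone_size_p=0.4, shm_rate=0.003,
                    founder_switch_probs=0.3, plasmablast_prob=0.05)
    return simulate_repertoire(germline, cfg, seed=7)
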