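import pytest

from waxyphylo.synthetic_data import SimConfig, make_reference, simulate_dataset


@pytest.fixture(scope="session")
def reference():
    return make_reference()


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=42, n_allo=4, n_auto=4,
                                      n_diploids_A=6, n_diploids_B=6,
                                      intron5_loss_in=(0,)))
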