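import pytest

import mitocomp as mc


@pytest.fixture(scope="session")
def sl_table():
    return mc.packaged_table("sl")


@pytest.fixture(scope="session")
def sr_table():
    return mc.packaged_table("sr")


@pytest.fixture(scope="session")
def sl_genome():
    """Synthetic genome on the S. longifissa annotation geometry."""
    genome, truth = mc.build_genome(mc.preset_config("sl", seed=1))
    return genome, truth


@pytest.fixture(scope="session")
def sr_genome():
    genome, truth = mc.build_genome(mc.preset_config("sr", seed=1))
    return genome, truth
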