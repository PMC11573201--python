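import numpy as np
import pytest

from clonedyn import SyntheticConfig, gen_clone_size_table


@pytest.fixture(scope="session")
def day8_table():
    """Default synthetic clone table restricted to day 8 (session-cached)."""
    cfg = SyntheticConfig(seed=20240, days=(8.0,))
    return gen_clone_size_table(cfg)


@pytest.fixture(scope="session")
def reference_divisions(day8_table):
    """Day-8 division counts with the one-cell filter, as the null reference."""
    sizes = day8_table["n_cells"].to_numpy()
    return np.log2(sizes[sizes > 1].astype(float))
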