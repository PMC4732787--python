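import numpy as np
import pytest

import ldlkit as lk


@pytest.fixture(scope="session")
def five_cell():
    return lk.load_five_cell_table()


@pytest.fixture(scope="session")
def twentyfive_cell():
    return lk.load_twentyfive_cell_table()


@pytest.fixture
def panel():
    """The worked example panel: non-HDL 136, VLDL 25, TG:VLDL 4.24."""
    return lk.LipidPanel("ex1", 45, "male", tc=184, hdl=48, tg=106, ldl_direct=111)


@pytest.fixture(scope="session")
def random_panels():
    """10,000 random valid panels with direct LDL-C and TG < 400."""
    rng = np.random.default_rng(42)
    n = 10_000
    tg = rng.uniform(0.0, 399.9, n)
    hdl = rng.uniform(25.0, 90.0, n)
    ldl = rng.uniform(20.0, 250.0, n)
    vldl = rng.uniform(1.0, 120.0, n)
    return [
        lk.LipidPanel(
            f"r{i}", int(rng.integers(20, 88)), "unknown",
            tc=float(hdl[i] + ldl[i] + vldl[i]), hdl=float(hdl[i]),
            tg=float(tg[i]), ldl_direct=float(ldl[i]),
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at the study size, seed 1."""
    return lk.generate_cohort(lk.SyntheticCohortConfig(n=5642, seed=1))
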