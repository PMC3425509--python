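import numpy as np
import pytest

import polyrec as pr
from polyrec.synthetic_data import (DEFAULT_MG_GRID_UM, DEFAULT_MN_GRID_UM,
                                    CationCondition, get_template)


@pytest.fixture(scope="session")
def original_template():
    return get_template("original")


@pytest.fixture(scope="session")
def swapped_template():
    return get_template("swapped")


# --- shared, session-scoped simulations at the study's read depths ---------
# These back both the module tests and the acceptance criteria; regenerating
# them per test would dominate the suite runtime.


@pytest.fixture(scope="session")
def dpo4_mn_titration():
    """Dpo4 preset, default Mn grid, duplicate wells, 2000 reads/well."""
    return pr.run_titration("dpo4_paper", "original", "mn",
                            DEFAULT_MN_GRID_UM, 2000, seed=101)


@pytest.fixture(scope="session")
def dpo4_mg_titration():
    return pr.run_titration("dpo4_paper", "original", "mg",
                            DEFAULT_MG_GRID_UM, 5000, seed=102)


@pytest.fixture(scope="session")
def klenow_mn_titration():
    return pr.run_titration("klenow_paper", "original", "mn",
                            DEFAULT_MN_GRID_UM, 2000, seed=103)


@pytest.fixture(scope="session")
def klenow_mg_titration():
    return pr.run_titration("klenow_paper", "original", "mg",
                            DEFAULT_MG_GRID_UM, 5000, seed=104)


@pytest.fixture(scope="session")
def klenow_800_well():
    """One deep Klenow well at 800 uM Mn2+ (lag-one coupling active)."""
    return pr.run_single_condition("klenow_paper", "original",
                                   CationCondition(mn_uM=800.0), 20000,
                                   seed=105)


@pytest.fixture(scope="session")
def dpo4_800_well():
    """One deep Dpo4 well at 800 uM Mn2+ (errors uncoupled, lag1_boost=0)."""
    return pr.run_single_condition("dpo4_paper", "original",
                                   CationCondition(mn_uM=800.0), 20000,
                                   seed=106)
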