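import numpy as np
import pandas as pd
import pytest

from ldlkit import MhFactorTable, SyntheticCohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_2x2_table():
    """{TG<100: [4.0, 5.0]; TG>=100: [5.5, 6.5]} with non-HDL cut at 130."""
    return MhFactorTable(
        tg_bounds=np.array([0.0, 100.0]),
        nonhdl_bounds=np.array([0.0, 130.0]),
        factors=np.array([[4.0, 5.0], [5.5, 6.5]]),
        provenance="toy 2x2",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded noiseless cohort, n=4000, ratio model on."""
    return generate_cohort(SyntheticCohortConfig(n=4000, seed=7))


def random_panels(rng, n, units="mmol/L"):
    """Valid random panels: TC > HDL, TG within the study range (mmol/L)."""
    hdl = rng.uniform(0.5, 3.0, n)
    ldlish = rng.uniform(0.5, 6.0, n)
    tg = rng.uniform(0.1, 9.0, n)
    tc = hdl + ldlish + tg / rng.uniform(4.0, 9.0, n)
    return tc, hdl, tg


@pytest.fixture
def panels_csv(tmp_path):
    def _write(rows, name="panels.csv", columns=None):
        columns = columns or [
            "patient_id", "visit_date", "age", "sex", "tc", "hdl", "tg", "units",
        ]
        frame = pd.DataFrame(rows, columns=columns)
        path = tmp_path / name
        frame.to_csv(path, index=False)
        return path

    return _write
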