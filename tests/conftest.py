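import numpy as np
import pytest

from tamnk import ExpressionMatrix, SimulationConfig, simulate_single_cell


@pytest.fixture(scope="session")
def small_lognorm():
    """10-gene x 6-observation continuous matrix for enrichment tests."""
    rng = np.random.default_rng(0)
    vals = rng.gamma(2.0, 2.0, size=(10, 6))
    return ExpressionMatrix(
        vals, [f"G{i}" for i in range(10)], [f"S{j}" for j in range(6)], "lognorm"
    )


@pytest.fixture(scope="session")
def tumor_dominant_sim():
    """Tumor-cell-majority simulation used by the doublet-flagging tests."""
    cfg = SimulationConfig(
        n_cells_per_type={"M0": 40, "M1": 40, "M2": 40, "MONOCYTE": 40,
                          "NK_LIKE": 40, "TUMOR": 300},
        doublet_rate=0.0,
        seed=5,
    )
    return simulate_single_cell(cfg)
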