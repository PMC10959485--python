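import numpy as np
import pandas as pd
import pytest

from clinesel.synthetic_garden import (FitnessSpec, PopulationSpec,
                                       SimulationConfig,
                                       simulate_common_garden)
from clinesel.trial_data import TrialTable

TRAITS = ("BST", "FYH", "FFI", "SW")


def make_config(seed=0, populations=None, G=None, E=None, block_sd=None,
                fitness=None, **kwargs) -> SimulationConfig:
    """Compact simulation config for tests; single mid-latitude population
    of 40 families x 8 seedlings unless overridden."""
    if populations is None:
        populations = (PopulationSpec("P1", 61.0, 40, 8, 2),)
    if G is None:
        G = np.diag([10.1, 35.375, 0.0675, 0.0225])
    if E is None:
        E = np.diag([73.5, 214.925, 0.7625, 1e-6])
    return SimulationConfig(
        seed=seed,
        populations=populations,
        cline_intercepts={"BST": 204.07, "FYH": 191.77, "FFI": 14.37, "SW": 2.126},
        cline_slopes={"BST": -1.666, "FYH": -2.314, "FFI": -0.202, "SW": -0.015},
        G=np.asarray(G, float),
        E=np.asarray(E, float),
        block_sd=block_sd or {"BST": 1.5, "FYH": 4.0, "FFI": 0.1, "SW": 0.0},
        ffi_thresholds=(0.579, 1.563, 2.428, 3.339),
        fitness=fitness or FitnessSpec(),
        **kwargs,
    )


def toy_table(records: pd.DataFrame, meta: pd.DataFrame | None = None) -> TrialTable:
    """Wrap a bare records frame as a TrialTable for model-fitting tests."""
    rec = records.copy()
    if "excluded" not in rec.columns:
        rec["excluded"] = False
    if "block" not in rec.columns:
        rec["block"] = "B1"
    if meta is None:
        fams = rec["family_id"].unique()
        meta = pd.DataFrame({"family_id": fams, "population": "P1",
                             "latitude": 61.0, "seed_weight": 1.2})
    return TrialTable(records=rec, meta=meta)


def balanced_table(rng, n_fam, n_per, s2f, s2e, mean=10.0) -> TrialTable:
    """Perfectly balanced single-block one-way design with known components."""
    fam_eff = rng.normal(0, np.sqrt(s2f), n_fam)
    y = mean + np.repeat(fam_eff, n_per) + rng.normal(0, np.sqrt(s2e), n_fam * n_per)
    rec = pd.DataFrame({
        "family_id": np.repeat([f"F{i}" for i in range(n_fam)], n_per),
        "block": "B1",
        "y": y,
    })
    return toy_table(rec)


@pytest.fixture(scope="session")
def study_table():
    """One full-size study-condition simulation, shared across tests."""
    from clinesel.synthetic_garden import default_config
    table, truth = simulate_common_garden(default_config(11))
    return table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
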