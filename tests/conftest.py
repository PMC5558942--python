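import numpy as np
import pandas as pd
import pytest

from endotrend import RecordTable, SimConfig, simulate_records, simulate_tree


def make_records(species, masses, years, lats=None, lons=None, sexes=None):
    """Build a RecordTable from parallel lists, defaulting covariates."""
    n = len(masses)
    return RecordTable(pd.DataFrame({
        "species_id": species if not isinstance(species, str) else [species] * n,
        "mass": masses,
        "year": years,
        "latitude": lats if lats is not None else [45.0] * n,
        "longitude": lons if lons is not None else [-110.0] * n,
        "sex": sexes if sexes is not None else ["female"] * n,
    }))


@pytest.fixture(scope="session")
def small_sim():
    """A 12-species synthetic dataset shared across tests (fixed seed)."""
    cfg = SimConfig(
        n_species={("bird", "aquatic"): 3, ("bird", "terrestrial"): 4,
                   ("mammal", "aquatic"): 2, ("mammal", "terrestrial"): 3},
        n_records_range=(120, 220), seed=11)
    tree = simulate_tree(cfg.total_species, seed=12)
    records, meta, truth = simulate_records(cfg, tree=tree)
    return {"config": cfg, "tree": tree, "records": records,
            "meta": meta, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
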