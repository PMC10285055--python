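import numpy as np
import pandas as pd
import pytest

import herdblup as hb
from herdblup.io import attach_hys
from herdblup.joint_eval import prepare_study_data


def toy_records(rng, ped, n_herds=2, traits=("y",), missing_rate=0.0,
                countries=None, with_age=True):
    """Random toy performance table over the recorded subset of a pedigree."""
    animals = [a for a, f in zip(ped.animals, ped.founder_mask) if not f] or ped.animals
    n = len(animals)
    herd = [f"H{rng.integers(n_herds) + 1}" for _ in range(n)]
    hys = [f"{h}|2012|{rng.integers(2) + 1}" for h in herd]
    rows = {
        "animal_id": animals,
        "herd": herd,
        "hys": hys,
        "age_months": np.round(rng.normal(30, 3, size=n), 2) if with_age else 30.0,
    }
    if countries is not None:
        rows["country"] = [countries[rng.integers(len(countries))] for _ in range(n)]
    for t in traits:
        vals = rng.normal(10, 3, size=n)
        if missing_rate > 0:
            vals = np.where(rng.random(n) < missing_rate, np.nan, vals)
        rows[t] = vals
    df = pd.DataFrame(rows)
    # keep every record informative
    all_missing = df[list(traits)].isna().all(axis=1)
    if all_missing.any():
        df.loc[all_missing, traits[0]] = rng.normal(10, 3, size=int(all_missing.sum()))
    return df


@pytest.fixture(scope="session")
def desk_sim():
    """One seeded desk-scale two-country herdbook shared across tests."""
    cfg = hb.desk_scale_config(seed=42)
    return cfg, hb.simulate_study(cfg)


@pytest.fixture(scope="session")
def desk_study(desk_sim):
    cfg, sim = desk_sim
    perf = {c: attach_hys(sim.performance[c], cfg.season_rule)
            for c in sim.performance}
    return cfg, sim, prepare_study_data(sim.pedigree, perf, sim.shared_sires)
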