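import numpy as np
import pandas as pd
import pytest

import cagesurv as cs


@pytest.fixture
def fullsib_pedigree():
    """Two founders and a full-sib pair."""
    return cs.Pedigree.from_records(
        [
            (1, 0, 0, 0, "M"),
            (2, 0, 0, 0, "F"),
            (3, 1, 2, 1, "F"),
            (4, 1, 2, 1, "F"),
        ]
    )


def random_pedigree(n_ids: int, seed: int, n_founders: int = 10) -> cs.Pedigree:
    """Random multi-generation pedigree: parents drawn from earlier ids."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n_founders + 1):
        records.append((i, 0, 0, 0, "M" if i % 2 else "F"))
    for i in range(n_founders + 1, n_ids + 1):
        s, d = rng.choice(i - 1, size=2, replace=False) + 1
        records.append((i, int(s), int(d), 1, "F"))
    return cs.Pedigree.from_records(records)


@pytest.fixture(scope="session")
def small_sim():
    """One small default (logistic) simulation shared by read-only tests."""
    cfg = cs.SimConfig(
        n_sires=10,
        dams_per_sire=6,
        offspring_per_dam=7,
        n_generations=3,
        n_batches=1,
        layout=((2, 2),),
        seed=33,
    )
    pedigree, cages, table, effects, truth = cs.simulate(cfg)
    return dict(
        config=cfg,
        pedigree=pedigree,
        cages=cages,
        table=table,
        effects=effects,
        truth=truth,
    )


def days_only_table(days: pd.DataFrame) -> cs.SurvivalTable:
    """Wrap a day-scale frame as a SurvivalTable without monthly records."""
    empty = pd.DataFrame(
        columns=["id", "cage", "class_id", "month", "value", "alive_mates"]
    )
    return cs.SurvivalTable(monthly=empty, days=days)


@pytest.fixture(scope="session")
def gaussian_days_sim():
    """Gaussian day-scale records on a two-generation population (~640 hens)."""
    cfg = cs.SimConfig(
        n_sires=16,
        dams_per_sire=5,
        offspring_per_dam=8,
        n_generations=2,
        n_batches=1,
        layout=((2, 2),),
        seed=5,
    )
    pedigree, cages = cs.generate_population(cfg)
    days, effects, truth = cs.simulate_gaussian_days(
        pedigree, cages, cs.GaussianConfig(), rng=17
    )
    return dict(
        pedigree=pedigree,
        cages=cages,
        days=days,
        table=days_only_table(days),
        effects=effects,
        truth=truth,
    )
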