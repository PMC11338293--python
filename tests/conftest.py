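import numpy as np
import pandas as pd
import pytest

from matesearch import (
    AgentTable,
    default_synthetic_stats,
    generate_population,
    mv_matrix,
)
from matesearch.agents import AGENT_COLS, PREF_COLS, TRAIT_COLS


@pytest.fixture(scope="session")
def stats():
    return default_synthetic_stats(seed=0)


@pytest.fixture(scope="session")
def small_pop(stats):
    """A 60-agent single-market population used across tests."""
    return generate_population(stats, 60, seed=1)


@pytest.fixture(scope="session")
def small_mv(small_pop):
    return mv_matrix(small_pop)


def make_agent_table(prefs_f, traits_f, prefs_m, traits_m) -> AgentTable:
    """Build a table directly from per-sex preference/trait row lists."""
    prefs_f, traits_f = np.atleast_2d(prefs_f), np.atleast_2d(traits_f)
    prefs_m, traits_m = np.atleast_2d(prefs_m), np.atleast_2d(traits_m)
    rows = []
    agent_id = 0
    for sex, prefs, traits in (("female", prefs_f, traits_f), ("male", prefs_m, traits_m)):
        for p, t in zip(prefs, traits):
            rows.append(
                {"agent_id": agent_id, "sex": sex, "market_id": 0}
                | dict(zip(PREF_COLS, np.asarray(p, dtype=float)))
                | dict(zip(TRAIT_COLS, np.asarray(t, dtype=float)))
            )
            agent_id += 1
    return AgentTable(pd.DataFrame(rows)[AGENT_COLS])


@pytest.fixture
def paired_market():
    """4-agent market where every agent has a unique mutually-best partner.

    Female 0 and male 2 match each other exactly; female 1 and male 3 match
    each other exactly; the cross pairs are poor matches.
    """
    a = np.full(16, 8.0)
    b = np.full(16, 2.0)
    return make_agent_table(
        prefs_f=[a, b], traits_f=[a, b], prefs_m=[a, b], traits_m=[a, b]
    )
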