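"""True mate values from preference-trait Euclidean distances.

An agent's mate value to a focal agent is a similarity score on the 0-10
rating scale: the Euclidean distance between the focal agent's 16-dimensional
ideal-preference vector and the potential mate's 16-dimensional trait vector,
linearly rescaled so that a perfect match scores 10 and the largest distance
possible on a bounded 16-dimensional 0-10 space (sqrt(16) * 10 = 40) scores 0.
Mate value is asymmetric by construction: mv(i, j) depends only on i's
preferences and j's traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .agents import FEMALE, MALE, N_DIMS, AgentTable

MAX_DISTANCE = np.sqrt(N_DIMS) * 10.0  # = 40, the diameter of the rating space
SCALE_MAX = 10.0


def mate_value(preferences: np.ndarray, traits: np.ndarray) -> float:
    """Mate value of one potential mate to one focal agent.

    ``mv = 10 * (1 - d / 40)`` with ``d`` the Euclidean preference-trait
    distance. Inputs on the 0-10 scale give values in [0, 10]; out-of-range
    inputs are allowed and can produce values slightly outside that band.
    """
    preferences = np.asarray(preferences, dtype=float)
    traits = np.asarray(traits, dtype=float)
    if preferences.shape != traits.shape:
        raise ValueError(
            f"length mismatch: {preferences.shape} vs {traits.shape}"
        )
    d = float(np.linalg.norm(preferences - traits))
    return SCALE_MAX * (1.0 - d / MAX_DISTANCE)


@dataclass
class MateValueMatrix:
    """True mate values of every opposite-sex mate to every focal agent.

    ``f_to_m[i, j]`` is the mate value of male ``male_ids[j]`` to female
    ``female_ids[i]``; ``m_to_f`` is the male-focal counterpart.
    """

    female_ids: np.ndarray
    male_ids: np.ndarray
    f_to_m: np.ndarray  # (n_female, n_male)
    m_to_f: np.ndarray  # (n_male, n_female)
    market_id: int = 0

    @property
    def n_female(self) -> int:
        return len(self.female_ids)

    @property
    def n_male(self) -> int:
        return len(self.male_ids)

    def pooled_values(self) -> np.ndarray:
        """All entries across both focal sexes, flattened."""
        return np.concatenate([self.f_to_m.ravel(), self.m_to_f.ravel()])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for focal_ids, mate_ids, block in (
            (self.female_ids, self.male_ids, self.f_to_m),
            (self.male_ids, self.female_ids, self.m_to_f),
        ):
            fi, mj = np.meshgrid(np.arange(len(focal_ids)), np.arange(len(mate_ids)),
                                 indexing="ij")
            rows.append(pd.DataFrame({
                "focal_id": focal_ids[fi.ravel()],
                "mate_id": mate_ids[mj.ravel()],
                "mv": block.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


def mv_matrix(pop: AgentTable) -> MateValueMatrix:
    """Compute the full mate-value matrix for a single-market population."""
    markets = pop.market_ids
    if len(markets) != 1:
        raise ValueError(
            f"mv_matrix expects a single market, got {len(markets)}; "
            "use AgentTable.market() first"
        )
    female_ids = pop.ids(FEMALE)
    male_ids = pop.ids(MALE)
    if len(female_ids) == 0 or len(male_ids) == 0:
        raise ValueError("market must contain agents of both sexes")
    f_to_m = SCALE_MAX * (
        1.0 - cdist(pop.preferences(FEMALE), pop.traits(MALE)) / MAX_DISTANCE
    )
    m_to_f = SCALE_MAX * (
        1.0 - cdist(pop.preferences(MALE), pop.traits(FEMALE)) / MAX_DISTANCE
    )
    return MateValueMatrix(
        female_ids=female_ids,
        male_ids=male_ids,
        f_to_m=f_to_m,
        m_to_f=m_to_f,
        market_id=int(markets[0]),
    )
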