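"""Core data containers: agent tables and pairings.

An :class:`AgentTable` holds one or more simulated mating markets. Every agent
has a sex, a market id, a 16-dimensional ideal-preference vector and a
16-dimensional trait vector, all on the questionnaire's 0-10 scale.

A :class:`PairingOutcome` is the result of a mate-choice model: a symmetric
partner assignment in which unmatched agents are explicitly single. A
:class:`ReferencePairing` is the ground-truth couple structure (real dyads or
couples generated by a "true" model) against which candidate models are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

FEMALE = "female"
MALE = "male"

N_DIMS = 16
PREF_COLS = [f"pref_{i}" for i in range(1, N_DIMS + 1)]
TRAIT_COLS = [f"trait_{i}" for i in range(1, N_DIMS + 1)]
AGENT_COLS = ["agent_id", "sex", "market_id"] + PREF_COLS + TRAIT_COLS


@dataclass
class AgentTable:
    """Table of agents; thin wrapper around a pandas DataFrame.

    The frame has columns ``agent_id, sex, market_id, pref_1..pref_16,
    trait_1..trait_16``. Agent ids are unique integers; sex is ``"female"``
    or ``"male"``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in AGENT_COLS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"agent table missing columns: {missing}")
        if self.frame["agent_id"].duplicated().any():
            raise ValueError("agent_id values must be unique")
        vals = self.frame[PREF_COLS + TRAIT_COLS].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("agent preference/trait values must be finite")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def agent_ids(self) -> np.ndarray:
        return self.frame["agent_id"].to_numpy()

    @property
    def market_ids(self) -> np.ndarray:
        return np.unique(self.frame["market_id"].to_numpy())

    def market(self, market_id: int) -> "AgentTable":
        sub = self.frame[self.frame["market_id"] == market_id]
        if sub.empty:
            raise KeyError(f"no agents in market {market_id}")
        return AgentTable(sub.copy())

    def sex_block(self, sex: str) -> pd.DataFrame:
        return self.frame[self.frame["sex"] == sex]

    def preferences(self, sex: str) -> np.ndarray:
        return self.sex_block(sex)[PREF_COLS].to_numpy(dtype=float)

    def traits(self, sex: str) -> np.ndarray:
        return self.sex_block(sex)[TRAIT_COLS].to_numpy(dtype=float)

    def ids(self, sex: str) -> np.ndarray:
        return self.sex_block(sex)["agent_id"].to_numpy()

    def subset(self, agent_ids: Iterable[int], market_id: int | None = None) -> "AgentTable":
        """Select agents by id, optionally re-housing them in a new market."""
        wanted = set(int(a) for a in agent_ids)
        sub = self.frame[self.frame["agent_id"].isin(wanted)].copy()
        if len(sub) != len(wanted):
            raise KeyError("some requested agent ids are absent from the table")
        if market_id is not None:
            sub["market_id"] = market_id
        return AgentTable(sub)

    def to_csv(self, path: str | Path) -> None:
        self.frame[AGENT_COLS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgentTable":
        return cls(pd.read_csv(path))


SINGLE = None  # sentinel partner value for unmatched agents


@dataclass
class PairingOutcome:
    """Symmetric partner assignment with explicit singles.

    ``partners`` maps every agent id to its partner's id, or ``None`` for
    singles. ``received`` optionally records the final investment (or pursuit
    count) each agent received from its chosen mate.
    """

    partners: dict[int, int | None]
    received: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.partners.items():
            if b is None:
                continue
            if b == a:
                raise ValueError(f"agent {a} paired with itself")
            if self.partners.get(b) != a:
                raise ValueError(f"pairing not symmetric at agents {a}, {b}")

    @property
    def agent_ids(self) -> set[int]:
        return set(self.partners)

    @property
    def n_couples(self) -> int:
        return sum(1 for a, b in self.partners.items() if b is not None) // 2

    @property
    def n_singles(self) -> int:
        return sum(1 for b in self.partners.values() if b is None)

    def couples(self) -> list[tuple[int, int]]:
        """Unordered couple list, each couple once (smaller id first)."""
        return sorted(
            (a, b) for a, b in self.partners.items() if b is not None and a < b
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"agent_id": a, "partner_id": "" if b is None else b}
            for a, b in sorted(self.partners.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairingOutcome":
        df = pd.read_csv(path)
        partners: dict[int, int | None] = {}
        for _, row in df.iterrows():
            pid = row["partner_id"]
            partners[int(row["agent_id"])] = None if pd.isna(pid) else int(pid)
        return cls(partners)


@dataclass
class ReferencePairing:
    """Ground-truth couples: a symmetric agent->partner map with no singles."""

    partners: dict[int, int]

    def __post_init__(self) -> None:
        for a, b in self.partners.items():
            if b == a:
                raise ValueError(f"agent {a} paired with itself")
            if self.partners.get(b) != a:
                raise ValueError(f"reference pairing not an involution at {a}")

    @classmethod
    def from_couples(cls, couples: Iterable[tuple[int, int]]) -> "ReferencePairing":
        partners: dict[int, int] = {}
        for a, b in couples:
            partners[int(a)] = int(b)
            partners[int(b)] = int(a)
        return cls(partners)

    @classmethod
    def from_outcome(cls, outcome: PairingOutcome) -> "ReferencePairing":
        """Keep only the paired agents of a model outcome as reference couples."""
        return cls.from_couples(outcome.couples())

    def couples(self) -> list[tuple[int, int]]:
        return sorted((a, b) for a, b in self.partners.items() if a < b)

    @property
    def n_couples(self) -> int:
        return len(self.partners) // 2

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"agent_id": a, "partner_id": b} for a, b in sorted(self.partners.items())]
        ).to_csv(path, index=False)


def mutual_pairing(
    pref_f: np.ndarray,
    pref_m: np.ndarray,
    female_ids: np.ndarray,
    male_ids: np.ndarray,
    received_f: np.ndarray | None = None,
    received_m: np.ndarray | None = None,
) -> PairingOutcome:
    """Pair by mutual plurality: agents pair iff each is the other's top choice.

    ``pref_f[i]`` is the index (into ``male_ids``) of female i's most-pursued /
    most-invested male, and symmetrically for ``pref_m``. Everyone whose top
    choice does not reciprocate is single.
    """
    partners: dict[int, int | None] = {int(a): None for a in female_ids}
    partners.update({int(a): None for a in male_ids})
    received: dict[int, float] = {}
    for i, j in enumerate(pref_f):
        j = int(j)
        if int(pref_m[j]) == i:
            f, m = int(female_ids[i]), int(male_ids[j])
            partners[f] = m
            partners[m] = f
            if received_f is not None and received_m is not None:
                received[f] = float(received_f[i, j])
                received[m] = float(received_m[j, i])
    return PairingOutcome(partners, received)
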