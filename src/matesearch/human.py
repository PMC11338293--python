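"""Dyad questionnaire ingestion.

Reads couples' questionnaire data — one row per participant, two participants
per romantic dyad — and converts it into an :class:`AgentTable` plus the
reference pairing of real couples. The questionnaire covers 16 mate-choice
dimensions: age plus 15 paired-item dimensions, each of the 15 measured by
two items averaged into a composite. Participants rate their *ideal partner*
(preferences) and *themselves* (traits) on the same items, on an 11-point
0-10 scale; self-reported age is in years and is mapped onto the 0-10 scale
by a configurable linear transform anchored at the questionnaire's age bins
("Under 20" = 0, "Over 75" = 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import (
    AGENT_COLS,
    FEMALE,
    MALE,
    PREF_COLS,
    TRAIT_COLS,
    AgentTable,
    ReferencePairing,
)

logger = logging.getLogger(__name__)

#: the 15 two-item dimensions; age (single item) is the 16th dimension.
#: The questionnaire's sixteenth named dimension beyond age is taken to be
#: "resources"; all names are configurable through the column map.
PAIRED_DIMENSIONS = [
    "affectionateness",
    "ambition",
    "artistic_ability",
    "disposition",
    "family_support",
    "health",
    "humor",
    "intelligence",
    "kindness",
    "parenting",
    "physical_attractiveness",
    "religiosity",
    "resources",
    "sexiness",
    "status",
]
DIMENSIONS = ["age"] + PAIRED_DIMENSIONS  # 16 total
N_ITEMS = 31  # 15 dimensions x 2 items + 1 age item


def _default_items(prefix: str) -> list[str]:
    cols = [f"{prefix}_age"]
    for dim in PAIRED_DIMENSIONS:
        cols += [f"{prefix}_{dim}_1", f"{prefix}_{dim}_2"]
    return cols


@dataclass
class ColumnMap:
    """Names of the questionnaire columns in the input CSV."""

    participant_id: str = "participant_id"
    dyad_id: str = "dyad_id"
    sex: str = "sex"
    age_years: str = "self_age"  # self-reported age in years (also item slot 0)
    ideal_items: list[str] = field(default_factory=lambda: _default_items("ideal"))
    self_items: list[str] = field(default_factory=lambda: _default_items("self"))
    partner_items: list[str] | None = None
    metadata: list[str] = field(default_factory=list)  # e.g. relationship status/length
    female_code: str = "female"
    male_code: str = "male"

    def __post_init__(self) -> None:
        for name, items in (("ideal", self.ideal_items), ("self", self.self_items)):
            if len(items) != N_ITEMS:
                raise ValueError(
                    f"{name}_items must list {N_ITEMS} columns, got {len(items)}"
                )


@dataclass
class ParticipantRecord:
    """One validated questionnaire respondent."""

    participant_id: int
    dyad_id: int
    sex: str
    age_years: float
    ideal: np.ndarray  # 31 item ratings, 0-10 (item order of ColumnMap)
    self_ratings: np.ndarray  # 31 item ratings; slot 0 is age in years
    partner_ratings: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def read_participants(
    path: str | Path, column_map: ColumnMap | None = None
) -> list[ParticipantRecord]:
    """Read and validate participant rows; drop incomplete dyads.

    Dyads missing a partner or any questionnaire item are dropped with a
    logged count. Ratings outside [0, 10] raise with the offending rows.
    """
    cm = column_map or ColumnMap()
    df = pd.read_csv(path)
    required = [cm.participant_id, cm.dyad_id, cm.sex, cm.age_years]
    missing_cols = [c for c in required + cm.ideal_items + cm.self_items if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input CSV missing columns: {missing_cols}")

    rating_cols = cm.ideal_items + [c for c in cm.self_items if c != cm.self_items[0]]
    ratings = df[rating_cols].apply(pd.to_numeric, errors="coerce")
    bad = ((ratings < 0) | (ratings > 10)).any(axis=1)
    if bad.any():
        raise ValueError(
            f"ratings outside [0, 10] in rows {df.index[bad].tolist()}"
        )

    # completeness: every item present
    complete = df[cm.ideal_items + cm.self_items].notna().all(axis=1)
    df = df.assign(_complete=complete)

    records: list[ParticipantRecord] = []
    n_dropped = 0
    for dyad_id, group in df.groupby(cm.dyad_id):
        ok = (
            len(group) == 2
            and group["_complete"].all()
            and set(group[cm.sex]) == {cm.female_code, cm.male_code}
        )
        if not ok:
            n_dropped += 1
            continue
        for _, row in group.iterrows():
            sex = FEMALE if row[cm.sex] == cm.female_code else MALE
            records.append(
                ParticipantRecord(
                    participant_id=int(row[cm.participant_id]),
                    dyad_id=int(dyad_id),
                    sex=sex,
                    age_years=float(row[cm.age_years]),
                    ideal=group.loc[row.name, cm.ideal_items].to_numpy(dtype=float),
                    self_ratings=group.loc[row.name, cm.self_items].to_numpy(dtype=float),
                    partner_ratings=(
                        group.loc[row.name, cm.partner_items].to_numpy(dtype=float)
                        if cm.partner_items
                        else None
                    ),
                    metadata={k: row[k] for k in cm.metadata if k in row},
                )
            )
    if n_dropped:
        logger.warning("dropped %d incomplete or invalid dyads", n_dropped)
    return records


@dataclass
class AgeTransform:
    """Linear map from age in years to the questionnaire's 0-10 bin scale.

    Default anchors: 20 years ("Under 20" bin boundary) -> 0 and 75 years
    ("Over 75" boundary) -> 10, clamped outside the anchors.
    """

    lo_years: float = 20.0
    hi_years: float = 75.0

    def __call__(self, years: float) -> float:
        scale = 10.0 * (years - self.lo_years) / (self.hi_years - self.lo_years)
        return float(np.clip(scale, 0.0, 10.0))


def composite_dimensions(
    record: ParticipantRecord,
    age_transform: AgeTransform | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse the 31 items into 16-dimension preference and trait vectors.

    Dimension 1 is age (the ideal-age rating as-is; self age in years passed
    through ``age_transform``, identity if None); the remaining 15 dimensions
    are means of their two items.
    """
    for name, arr in (("ideal", record.ideal), ("self", record.self_ratings)):
        if arr is None or len(arr) != N_ITEMS or np.any(~np.isfinite(arr)):
            raise ValueError(f"record {record.participant_id}: missing {name} items")

    def collapse(items: np.ndarray, age_value: float) -> np.ndarray:
        pairs = items[1:].reshape(15, 2).mean(axis=1)
        return np.concatenate([[age_value], pairs])

    prefs = collapse(record.ideal, float(record.ideal[0]))
    self_age = (
        age_transform(record.age_years) if age_transform else record.age_years
    )
    traits = collapse(record.self_ratings, self_age)
    return prefs, traits


def to_agent_table(
    records: list[ParticipantRecord],
    age_transform: AgeTransform | None = None,
    trait_source: str = "self",
) -> tuple[AgentTable, ReferencePairing]:
    """Build a one-market AgentTable plus the real-couple reference pairing.

    By default traits come from self-ratings; ``trait_source="partner"`` uses
    partner-rated traits where available.
    """
    if trait_source not in ("self", "partner"):
        raise ValueError("trait_source must be 'self' or 'partner'")
    transform = age_transform or AgeTransform()

    rows = []
    dyad_members: dict[int, list[int]] = {}
    for agent_id, rec in enumerate(records):
        source = rec
        if trait_source == "partner":
            if rec.partner_ratings is None:
                raise ValueError(
                    f"record {rec.participant_id} lacks partner ratings"
                )
            source = ParticipantRecord(
                participant_id=rec.participant_id,
                dyad_id=rec.dyad_id,
                sex=rec.sex,
                age_years=rec.age_years,
                ideal=rec.ideal,
                self_ratings=rec.partner_ratings,
            )
        prefs, traits = composite_dimensions(source, transform)
        rows.append(
            {"agent_id": agent_id, "sex": rec.sex, "market_id": 0}
            | dict(zip(PREF_COLS, prefs))
            | dict(zip(TRAIT_COLS, traits))
        )
        dyad_members.setdefault(rec.dyad_id, []).append(agent_id)

    couples = []
    for dyad_id, members in dyad_members.items():
        if len(members) != 2:
            raise ValueError(f"dyad {dyad_id} does not have exactly 2 members")
        a, b = members
        if records[a].sex == records[b].sex:
            raise ValueError(
                f"dyad {dyad_id} has same-sex members; markets are opposite-sex"
            )
        couples.append((a, b))

    table = AgentTable(pd.DataFrame(rows)[AGENT_COLS])
    return table, ReferencePairing.from_couples(couples)
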