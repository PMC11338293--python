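"""Synthetic agent-population generation.

Populations of simulated mate-seekers are built so that the marginal
distributions and the 32x32 preference+trait correlation structure of each sex
mimic a target human sample. Generation is a three-step procedure per sex:

1. resample each of the 32 dimensions independently (with replacement) up to
   the requested size — or, if no raw value pools are supplied, draw Gaussians
   with the target mean and SD;
2. standardize the columns and multiply by the Cholesky factor of the target
   correlation matrix, imposing the requested correlation structure;
3. rescale each column to the target mean and standard deviation.

Values are deliberately not clipped to the 0-10 rating scale: the rescaling
can push individual values slightly out of range, and clipping would distort
the covariance the procedure exists to preserve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import AGENT_COLS, FEMALE, MALE, N_DIMS, PREF_COLS, TRAIT_COLS, AgentTable

logger = logging.getLogger(__name__)

N_STAT_DIMS = 2 * N_DIMS  # 16 preference + 16 trait dimensions
PSD_TOL = 1e-8

DEFAULT_DIM_NAMES = [f"pref_{i}" for i in range(1, N_DIMS + 1)] + [
    f"trait_{i}" for i in range(1, N_DIMS + 1)
]


@dataclass
class SexStats:
    """Target moments for one sex: means, SDs and 32x32 correlation matrix."""

    means: np.ndarray
    sds: np.ndarray
    corr: np.ndarray
    source_values: np.ndarray | None = None  # optional raw pools, (n_raw, 32)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.source_values is not None:
            self.source_values = np.asarray(self.source_values, dtype=float)

    def validate(self) -> None:
        if self.means.shape != (N_STAT_DIMS,) or self.sds.shape != (N_STAT_DIMS,):
            raise ValueError(f"means/sds must have length {N_STAT_DIMS}")
        if self.corr.shape != (N_STAT_DIMS, N_STAT_DIMS):
            raise ValueError(f"corr must be {N_STAT_DIMS}x{N_STAT_DIMS}")
        if np.any(self.sds <= 0):
            raise ValueError("all sds must be positive")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise ValueError("corr must have unit diagonal")
        smallest = float(np.linalg.eigvalsh(self.corr)[0])
        if smallest < -PSD_TOL:
            raise ValueError(
                f"corr is not positive semidefinite: smallest eigenvalue {smallest:.3e}"
            )


@dataclass
class GenerationStats:
    """Per-sex generation statistics with shared dimension names."""

    female: SexStats
    male: SexStats
    dimensions: list[str] = field(default_factory=lambda: list(DEFAULT_DIM_NAMES))

    def validate(self) -> None:
        if len(self.dimensions) != N_STAT_DIMS:
            raise ValueError(f"need exactly {N_STAT_DIMS} dimension names")
        self.female.validate()
        self.male.validate()

    def to_json(self, path: str | Path) -> None:
        def encode(s: SexStats) -> dict:
            d = {
                "means": s.means.tolist(),
                "sds": s.sds.tolist(),
                "corr": s.corr.tolist(),
            }
            if s.source_values is not None:
                d["source_values"] = s.source_values.tolist()
            return d

        payload = {
            "dimensions": self.dimensions,
            "female": encode(self.female),
            "male": encode(self.male),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerationStats":
        payload = json.loads(Path(path).read_text())

        def decode(d: dict) -> SexStats:
            return SexStats(
                means=np.array(d["means"], dtype=float),
                sds=np.array(d["sds"], dtype=float),
                corr=np.array(d["corr"], dtype=float),
                source_values=(
                    np.array(d["source_values"], dtype=float)
                    if "source_values" in d
                    else None
                ),
            )

        return cls(
            female=decode(payload["female"]),
            male=decode(payload["male"]),
            dimensions=list(payload["dimensions"]),
        )


def _cholesky_factor(corr: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, repairing near-PSD matrices with diagonal jitter."""
    smallest = float(np.linalg.eigvalsh(corr)[0])
    if smallest < -PSD_TOL:
        raise ValueError(
            f"correlation matrix not positive semidefinite: "
            f"smallest eigenvalue {smallest:.3e}"
        )
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(corr + jitter * np.eye(corr.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    raise ValueError("Cholesky factorization failed even after jitter repair")


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _generate_sex(
    stats: SexStats, n: int, rng: np.random.Generator
) -> np.ndarray:
    if stats.source_values is not None:
        idx = rng.integers(0, stats.source_values.shape[0], size=(n, N_STAT_DIMS))
        raw = stats.source_values[idx, np.arange(N_STAT_DIMS)]
    else:
        raw = rng.normal(stats.means, stats.sds, size=(n, N_STAT_DIMS))
    z = _standardize(raw)
    correlated = z @ _cholesky_factor(stats.corr).T
    out = _standardize(correlated) * stats.sds + stats.means
    n_out = int(np.sum((out < 0) | (out > 10)))
    if n_out:
        logger.info("%d generated values fall outside the 0-10 scale (kept)", n_out)
    return out


def generate_population(
    stats: GenerationStats, n_agents: int, seed: int
) -> AgentTable:
    """Generate ``n_agents`` agents, half female and half male, in one market.

    Each sex is generated separately from its own statistics. Identical
    arguments always produce an identical table.
    """
    if n_agents % 2 != 0:
        raise ValueError(f"n_agents must be even, got {n_agents}")
    if n_agents < 4:
        raise ValueError("need at least 2 agents per sex")
    stats.validate()
    rng = np.random.default_rng(seed)
    half = n_agents // 2

    rows = []
    for sex, sex_stats in ((FEMALE, stats.female), (MALE, stats.male)):
        values = _generate_sex(sex_stats, half, rng)
        block = pd.DataFrame(values, columns=PREF_COLS + TRAIT_COLS)
        block.insert(0, "sex", sex)
        rows.append(block)
    frame = pd.concat(rows, ignore_index=True)
    frame.insert(0, "agent_id", np.arange(n_agents))
    frame.insert(2, "market_id", 0)
    return AgentTable(frame[AGENT_COLS])


def split_markets(pop: AgentTable, n_groups: int, seed: int) -> AgentTable:
    """Randomly partition a population into equally sized, sex-balanced markets."""
    if n_groups < 1:
        raise ValueError("n_groups must be positive")
    frame = pop.frame.copy()
    rng = np.random.default_rng(seed)
    market = np.empty(len(frame), dtype=int)
    for sex in (FEMALE, MALE):
        idx = np.flatnonzero((frame["sex"] == sex).to_numpy())
        if len(idx) % n_groups != 0:
            raise ValueError(
                f"{len(idx)} {sex} agents cannot be split evenly into "
                f"{n_groups} groups"
            )
        perm = rng.permutation(idx)
        market[perm] = np.repeat(np.arange(n_groups), len(idx) // n_groups)
    frame["market_id"] = market
    return AgentTable(frame)


def default_synthetic_stats(seed: int = 0) -> GenerationStats:
    """Plausible fixture statistics for fully synthetic runs.

    Means fall in [4, 8] and SDs in [1, 2] on the 0-10 rating scale. The
    correlation matrix comes from a random two-factor structure with an extra
    shared loading on the trait block, giving moderate positive trait
    intercorrelations resembling a general desirability factor.
    """
    rng = np.random.default_rng(seed)

    def sex_stats() -> SexStats:
        means = rng.uniform(4, 8, N_STAT_DIMS)
        sds = rng.uniform(1, 2, N_STAT_DIMS)
        loadings = rng.normal(0.0, 0.35, size=(N_STAT_DIMS, 2))
        # shared positive loading on traits: a mild general desirability factor
        general = np.zeros((N_STAT_DIMS, 1))
        general[N_DIMS:, 0] = rng.uniform(0.3, 0.55, N_DIMS)
        w = np.hstack([loadings, general])
        cov = w @ w.T + np.diag(rng.uniform(0.4, 1.0, N_STAT_DIMS))
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        return SexStats(means=means, sds=sds, corr=corr)

    stats = GenerationStats(female=sex_stats(), male=sex_stats())
    stats.validate()
    return stats
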