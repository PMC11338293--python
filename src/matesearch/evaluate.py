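"""Couple-simulation evaluation of mate-search models.

A candidate mate-choice model is scored by how well it reproduces a reference
set of pairings. Two metrics are used:

- *end-state accuracy*: the percent of agents who finish in the same end
  state (same partner, or single in both) as in the reference outcome;
- *couple recovery*: the percent of reference couples whose two members are
  paired with each other in the candidate outcome.

The module also houses the three experiments built on these metrics: the
model-selection comparison (how well each of the seven search models
reproduces full-information choices across observation blocks), the
two-population proof of concept (can couple simulation identify which model
truly generated a set of couples?), and the noise sweep (how does recovery
degrade as perception noise grows?), plus a small parameter grid search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agents import FEMALE, MALE, AgentTable, PairingOutcome, ReferencePairing
from .allocation import run_allocation
from .bandits import LEARNING_MODELS, MODELS, NoiseSpec, SearchParams, calibrate_noise, run_search
from .matevalue import mv_matrix
from .population import GenerationStats, generate_population, split_markets


@dataclass
class AccuracyResult:
    """A recovery-rate estimate with its confidence interval (percent scale)."""

    model: str
    accuracy: float
    n_units: int
    ci_low: float
    ci_high: float
    method: str  # "agent_endstate" or "couple_recovery"
    indicators: np.ndarray | None = None
    replicates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.accuracy <= self.ci_high <= 100):
            raise ValueError(
                f"inconsistent accuracy/CI: {self.ci_low}, {self.accuracy}, {self.ci_high}"
            )


def _normal_ci(indicators: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    from scipy.stats import norm

    p = indicators.mean()
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p * (1 - p) / len(indicators))
    return (
        float(np.clip(100 * (p - half), 0, 100)),
        float(np.clip(100 * (p + half), 0, 100)),
    )


def endstate_accuracy(
    candidate: PairingOutcome, reference: PairingOutcome, model: str = ""
) -> AccuracyResult:
    """Percent of agents finishing in the same end state as in the reference."""
    if candidate.agent_ids != reference.agent_ids:
        raise ValueError("candidate and reference cover different agent sets")
    ids = sorted(candidate.agent_ids)
    indicators = np.array(
        [candidate.partners[a] == reference.partners[a] for a in ids], dtype=float
    )
    lo, hi = _normal_ci(indicators)
    acc = float(100 * indicators.mean())
    return AccuracyResult(
        model=model,
        accuracy=acc,
        n_units=len(ids),
        ci_low=min(lo, acc),
        ci_high=max(hi, acc),
        method="agent_endstate",
        indicators=indicators,
    )


def couple_recovery(
    candidate: PairingOutcome,
    reference: ReferencePairing,
    model: str = "",
) -> AccuracyResult:
    """Percent of reference couples reproduced intact by the candidate."""
    indicators = np.array(
        [candidate.partners.get(a) == b for a, b in reference.couples()],
        dtype=float,
    )
    if len(indicators) == 0:
        raise ValueError("reference pairing contains no couples")
    lo, hi = _normal_ci(indicators)
    acc = float(100 * indicators.mean())
    return AccuracyResult(
        model=model,
        accuracy=acc,
        n_units=len(indicators),
        ci_low=min(lo, acc),
        ci_high=max(hi, acc),
        method="couple_recovery",
        indicators=indicators,
    )


def bootstrap_ci(
    unit_indicators: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI (percent scale) for a mean of 0/1 indicators."""
    x = np.asarray(unit_indicators, dtype=float)
    if x.size == 0:
        raise ValueError("cannot bootstrap an empty indicator list")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = 100 * x[idx].mean(axis=1)
    alpha = (1 - level) / 2
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha))


@dataclass
class CoupleSample:
    """A sex-balanced sample of couples re-housed in one new market."""

    agents: AgentTable
    reference: ReferencePairing
    source_markets: list[int]


def sample_couples(
    couple_pop: tuple[AgentTable, PairingOutcome | ReferencePairing],
    n_agents: int,
    seed: int = 0,
) -> CoupleSample:
    """Draw ``n_agents/2`` couples uniformly without replacement across markets.

    Singles never enter the sample; the drawn couples form a single new
    mating market that is (almost surely) not identical to any couple's
    original market.
    """
    pop, pairing = couple_pop
    if n_agents % 2 != 0:
        raise ValueError("n_agents must be even")
    couples = pairing.couples()
    n_pairs = n_agents // 2
    if len(couples) < n_pairs:
        raise ValueError(
            f"requested {n_pairs} couples but only {len(couples)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = [couples[i] for i in rng.choice(len(couples), n_pairs, replace=False)]
    ids = [a for pair in chosen for a in pair]
    agents = pop.subset(ids, market_id=0)
    markets = sorted(set(int(x) for x in agents.frame["market_id"].unique()))
    return CoupleSample(
        agents=agents,
        reference=ReferencePairing.from_couples(chosen),
        source_markets=markets,
    )


# ---------------------------------------------------------------------------
# experiment 1: model selection against full-information choices


@dataclass
class ModelSelectionConfig:
    models: tuple[str, ...] = MODELS
    p: float = 0.5
    budget: int = 10_000
    block_size: int = 1_000
    n_iterations: int = 10
    ram_steps: int = 50


def run_model_selection(
    pop: AgentTable,
    config: ModelSelectionConfig = ModelSelectionConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Score every search model against the full-information RAM reference.

    Returns a tidy frame (model, iteration, block_end, accuracy) of end-state
    accuracies at each observation block, for ``n_iterations`` independent
    repetitions of each model.
    """
    mv = mv_matrix(pop)
    rng = np.random.default_rng(seed)
    reference = run_allocation(mv, n_steps=config.ram_steps, seed=int(rng.integers(2**31)))
    noise = calibrate_noise(mv, config.p)

    rows = []
    for model in config.models:
        for it in range(config.n_iterations):
            params = SearchParams(
                model=model, budget=config.budget, block_size=config.block_size
            )
            traj, _ = run_search(pop, mv, params, noise, seed=int(rng.integers(2**31)))
            for block_end, pairing in traj:
                res = endstate_accuracy(pairing, reference, model=model)
                rows.append(
                    {
                        "model": model,
                        "iteration": it,
                        "block_end": block_end,
                        "accuracy": res.accuracy,
                    }
                )
    return pd.DataFrame(rows)


def summarize_model_selection(results: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per model per block across iterations."""
    return (
        results.groupby(["model", "block_end"], as_index=False)["accuracy"]
        .mean()
        .sort_values(["model", "block_end"], ignore_index=True)
    )


# ---------------------------------------------------------------------------
# experiment 2: two-population proof of concept


@dataclass
class ProofOfConceptConfig:
    n_markets: int = 50
    market_size: int = 500
    obs_per_mate: int = 30
    p: float = 0.5
    rwts_prior_sd: float = 0.10
    n_samples: int = 100
    sample_size: int = 500
    true_models: tuple[str, str] = ("nonlearning", "rwts")
    candidate_models: tuple[str, str] = ("nonlearning", "rwts")


def _search_params_for(model: str, n_mates: int, config) -> SearchParams:
    budget = config.obs_per_mate * n_mates
    prior_sd = config.rwts_prior_sd if model == "rwts" else None
    return SearchParams(model=model, prior_sd=prior_sd, budget=budget, block_size=budget)


def _form_couples(
    pop: AgentTable, model: str, config, rng: np.random.Generator
) -> PairingOutcome:
    """Run ``model`` in every market of ``pop``; merge the final pairings."""
    partners: dict[int, int | None] = {}
    for market_id in pop.market_ids:
        market = pop.market(int(market_id))
        mv = mv_matrix(market)
        noise = calibrate_noise(mv, config.p)
        params = _search_params_for(model, mv.n_male, config)
        traj, _ = run_search(market, mv, params, noise, seed=int(rng.integers(2**31)))
        partners.update(traj.final_pairing.partners)
    return PairingOutcome(partners)


def run_proof_of_concept(
    stats: GenerationStats,
    config: ProofOfConceptConfig = ProofOfConceptConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """The two-population identifiability experiment.

    One agent population is generated and cloned; couples are formed in each
    clone under a different "true" model. Candidate models are then run on
    repeated couple samples from each population and scored by couple
    recovery. Returns one row per (true model, candidate model) cell with the
    mean recovery and a normal-approximation CI across samples.
    """
    rng = np.random.default_rng(seed)
    pop = generate_population(
        stats, config.n_markets * config.market_size, seed=int(rng.integers(2**31))
    )
    pop = split_markets(pop, config.n_markets, seed=int(rng.integers(2**31)))

    rows = []
    for true_model in config.true_models:
        outcome = _form_couples(pop, true_model, config, rng)
        couple_pop = (pop, outcome)
        per_candidate: dict[str, list[float]] = {m: [] for m in config.candidate_models}
        for _ in range(config.n_samples):
            sample = sample_couples(
                couple_pop, config.sample_size, seed=int(rng.integers(2**31))
            )
            mv = mv_matrix(sample.agents)
            noise = calibrate_noise(mv, config.p)
            for cand in config.candidate_models:
                params = _search_params_for(cand, mv.n_male, config)
                traj, _ = run_search(
                    sample.agents, mv, params, noise, seed=int(rng.integers(2**31))
                )
                res = couple_recovery(traj.final_pairing, sample.reference, model=cand)
                per_candidate[cand].append(res.accuracy)
        for cand, accs in per_candidate.items():
            accs_arr = np.asarray(accs)
            half = 1.959964 * accs_arr.std(ddof=1) / np.sqrt(len(accs_arr))
            rows.append(
                {
                    "true_model": true_model,
                    "candidate_model": cand,
                    "accuracy": float(accs_arr.mean()),
                    "ci_low": float(max(accs_arr.mean() - half, 0)),
                    "ci_high": float(min(accs_arr.mean() + half, 100)),
                    "n_samples": len(accs_arr),
                    "n_couples_per_sample": config.sample_size // 2,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# experiment 3: recovery across noise levels


@dataclass
class NoiseSweepConfig:
    obs_per_mate: int = 30
    rwts_prior_sd: float = 0.10
    p: float = 0.5  # unused per-run; sweep passes each level explicitly
    models: tuple[str, ...] = ("nonlearning", "rwts")
    n_boot: int = 10_000


def run_noise_sweep(
    agents: AgentTable,
    reference: ReferencePairing,
    noise_levels: Iterable[float],
    config: NoiseSweepConfig = NoiseSweepConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Couple recovery of each model at each perceptual-noise fraction.

    ``agents`` is a single market (e.g. real dyad members); ``reference`` the
    true couples. CIs are bootstrap percentile intervals over couples.
    """
    mv = mv_matrix(agents)
    rng = np.random.default_rng(seed)
    rows = []
    for p in noise_levels:
        noise = calibrate_noise(mv, p)
        for model in config.models:
            params = _search_params_for(model, mv.n_male, config)
            traj, _ = run_search(agents, mv, params, noise, seed=int(rng.integers(2**31)))
            res = couple_recovery(traj.final_pairing, reference, model=model)
            lo, hi = bootstrap_ci(
                res.indicators, n_boot=config.n_boot, seed=int(rng.integers(2**31))
            )
            rows.append(
                {
                    "p": p,
                    "model": model,
                    "accuracy": res.accuracy,
                    "ci_low": min(lo, res.accuracy),
                    "ci_high": max(hi, res.accuracy),
                    "n_couples": res.n_units,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parameter grid search at reduced scale


@dataclass
class GridSearchConfig:
    n_agents: int = 60
    p: float = 0.5
    obs_per_mate: int = 30
    block_size: int | None = None  # default: one block
    n_reps: int = 3
    stats: GenerationStats | None = None


def grid_search(
    model: str,
    param_grid: dict[str, Sequence[float]],
    config: GridSearchConfig = GridSearchConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Mean end-state accuracy of ``model`` over a parameter grid.

    Runs the model-comparison at reduced scale for every point of the
    cartesian product of ``param_grid`` values and reports mean final-block
    end-state accuracy across replicates; the best row maximizes accuracy.
    """
    from .population import default_synthetic_stats

    rng = np.random.default_rng(seed)
    stats = config.stats if config.stats is not None else default_synthetic_stats(
        int(rng.integers(2**31))
    )
    pop = generate_population(stats, config.n_agents, seed=int(rng.integers(2**31)))
    mv = mv_matrix(pop)
    reference = run_allocation(mv, seed=int(rng.integers(2**31)))
    noise = calibrate_noise(mv, config.p)
    budget = config.obs_per_mate * mv.n_male
    block = config.block_size or budget

    names = list(param_grid)
    rows = []
    for values in itertools.product(*(param_grid[k] for k in names)):
        overrides = dict(zip(names, values))
        accs = []
        for _ in range(config.n_reps):
            params = SearchParams(model=model, budget=budget, block_size=block, **overrides)
            traj, _ = run_search(pop, mv, params, noise, seed=int(rng.integers(2**31)))
            accs.append(endstate_accuracy(traj.final_pairing, reference).accuracy)
        rows.append({**overrides, "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
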