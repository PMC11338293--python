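"""Partial-information mate search as a multi-armed bandit problem.

Under partial information every potential mate is an arm of a bandit: pursuing
(observing) a mate returns that mate's true mate value plus Gaussian
perceptual noise, and agents must balance exploring the market against
exploiting the mates they already believe are best. Seven models are
implemented:

``nonlearning``
    One observation of every mate, then full resource-allocation mate choice
    on the perceived values. The no-learning baseline.
``eg`` / ``ucb`` / ``ts``
    Mate-value-as-reward learners: epsilon-greedy, UCB1, and Thompson
    sampling with a conjugate normal-normal posterior. All start from an
    optimistic initial estimate (mv = 10 for every mate) so that every arm is
    worth a first look.
``rweg`` / ``rwucb`` / ``rwts``
    The same learners with the reward score multiplied by a reciprocity
    weight — the ratio of pursuits received from a mate to pursuits sent to
    them — steering search toward mutually interested partners.

All agents of both sexes search synchronously: each trial every agent chooses
one mate using the counts as they stood at the end of the previous trial, then
all observations and counts update jointly. Pursuit counts are public in the
sense that an agent's reciprocity weight for a mate uses how often that mate
has pursued *them*. At the end of each block of trials a provisional pairing
snapshot is taken: an agent pairs with its most-pursued mate iff that mate's
most-pursued agent is them (mutual plurality); pairing never removes agents
from the market.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .agents import PairingOutcome, mutual_pairing
from .allocation import _argmax_random_ties, run_allocation
from .matevalue import MateValueMatrix

MODELS = ("nonlearning", "eg", "ucb", "ts", "rweg", "rwucb", "rwts")
LEARNING_MODELS = MODELS[1:]

#: tuned parameter defaults: epsilon for (rw)eg, c for (rw)ucb, prior SD for (rw)ts
DEFAULT_PARAMS = {
    "eg": {"epsilon": 0.2},
    "ucb": {"c": 1.5},
    "ts": {"prior_sd": 0.2},
    "rweg": {"epsilon": 0.15},
    "rwucb": {"c": 0.2},
    "rwts": {"prior_sd": 0.25},
    "nonlearning": {},
}


@dataclass(frozen=True)
class NoiseSpec:
    """Observation noise: ``p`` is the fraction of perception variance that is
    noise; ``sd`` the implied noise standard deviation in mate-value units."""

    p: float
    sd: float


def calibrate_noise(mv: MateValueMatrix, p: float) -> NoiseSpec:
    """Scale the noise SD so a fraction ``p`` of perception variance is noise.

    With V the pooled variance of all true mate values across focal agents,
    ``sd = sqrt(V * p / (1 - p))`` makes ``sd^2 / (sd^2 + V) = p`` exactly.
    """
    if not 0 <= p < 1:
        raise ValueError(f"noise fraction p must be in [0, 1), got {p}")
    v = float(np.var(mv.pooled_values()))
    return NoiseSpec(p=p, sd=float(np.sqrt(v * p / (1.0 - p))))


def observe(mv_true, noise: NoiseSpec, rng: np.random.Generator):
    """One noisy observation: Normal(true mate value, noise.sd), unclipped."""
    mv_true = np.asarray(mv_true, dtype=float)
    if noise.sd == 0:
        return mv_true.copy() if mv_true.ndim else float(mv_true)
    draw = rng.normal(mv_true, noise.sd)
    return draw if np.ndim(mv_true) else float(draw)


def ucb_score(estimate, t: int, n_obs, c: float):
    """UCB1 score: estimate + c * sqrt(ln t / N); unvisited arms score +inf."""
    if t < 1:
        raise ValueError(f"trial counter t must be >= 1, got {t}")
    estimate = np.asarray(estimate, dtype=float)
    n_obs = np.asarray(n_obs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        # 0/0 at (t=1, N=0) is overridden by the +inf unvisited-arm rule
        bonus = c * np.sqrt(np.log(t) / n_obs)
    score = np.where(n_obs == 0, np.inf, estimate + bonus)
    return score if score.ndim else float(score)


def ts_update(mu, sigma, x, obs_sd: float):
    """Conjugate normal-normal posterior update with known observation SD.

    Returns the precision-weighted posterior mean and the SD of the combined
    precision; the posterior SD strictly shrinks with every update.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0) or obs_sd <= 0:
        raise ValueError("prior sigma and obs_sd must be positive")
    prior_prec = 1.0 / sigma**2
    obs_prec = 1.0 / obs_sd**2
    post_prec = prior_prec + obs_prec
    mu_post = (mu * prior_prec + np.asarray(x, dtype=float) * obs_prec) / post_prec
    sigma_post = np.sqrt(1.0 / post_prec)
    if mu_post.ndim:
        return mu_post, sigma_post
    return float(mu_post), float(sigma_post)


def reciprocity_weight(obs_received, obs_sent):
    """Ratio of pursuits received from a mate to pursuits sent to them.

    Counts are expected to include the +1 virtual mutual pursuit used at
    initialization, so the ratio starts at the neutral value 1 and the
    denominator is never zero. A mate who never reciprocates drives the
    weight toward zero, extinguishing pursuit.
    """
    obs_received = np.asarray(obs_received, dtype=float)
    obs_sent = np.asarray(obs_sent, dtype=float)
    if np.any(obs_sent <= 0):
        raise ValueError("obs_sent must be positive (include virtual counts)")
    w = obs_received / obs_sent
    return w if w.ndim else float(w)


@dataclass
class SearchParams:
    """Parameters of one search model run.

    ``epsilon``, ``c`` and ``prior_sd`` default to the tuned per-model values
    in :data:`DEFAULT_PARAMS` when left as None. ``assumed_obs_sd`` is the
    observation SD Thompson agents use in their Bayesian update; by default
    they use the true calibrated noise SD.
    """

    model: str
    epsilon: float | None = None
    c: float | None = None
    prior_sd: float | None = None
    initial_estimate: float = 10.0
    budget: int = 10_000
    block_size: int = 1_000
    assumed_obs_sd: float | None = None

    def resolved(self) -> "SearchParams":
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.budget % self.block_size != 0:
            raise ValueError(
                f"budget {self.budget} must be divisible by block_size {self.block_size}"
            )
        defaults = DEFAULT_PARAMS[self.model]
        return replace(
            self,
            epsilon=self.epsilon if self.epsilon is not None else defaults.get("epsilon"),
            c=self.c if self.c is not None else defaults.get("c"),
            prior_sd=self.prior_sd if self.prior_sd is not None else defaults.get("prior_sd"),
        )


@dataclass
class SearchState:
    """Learning state of one sex block: row = focal agent, column = mate.

    ``received`` is a transposed view of the opposite block's ``pulls``, so
    pursuit counts stay consistent without double bookkeeping.
    """

    estimate: np.ndarray  # learned mate value (or posterior mean for TS)
    pulls: np.ndarray  # observations sent, per mate
    received: np.ndarray  # pursuits received from each mate
    mu: np.ndarray  # TS posterior mean
    sigma: np.ndarray  # TS posterior SD
    t: int = 0  # completed trials (shared across the block)

    @classmethod
    def initial(cls, n_focal: int, n_mates: int, params: SearchParams) -> "SearchState":
        shape = (n_focal, n_mates)
        prior_sd = params.prior_sd if params.prior_sd is not None else 1.0
        return cls(
            estimate=np.full(shape, params.initial_estimate, dtype=float),
            pulls=np.zeros(shape, dtype=np.int64),
            received=np.zeros(shape, dtype=np.int64),
            mu=np.full(shape, params.initial_estimate, dtype=float),
            sigma=np.full(shape, prior_sd, dtype=float),
        )


def choose_mate(
    model: str,
    state: SearchState,
    params: SearchParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Choose one mate per focal agent (row); ties broken uniformly at random.

    Works on whole sex blocks at once; a single agent is a 1-row state.
    """
    if model not in LEARNING_MODELS:
        raise ValueError(f"unknown learning model {model!r}")
    n, m = state.estimate.shape
    t_now = state.t + 1  # the trial being decided

    if model in ("rweg", "rwucb", "rwts"):
        weight = reciprocity_weight(state.received + 1, state.pulls + 1)
    else:
        weight = 1.0

    if model in ("eg", "rweg"):
        score = weight * state.estimate
    elif model in ("ucb", "rwucb"):
        base = ucb_score(state.estimate, t_now, state.pulls, params.c)
        # reciprocity weights the summed reward estimate (value + bonus)
        score = weight * base if model == "rwucb" else base
    else:  # ts, rwts
        draws = rng.normal(state.mu, state.sigma)
        score = weight * draws if model == "rwts" else draws

    choice = _argmax_random_ties(score, rng)
    if model in ("eg", "rweg"):
        explore = rng.random(n) < params.epsilon
        if explore.any():
            choice = choice.copy()
            choice[explore] = rng.integers(0, m, size=int(explore.sum()))
    return choice


@dataclass
class BlockTrajectory:
    """Provisional pairing snapshots, one per completed observation block."""

    records: list[tuple[int, PairingOutcome]] = field(default_factory=list)

    def append(self, block_end: int, pairing: PairingOutcome) -> None:
        self.records.append((block_end, pairing))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def final_pairing(self) -> PairingOutcome:
        return self.records[-1][1]

    def to_frame(self):
        """Long-format frame: block, agent_id, provisional_partner_id."""
        import pandas as pd

        rows = [
            {"block": block_end, "agent_id": a,
             "provisional_partner_id": b if b is not None else pd.NA}
            for block_end, pairing in self.records
            for a, b in sorted(pairing.partners.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _provisional_pairing(
    mv: MateValueMatrix,
    pulls_f: np.ndarray,
    pulls_m: np.ndarray,
    rng: np.random.Generator,
) -> PairingOutcome:
    pref_f = _argmax_random_ties(pulls_f.astype(float), rng)
    pref_m = _argmax_random_ties(pulls_m.astype(float), rng)
    return mutual_pairing(
        pref_f, pref_m, mv.female_ids, mv.male_ids,
        received_f=pulls_m.T, received_m=pulls_f.T,
    )


def _update_estimates(
    state: SearchState,
    choice: np.ndarray,
    x: np.ndarray,
    params: SearchParams,
    obs_sd: float,
    thompson: bool,
) -> None:
    rows = np.arange(len(choice))
    if thompson:
        mu_new, sigma_new = ts_update(
            state.mu[rows, choice], state.sigma[rows, choice], x, obs_sd
        )
        state.mu[rows, choice] = mu_new
        state.sigma[rows, choice] = sigma_new
        state.estimate[rows, choice] = mu_new
    else:
        # incremental mean; the first observation replaces the optimistic init
        n_prev = state.pulls[rows, choice]
        est = state.estimate[rows, choice]
        state.estimate[rows, choice] = est + (x - est) / (n_prev + 1)
    state.pulls[rows, choice] += 1
    state.t += 1


def run_search(
    pop,
    mv: MateValueMatrix,
    params: SearchParams,
    noise: NoiseSpec,
    seed: int = 0,
) -> tuple[BlockTrajectory, dict[str, SearchState]]:
    """Run one search model for all agents of a single market.

    ``pop`` is accepted for interface symmetry but the mate-value matrix fully
    determines the search environment. Returns the block-end provisional
    pairing trajectory and the final learning state per sex.
    """
    params = params.resolved()
    rng = np.random.default_rng(seed)
    n_f, n_m = mv.f_to_m.shape
    trajectory = BlockTrajectory()

    if params.model == "nonlearning":
        # one observation of every mate, then full-information-style RAM on
        # the perceived matrix
        perceived = MateValueMatrix(
            female_ids=mv.female_ids,
            male_ids=mv.male_ids,
            f_to_m=np.asarray(observe(mv.f_to_m, noise, rng)),
            m_to_f=np.asarray(observe(mv.m_to_f, noise, rng)),
            market_id=mv.market_id,
        )
        outcome = run_allocation(perceived, seed=int(rng.integers(2**31)))
        n_blocks = max(params.budget // params.block_size, 1)
        for b in range(1, n_blocks + 1):
            trajectory.append(b * params.block_size, outcome)
        state_f = SearchState.initial(n_f, n_m, params)
        state_m = SearchState.initial(n_m, n_f, params)
        state_f.pulls[:] = 1
        state_m.pulls[:] = 1
        state_f.t = n_m
        state_m.t = n_f
        state_f.received = state_m.pulls.T
        state_m.received = state_f.pulls.T
        return trajectory, {"female": state_f, "male": state_m}

    state_f = SearchState.initial(n_f, n_m, params)
    state_m = SearchState.initial(n_m, n_f, params)
    # received counts are live transposed views of the other block's pulls
    state_f.received = state_m.pulls.T
    state_m.received = state_f.pulls.T

    thompson = params.model in ("ts", "rwts")
    obs_sd = params.assumed_obs_sd if params.assumed_obs_sd is not None else noise.sd
    obs_sd = max(obs_sd, 1e-9)  # keep the Bayesian update defined at zero noise

    rows_f = np.arange(n_f)
    rows_m = np.arange(n_m)
    for trial in range(1, params.budget + 1):
        # both sexes choose from the end-of-previous-trial counts, then all
        # observations and counts update jointly (synchronous dynamics)
        c_f = choose_mate(params.model, state_f, params, rng)
        c_m = choose_mate(params.model, state_m, params, rng)
        x_f = observe(mv.f_to_m[rows_f, c_f], noise, rng)
        x_m = observe(mv.m_to_f[rows_m, c_m], noise, rng)
        _update_estimates(state_f, c_f, np.asarray(x_f), params, obs_sd, thompson)
        _update_estimates(state_m, c_m, np.asarray(x_m), params, obs_sd, thompson)
        if trial % params.block_size == 0:
            trajectory.append(
                trial, _provisional_pairing(mv, state_f.pulls, state_m.pulls, rng)
            )
    return trajectory, {"female": state_f, "male": state_m}
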