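"""Full-information resource-allocation mate choice (RAM).

Each agent holds a fixed budget of courtship resources. Allocation starts
proportional to true mate value and is then iteratively redistributed: on each
step an agent reweights every potential mate by the product of the resources
the agent sent to that mate and the resources that mate sent back on the
previous step. The product rewards mutual investment and extinguishes
unreciprocated pursuit, so agents typically converge on a single mate with
high mutual investment. After the final step, agents pair with the mate in
whom they are most invested if and only if that mate is most invested in them
in return; everyone else is single.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .agents import PairingOutcome, mutual_pairing
from .matevalue import MateValueMatrix

logger = logging.getLogger(__name__)

WEIGHT_RULES = ("product", "sum", "geometric")


@dataclass
class AllocationState:
    """Current resource allocation of both sexes.

    ``sent_f[i, j]`` is the amount female i currently sends to male j;
    ``sent_m[j, i]`` the reverse direction. Every row sums to ``budget``.
    """

    sent_f: np.ndarray
    sent_m: np.ndarray
    budget: float
    step_index: int = 0

    def row_sums(self) -> np.ndarray:
        return np.concatenate([self.sent_f.sum(axis=1), self.sent_m.sum(axis=1)])


def _proportional_rows(weights: np.ndarray, budget: float) -> np.ndarray:
    """Each row scaled to sum to ``budget``; all-zero rows become uniform."""
    totals = weights.sum(axis=1, keepdims=True)
    out = np.empty_like(weights, dtype=float)
    zero = (totals == 0).ravel()
    nonzero = ~zero
    out[nonzero] = budget * weights[nonzero] / totals[nonzero]
    if zero.any():
        out[zero] = budget / weights.shape[1]
    return out


def initial_allocation(mv: MateValueMatrix, budget: float = 10.0) -> AllocationState:
    """Allocate each agent's budget across mates in proportion to mate value."""
    if budget <= 0:
        raise ValueError(f"budget must be positive, got {budget}")
    f = np.asarray(mv.f_to_m, dtype=float)
    m = np.asarray(mv.m_to_f, dtype=float)
    if (f < 0).any() or (m < 0).any():
        logger.warning("negative mate values floored at 0 for allocation")
        f = np.maximum(f, 0.0)
        m = np.maximum(m, 0.0)
    return AllocationState(
        sent_f=_proportional_rows(f, budget),
        sent_m=_proportional_rows(m, budget),
        budget=budget,
        step_index=0,
    )


def _combine(sent: np.ndarray, received: np.ndarray, rule: str) -> np.ndarray:
    if rule == "product":
        return sent * received
    if rule == "sum":
        return sent + received
    if rule == "geometric":
        return np.sqrt(sent * received)
    raise ValueError(f"unknown weight rule {rule!r}; choose from {WEIGHT_RULES}")


def reallocate_step(state: AllocationState, weight_rule: str = "product") -> AllocationState:
    """One reallocation step: reweight by resources sent and received.

    Rows whose weights are all zero (a fully stalled agent) keep their
    previous allocation so the dynamics remain total.
    """
    w_f = _combine(state.sent_f, state.sent_m.T, weight_rule)
    w_m = _combine(state.sent_m, state.sent_f.T, weight_rule)

    new_f = _proportional_rows(w_f, state.budget)
    new_m = _proportional_rows(w_m, state.budget)
    stalled_f = w_f.sum(axis=1) == 0
    stalled_m = w_m.sum(axis=1) == 0
    if stalled_f.any():
        new_f[stalled_f] = state.sent_f[stalled_f]
    if stalled_m.any():
        new_m[stalled_m] = state.sent_m[stalled_m]
    return AllocationState(new_f, new_m, state.budget, state.step_index + 1)


def _argmax_random_ties(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise argmax with ties broken uniformly at random."""
    top = scores.max(axis=1, keepdims=True)
    tied = scores == top
    keys = rng.random(scores.shape)
    keys[~tied] = -1.0
    return keys.argmax(axis=1)


def run_allocation(
    mv: MateValueMatrix,
    n_steps: int = 50,
    budget: float = 10.0,
    seed: int = 0,
    weight_rule: str = "product",
) -> PairingOutcome:
    """Run the full RAM dynamics and return the mutual-plurality pairing."""
    rng = np.random.default_rng(seed)
    state = initial_allocation(mv, budget)
    for _ in range(n_steps):
        state = reallocate_step(state, weight_rule)
    pref_f = _argmax_random_ties(state.sent_f, rng)
    pref_m = _argmax_random_ties(state.sent_m, rng)
    return mutual_pairing(
        pref_f,
        pref_m,
        mv.female_ids,
        mv.male_ids,
        received_f=state.sent_m.T,
        received_m=state.sent_f.T,
    )
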