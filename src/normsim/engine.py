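"""Population dynamics: matching, stepping, stationarity and replications.

The population is well mixed.  Each time step a uniform random perfect
matching splits the ``N`` agents into ``N/2`` pairs, one member of each
pair is chosen as dictator with probability 1/2, and every recipient is
updated from the donation of its dictator via the rules in
:mod:`normsim.model_core` (vectorised over all recipients at once).

A run consists of a transient of ``transient`` steps followed by
1000-step windows; after each window an OLS line is fitted to the
population-mean donation against the step index over that window, and
the run stops as soon as the absolute slope drops strictly below the
threshold (stationarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .model_core import ModelParams

__all__ = [
    "PopulationState",
    "RunResult",
    "init_population",
    "step",
    "run_to_stationarity",
    "run_replications",
    "replication_rng",
]

logger = logging.getLogger(__name__)

#: default stationarity-detection settings
DEFAULT_TRANSIENT = 10_000
DEFAULT_WINDOW = 1_000
DEFAULT_SLOPE_TOL = 1e-4
DEFAULT_MAX_STEPS = 200_000


@dataclass
class PopulationState:
    """Per-agent aspirations, donations and trait masks at one time step."""

    aspirations: np.ndarray
    donations: np.ndarray
    envious_mask: np.ndarray
    frozen_mask: np.ndarray
    t: int = 0

    @property
    def n_agents(self) -> int:
        return self.aspirations.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(
            aspirations=self.aspirations.copy(),
            donations=self.donations.copy(),
            envious_mask=self.envious_mask.copy(),
            frozen_mask=self.frozen_mask.copy(),
            t=self.t,
        )


@dataclass
class RunResult:
    """Outcome of a single replication.

    ``mean_donation_series[k]`` is the population-mean donation after
    step ``k + 1``; ``converged_at`` is the step count at termination and
    ``converged`` is False only if the ``max_steps`` guard fired first.
    """

    mean_donation_series: np.ndarray
    final_aspirations: np.ndarray
    final_donations: np.ndarray
    converged_at: int
    converged: bool
    params: ModelParams

    @property
    def final_mean_donation(self) -> float:
        return float(self.final_donations.mean())


def init_population(params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Draw the initial population.

    Aspirations are i.i.d. uniform on [0, endowment] and each agent's
    initial donation is the complement ``endowment - aspiration``.  The
    first ``n_free_riders`` agents are frozen at
    ``free_rider_donation`` (their aspiration is set to the same value;
    it never enters the dynamics).  Envy is a Bernoulli trait drawn once
    per non-frozen agent.
    """
    n = params.n_agents
    phi = params.endowment
    aspirations = rng.uniform(0.0, phi, size=n)
    donations = phi - aspirations
    frozen = np.zeros(n, dtype=bool)
    envious = np.zeros(n, dtype=bool)
    if params.n_free_riders:
        frozen[: params.n_free_riders] = True
        aspirations[frozen] = params.free_rider_donation
        donations[frozen] = params.free_rider_donation
    if params.envy_probability > 0:
        envious = rng.random(n) < params.envy_probability
        envious &= ~frozen
    return PopulationState(aspirations, donations, envious, frozen, t=0)


def step(state: PopulationState, params: ModelParams, rng: np.random.Generator,
         inplace: bool = False) -> PopulationState:
    """Play one round of Dictator Games and update all recipients.

    A uniform random perfect matching pairs every agent exactly once;
    within each pair the dictator is chosen uniformly.  Each recipient
    receives a payoff equal to its dictator's current donation and is
    updated in place of its old values; dictators and frozen agents are
    untouched.
    """
    if not inplace:
        state = state.copy()
    n = state.n_agents
    phi = params.endowment

    pairs = rng.permutation(n).reshape(-1, 2)
    coin = rng.integers(0, 2, size=pairs.shape[0])
    rows = np.arange(pairs.shape[0])
    dictators = pairs[rows, coin]
    recipients = pairs[rows, 1 - coin]
    payoffs = state.donations[dictators]

    live = ~state.frozen_mask[recipients]
    idx = recipients[live]
    pi = payoffs[live]
    a = state.aspirations[idx]

    # stimulus (clamped) and aspiration update, vectorised
    denom = phi - a
    raw = np.where(denom > 0, (pi - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s = np.clip(raw, -1.0, 1.0)
    new_a = np.where(s >= 0, a + (phi - a) * params.learning_rate * s,
                     a + a * params.learning_rate * s)

    # habituation, then bound against the updated aspiration
    new_d = (1.0 - params.habituation) * state.donations[idx] + params.habituation * pi
    new_d = np.maximum(0.0, np.minimum(new_d, phi - new_a))

    if params.noise_scale > 0:
        eps = rng.normal(0.0, params.noise_scale, size=new_d.shape)
        new_d = np.clip(new_d * (1.0 + eps), 0.0, phi)

    env = state.envious_mask[idx]
    if env.any():
        new_d = np.where(env, np.minimum(new_d, 0.5 * phi), new_d)

    state.aspirations[idx] = new_a
    state.donations[idx] = np.clip(new_d, 0.0, phi)
    state.t += 1
    return state


def window_slope(series: np.ndarray) -> float:
    """OLS slope of a series against its (0-based) index."""
    x = np.arange(series.shape[0], dtype=float)
    return float(np.polyfit(x, series, 1)[0])


def run_to_stationarity(
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
    *,
    transient: int = DEFAULT_TRANSIENT,
    window: int = DEFAULT_WINDOW,
    slope_tol: float = DEFAULT_SLOPE_TOL,
    max_steps: int = DEFAULT_MAX_STEPS,
    initial_state: Optional[PopulationState] = None,
) -> RunResult:
    """Run one replication until the mean donation is stationary.

    After the transient, 1000-step windows are simulated until the
    absolute OLS slope of the population-mean donation over the last
    window falls strictly below ``slope_tol``.  If ``max_steps`` is
    reached first the partial result is returned with
    ``converged=False`` and a warning is logged.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = init_population(params, rng) if initial_state is None else initial_state.copy()

    means: List[float] = []

    def advance(k: int) -> None:
        for _ in range(k):
            step(state, params, rng, inplace=True)
            means.append(state.donations.mean())

    advance(transient)
    converged = False
    while True:
        advance(window)
        slope = window_slope(np.asarray(means[-window:]))
        if abs(slope) < slope_tol:
            converged = True
            break
        if len(means) + window > max_steps:
            logger.warning(
                "run did not reach stationarity within %d steps (last slope %.3g)",
                len(means), slope)
            break

    return RunResult(
        mean_donation_series=np.asarray(means),
        final_aspirations=state.aspirations.copy(),
        final_donations=state.donations.copy(),
        converged_at=len(means),
        converged=converged,
        params=params,
    )


def replication_rng(base_seed: int, *key: int) -> np.random.Generator:
    """Independent generator for one replication.

    Streams are spawned as ``SeedSequence(base_seed, spawn_key=key)``,
    so any (cell, replication) index tuple maps to a reproducible,
    statistically independent stream.
    """
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))


def run_replications(
    params: ModelParams,
    n_reps: int,
    base_seed: int,
    **run_kwargs,
) -> List[RunResult]:
    """Run ``n_reps`` independent replications of one condition.

    Per-replication RNG streams derive deterministically from
    ``base_seed`` and the replication index, so results are bitwise
    reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    results = []
    for rep in range(n_reps):
        rng = replication_rng(base_seed, rep)
        results.append(run_to_stationarity(params, rng, **run_kwargs))
    return results
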