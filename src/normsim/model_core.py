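"""Pure update rules of the aspiration-learning Dictator Game model.

Every function here is stateless and operates elementwise on scalars or
NumPy arrays, so the same code serves both the single-agent reference
path (:func:`recipient_update`) and the vectorised population engine.

The model: each agent carries an aspiration level ``A`` (the share of the
endowment it expects to receive as a recipient) and a donation ``D`` (the
share it gives away when acting as dictator).  After receiving a payoff
``pi`` as recipient, an agent

1. computes a normalised stimulus ``s = (pi - A) / (endowment - A)``,
2. moves its aspiration towards the endowment (positive stimulus) or
   towards zero (negative stimulus) at learning rate ``l``,
3. habituates its donation towards the payoff just received with weight
   ``h``,
4. caps the donation so that the amount kept is never below the new
   aspiration,

optionally followed by multiplicative trembling-hand noise and, for
inequity-averse agents, a hard cap at half the endowment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "AgentValues",
    "compute_stimulus",
    "update_aspiration",
    "update_donation_habituation",
    "apply_aspiration_bound",
    "apply_trembling_hand",
    "apply_envy_cap",
    "recipient_update",
]


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of one simulation condition.

    Parameters
    ----------
    endowment : float
        Size of the pie split in each Dictator Game (money units).
    learning_rate : float
        Weight ``l`` in [0, 1] of the stimulus in the aspiration update.
    habituation : float
        Weight ``h`` in [0, 1] of the received donation in the donation
        update; 0 means agents ignore what they receive, 1 means they
        copy it.
    noise_scale : float
        Standard deviation ``delta`` of the multiplicative trembling-hand
        perturbation; 0 gives the deterministic model.
    envy_probability : float
        Probability that an agent is inequity-averse (donation capped at
        half the endowment).  A persistent trait assigned at
        initialisation, not a per-round coin flip.
    n_free_riders : int
        Number of frozen agents whose donation is fixed at
        ``free_rider_donation`` and who never update.
    free_rider_donation : float
        Donation value of the frozen agents (usually 0).
    n_agents : int
        Population size ``N``; must be even so each step yields a perfect
        matching.
    seed : int or None
        Default RNG seed used when no generator is supplied.
    """

    endowment: float = 1.0
    learning_rate: float = 0.5
    habituation: float = 0.5
    noise_scale: float = 0.0
    envy_probability: float = 0.0
    n_free_riders: int = 0
    free_rider_donation: float = 0.0
    n_agents: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.endowment > 0):
            raise ValueError("endowment must be positive")
        for name in ("learning_rate", "habituation", "envy_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if not (0 <= self.n_free_riders <= self.n_agents):
            raise ValueError("n_free_riders must lie in [0, n_agents]")
        if not (0.0 <= self.free_rider_donation <= self.endowment):
            raise ValueError("free_rider_donation must lie in [0, endowment]")
        if self.n_agents < 2 or self.n_agents % 2:
            raise ValueError("n_agents must be even and >= 2")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class AgentValues:
    """State of a single agent: aspiration, donation and trait flags."""

    aspiration: float
    donation: float
    is_envious: bool = False
    is_frozen: bool = False


def _check_range(name: str, value, lo, hi) -> None:
    arr = np.asarray(value)
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"{name} out of range [{lo}, {hi}]")


def compute_stimulus(payoff, aspiration, endowment: float = 1.0):
    """Normalised mismatch between received payoff and aspiration.

    Returns ``(payoff - aspiration) / (endowment - aspiration)`` where the
    aspiration is below the endowment, and 0 where it equals it.  The raw
    ratio can fall below -1 whenever ``aspiration > endowment / 2`` and
    the payoff is small, so the result is clamped to [-1, 1]: this keeps
    the stimulus on its nominal scale and guarantees the aspiration
    update cannot produce negative aspirations.
    """
    _check_range("payoff", payoff, 0.0, endowment)
    _check_range("aspiration", aspiration, 0.0, endowment)
    payoff = np.asarray(payoff, dtype=float)
    aspiration = np.asarray(aspiration, dtype=float)
    denom = endowment - aspiration
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom > 0, (payoff - aspiration) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(raw, -1.0, 1.0)[()]


def update_aspiration(aspiration, stimulus, learning_rate: float, endowment: float = 1.0):
    """Move the aspiration towards the endowment (s >= 0) or zero (s < 0).

    ``A + (endowment - A) * l * s`` on the non-negative branch and
    ``A + A * l * s`` on the negative branch; with ``s`` and ``l`` in
    range the result always stays in [0, endowment].
    """
    aspiration = np.asarray(aspiration, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    up = aspiration + (endowment - aspiration) * learning_rate * stimulus
    down = aspiration + aspiration * learning_rate * stimulus
    return np.where(stimulus >= 0, up, down)[()]


def update_donation_habituation(donation, payoff, habituation: float):
    """Convex combination ``(1 - h) * D + h * payoff`` of old donation and payoff."""
    donation = np.asarray(donation, dtype=float)
    payoff = np.asarray(payoff, dtype=float)
    return ((1.0 - habituation) * donation + habituation * payoff)[()]


def apply_aspiration_bound(donation, aspiration, endowment: float = 1.0):
    """Cap the donation so the dictator keeps at least her aspiration.

    ``max(0, min(D, endowment - A))``; the input donation may transiently
    exceed the endowment upstream.
    """
    donation = np.asarray(donation, dtype=float)
    aspiration = np.asarray(aspiration, dtype=float)
    return np.maximum(0.0, np.minimum(donation, endowment - aspiration))[()]


def apply_trembling_hand(donation, noise_scale: float, rng: np.random.Generator,
                         endowment: float = 1.0):
    """Multiplicative Gaussian perturbation ``D * (1 + eps)``, eps ~ N(0, delta).

    Models imperfect decision making.  The perturbed donation is clipped
    to [0, endowment]; it may exceed the aspiration bound, which only
    holds in the absence of noise.  ``noise_scale == 0`` returns the
    donation unchanged (no draw is consumed).
    """
    donation = np.asarray(donation, dtype=float)
    if noise_scale == 0:
        return donation[()]
    eps = rng.normal(0.0, noise_scale, size=donation.shape)
    return np.clip(donation * (1.0 + eps), 0.0, endowment)[()]


def apply_envy_cap(donation, endowment: float = 1.0):
    """Inequity-aversion cap: donations never exceed half the pie."""
    return np.minimum(np.asarray(donation, dtype=float), 0.5 * endowment)[()]


def recipient_update(agent: AgentValues, payoff: float, params: ModelParams,
                     rng: Optional[np.random.Generator] = None) -> AgentValues:
    """Full post-game update of a single recipient.

    Only recipients learn: the dictator of a pair is never modified.
    Frozen agents are returned unchanged.  The sub-operations are applied
    in a fixed order: stimulus, aspiration update, donation habituation,
    aspiration bound (against the *new* aspiration), trembling-hand
    noise, envy cap for envious agents, and a final clip to
    [0, endowment].
    """
    if agent.is_frozen:
        return agent
    phi = params.endowment
    _check_range("payoff", payoff, 0.0, phi)
    s = compute_stimulus(payoff, agent.aspiration, phi)
    new_a = float(update_aspiration(agent.aspiration, s, params.learning_rate, phi))
    new_d = float(update_donation_habituation(agent.donation, payoff, params.habituation))
    new_d = float(apply_aspiration_bound(new_d, new_a, phi))
    if params.noise_scale > 0:
        if rng is None:
            raise ValueError("rng required when noise_scale > 0")
        new_d = float(apply_trembling_hand(new_d, params.noise_scale, rng, phi))
    if agent.is_envious:
        new_d = float(apply_envy_cap(new_d, phi))
    new_d = float(np.clip(new_d, 0.0, phi))
    return AgentValues(aspiration=new_a, donation=new_d,
                       is_envious=agent.is_envious, is_frozen=agent.is_frozen)
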