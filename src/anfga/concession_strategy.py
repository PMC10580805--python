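"""Multi-state concession strategy.

Each round a responding agent summarizes the negotiation into four states —
opponent response (sigma), own last-offer satisfaction (rho), tightness
against the current acceptance threshold (delta), and time pressure (tau) —
aggregates them into a concession value, lowers its acceptance threshold
accordingly, and accepts or counters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .fuzzy_preference import (
    ConfigurationError,
    IssueDomain,
    PreferenceProfile,
    _offer_values,
    aggregate_satisfaction,
)

__all__ = [
    "StrategyParams",
    "ConcessionState",
    "Action",
    "STRATEGY_OMEGA",
    "offer_distance",
    "response_state",
    "internal_state",
    "time_pressure",
    "concession_value",
    "update_threshold",
    "decide_action",
]

#: concession exponents bound to the named strategies
STRATEGY_OMEGA = {"competition": 1.2, "collaboration": 0.8, "win_win": 1.0}


class Action(Enum):
    ACCEPT = "Accept"
    OFFER = "Offer"


@dataclass(frozen=True)
class StrategyParams:
    """Concession-strategy knobs.

    lam:    minimum time pressure at round 0 (in [0, 1]).
    beta_t: time concession rate (in (0, 1]); lower = flatter early schedule.
    omega:  concession exponent; >1 concedes slower (competition), <1 faster
            (collaboration).
    """

    lam: float = 0.1
    beta_t: float = 0.25
    omega: float = 1.0
    theta0_rule: str = "max_satisfaction"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigurationError(f"lam must be in [0,1], got {self.lam}")
        if not 0.0 < self.beta_t <= 1.0:
            raise ConfigurationError(f"beta_t must be in (0,1], got {self.beta_t}")
        if self.omega <= 0:
            raise ConfigurationError(f"omega must be > 0, got {self.omega}")

    @classmethod
    def named(cls, strategy: str, lam: float = 0.1, beta_t: float = 0.25) -> "StrategyParams":
        """Build params for one of the named strategies
        (competition / collaboration / win_win)."""
        if strategy not in STRATEGY_OMEGA:
            raise ConfigurationError(
                f"unknown strategy {strategy!r}; choose from {sorted(STRATEGY_OMEGA)}"
            )
        return cls(lam=lam, beta_t=beta_t, omega=STRATEGY_OMEGA[strategy])


@dataclass(frozen=True)
class ConcessionState:
    sigma: float
    rho: float
    delta: float
    tau: float


def offer_distance(A, B, domains: Sequence[IssueDomain]) -> float:
    """RMS of domain-normalized per-issue differences; in [0, 1]."""
    a = _offer_values(A)
    b = _offer_values(B)
    widths = np.array([dom.width for dom in domains], dtype=float)
    if np.any(widths <= 0):
        raise ConfigurationError("zero-width issue domain")
    L = np.abs(a - b) / widths
    return float(math.sqrt(float(np.mean(L * L))))


def response_state(A0, B0, A, B, domains: Sequence[IssueDomain]) -> float:
    """Opponent response state sigma = G(A,B)/G(A0,B0), clamped to [0, 1].

    A0/B0 are the first own offer and first counteroffer; A/B the latest
    pair.  A degenerate opening (G(A0,B0)=0) yields sigma = 0.
    """
    g0 = offer_distance(A0, B0, domains)
    if g0 == 0.0:
        return 0.0
    g = offer_distance(A, B, domains)
    return float(np.clip(g / g0, 0.0, 1.0))


def internal_state(
    profile: PreferenceProfile, last_own_offer, theta_prev: float
) -> tuple[float, float]:
    """(rho, delta): own satisfaction with the last own offer and its
    tightness 1 - (rho - theta_prev) against the threshold in force."""
    rho = aggregate_satisfaction(profile, last_own_offer)
    delta = 1.0 - (rho - theta_prev)
    return rho, delta


def time_pressure(r: int, rmax: int, params: StrategyParams) -> float:
    """tau = lam + (1-lam) * (r/rmax)^(1/beta_t); lam at r=0, 1 at r=rmax."""
    if rmax < 1:
        raise ValueError(f"rmax must be >= 1, got {rmax}")
    if not 0 <= r <= rmax:
        raise ValueError(f"round {r} outside [0, {rmax}]")
    return params.lam + (1.0 - params.lam) * (r / rmax) ** (1.0 / params.beta_t)


def concession_value(state: ConcessionState, params: StrategyParams) -> float:
    """Per-round concession ((1 - (sigma+rho+delta)/3 + tau) / 4) ** omega.

    The base (one minus the mean of the three desire states, plus time
    pressure, over 4) is clamped at 0 before exponentiation.
    """
    base = (1.0 - (state.sigma + state.rho + state.delta) / 3.0 + state.tau) / 4.0
    base = max(base, 0.0)
    return base**params.omega


def update_threshold(theta_prev: float, delta_conc: float) -> float:
    """New acceptance threshold, floored at 0."""
    return max(0.0, theta_prev - delta_conc)


def decide_action(theta_r: float, incoming_satisfaction: float) -> Action:
    """Accept iff the incoming offer's satisfaction meets the threshold."""
    if incoming_satisfaction >= theta_r:
        return Action.ACCEPT
    return Action.OFFER
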