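"""Negotiating agents.

All agents share the same machinery: a private fuzzy preference profile, an
acceptance threshold that is lowered by the concession strategy on every
received offer, and a threshold-constrained candidate offer pool.  They
differ in how the next offer is picked from that pool:

``anfga``          GA opponent model; proposes the candidate the estimated
                   opponent likes best.
``fcan``           no opponent model; proposes the candidate closest (in
                   normalized RMS distance) to the opponent's last offer.
``anf_time``       purely time-dependent threshold schedule, offer selection
                   as ``fcan``.
``complete_info``  like ``anfga`` but scores candidates with the true
                   opponent profile (no GA).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .concession_strategy import (
    Action,
    ConcessionState,
    StrategyParams,
    concession_value,
    decide_action,
    internal_state,
    response_state,
    time_pressure,
    update_threshold,
)
from .fuzzy_preference import (
    ConfigurationError,
    IssueDomain,
    PreferenceProfile,
    _offer_values,
    aggregate_satisfaction,
    satisfaction_matrix,
)
from .ga_opponent_model import (
    ConcessionLedger,
    GAParams,
    OpponentEstimate,
    build_estimate,
    evolve,
)

__all__ = [
    "AGENT_KINDS",
    "DEFAULT_SAMPLE_BUDGET",
    "NegotiationAgent",
    "AnfgaAgent",
    "FcanAgent",
    "TimeAgent",
    "CompleteInfoAgent",
    "candidate_set",
    "own_best_offer",
    "threshold_time",
    "make_agent",
]

DEFAULT_SAMPLE_BUDGET = 5000

AGENT_KINDS = ("anfga", "fcan", "anf_time", "complete_info")


def own_best_offer(
    profile: PreferenceProfile, domains: Sequence[IssueDomain]
) -> np.ndarray:
    """Highest own-satisfaction grid offer; ties broken by the lowest value
    per issue (and hence by lowest issue index)."""
    vals = []
    for mf, dom in zip(profile.memberships, domains):
        grid = dom.grid()
        mus = np.asarray(mf(grid))
        vals.append(grid[int(np.argmax(mus))])  # argmax returns first (lowest) max
    return np.asarray(vals, dtype=float)


def _grid_size(domains: Sequence[IssueDomain]) -> int:
    size = 1
    for dom in domains:
        size *= dom.n_values
        if size > 10**12:
            break
    return size


def candidate_set(
    profile: PreferenceProfile,
    domains: Sequence[IssueDomain],
    theta: float,
    sample_budget: int = DEFAULT_SAMPLE_BUDGET,
    rng: np.random.Generator | None = None,
    anchor=None,
) -> np.ndarray:
    """Grid offers with own satisfaction >= theta, as an (N, n) array.

    Exhaustive scan when the discretized space has at most ``sample_budget``
    points; otherwise ``sample_budget`` seeded uniform grid samples with
    single-issue greedy repair of offers below threshold.  The own-best
    offer is always included, so the result is never empty.

    When an ``anchor`` offer is given (the opponent's last offer), half the
    sampled genes are pinned to its grid-snapped values before repair, so
    the sampled pool contains minimally modified compromise offers.  The
    exhaustive branch ignores the anchor.
    """
    best = own_best_offer(profile, domains)
    if _grid_size(domains) <= sample_budget:
        grids = [dom.grid() for dom in domains]
        mesh = np.meshgrid(*grids, indexing="ij")
        offers = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        if rng is None:
            rng = np.random.default_rng()
        cols = [dom.grid()[rng.integers(dom.n_values, size=sample_budget)]
                for dom in domains]
        offers = np.stack(cols, axis=1)
        if anchor is not None:
            snapped = np.array(
                [dom.grid()[np.argmin(np.abs(dom.grid() - v))]
                 for dom, v in zip(domains, _offer_values(anchor))]
            )
            pin = rng.random(offers.shape) < 0.5
            offers = np.where(pin, snapped[None, :], offers)
        offers = _greedy_repair(profile, offers, best, theta)
    psi = satisfaction_matrix(profile, offers)
    offers = offers[psi >= theta]
    return np.vstack([best[None, :], offers])


def _greedy_repair(
    profile: PreferenceProfile,
    offers: np.ndarray,
    best: np.ndarray,
    theta: float,
) -> np.ndarray:
    """Push sub-threshold offers over theta by swapping, one issue at a
    time, the issue with the largest satisfaction gain to its best value."""
    n = profile.n_issues
    w = profile.weights
    mus = np.stack(
        [np.asarray(mf(offers[:, i])) for i, mf in enumerate(profile.memberships)],
        axis=1,
    )
    best_mus = np.array(
        [float(mf(best[i])) for i, mf in enumerate(profile.memberships)]
    )
    psi = mus @ w
    for _ in range(n):
        failing = psi < theta
        if not failing.any():
            break
        gains = w[None, :] * (best_mus[None, :] - mus[failing])
        pick = np.argmax(gains, axis=1)
        rows = np.nonzero(failing)[0]
        offers[rows, pick] = best[pick]
        mus[rows, pick] = best_mus[pick]
        psi = mus @ w
    return offers


def threshold_time(
    r: int, rmax: int, params: StrategyParams, u_min: float = 0.0
) -> float:
    """Time-only acceptance threshold 1 - (1 - u_min) * tau(r); falls to
    u_min at the deadline."""
    return 1.0 - (1.0 - u_min) * time_pressure(r, rmax, params)


class NegotiationAgent:
    """Base bidder: concession bookkeeping shared by all agent kinds."""

    kind = "base"

    def __init__(
        self,
        role: str,
        profile: PreferenceProfile,
        domains: Sequence[IssueDomain],
        strategy: StrategyParams,
        sample_budget: int = DEFAULT_SAMPLE_BUDGET,
    ) -> None:
        if len(domains) != profile.n_issues:
            raise ConfigurationError("profile/domain issue count mismatch")
        self.role = role
        self.profile = profile
        self.domains = tuple(domains)
        self.strategy = strategy
        self.sample_budget = sample_budget
        self.best = own_best_offer(profile, domains)
        self.theta0 = aggregate_satisfaction(profile, self.best)
        self.reset(rmax=1, rng=np.random.default_rng())

    # -- lifecycle ----------------------------------------------------------

    def reset(self, rmax: int, rng: np.random.Generator) -> None:
        """Prepare for a fresh negotiation with deadline ``rmax``."""
        self.rmax = rmax
        self.rng = rng
        self.theta = self.theta0
        self.own_history: list[np.ndarray] = []
        self.opp_history: list[np.ndarray] = []
        self.pairs: list[tuple[np.ndarray, np.ndarray]] = []
        self.ledger = ConcessionLedger.for_domains(self.domains)
        self.estimate: OpponentEstimate | None = None
        self.thresholds: list[float] = []
        #: (round, best GA fitness) per opponent-model update
        self.ga_fitness_log: list[tuple[int, float]] = []
        self._ga_population = None

    # -- protocol hooks -----------------------------------------------------

    def receive(self, offer, r: int) -> Action:
        """Record the incoming offer, concede, and accept or signal a
        counteroffer."""
        incoming = _offer_values(offer)
        self._update_threshold_on_receive(incoming, r)
        if self.opp_history:
            self.ledger.update(self.opp_history[-1], incoming)
        last_own = self.own_history[-1] if self.own_history else self.best
        self.pairs.append((last_own, incoming))
        self.opp_history.append(incoming)
        self.thresholds.append(self.theta)
        return decide_action(self.theta, aggregate_satisfaction(self.profile, incoming))

    def propose(self, r: int) -> np.ndarray:
        """Produce the round-``r`` offer (first proposal is the own-best)."""
        if not self.own_history:
            offer = self.best.copy()
        else:
            offer = self._select_offer(self._candidates(r), r)
        self.own_history.append(offer)
        return offer

    # -- internals ----------------------------------------------------------

    def _update_threshold_on_receive(self, incoming: np.ndarray, r: int) -> None:
        tau = time_pressure(r, self.rmax, self.strategy)
        last_own = self.own_history[-1] if self.own_history else self.best
        a0 = self.own_history[0] if self.own_history else self.best
        b0 = self.opp_history[0] if self.opp_history else incoming
        sigma = response_state(a0, b0, last_own, incoming, self.domains)
        rho, delta = internal_state(self.profile, last_own, self.theta)
        state = ConcessionState(sigma=sigma, rho=rho, delta=delta, tau=tau)
        self.theta = update_threshold(self.theta, concession_value(state, self.strategy))

    def _candidates(self, r: int) -> np.ndarray:
        anchor = self.opp_history[-1] if self.opp_history else None
        return candidate_set(
            self.profile, self.domains, self._proposal_threshold(r),
            self.sample_budget, self.rng, anchor=anchor,
        )

    def _proposal_threshold(self, r: int) -> float:
        return self.theta

    def _select_offer(self, candidates: np.ndarray, r: int) -> np.ndarray:
        raise NotImplementedError

    def _opponent_distances(
        self, candidates: np.ndarray, issue_weights: np.ndarray | None = None
    ) -> np.ndarray:
        """Squared normalized distance to the opponent's last offer,
        optionally weighted per issue."""
        target = self.opp_history[-1]
        widths = np.array([dom.width for dom in self.domains])
        L = (candidates - target[None, :]) / widths[None, :]
        if issue_weights is None:
            return np.mean(L * L, axis=1)
        return (L * L) @ issue_weights

    def _closest_to_opponent(self, candidates: np.ndarray) -> np.ndarray:
        return candidates[int(np.argmin(self._opponent_distances(candidates)))].copy()

    def _argmax_with_distance_tiebreak(
        self,
        candidates: np.ndarray,
        scores: np.ndarray,
        tol: float = 1e-9,
        issue_weights: np.ndarray | None = None,
    ) -> np.ndarray:
        """Highest-scoring candidate; near-ties (within ``tol``) resolved by
        (optionally issue-weighted) closeness to the opponent's last offer."""
        top = scores >= scores.max() - tol
        if top.sum() > 1 and self.opp_history:
            tied = candidates[top]
            d = self._opponent_distances(tied, issue_weights)
            return tied[int(np.argmin(d))].copy()
        return candidates[int(np.argmax(scores))].copy()


class AnfgaAgent(NegotiationAgent):
    """Full model: GA opponent estimate, offers maximize estimated opponent
    satisfaction (optionally the product with own satisfaction)."""

    kind = "anfga"

    #: estimated satisfactions within this of the maximum count as tied;
    #: the opponent model is too coarse to split finer differences, so ties
    #: go to the candidate nearest the opponent's last offer
    TIE_TOL = 0.05

    def __init__(
        self,
        role,
        profile,
        domains,
        strategy,
        ga_params: GAParams | None = None,
        sample_budget: int = DEFAULT_SAMPLE_BUDGET,
        score: str = "opponent",
    ) -> None:
        super().__init__(role, profile, domains, strategy, sample_budget)
        self.ga_params = ga_params or GAParams()
        if score not in ("opponent", "product"):
            raise ConfigurationError(f"unknown score rule {score!r}")
        self.score = score

    def _select_offer(self, candidates: np.ndarray, r: int) -> np.ndarray:
        # with warm_start the previous round's final population seeds the
        # next GA run instead of a fresh random population
        trace: list[float] = []
        pop = evolve(
            self.profile, self.domains, self.pairs, self.ga_params, rng=self.rng,
            initial_population=self._ga_population if self.ga_params.warm_start else None,
            n_best=self.ga_params.population_size,
            trace=trace,
        )
        self.ga_fitness_log.append((r, trace[-1] if trace else float("nan")))
        if self.ga_params.warm_start:
            self._ga_population = pop
        elites = pop[: max(1, self.ga_params.elite_count)]
        self.estimate = build_estimate(elites, self.ledger)
        scores = self.estimate.satisfaction_many(candidates)
        if self.score == "product":
            scores = scores * satisfaction_matrix(self.profile, candidates)
        return self._argmax_with_distance_tiebreak(
            candidates, scores, self.TIE_TOL, self.estimate.refined_weights
        )


class FcanAgent(NegotiationAgent):
    """Same concession strategy, no opponent model: proposes the candidate
    nearest the opponent's last offer."""

    kind = "fcan"

    def _select_offer(self, candidates: np.ndarray, r: int) -> np.ndarray:
        return self._closest_to_opponent(candidates)


class TimeAgent(NegotiationAgent):
    """Time-dependent threshold schedule; otherwise like ``fcan``."""

    kind = "anf_time"

    def __init__(
        self,
        role,
        profile,
        domains,
        strategy,
        u_min: float = 0.0,
        sample_budget: int = DEFAULT_SAMPLE_BUDGET,
    ) -> None:
        super().__init__(role, profile, domains, strategy, sample_budget)
        self.u_min = u_min

    def _update_threshold_on_receive(self, incoming: np.ndarray, r: int) -> None:
        self.theta = min(
            self.theta, threshold_time(r, self.rmax, self.strategy, self.u_min)
        )

    def _proposal_threshold(self, r: int) -> float:
        return min(self.theta, threshold_time(r, self.rmax, self.strategy, self.u_min))

    def _select_offer(self, candidates: np.ndarray, r: int) -> np.ndarray:
        return self._closest_to_opponent(candidates)


class CompleteInfoAgent(NegotiationAgent):
    """Oracle bidder: sees the true opponent profile, no GA."""

    kind = "complete_info"

    def __init__(
        self,
        role,
        profile,
        domains,
        strategy,
        opponent_profile: PreferenceProfile,
        sample_budget: int = DEFAULT_SAMPLE_BUDGET,
    ) -> None:
        super().__init__(role, profile, domains, strategy, sample_budget)
        self.opponent_profile = opponent_profile

    def _select_offer(self, candidates: np.ndarray, r: int) -> np.ndarray:
        scores = satisfaction_matrix(self.opponent_profile, candidates)
        return self._argmax_with_distance_tiebreak(candidates, scores)


def make_agent(
    kind: str,
    role: str,
    profile: PreferenceProfile,
    domains: Sequence[IssueDomain],
    strategy: StrategyParams,
    ga_params: GAParams | None = None,
    opponent_profile: PreferenceProfile | None = None,
    u_min: float = 0.0,
    sample_budget: int = DEFAULT_SAMPLE_BUDGET,
) -> NegotiationAgent:
    """Factory over the four agent kinds."""
    if kind == "anfga":
        return AnfgaAgent(role, profile, domains, strategy, ga_params, sample_budget)
    if kind == "fcan":
        return FcanAgent(role, profile, domains, strategy, sample_budget)
    if kind == "anf_time":
        return TimeAgent(role, profile, domains, strategy, u_min, sample_budget)
    if kind == "complete_info":
        if opponent_profile is None:
            raise ConfigurationError("complete_info agent needs the opponent profile")
        return CompleteInfoAgent(
            role, profile, domains, strategy, opponent_profile, sample_budget
        )
    raise ConfigurationError(f"unknown agent kind {kind!r}; choose from {AGENT_KINDS}")
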