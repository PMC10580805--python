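"""Genetic-algorithm opponent preference learner.

From the exchanged offer history the agent evolves a population of candidate
opponent profiles (free genes: per-issue weight and plateau breakpoints b, c;
support bounds a, d are pinned to the agent's own and the plateau height to
1).  The best individual's weights are averaged with weights inferred from
the opponent's per-issue concession behaviour to give the refined estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fuzzy_preference import (
    ConfigurationError,
    IssueDomain,
    PreferenceProfile,
    TrapezoidMembership,
    _offer_values,
    aggregate_satisfaction,
)

__all__ = [
    "GAParams",
    "CandidateProfile",
    "OpponentEstimate",
    "ConcessionLedger",
    "init_population",
    "fitness",
    "population_fitness",
    "select",
    "crossover",
    "mutate",
    "evolve",
    "concession_weights",
    "refine_weights",
]


@dataclass(frozen=True)
class GAParams:
    population_size: int = 100
    max_iteration: int = 50
    mutation_rate: float = 0.5
    elite_rate: float = 0.1
    #: probability a crossover parent is drawn uniformly from the whole
    #: population instead of from the roulette-selected pool
    potential_stock_rate: float = 0.1
    #: "single_issue": one issue's (w,b,c) redrawn per mutated child;
    #: "per_gene": each issue redrawn independently with mutation_rate
    mutation_mode: str = "single_issue"
    warm_start: bool = False
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.max_iteration < 1:
            raise ConfigurationError("max_iteration must be >= 1")
        for name in ("mutation_rate", "elite_rate", "potential_stock_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.elite_count >= self.population_size:
            raise ConfigurationError("elite count must be < population size")
        if self.mutation_mode not in ("single_issue", "per_gene"):
            raise ConfigurationError(f"unknown mutation_mode {self.mutation_mode!r}")

    @property
    def elite_count(self) -> int:
        return int(round(self.elite_rate * self.population_size))


@dataclass
class CandidateProfile:
    """One GA individual: a hypothesized opponent preference profile.

    ``a``/``d`` are fixed (copied from the learning agent); free genes are
    the weights and the plateau bounds ``b``, ``c``; plateau height is 1.
    """

    weights: np.ndarray
    b: np.ndarray
    c: np.ndarray
    a: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (
            np.all(self.a <= self.b + 1e-12)
            and np.all(self.b <= self.c + 1e-12)
            and np.all(self.c <= self.d + 1e-12)
        ):
            raise ConfigurationError("candidate breakpoints must satisfy a<=b<=c<=d")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ConfigurationError("candidate weights must be non-negative and sum to 1")

    @property
    def n_issues(self) -> int:
        return self.weights.size

    def to_profile(self) -> PreferenceProfile:
        mfs = [
            TrapezoidMembership(float(a), float(b), float(c), float(d), 1.0)
            for a, b, c, d in zip(self.a, self.b, self.c, self.d)
        ]
        return PreferenceProfile(self.weights, mfs)

    def satisfaction(self, offer) -> float:
        return aggregate_satisfaction(self.to_profile(), offer)

    def copy(self) -> "CandidateProfile":
        return CandidateProfile(
            self.weights.copy(), self.b.copy(), self.c.copy(), self.a, self.d
        )


@dataclass
class ConcessionLedger:
    """Accumulated per-issue movement of the opponent's counteroffers."""

    widths: np.ndarray
    steps: np.ndarray
    c: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        self.steps = np.asarray(self.steps, dtype=float)
        if self.c is None:
            self.c = np.zeros_like(self.widths)
        else:
            self.c = np.asarray(self.c, dtype=float)

    @classmethod
    def for_domains(cls, domains: Sequence[IssueDomain]) -> "ConcessionLedger":
        return cls(
            widths=np.array([dom.width for dom in domains]),
            steps=np.array([dom.step for dom in domains]),
        )

    def update(self, prev_offer, new_offer) -> None:
        """Add the per-issue absolute movement between consecutive
        counteroffers (call once per received counteroffer from the 2nd on)."""
        self.c += np.abs(_offer_values(new_offer) - _offer_values(prev_offer))

    @property
    def n_issues(self) -> int:
        return self.widths.size


@dataclass(frozen=True)
class OpponentEstimate:
    """GA-learned opponent model plus refined weights.

    ``members`` holds the elite individuals of the final generation; the
    estimated satisfaction of an offer is averaged over them (with each
    member's issue weights rescaled by ``refined_weights``), which damps the
    run-to-run wobble of any single individual.
    """

    ga_profile: CandidateProfile
    ga_weights: np.ndarray
    concession_weights: np.ndarray
    refined_weights: np.ndarray
    members: tuple[CandidateProfile, ...] = ()

    def _ensemble_arrays(self):
        pool = self.members if self.members else (self.ga_profile,)
        B = np.stack([m.b for m in pool])
        C = np.stack([m.c for m in pool])
        return B, C, pool[0].a, pool[0].d

    def satisfaction(self, offer) -> float:
        """Estimated opponent utility of one offer."""
        return float(self.satisfaction_many(_offer_values(offer)[None, :])[0])

    def satisfaction_many(self, offers: np.ndarray) -> np.ndarray:
        offers = np.asarray(offers, dtype=float)
        B, C, a, d = self._ensemble_arrays()
        # (k, N, n) membership for every ensemble member
        mus = _membership_matrix(offers[None, :, :], B[:, None, :], C[:, None, :], a, d)
        return mus.mean(axis=0) @ self.refined_weights


# ---------------------------------------------------------------------------
# vectorized membership evaluation for populations


def _membership_matrix(x, b, c, a, d):
    """Trapezoid membership (beta=1) broadcast over populations.

    x: (..., n) values; b, c: broadcastable to x; a, d: (n,).
    """
    left_den = np.where(b == a, 1.0, b - a)
    right_den = np.where(c == d, 1.0, c - d)
    left = 1.0 - ((x - b) / left_den) ** 2
    right = 1.0 - ((x - c) / right_den) ** 2
    mu = np.where(
        (x >= b) & (x <= c),
        1.0,
        np.where((x <= a) | (x >= d), 0.0, np.where(x < b, left, right)),
    )
    return mu


#: observations are censored into the candidates' support before fitness
#: evaluation: a counteroffer value beyond the fixed [a, d] range is scored
#: at the nearest representable point (small interior margin so edge
#: plateaus can match it).  Without this, issues the opponent holds outside
#: the learner's range always score zero and weight genes are pushed off
#: exactly the issues the opponent cares about most.
CENSOR_MARGIN = 0.02


def _history_arrays(own_profile: PreferenceProfile, history):
    own_psi = np.array([aggregate_satisfaction(own_profile, A) for A, _ in history])
    opp_offers = np.stack([_offer_values(B) for _, B in history])
    return own_psi, opp_offers


def _censor(opp: np.ndarray, a: np.ndarray, d: np.ndarray) -> np.ndarray:
    m = CENSOR_MARGIN * (d - a)
    return np.clip(opp, a + m, d - m)


def population_fitness(
    population: Sequence[CandidateProfile],
    own_profile: PreferenceProfile,
    history: Sequence[tuple],
) -> np.ndarray:
    """Fitness of every individual at once (see :func:`fitness`)."""
    if len(history) == 0:
        raise ValueError("fitness requires a non-empty offer history")
    own_psi, opp = _history_arrays(own_profile, history)
    W = np.stack([ind.weights for ind in population])  # (m, n)
    B = np.stack([ind.b for ind in population])
    C = np.stack([ind.c for ind in population])
    a = population[0].a
    d = population[0].d
    opp = _censor(opp, a, d)
    # (m, R, n): candidate membership of each historical counteroffer
    mu = _membership_matrix(opp[None, :, :], B[:, None, :], C[:, None, :], a, d)
    psi_cand = np.einsum("mn,mrn->mr", W, mu)
    return psi_cand @ own_psi / len(history)


def fitness(
    candidate: CandidateProfile,
    own_profile: PreferenceProfile,
    history: Sequence[tuple],
) -> float:
    """Mean over rounds of (own satisfaction of own offer) x (candidate's
    satisfaction of the opponent's offer); in [0, 1] for unit plateaus.

    Counteroffer values outside the candidates' fixed [a, d] range are
    censored to the nearest interior point (see ``CENSOR_MARGIN``).
    """
    return float(population_fitness([candidate], own_profile, history)[0])


# ---------------------------------------------------------------------------
# GA operators


def _random_individual(
    a: np.ndarray, d: np.ndarray, rng: np.random.Generator
) -> CandidateProfile:
    n = a.size
    w = rng.uniform(0.0, 1.0, size=n)
    total = w.sum()
    w = w / total if total > 0 else np.full(n, 1.0 / n)
    bc = np.sort(rng.uniform(a, d, size=(2, n)), axis=0)
    return CandidateProfile(w, bc[0], bc[1], a, d)


def init_population(
    own_profile: PreferenceProfile,
    domains: Sequence[IssueDomain],
    params: GAParams,
    rng: np.random.Generator,
) -> list[CandidateProfile]:
    """m random candidates; b, c uniform within the agent's own [a, d]."""
    a = np.array([mf.a for mf in own_profile.memberships])
    d = np.array([mf.d for mf in own_profile.memberships])
    return [_random_individual(a, d, rng) for _ in range(params.population_size)]


def select(
    population: Sequence[CandidateProfile],
    fitnesses: np.ndarray,
    params: GAParams,
    rng: np.random.Generator,
) -> list[CandidateProfile]:
    """Elite retention + roulette: the e fittest pass unchanged, the other
    m-e slots are fitness-proportional draws with replacement."""
    f = np.asarray(fitnesses, dtype=float)
    m = len(population)
    e = params.elite_count
    order = np.argsort(-f, kind="stable")
    elites = [population[i] for i in order[:e]]
    total = f.sum()
    if total <= 0:
        p = np.full(m, 1.0 / m)
    else:
        p = f / total
    drawn = rng.choice(m, size=m - e, replace=True, p=p)
    return elites + [population[i] for i in drawn]


def crossover(
    p1: CandidateProfile, p2: CandidateProfile, rng: np.random.Generator
) -> CandidateProfile:
    """Child from two parents: with prob 1/2 each issue's (w, b, c) triple is
    copied whole from either parent; otherwise genes are averaged."""
    n = p1.n_issues
    if rng.random() < 0.5:  # rule (a): per-issue copy
        take_p1 = rng.random(n) < 0.5
        w = np.where(take_p1, p1.weights, p2.weights)
        b = np.where(take_p1, p1.b, p2.b)
        c = np.where(take_p1, p1.c, p2.c)
    else:  # rule (b): arithmetic mean
        w = 0.5 * (p1.weights + p2.weights)
        b = 0.5 * (p1.b + p2.b)
        c = 0.5 * (p1.c + p2.c)
    total = w.sum()
    w = w / total if total > 0 else np.full(n, 1.0 / n)
    lo = np.minimum(b, c)
    hi = np.maximum(b, c)
    b = np.clip(lo, p1.a, p1.d)
    c = np.clip(hi, p1.a, p1.d)
    return CandidateProfile(w, b, c, p1.a, p1.d)


def mutate(
    child: CandidateProfile, params: GAParams, rng: np.random.Generator
) -> CandidateProfile:
    """Random-redraw mutation; invariants restored afterwards."""
    n = child.n_issues
    if params.mutation_mode == "per_gene":
        mask = rng.random(n) < params.mutation_rate
        if not mask.any():
            return child
        idx = np.nonzero(mask)[0]
    else:
        if rng.random() >= params.mutation_rate:
            return child
        idx = np.array([rng.integers(n)])
    w = child.weights.copy()
    b = child.b.copy()
    c = child.c.copy()
    for i in idx:
        w[i] = rng.uniform(0.0, 1.0)
        lo, hi = sorted(rng.uniform(child.a[i], child.d[i], size=2))
        b[i], c[i] = lo, hi
    total = w.sum()
    w = w / total if total > 0 else np.full(n, 1.0 / n)
    return CandidateProfile(w, b, c, child.a, child.d)


def _fitness_arrays(W, B, C, a, d, own_psi, opp) -> np.ndarray:
    mu = _membership_matrix(opp[None, :, :], B[:, None, :], C[:, None, :], a, d)
    psi_cand = np.einsum("mn,mrn->mr", W, mu)
    return psi_cand @ own_psi / own_psi.size


def _renormalize_rows(W: np.ndarray) -> np.ndarray:
    totals = W.sum(axis=1, keepdims=True)
    n = W.shape[1]
    return np.where(totals > 0, W / np.where(totals == 0, 1.0, totals), 1.0 / n)


def evolve(
    own_profile: PreferenceProfile,
    domains: Sequence[IssueDomain],
    history: Sequence[tuple],
    params: GAParams,
    rng: np.random.Generator | None = None,
    initial_population: Sequence[CandidateProfile] | None = None,
    trace: list | None = None,
    n_best: int = 1,
) -> CandidateProfile | list[CandidateProfile]:
    """Run the full GA and return the best individual of the final
    generation (or, with ``n_best > 1``, the top individuals as a list).

    If ``trace`` is a list, the best fitness of every generation is appended
    to it (non-decreasing under elitism).

    Each generation: elite+roulette selection, crossover of parents drawn
    from the selected pool (with a small chance of drawing a "potential
    stock" parent uniformly from the whole population), then mutation.
    Elites are carried unchanged, so best fitness never decreases.

    The generation loop operates on stacked gene arrays for speed; the
    operators match :func:`select`, :func:`crossover`, and :func:`mutate`.
    """
    if len(history) == 0:
        raise ValueError("evolve requires a non-empty offer history")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if initial_population is not None:
        population = list(initial_population)
    else:
        population = init_population(own_profile, domains, params, rng)
    m = params.population_size
    e = params.elite_count
    n = population[0].n_issues
    a = population[0].a
    d = population[0].d
    W = np.stack([ind.weights for ind in population])
    B = np.stack([ind.b for ind in population])
    C = np.stack([ind.c for ind in population])
    own_psi, opp = _history_arrays(own_profile, history)
    opp = _censor(opp, a, d)

    for _ in range(params.max_iteration):
        f = _fitness_arrays(W, B, C, a, d, own_psi, opp)
        if trace is not None:
            trace.append(float(f.max()))
        order = np.argsort(-f, kind="stable")
        elite_idx = order[:e]
        total = f.sum()
        p = f / total if total > 0 else np.full(m, 1.0 / m)
        pool_idx = np.concatenate(
            [elite_idx, rng.choice(m, size=m - e, replace=True, p=p)]
        )
        # parents: from the selected pool, or (potential stocks) uniformly
        # from the whole population
        k = m - e
        par = pool_idx[rng.integers(m, size=(k, 2))]
        stock = rng.random((k, 2)) < params.potential_stock_rate
        par = np.where(stock, rng.integers(m, size=(k, 2)), par)
        p1w, p2w = W[par[:, 0]], W[par[:, 1]]
        p1b, p2b = B[par[:, 0]], B[par[:, 1]]
        p1c, p2c = C[par[:, 0]], C[par[:, 1]]
        rule_a = (rng.random(k) < 0.5)[:, None]
        take1 = rng.random((k, n)) < 0.5
        cw = np.where(rule_a, np.where(take1, p1w, p2w), 0.5 * (p1w + p2w))
        cb = np.where(rule_a, np.where(take1, p1b, p2b), 0.5 * (p1b + p2b))
        cc = np.where(rule_a, np.where(take1, p1c, p2c), 0.5 * (p1c + p2c))
        lo = np.clip(np.minimum(cb, cc), a, d)
        hi = np.clip(np.maximum(cb, cc), a, d)
        cb, cc = lo, hi
        # mutation
        if params.mutation_mode == "per_gene":
            mmask = rng.random((k, n)) < params.mutation_rate
        else:
            hit = rng.random(k) < params.mutation_rate
            issue = rng.integers(n, size=k)
            mmask = np.zeros((k, n), dtype=bool)
            mmask[np.arange(k), issue] = hit
        if mmask.any():
            rw = rng.uniform(size=(k, n))
            r1 = rng.uniform(a, d, size=(k, n))
            r2 = rng.uniform(a, d, size=(k, n))
            rb, rc = np.minimum(r1, r2), np.maximum(r1, r2)
            cw = np.where(mmask, rw, cw)
            cb = np.where(mmask, rb, cb)
            cc = np.where(mmask, rc, cc)
        cw = _renormalize_rows(cw)
        W = np.vstack([W[elite_idx], cw])
        B = np.vstack([B[elite_idx], cb])
        C = np.vstack([C[elite_idx], cc])

    f = _fitness_arrays(W, B, C, a, d, own_psi, opp)
    if n_best <= 1:
        i = int(np.argmax(f))
        return CandidateProfile(W[i].copy(), B[i].copy(), C[i].copy(), a, d)
    top = np.argsort(-f, kind="stable")[:n_best]
    return [
        CandidateProfile(W[i].copy(), B[i].copy(), C[i].copy(), a, d) for i in top
    ]


# ---------------------------------------------------------------------------
# weight refinement


def concession_weights(ledger: ConcessionLedger) -> np.ndarray:
    """Weights inversely proportional to accumulated concession times domain
    width; zero concessions are floored at the issue's grid step."""
    c = np.maximum(ledger.c, ledger.steps)
    raw = 1.0 / (c * ledger.widths)
    return raw / raw.sum()


def refine_weights(w_g: np.ndarray, w_c: np.ndarray) -> np.ndarray:
    """Element-wise mean of GA weights and concession weights."""
    w_g = np.asarray(w_g, dtype=float)
    w_c = np.asarray(w_c, dtype=float)
    if w_g.shape != w_c.shape:
        raise ValueError("weight vectors must have the same length")
    return 0.5 * (w_g + w_c)


def build_estimate(
    best: CandidateProfile | Sequence[CandidateProfile],
    ledger: ConcessionLedger,
) -> OpponentEstimate:
    """Assemble the refined opponent estimate from the GA winner(s) and the
    concession ledger.

    With several winners (the final elites) the GA weight vector is their
    mean, which is far less noisy than any single individual's weights.
    """
    members = (best,) if isinstance(best, CandidateProfile) else tuple(best)
    w_g = np.mean([m.weights for m in members], axis=0)
    w_g = w_g / w_g.sum()
    w_c = concession_weights(ledger)
    w = refine_weights(w_g, w_c)
    return OpponentEstimate(
        ga_profile=members[0],
        ga_weights=w_g,
        concession_weights=w_c,
        refined_weights=w,
        members=members,
    )
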