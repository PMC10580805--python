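"""Issues, offers, and fuzzy preference profiles.

A negotiable attribute ("issue") takes values on a discretized numeric
interval.  A party's satisfaction with a value is a trapezoid membership
curve with quadratic shoulders; per-issue satisfactions are combined into
a single utility by a weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IssueDomain",
    "TrapezoidMembership",
    "PreferenceProfile",
    "Offer",
    "eval_membership",
    "trapezoid_mu",
    "aggregate_satisfaction",
    "satisfaction_matrix",
]

#: tolerance on weight normalization checks
WEIGHT_ATOL = 1e-9
#: constructors renormalize weight vectors whose sum is within this of 1
WEIGHT_RENORM_ATOL = 1e-6


class ConfigurationError(ValueError):
    """Raised when a domain, membership, or profile violates its invariants."""


@dataclass(frozen=True)
class IssueDomain:
    """One negotiable attribute with a finite discretized value set.

    Parameters
    ----------
    name:
        Issue label.
    lo, hi:
        Interval bounds, ``lo < hi``.
    step:
        Grid resolution; the finite value set is ``lo, lo+step, ...``
        (``floor((hi-lo)/step)+1`` points). Defaults to ``(hi-lo)/100``.
    """

    name: str
    lo: float
    hi: float
    step: float | None = None

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError(f"{self.name}: require lo < hi, got [{self.lo}, {self.hi}]")
        if self.step is None:
            object.__setattr__(self, "step", (self.hi - self.lo) / 100.0)
        if self.step <= 0:
            raise ConfigurationError(f"{self.name}: step must be > 0")
        if self.n_values < 2:
            raise ConfigurationError(f"{self.name}: step too coarse, fewer than 2 values")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def n_values(self) -> int:
        return int(np.floor((self.hi - self.lo) / self.step + 1e-9)) + 1

    def grid(self) -> np.ndarray:
        """The finite value set as an array of length ``n_values``."""
        return self.lo + self.step * np.arange(self.n_values)

    def contains(self, x: float) -> bool:
        return self.lo - 1e-12 <= x <= self.hi + 1e-12


@dataclass(frozen=True)
class TrapezoidMembership:
    """Trapezoid satisfaction curve: zero outside ``[a, d]``, plateau
    ``beta`` on ``[b, c]``, quadratic shoulders in between."""

    a: float
    b: float
    c: float
    d: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"breakpoints must be ordered a<=b<=c<=d, got {(self.a, self.b, self.c, self.d)}"
            )
        if not (0.0 < self.beta <= 1.0):
            raise ConfigurationError(f"beta must be in (0, 1], got {self.beta}")

    def __call__(self, x) -> float | np.ndarray:
        return trapezoid_mu(x, self.a, self.b, self.c, self.d, self.beta)


def trapezoid_mu(x, a: float, b: float, c: float, d: float, beta: float = 1.0):
    """Vectorized trapezoid membership.

    ``beta`` on [b, c]; 0 for x <= a or x >= d (plateau takes precedence at
    degenerate shared points); quadratic shoulders
    ``beta*(1 - ((x-b)/(b-a))**2)`` on (a, b) and
    ``beta*(1 - ((x-c)/(c-d))**2)`` on (c, d).
    """
    x = np.asarray(x, dtype=float)
    left_den = b - a if b != a else 1.0
    right_den = c - d if c != d else 1.0
    left = beta * (1.0 - ((x - b) / left_den) ** 2)
    right = beta * (1.0 - ((x - c) / right_den) ** 2)
    out = np.select(
        [(x >= b) & (x <= c), (x <= a) | (x >= d), x < b],
        [beta, 0.0, left],
        default=right,
    )
    if out.ndim == 0:
        return float(out)
    return out


def eval_membership(mf: TrapezoidMembership, x: float) -> float:
    """Satisfaction of value ``x`` under the trapezoid ``mf`` (in [0, beta])."""
    return float(trapezoid_mu(x, mf.a, mf.b, mf.c, mf.d, mf.beta))


def _normalize_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ConfigurationError("weights must be a non-empty 1-d sequence")
    if np.any(w < 0):
        raise ConfigurationError("weights must be non-negative")
    total = float(w.sum())
    if abs(total - 1.0) > WEIGHT_RENORM_ATOL:
        raise ConfigurationError(f"weights must sum to 1 (got {total})")
    return w / total


@dataclass(frozen=True)
class PreferenceProfile:
    """Per-issue weights and trapezoid memberships; a party's private utility.

    Weights are renormalized on construction (must already sum to 1 within
    1e-6) and afterwards sum to 1 within 1e-9.
    """

    weights: np.ndarray
    memberships: tuple[TrapezoidMembership, ...]

    def __init__(
        self,
        weights: Sequence[float],
        memberships: Iterable[TrapezoidMembership],
    ) -> None:
        w = _normalize_weights(weights)
        mfs = tuple(memberships)
        if len(mfs) != w.size:
            raise ConfigurationError(
                f"{w.size} weights but {len(mfs)} membership functions"
            )
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "memberships", mfs)
        w.setflags(write=False)

    @property
    def n_issues(self) -> int:
        return len(self.memberships)

    def __len__(self) -> int:
        return self.n_issues


@dataclass(frozen=True)
class Offer:
    """One candidate plan: a crisp value per issue (fixed issue order)."""

    values: tuple[float, ...]

    def __init__(self, values: Sequence[float]) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, i: int) -> float:
        return self.values[i]


def _offer_values(offer) -> np.ndarray:
    if isinstance(offer, Offer):
        return offer.as_array()
    return np.asarray(offer, dtype=float)


def aggregate_satisfaction(profile: PreferenceProfile, offer) -> float:
    """Weighted-sum utility ``sum_i w_i * mu_i(v_i)`` of an offer.

    With all plateau heights at 1 the result lies in [0, 1].
    """
    v = _offer_values(offer)
    if v.shape != (profile.n_issues,):
        raise ValueError(
            f"offer has {v.size} values for a {profile.n_issues}-issue profile"
        )
    mus = np.array([mf(x) for mf, x in zip(profile.memberships, v)])
    return float(profile.weights @ mus)


def satisfaction_matrix(profile: PreferenceProfile, offers: np.ndarray) -> np.ndarray:
    """Utilities of many offers at once.

    Parameters
    ----------
    offers:
        Array of shape ``(N, n_issues)``.

    Returns
    -------
    Array of shape ``(N,)``.
    """
    offers = np.asarray(offers, dtype=float)
    if offers.ndim != 2 or offers.shape[1] != profile.n_issues:
        raise ValueError("offers must have shape (N, n_issues)")
    psi = np.zeros(offers.shape[0])
    for i, mf in enumerate(profile.memberships):
        psi += profile.weights[i] * np.asarray(mf(offers[:, i]))
    return psi
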