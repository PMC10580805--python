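"""Alternating-offers protocol runner and outcome metrics.

One *round* is a single offer by one side.  The proposer of round ``r``
sends an offer; the receiver updates its states and threshold, then accepts
(agreement at round ``r``) or becomes the proposer of round ``r+1``.  If
round ``rmax`` ends without acceptance the negotiation fails.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .agents import NegotiationAgent
from .concession_strategy import Action
from .fuzzy_preference import ConfigurationError, aggregate_satisfaction

__all__ = [
    "RoundRecord",
    "Transcript",
    "MetricsReport",
    "run_negotiation",
    "compute_metrics",
]


@dataclass(frozen=True)
class RoundRecord:
    round: int
    proposer: str
    offer: tuple[float, ...]
    responder_threshold: float
    action: str


@dataclass
class Transcript:
    """Full history of one negotiation."""

    scenario_id: str
    first_mover: str
    rmax: int
    rounds: list[RoundRecord] = field(default_factory=list)
    outcome: str = "Failure"
    agreement: tuple[float, ...] | None = None
    psi_pa: float | None = None
    psi_da: float | None = None

    @property
    def succeeded(self) -> bool:
        return self.outcome == "Agreement"

    @property
    def final_round(self) -> int:
        return self.rounds[-1].round if self.rounds else 0

    @property
    def joint_satisfaction(self) -> float | None:
        if not self.succeeded:
            return None
        return self.psi_pa + self.psi_da

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class MetricsReport:
    """Batch outcome summary: counts, joint satisfaction, rounds, success
    rate."""

    t_all: int
    t_suc: int
    ajs: float
    anr: float
    nsr: float

    def to_dict(self) -> dict:
        return asdict(self)


def run_negotiation(
    scenario,
    agent_pa: NegotiationAgent,
    agent_da: NegotiationAgent,
    rmax: int,
    first_mover: str = "PA",
    seed: int | np.random.SeedSequence | None = None,
) -> Transcript:
    """Run one alternating-offers negotiation to agreement or deadline.

    A master seed derives independent substreams for the two agents, so runs
    are fully reproducible.
    """
    if rmax < 1:
        raise ConfigurationError(f"rmax must be >= 1, got {rmax}")
    if first_mover not in ("PA", "DA"):
        raise ConfigurationError(f"first_mover must be PA or DA, got {first_mover!r}")
    scenario.validate()

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pa, s_da = ss.spawn(2)
    agent_pa.reset(rmax, np.random.default_rng(s_pa))
    agent_da.reset(rmax, np.random.default_rng(s_da))

    proposer, receiver = (
        (agent_pa, agent_da) if first_mover == "PA" else (agent_da, agent_pa)
    )
    transcript = Transcript(
        scenario_id=scenario.label or "unnamed",
        first_mover=first_mover,
        rmax=rmax,
    )
    for r in range(1, rmax + 1):
        offer = proposer.propose(r)
        action = receiver.receive(offer, r)
        transcript.rounds.append(
            RoundRecord(
                round=r,
                proposer=proposer.role,
                offer=tuple(float(v) for v in offer),
                responder_threshold=receiver.theta,
                action=action.value,
            )
        )
        if action is Action.ACCEPT:
            transcript.outcome = "Agreement"
            transcript.agreement = tuple(float(v) for v in offer)
            transcript.psi_pa = aggregate_satisfaction(agent_pa.profile, offer)
            transcript.psi_da = aggregate_satisfaction(agent_da.profile, offer)
            break
        proposer, receiver = receiver, proposer
    return transcript


def compute_metrics(transcripts: Sequence[Transcript]) -> MetricsReport:
    """AJS / ANR / NSR over a batch.

    With zero successes AJS is reported as 0 and ANR as the deadline.
    """
    if len(transcripts) == 0:
        raise ValueError("compute_metrics requires at least one transcript")
    successes = [t for t in transcripts if t.succeeded]
    t_all = len(transcripts)
    t_suc = len(successes)
    if t_suc == 0:
        ajs = 0.0
        anr = float(max(t.rmax for t in transcripts))
    else:
        ajs = float(np.mean([t.joint_satisfaction for t in successes]))
        anr = float(np.mean([t.final_round for t in successes]))
    return MetricsReport(t_all=t_all, t_suc=t_suc, ajs=ajs, anr=anr, nsr=t_suc / t_all)
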