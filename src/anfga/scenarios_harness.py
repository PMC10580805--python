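"""Scenario fixtures, synthetic scenario generation, and experiment sweeps.

A scenario bundles the ordered issue domains with the two parties' private
preference profiles.  The printed five-issue doctor/patient example ships as
``table2_fixture``; ``sample_scenario`` draws questionnaire-style synthetic
scenarios with controllable overlap between the parties' plateaus; and
``run_sweep`` reproduces the deadline / issue-count / information
experiments at a configurable batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .agents import DEFAULT_SAMPLE_BUDGET, make_agent
from .concession_strategy import STRATEGY_OMEGA, StrategyParams
from .fuzzy_preference import (
    ConfigurationError,
    IssueDomain,
    PreferenceProfile,
    TrapezoidMembership,
)
from .ga_opponent_model import GAParams
from .negotiation_engine import Transcript, compute_metrics, run_negotiation

__all__ = [
    "Scenario",
    "GeneratorConfig",
    "SweepConfig",
    "table2_fixture",
    "sample_scenario",
    "load_scenario",
    "save_scenario",
    "parse_roster_entry",
    "build_agents",
    "run_batch",
    "run_sweep",
]


class GenerationError(RuntimeError):
    """Raised when a synthetic scenario cannot be placed feasibly."""


@dataclass(frozen=True)
class Scenario:
    """Ordered issue domains plus the PA and DA preference profiles."""

    domains: tuple[IssueDomain, ...]
    pa: PreferenceProfile
    da: PreferenceProfile
    label: str = ""

    def validate(self) -> None:
        n = len(self.domains)
        for name, prof in (("PA", self.pa), ("DA", self.da)):
            if prof.n_issues != n:
                raise ConfigurationError(f"{name} profile has {prof.n_issues} issues, expected {n}")
            for mf, dom in zip(prof.memberships, self.domains):
                if not (dom.contains(mf.a) and dom.contains(mf.d)):
                    raise ConfigurationError(
                        f"{name} membership [{mf.a}, {mf.d}] outside domain "
                        f"{dom.name} [{dom.lo}, {dom.hi}]"
                    )

    @property
    def n_issues(self) -> int:
        return len(self.domains)

    def profile(self, role: str) -> PreferenceProfile:
        return self.pa if role == "PA" else self.da


def table2_fixture() -> Scenario:
    """The printed five-issue doctor/patient preference scenario.

    Cost in thousand RMB on [0, 8]; effectiveness and convenience as 1-10
    ranks; side-effects and risk as probabilities on [0, 1].  All plateau
    heights are 1.
    """
    domains = (
        IssueDomain("Cost", 0.0, 8.0, 0.08),
        IssueDomain("Effective", 1.0, 10.0, 1.0),
        IssueDomain("Side-effects", 0.0, 1.0, 0.01),
        IssueDomain("Risk", 0.0, 1.0, 0.01),
        IssueDomain("Convenience", 1.0, 10.0, 1.0),
    )
    pa = PreferenceProfile(
        weights=[0.2, 0.1, 0.2, 0.3, 0.2],
        memberships=[
            TrapezoidMembership(2.0, 3.5, 4.0, 6.0),
            TrapezoidMembership(8.0, 9.0, 10.0, 10.0),
            TrapezoidMembership(0.0, 0.05, 0.1, 0.2),
            TrapezoidMembership(0.0, 0.02, 0.05, 0.15),
            TrapezoidMembership(8.0, 9.0, 10.0, 10.0),
        ],
    )
    da = PreferenceProfile(
        weights=[0.25, 0.15, 0.3, 0.2, 0.1],
        memberships=[
            TrapezoidMembership(4.0, 5.0, 7.0, 8.0),
            TrapezoidMembership(6.0, 7.0, 8.0, 9.0),
            TrapezoidMembership(0.1, 0.15, 0.2, 0.25),
            TrapezoidMembership(0.05, 0.1, 0.15, 0.2),
            TrapezoidMembership(6.0, 7.0, 8.0, 9.0),
        ],
    )
    return Scenario(domains=domains, pa=pa, da=da, label="table2")


# ---------------------------------------------------------------------------
# scenario file I/O (YAML; JSON is a YAML subset so both load)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    doc = {
        "label": scenario.label,
        "issues": [
            {"name": d.name, "lo": d.lo, "hi": d.hi, "step": d.step}
            for d in scenario.domains
        ],
        "agents": {
            role: {
                "weights": [float(w) for w in prof.weights],
                "membership": [
                    [mf.a, mf.b, mf.c, mf.d, mf.beta] for mf in prof.memberships
                ],
            }
            for role, prof in (("PA", scenario.pa), ("DA", scenario.da))
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> Scenario:
    doc = yaml.safe_load(Path(path).read_text())
    domains = tuple(
        IssueDomain(i["name"], float(i["lo"]), float(i["hi"]), float(i["step"]))
        for i in doc["issues"]
    )
    profiles = {}
    for role in ("PA", "DA"):
        spec = doc["agents"][role]
        mfs = [TrapezoidMembership(*[float(x) for x in row]) for row in spec["membership"]]
        profiles[role] = PreferenceProfile(spec["weights"], mfs)
    scenario = Scenario(
        domains=domains, pa=profiles["PA"], da=profiles["DA"],
        label=doc.get("label") or "",
    )
    scenario.validate()
    return scenario


# ---------------------------------------------------------------------------
# synthetic scenario generation


@dataclass(frozen=True)
class GeneratorConfig:
    """Controls the questionnaire-style synthetic scenario generator.

    Per issue the two parties get equal-width supports; the DA support is
    shifted against the PA's by ``(1 - overlap) * support_width`` in a
    random direction (clipped to the domain), so ``overlap=1`` gives
    coinciding supports and ``overlap=0`` disjoint (tangent) ones.  Plateau
    placement inside the support is likewise interpolated between an
    independent draw (0) and the PA's placement (1).  Defaults are
    calibrated so the qualitative strategy orderings of the deadline sweep
    hold (conflictful but solvable scenarios, maximum joint satisfaction
    well below 2).
    """

    n_issues: int = 5
    plateau_fraction: float = 0.25
    support_fraction: float = 0.4
    overlap: float = 0.4
    weight_concentration: float = 6.0
    #: relative plateau position inside the support; None draws it uniformly
    #: (correlated between the parties through ``overlap``)
    plateau_position: float | None = 0.5
    #: pushes the parties' plateaus toward opposite ends of their supports
    #: (0 = both at plateau_position, 1 = extreme ends); adds conflict
    #: without reducing support overlap
    polarization: float = 1.0
    domain_lo: float = 0.0
    domain_hi: float = 10.0
    grid_points: int = 101
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_issues < 1:
            raise ConfigurationError("n_issues must be >= 1")
        for name in ("plateau_fraction", "support_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0,1], got {v}")
        if not 0.0 <= self.overlap <= 1.0:
            raise ConfigurationError("overlap must be in [0,1]")
        if self.weight_concentration <= 0:
            raise ConfigurationError("weight_concentration must be > 0")


def sample_scenario(
    config: GeneratorConfig, rng: np.random.Generator, label: str = ""
) -> Scenario:
    """Draw a random scenario with partially overlapping party preferences.

    With ``overlap > 0`` the draw is retried until at least one issue has
    intersecting supports, so some offer satisfies both parties.
    """
    for _ in range(config.max_retries):
        domains = tuple(
            IssueDomain(
                f"issue{i}",
                config.domain_lo,
                config.domain_hi,
                (config.domain_hi - config.domain_lo) / (config.grid_points - 1),
            )
            for i in range(config.n_issues)
        )
        mfs = {"PA": [], "DA": []}
        for dom in domains:
            ws = config.support_fraction * dom.width
            wp = config.plateau_fraction * ws
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shift = sign * (1 - config.overlap) * ws
            # place the PA support so the shifted DA support stays in bounds
            lo_a = dom.lo + max(0.0, -shift)
            hi_a = dom.lo + dom.width - ws - max(0.0, shift)
            if hi_a < lo_a:  # domain too narrow for the full shift
                lo_a = hi_a = dom.lo + (dom.width - ws) / 2 - shift / 2
            a_pa = lo_a + rng.uniform() * (hi_a - lo_a)
            a_da = float(
                np.clip(a_pa + shift, dom.lo, dom.lo + dom.width - ws)
            )
            if config.plateau_position is None:
                u_plat_pa = rng.uniform()
                u_plat_da = config.overlap * u_plat_pa + (1 - config.overlap) * rng.uniform()
            else:
                u_plat_pa = u_plat_da = config.plateau_position
            # polarization slides the plateaus apart along the shift direction
            pol = 0.5 * config.polarization * sign
            u_plat_pa = float(np.clip(u_plat_pa - pol, 0.0, 1.0))
            u_plat_da = float(np.clip(u_plat_da + pol, 0.0, 1.0))
            b_pa = a_pa + u_plat_pa * (ws - wp)
            b_da = a_da + u_plat_da * (ws - wp)
            mfs["PA"].append(
                TrapezoidMembership(a_pa, b_pa, min(b_pa + wp, a_pa + ws), a_pa + ws)
            )
            mfs["DA"].append(
                TrapezoidMembership(a_da, b_da, min(b_da + wp, a_da + ws), a_da + ws)
            )
        profiles = {}
        for role in ("PA", "DA"):
            w = rng.gamma(config.weight_concentration, size=config.n_issues)
            w = np.maximum(w, 1e-6)
            profiles[role] = PreferenceProfile(w / w.sum(), mfs[role])
        scenario = Scenario(
            domains=domains, pa=profiles["PA"], da=profiles["DA"], label=label
        )
        if config.overlap == 0 or _supports_intersect(scenario):
            scenario.validate()
            return scenario
    raise GenerationError("could not generate a feasible scenario (supports never intersect)")


def _supports_intersect(scenario: Scenario) -> bool:
    for mf_pa, mf_da in zip(scenario.pa.memberships, scenario.da.memberships):
        if max(mf_pa.a, mf_da.a) < min(mf_pa.d, mf_da.d):
            return True
    return False


# ---------------------------------------------------------------------------
# agent roster and sweeps


def parse_roster_entry(entry: str) -> tuple[str, str]:
    """Parse 'kind[:strategy]' into (kind, strategy); strategy defaults to
    collaboration."""
    kind, _, strategy = entry.partition(":")
    strategy = strategy or "collaboration"
    if strategy not in STRATEGY_OMEGA:
        raise ConfigurationError(f"unknown strategy {strategy!r} in roster entry {entry!r}")
    return kind, strategy


def build_agents(
    entry: str,
    scenario: Scenario,
    lam: float = 0.1,
    beta_t: float = 0.25,
    ga_params: GAParams | None = None,
    u_min: float = 0.0,
    sample_budget: int = DEFAULT_SAMPLE_BUDGET,
):
    """Construct the PA and DA agents for a self-play roster entry."""
    kind, strategy = parse_roster_entry(entry)
    params = StrategyParams.named(strategy, lam=lam, beta_t=beta_t)
    agents = {}
    for role in ("PA", "DA"):
        opp = scenario.profile("DA" if role == "PA" else "PA")
        agents[role] = make_agent(
            kind,
            role,
            scenario.profile(role),
            scenario.domains,
            params,
            ga_params=ga_params,
            opponent_profile=opp,
            u_min=u_min,
            sample_budget=sample_budget,
        )
    return agents["PA"], agents["DA"]


@dataclass(frozen=True)
class SweepConfig:
    """Experiment-sweep settings (desk scale by default: 50 negotiations per
    point; the printed experiments use 200)."""

    t_all: int = 50
    n_issues: int = 5
    rmax: int = 20
    deadlines: tuple[int, ...] = (10, 15, 20, 25, 30)
    issue_counts: tuple[int, ...] = (1, 3, 5, 7, 9)
    roster: tuple[str, ...] = ()
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    ga: GAParams = field(default_factory=GAParams)
    lam: float = 0.1
    beta_t: float = 0.25
    u_min: float = 0.0
    sample_budget: int = DEFAULT_SAMPLE_BUDGET
    seed: int = 0
    first_mover: str = "PA"


DEFAULT_ROSTERS = {
    "deadline": ("anf_time", "anfga:collaboration", "anfga:competition", "anfga:win_win"),
    "issues": ("anf_time", "anfga:collaboration", "anfga:competition", "anfga:win_win"),
    "information": ("fcan:collaboration", "anfga:collaboration", "complete_info:collaboration"),
}


def run_batch(
    entry: str,
    scenarios: Sequence[Scenario],
    rmax: int,
    config: SweepConfig,
    seeds: Sequence[np.random.SeedSequence],
) -> list[Transcript]:
    """Self-play negotiations of one roster entry over a scenario batch."""
    transcripts = []
    for scenario, seed in zip(scenarios, seeds):
        pa, da = build_agents(
            entry,
            scenario,
            lam=config.lam,
            beta_t=config.beta_t,
            ga_params=config.ga,
            u_min=config.u_min,
            sample_budget=config.sample_budget,
        )
        transcripts.append(
            run_negotiation(scenario, pa, da, rmax, config.first_mover, seed)
        )
    return transcripts


def _sweep_points(kind: str, config: SweepConfig):
    if kind == "deadline" or kind == "information":
        return [(d, config.n_issues, d) for d in config.deadlines]
    if kind == "issues":
        return [(n, n, config.rmax) for n in config.issue_counts]
    raise ConfigurationError(f"unknown sweep kind {kind!r}")


def run_sweep(
    kind: str, config: SweepConfig, progress: bool = False
) -> pd.DataFrame:
    """Run one sweep (deadline / issues / information) and tabulate metrics.

    Within a sweep point every roster entry sees byte-identical scenarios
    and negotiation seeds (matched-seed discipline).
    """
    roster = config.roster or DEFAULT_ROSTERS[kind]
    rows = []
    points = _sweep_points(kind, config)
    iterator = points
    if progress:
        from tqdm import tqdm

        iterator = tqdm(points, desc=f"{kind} sweep")
    for sweep_var, n_issues, rmax in iterator:
        gen = replace(config.generator, n_issues=n_issues)
        root = np.random.SeedSequence((config.seed, hash(kind) & 0xFFFF, sweep_var))
        scen_ss, *run_ss = root.spawn(config.t_all + 1)
        scen_rngs = [np.random.default_rng(s) for s in scen_ss.spawn(config.t_all)]
        scenarios = [
            sample_scenario(gen, r, label=f"{kind}-{sweep_var}-{i}")
            for i, r in enumerate(scen_rngs)
        ]
        for entry in roster:
            transcripts = run_batch(entry, scenarios, rmax, config, run_ss)
            report = compute_metrics(transcripts)
            rows.append(
                {
                    "sweep_var": sweep_var,
                    "agent": entry,
                    "AJS": report.ajs,
                    "ANR": report.anr,
                    "NSR": report.nsr,
                    "T_suc": report.t_suc,
                    "T_all": report.t_all,
                }
            )
    return pd.DataFrame(rows)
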