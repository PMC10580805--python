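# anfga

Agent-based bilateral multi-issue auto-negotiation for doctor–patient
shared decision-making, with fuzzy-constraint preference modelling, a
multi-state concession strategy, and a genetic-algorithm opponent
preference learner.

A treatment plan is an *offer*: one numeric value per negotiable *issue*
(cost, efficacy, side-effects, ...). Each party's private preferences are
trapezoid satisfaction curves plus importance weights; utility is the
weighted sum of memberships. Two agents exchange offers under the
alternating-offers protocol: each round the receiver summarizes the
negotiation into four states (opponent response, own satisfaction,
threshold tightness, time pressure), lowers its acceptance threshold by the
resulting concession value, and accepts or counters. The `anfga` agent
additionally evolves a population of candidate opponent profiles against
the offer history and proposes the candidate offer its opponent model
scores highest.

## Agents

| kind            | behaviour |
|-----------------|-----------|
| `anfga`         | full model: state-based concessions + GA opponent model |
| `fcan`          | same concessions, no opponent model; proposes the feasible offer closest to the opponent's last offer |
| `anf_time`      | purely time-dependent threshold schedule |
| `complete_info` | oracle: sees the true opponent profile, no GA |

Named strategies bind the concession exponent: `competition` (1.2),
`collaboration` (0.8), `win_win` (1.0).

## CLI

```bash
# emit the built-in five-issue doctor/patient example scenario
anfga fixture table2 --out table2.yaml

# one negotiation, transcript as JSON
anfga simulate --scenario table2.yaml --pa anfga:collaboration \
    --da anfga:collaboration --rmax 20 --seed 1

# experiment sweeps (metrics CSV: AJS / ANR / NSR per sweep point and agent)
anfga sweep --kind deadline --t-all 50 --seed 0 --out results.csv
anfga plot results.csv --out metrics.png
```

Sweep kinds: `deadline` (deadlines 10–30, five issues), `issues` (1–9 issues
at deadline 20), `information` (FCAN vs ANFGA vs complete information).
A YAML config can override the roster, generator, GA, and strategy settings
(`--config`); `--t-all 200` reproduces the full-size batches.

## Library use

```python
import numpy as np
from anfga import run_negotiation, table2_fixture
from anfga.scenarios_harness import build_agents

scenario = table2_fixture()
pa, da = build_agents("anfga:collaboration", scenario)
transcript = run_negotiation(scenario, pa, da, rmax=20, seed=1)
print(transcript.outcome, transcript.psi_pa, transcript.psi_da)
```

Synthetic scenarios come from `anfga.scenarios_harness.sample_scenario`;
the generator's defaults are calibrated so that the qualitative strategy
orderings of the deadline sweep hold (collaboration always succeeds,
competition stalls at tight deadlines). See `GeneratorConfig` for the
knobs (support width, support overlap, plateau polarization, weight
concentration).
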