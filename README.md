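# lexinet

Multi-agent simulations of grounded linguistic categorization on social
networks.

`lexinet` implements a language-games model in which a population of agents
evolves shared color categories and a shared vocabulary purely through
pairwise interactions, and uses it to study how two aspects of network
centrality — topological centrality (how efficiently information propagates)
and centralization of authority (whether information flows hub→periphery or
periphery→hub) — shape the emergence of global agreement and its robustness
when the interaction topology or the stimulus environment changes
mid-simulation. It is aimed at researchers in language evolution, opinion
dynamics and agent-based modelling of cultural conventions.

## The model

**Stimuli** are points in CIE LAB color space; distances are Euclidean in
(L, a, b). Each agent categorizes stimuli with a set of adaptive networks:
category *C* responds to stimulus **x** with

    f_C(x) = Σ_{u∈C} w_u · z_u(x),      z_u(x) = exp(−‖x − m_u‖² / 2σ²),

a weighted sum of Gaussian *reactive units* centered on remembered stimuli
(σ = 1 by default). Classification is argmax over categories. A lexicon
maps categories to shared word tokens with association strengths in [0, 1].

**Games.** In each iteration one edge of the interaction graph is drawn and
the two agents play a *guessing game*: the speaker discriminates a topic
among 4 stimuli (all pairwise distances > 50), utters the word most strongly
associated with the topic's category, and the hearer points at the stimulus
best matching the category it associates with that word. Success and the
three failure branches trigger ±0.1 association updates with lateral
inhibition, unit-weight reinforcement β·z_u(topic), category creation
(gated by the agent's trailing 50-game communicative success and a 0.95
threshold), and multiplicative forgetting. The *naming game* is the
ungrounded variant: words map directly onto 16 discrete stimuli.

**Measures.** An agent's communicative success (CS) is its success fraction
over its last 50 games. Population curves: CS_S (mean trailing CS on the
training topology), CS_G (frozen evaluation games on the complete graph),
and CS_A / CS_B (frozen evaluation games per environment).

**Topologies.** Complete graphs, stars with role bias (a hub of degree *d*
speaks — or hears — with probability (d−1)/d), and connected 3-regular
graphs optimized for centrality objectives (average/max betweenness, max
closeness, average clustering, constraint variance) by a
connectivity-preserving double-edge-swap annealer, with an exhaustive
enumeration oracle for n ≤ 10.

## Worked example

```python
import numpy as np
from lexinet import (ExperimentConfig, run_experiment, build_star,
                     centrality_report)

print("star(16 leaves):", centrality_report(build_star(16)).summary())

cfg = ExperimentConfig(game_kind="guessing", topology="min-avg-betweenness",
                       size=16, iterations_per_node=625, repeats=3,
                       master_seed=0)
records = run_experiment(cfg)
cs_s = np.mean([r.final("CS_S") for r in records])
cs_g = np.mean([r.final("CS_G") for r in records])
print(f"min-avg-betweenness, 16 agents, 10000 games: "
      f"CS_S = {cs_s:.3f}, CS_G = {cs_g:.3f}")
```

prints

```
star(16 leaves): {'radius': 1, 'diameter': 2, 'closeness': 0.54, 'betweenness': 0.06, 'clustering': 0.0}
min-avg-betweenness, 16 agents, 10000 games: CS_S = 0.541, CS_G = 0.269
```

The star summary is the structural-properties row of a 17-node star (radius
1, diameter 2, mean closeness 0.54, mean betweenness 1/17 ≈ 0.06). The
simulation lines show the model's signature gap: after 625 iterations per
node on a decentralized degree-3 network, agents communicate well with
their neighbors (CS_S ≈ 0.54) while global agreement lags behind
(CS_G ≈ 0.27) — local conventions form faster than population-wide ones.

A CLI mirrors the library: `lexinet run config.yaml -o traj.csv` runs an
experiment from a YAML config, `lexinet report` compares end-of-phase
scores across conditions (one-way ANOVA with a Bartlett check and Tukey HSD
post-hoc), and `lexinet topology` builds and summarizes a graph.

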