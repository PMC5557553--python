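"""Experiment orchestration: populations, scheduling, phase changes, probes.

An experiment trains a population of agents by repeated pairwise games
scheduled on an interaction graph (one game per iteration, edge drawn
uniformly, roles assigned by the topology's role policy), for 625
iterations per node by default, optionally followed by a second phase in
which either the topology is swapped for the fully connected graph (same
agents) or the stimulus environment is switched from A to B (same
topology).

Communicative success is measured two ways: the *trailing* CS of an agent
is its success fraction over its last 50 games (population CS_S is the mean
across agents), while CS_G / CS_A / CS_B are measured by *frozen probes* —
evaluation games played with ``learn=False`` that leave every agent
bit-identical — with pairs drawn from the complete graph (CS_G) or the
training topology (CS_A/CS_B) and stimuli from the stated environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import environments as envs
from . import topology as topo
from .agents import Agent, NamingAgent, WordFactory
from .environments import (
    DiscreteEnvironment,
    Environment,
    sample_context,
    sample_discrete_context,
)
from .games import guessing_game, naming_game
from .topology import Topology, assign_roles

__all__ = [
    "ExperimentConfig",
    "TrajectoryRecord",
    "build_topology",
    "select_interaction",
    "run_phase",
    "probe_cs",
    "run_experiment",
    "trajectories_to_frame",
    "save_population",
    "load_population",
]

TOPOLOGY_NAMES = (
    "complete",
    "star",
    "min-avg-betweenness",
    "max-avg-betweenness",
    "max-max-closeness",
    "min-max-closeness",
    "max-avg-clustering",
    "min-avg-clustering",
    "max-var-constraint",
    "max-max-betweenness",
)

_OPTIMIZED = {
    "min-avg-betweenness": ("avg-betweenness", "minimize"),
    "max-avg-betweenness": ("avg-betweenness", "maximize"),
    "max-max-closeness": ("max-closeness", "maximize"),
    "min-max-closeness": ("max-closeness", "minimize"),
    "max-avg-clustering": ("avg-clustering", "maximize"),
    "min-avg-clustering": ("avg-clustering", "minimize"),
    "max-var-constraint": ("var-constraint", "maximize"),
    "max-max-betweenness": ("max-betweenness", "maximize"),
}


@dataclass
class ExperimentConfig:
    """Full description of one experimental condition.

    ``size`` counts graph nodes for complete/degree-3 topologies and leaves
    for the star (a size-16 star has 17 nodes).  ``probe_interval`` is in
    iterations; probes additionally run at the start and at each phase end.
    Set it to 0 to probe at phase boundaries only.
    """

    game_kind: str = "guessing"          # guessing | naming
    topology: str = "complete"
    size: int = 16
    role_mode: str = "balanced"
    phase2: str = "none"                 # none | topology-to-complete | environment-A-to-B
    iterations_per_node: int = 625
    repeats: int = 10
    probe_interval: int = 0
    probe_games_per_agent: int = 20
    master_seed: int = 0
    n_chips: int = 1269
    n_env: int = 600
    anneal_steps: int = 2000
    kernel_sigma: float = 1.0
    learning_rate: float = 1.0
    forgetting_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.game_kind not in ("guessing", "naming"):
            raise ValueError(f"unknown game kind {self.game_kind!r}")
        if self.topology not in TOPOLOGY_NAMES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.phase2 not in ("none", "topology-to-complete",
                               "environment-A-to-B"):
            raise ValueError(f"unknown phase2 {self.phase2!r}")
        if self.iterations_per_node <= 0 or self.repeats < 1:
            raise ValueError("iterations_per_node > 0 and repeats >= 1 required")

    @property
    def n_nodes(self) -> int:
        return self.size + 1 if self.topology == "star" else self.size


@dataclass
class TrajectoryRecord:
    """Time-indexed CS measurements for one replicate."""

    replicate: int
    iterations: list[int] = field(default_factory=list)
    series: dict[str, list[float]] = field(default_factory=dict)
    phase_boundary: int | None = None

    def append(self, iteration: int, values: dict[str, float]) -> None:
        self.iterations.append(int(iteration))
        for name, v in values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"CS value out of [0,1]: {name}={v}")
            self.series.setdefault(name, []).append(float(v))

    def at_iteration(self, iteration: int, series: str) -> float:
        idx = self.iterations.index(int(iteration))
        return self.series[series][idx]

    def final(self, series: str) -> float:
        return self.series[series][-1]


def build_topology(
    name: str,
    size: int,
    role_mode: str = "balanced",
    seed: int = 0,
    anneal_steps: int = 2000,
) -> Topology:
    """Build a named topology; ``size`` is leaves for the star."""
    if name == "complete":
        return topo.build_complete(size)
    if name == "star":
        return topo.build_star(size, mode=role_mode)
    objective, direction = _OPTIMIZED[name]
    return topo.optimize_regular_topology(
        size, degree=3, objective=objective, direction=direction,
        seed=seed, n_steps=anneal_steps)


def select_interaction(t: Topology, rng: np.random.Generator,
                       edges: list | None = None) -> tuple[int, int]:
    """Uniformly random edge of the interaction graph."""
    if edges is None:
        edges = t.edges
    return edges[int(rng.integers(len(edges)))]


def _play(population, i, j, ctx, words, game_kind, learn=True):
    if game_kind == "guessing":
        return guessing_game(population[i], population[j], ctx, words,
                             learn=learn)
    return naming_game(population[i], population[j], ctx, words, learn=learn)


def _sample_ctx(env, rng):
    if isinstance(env, DiscreteEnvironment):
        return sample_discrete_context(env, rng)
    return sample_context(env, rng)


def probe_cs(
    population,
    pair_source: str,
    env,
    n_probe_games: int,
    rng: np.random.Generator,
    game_kind: str = "guessing",
    t: Topology | None = None,
) -> float:
    """Success fraction over frozen (learn=False) evaluation games.

    ``pair_source`` is ``"all-pairs"`` (CS_G) or ``"topology-edges"``
    (CS_S-style probes on the training graph; requires ``t``).  Population
    state is untouched.
    """
    if n_probe_games < 1:
        raise ValueError("n_probe_games must be >= 1")
    n = len(population)
    edges = None
    if pair_source == "topology-edges":
        if t is None:
            raise ValueError("topology-edges probing requires a topology")
        edges = t.edges
    elif pair_source != "all-pairs":
        raise ValueError(f"unknown pair source {pair_source!r}")
    successes = 0
    for _ in range(n_probe_games):
        if edges is None:
            i, j = rng.choice(n, size=2, replace=False)
            if rng.random() < 0.5:
                i, j = j, i
            speaker, hearer = int(i), int(j)
        else:
            edge = select_interaction(t, rng, edges)
            speaker, hearer = assign_roles(t, edge, rng)
        ctx = _sample_ctx(env, rng)
        out = _play(population, speaker, hearer, ctx, None, game_kind,
                    learn=False)
        successes += out.success
    return successes / n_probe_games


def run_phase(
    population,
    t: Topology,
    env,
    n_iterations: int,
    rng: np.random.Generator,
    words: WordFactory,
    game_kind: str,
    record: TrajectoryRecord,
    probes: dict[str, tuple[str, object]],
    probe_rng: np.random.Generator,
    probe_interval: int,
    probe_games_per_agent: int,
    iteration_offset: int = 0,
    event_log=None,
) -> int:
    """Train for ``n_iterations`` games on one topology/environment.

    ``probes`` maps series names to ``(pair_source, environment)``; the
    special source ``"trailing"`` records the mean trailing-window CS of
    the population instead of playing probe games.  Probes fire every
    ``probe_interval`` iterations (if > 0) and at the phase end.
    ``event_log``, if given, receives one JSON line per game (iteration,
    speaker, hearer, branch, word token, success).  Returns the iteration
    counter after the phase.
    """
    if len(population) != t.n_nodes:
        raise ValueError("population size must match the topology")
    edges = t.edges
    n_probe = probe_games_per_agent * len(population)

    def measure(it: int) -> None:
        values = {}
        for name, (source, probe_env) in probes.items():
            if source == "trailing":
                values[name] = float(np.mean([a.cs() for a in population]))
            else:
                values[name] = probe_cs(population, source, probe_env,
                                        n_probe, probe_rng, game_kind, t)
        record.append(it, values)

    for k in range(1, n_iterations + 1):
        edge = select_interaction(t, rng, edges)
        speaker, hearer = assign_roles(t, edge, rng)
        ctx = _sample_ctx(env, rng)
        out = _play(population, speaker, hearer, ctx, words, game_kind,
                    learn=True)
        if event_log is not None:
            event_log.write(json.dumps(
                {"iteration": iteration_offset + k, "speaker": int(speaker),
                 "hearer": int(hearer), "branch": out.failure_branch,
                 "word": out.word_used, "success": out.success}) + "\n")
        if (probe_interval and k % probe_interval == 0) or k == n_iterations:
            measure(iteration_offset + k)
    if n_iterations == 0:
        pass  # empty fragment, agents untouched
    return iteration_offset + n_iterations


def _replicate_seeds(master_seed: int, replicate: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return [int(s) % (2**31) for s in ss.generate_state(4)]


def _make_environments(cfg: ExperimentConfig, env_seed: int):
    """Training/probe environments for one replicate.

    Returns ``(phase1_env, phase2_env, probe_envs)`` where phase2_env is
    None unless the design switches environments.
    """
    if cfg.game_kind == "naming":
        env_a, env_b = envs.make_discrete_environment_pair(seed=env_seed)
        if cfg.phase2 == "environment-A-to-B":
            return env_a, env_b, {"A": env_a, "B": env_b}
        return env_a, None, {"train": env_a}
    base = envs.generate_base_chipset(cfg.n_chips, seed=env_seed)
    if cfg.phase2 == "environment-A-to-B":
        env_a = envs.make_weighted_environment(
            base, envs.FOCAL_A, n_env=cfg.n_env, seed=env_seed + 1, label="A")
        env_b = envs.make_weighted_environment(
            base, envs.FOCAL_B, n_env=cfg.n_env, seed=env_seed + 2, label="B")
        return env_a, env_b, {"A": env_a, "B": env_b}
    base_env = Environment(chips=base.chips, label="base")
    return base_env, None, {"train": base_env}


def run_replicate(cfg: ExperimentConfig, replicate: int,
                  population=None) -> TrajectoryRecord:
    """Run one replicate of the configured experiment design."""
    topo_seed, env_seed, game_seed, probe_seed = _replicate_seeds(
        cfg.master_seed, replicate)
    t = build_topology(cfg.topology, cfg.size, cfg.role_mode,
                       seed=topo_seed, anneal_steps=cfg.anneal_steps)
    phase1_env, phase2_env, probe_envs = _make_environments(cfg, env_seed)
    rng = np.random.default_rng(game_seed)
    probe_rng = np.random.default_rng(probe_seed)
    words = WordFactory()
    if population is None:
        if cfg.game_kind == "guessing":
            population = [Agent(kernel_sigma=cfg.kernel_sigma,
                                learning_rate=cfg.learning_rate,
                                forgetting_rate=cfg.forgetting_rate)
                          for _ in range(t.n_nodes)]
        else:
            population = [NamingAgent() for _ in range(t.n_nodes)]

    if cfg.phase2 == "environment-A-to-B":
        probes = {"CS_A": ("topology-edges", probe_envs["A"]),
                  "CS_B": ("topology-edges", probe_envs["B"])}
    else:
        probes = {"CS_S": ("trailing", None),
                  "CS_G": ("all-pairs", probe_envs["train"])}

    record = TrajectoryRecord(replicate=replicate)
    n_iters = cfg.iterations_per_node * t.n_nodes
    offset = run_phase(population, t, phase1_env, n_iters, rng, words,
                       cfg.game_kind, record, probes, probe_rng,
                       cfg.probe_interval, cfg.probe_games_per_agent)

    if cfg.phase2 != "none":
        record.phase_boundary = offset
        if cfg.phase2 == "topology-to-complete":
            t2, env2 = topo.build_complete(t.n_nodes), phase1_env
        else:
            t2, env2 = t, phase2_env
        run_phase(population, t2, env2, n_iters, rng, words,
                  cfg.game_kind, record, probes, probe_rng,
                  cfg.probe_interval, cfg.probe_games_per_agent,
                  iteration_offset=offset)
    record._population = population  # kept for checkpointing by callers
    return record


def run_experiment(cfg: ExperimentConfig) -> list[TrajectoryRecord]:
    """All replicates of the configured design, independently seeded."""
    return [run_replicate(cfg, r) for r in range(cfg.repeats)]


def trajectories_to_frame(records: list[TrajectoryRecord],
                          condition: str = "") -> pd.DataFrame:
    """Tidy trajectory table: replicate, iteration, series, value, phase."""
    rows = []
    for rec in records:
        for name, values in rec.series.items():
            for it, v in zip(rec.iterations, values):
                phase = 1
                if rec.phase_boundary is not None and it > rec.phase_boundary:
                    phase = 2
                rows.append((condition, rec.replicate, it, name, v, phase))
    return pd.DataFrame(rows, columns=["condition", "replicate", "iteration",
                                       "series", "value", "phase"])


def save_population(population, path: str | Path) -> None:
    kind = "guessing" if isinstance(population[0], Agent) else "naming"
    payload = {"kind": kind, "agents": [a.to_dict() for a in population]}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_population(path: str | Path):
    payload = json.loads(Path(path).read_text())
    cls = Agent if payload["kind"] == "guessing" else NamingAgent
    return [cls.from_dict(d) for d in payload["agents"]]
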