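"""Population-level stochastic execution of a domain model.

Binds the single-entity state machines, the compartment graph, a set of
interaction rules, and per-compartment molecule fields into a synchronous
multi-agent simulation.  One step proceeds as:

1. snapshot every living agent's active states and compartment;
2. sample interaction rules against the snapshot — each eligible actor
   draws one uniformly random eligible (co-located) partner and fires with
   the rule's per-step rate, asserting predicates, marking kills, or
   queueing spawns;
3. step every living agent's machine against an environment built from the
   snapshot (own active states for ``in_<state>`` predicates, molecule
   fields for ``<Molecule>_present`` predicates, sampled interactions for
   everything else);
4. apply emissions: ``secrete_<Molecule>`` increments the local field,
   ``proliferate`` spawns one daughter in the machine's initial states;
5. attempt one migration per agent along an allowed migration rule, with a
   per-type move probability, keeping the location region in sync;
6. decay molecule fields.

Kills assert the ``killed`` predicate; the victim's own machine decides
what death looks like (a state in ``death_states``), and an agent whose
death state has been active for a full step is removed — leaving one step
during which apoptotic cells can still be ingested by phagocytes.

Agent iteration order is reshuffled every step from the run's seeded
generator, so no entity systematically acts first; identical seeds give
bit-identical trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import DomainModel
from .statechart import MachineConfig, StateMachine, initial_config, step_machine

__all__ = [
    "AgentInstance",
    "Effect",
    "InteractionRule",
    "SimConfig",
    "SimState",
    "PopulationTimeSeries",
    "KnockoutError",
    "init_sim",
    "step_sim",
    "run_sim",
    "apply_knockout",
    "apply_knockouts_to_perspective",
]

DEFAULT_DEATH_STATES = frozenset({"apoptotic", "dead"})

KILLED_PREDICATE = "killed"


class KnockoutError(KeyError):
    """A knockout name resolves to no interaction rule or perspective edge."""


@dataclass
class AgentInstance:
    id: int
    entity_type: str
    machine_config: MachineConfig
    compartment: str
    alive: bool = True
    parent_id: Optional[int] = None


@dataclass(frozen=True)
class Effect:
    """Outcome of a fired interaction: assert a predicate on one party,
    mark the partner killed, or spawn a new agent in the actor's
    compartment."""

    kind: str  # "assert_predicate" | "kill" | "spawn"
    predicate: Optional[str] = None
    on: str = "partner"  # assert_predicate only: "actor" | "partner"
    spawn_type: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("assert_predicate", "kill", "spawn"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "assert_predicate" and not self.predicate:
            raise ValueError("assert_predicate effect needs a predicate name")
        if self.kind == "spawn" and not self.spawn_type:
            raise ValueError("spawn effect needs an entity type")


@dataclass(frozen=True)
class InteractionRule:
    """A pairwise cell interaction, sampled once per eligible actor per
    step at probability ``rate`` (a parameter name)."""

    name: str
    actor_type: str
    actor_states: tuple[str, ...]
    partner_type: str
    partner_states: tuple[str, ...]
    effect: Effect
    rate: str
    co_location: bool = True


@dataclass(frozen=True)
class SimConfig:
    """Run configuration: who starts where, for how long, and which rules
    or perspective edges are knocked out."""

    initial_populations: Mapping[str, Mapping[str, int]]  # type -> comp -> n
    n_steps: int
    seed: int
    interaction_rules: tuple[InteractionRule, ...] = ()
    parameter_overrides: Mapping[str, float] = field(default_factory=dict)
    knockouts: tuple[str, ...] = ()
    death_states: frozenset[str] = DEFAULT_DEATH_STATES

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        for entity_type, by_comp in self.initial_populations.items():
            for comp, n in by_comp.items():
                if n < 0:
                    raise ValueError(
                        f"negative initial population for {entity_type} in {comp}"
                    )


def apply_knockout(
    sim_config: SimConfig,
    names: Sequence[str],
    model: Optional[DomainModel] = None,
) -> SimConfig:
    """Return a config with the named interaction rules / perspective edges
    disabled; everything else untouched.  Unknown names raise
    :class:`KnockoutError`."""
    known = {rule.name for rule in sim_config.interaction_rules}
    if model is not None:
        for p in model.perspectives:
            known |= {e.ident for e in p.sequential}
            known |= {e.ident for e in p.propagating}
    for name in names:
        if name not in known:
            raise KnockoutError(f"knockout target {name!r} does not resolve")
    if not names:
        return sim_config
    return replace(sim_config, knockouts=sim_config.knockouts + tuple(names))


def apply_knockouts_to_perspective(perspective, names: Sequence[str]):
    """Perspective with the named sequential/propagating edges removed."""
    from dataclasses import replace as _replace

    names = set(names)
    return _replace(
        perspective,
        sequential=tuple(e for e in perspective.sequential if e.ident not in names),
        propagating=tuple(e for e in perspective.propagating if e.ident not in names),
    )


# --------------------------------------------------------------------------
# Simulation state


@dataclass
class SimState:
    model: DomainModel
    config: SimConfig
    agents: list[AgentInstance]
    fields: dict[str, dict[str, float]]  # compartment -> molecule -> level
    rng: np.random.Generator
    step: int = 0
    next_id: int = 0
    births: dict[str, int] = field(default_factory=dict)
    deaths: dict[str, int] = field(default_factory=dict)
    event_log: list[dict] = field(default_factory=list)
    # caches built at init time
    sim_machines: dict[str, StateMachine] = field(default_factory=dict)
    mentioned: dict[str, tuple[str, ...]] = field(default_factory=dict)
    migration_targets: dict[str, list] = field(default_factory=dict)

    def living(self) -> list[AgentInstance]:
        return [a for a in self.agents if a.alive]

    def parameters(self) -> dict[str, float]:
        return {**self.model.parameters, **self.config.parameter_overrides}


def _sync_location(
    machine: StateMachine, config: MachineConfig, compartment: str
) -> None:
    """Point the location region's active path at the compartment leaf."""
    region = machine.location_region()
    if region is None or not machine.has_state(compartment):
        return
    if machine.region_of(compartment) is not region:
        return
    old = config.active[region.name]
    new = machine.path_to(compartment)
    if new == old:
        return
    k = 0
    while k < min(len(old), len(new)) and old[k] == new[k]:
        k += 1
    config.active[region.name] = new
    for name in new[k:]:
        config.elapsed[name] = 0


def _masked_machine(machine: StateMachine) -> StateMachine:
    """Machine with location-region transitions removed: spatial moves are
    the migration step's job during population runs."""
    region = machine.location_region()
    if region is None:
        return machine
    kept = tuple(
        t for t in machine.transitions if machine.region_of(t.source) is not region
    )
    return StateMachine(machine.entity_type, machine.regions, kept)


def init_sim(model: DomainModel, sim_config: SimConfig, force: bool = False) -> SimState:
    """Create the initial simulation state.

    The model must pass strict consistency checking unless ``force`` is
    set.  Cell populations become agents in their machines' initial
    configurations (location regions synced to the placement compartment);
    molecule populations become initial field levels.
    """
    from .consistency import check_model  # local import: layering

    if not force:
        report = check_model(model)
        if not report.passed:
            raise ValueError(
                f"model fails strict consistency ({len(report.violations)} "
                "violation(s)); pass force=True to simulate anyway"
            )
    comp_names = model.compartment_names()
    molecules = set(model.molecules())
    fields = {c: {m: 0.0 for m in molecules} for c in comp_names}
    state = SimState(
        model=model,
        config=sim_config,
        agents=[],
        fields=fields,
        rng=np.random.default_rng(sim_config.seed),
    )
    for entity_type, machine in model.state_machines.items():
        state.sim_machines[entity_type] = _masked_machine(machine)
        state.mentioned[entity_type] = tuple(
            sorted(state.sim_machines[entity_type].mentioned_predicates())
        )
    for rule in model.migration_rules:
        state.migration_targets.setdefault(rule.entity_type, []).append(
            (rule.from_compartment, rule.to_compartment, rule.condition_expr())
        )
    for entity_type in sorted(sim_config.initial_populations):
        by_comp = sim_config.initial_populations[entity_type]
        decl = model.entity(entity_type)  # KeyError on undeclared types
        for comp in sorted(by_comp):
            n = by_comp[comp]
            if comp not in comp_names:
                raise ValueError(f"unknown compartment {comp!r}")
            if decl.category == "molecule":
                state.fields[comp][entity_type] += n
                continue
            machine = model.state_machines.get(entity_type)
            for _ in range(n):
                config = (
                    initial_config(machine)
                    if machine is not None
                    else MachineConfig({}, {})
                )
                if machine is not None:
                    _sync_location(machine, config, comp)
                state.agents.append(
                    AgentInstance(state.next_id, entity_type, config, comp)
                )
                state.next_id += 1
    return state


_NO_RNG = np.random.default_rng(0)


def _allowed_targets(state: SimState, agent: AgentInstance, labels: set[str]) -> list[str]:
    targets = []
    for frm, to, expr in state.migration_targets.get(agent.entity_type, ()):
        if frm != agent.compartment:
            continue
        env = {}
        for name in expr.predicates():
            bare = name[3:] if name.startswith("in_") else name
            env[name] = bare in labels or name in labels
        if expr.evaluate(env, 0, {}, _NO_RNG):
            targets.append(to)
    return targets


def step_sim(model: DomainModel, state: SimState) -> SimState:
    """Advance the simulation one synchronized step (mutates and returns
    ``state``)."""
    params = state.parameters()
    rng = state.rng
    knockouts = set(state.config.knockouts)
    living = state.living()
    order = list(rng.permutation(len(living))) if living else []
    agents = [living[i] for i in order]

    # start-of-step snapshot
    snapshot: dict[int, set[str]] = {
        a.id: a.machine_config.active_states() for a in agents
    }

    # (ii) interaction sampling against the snapshot
    assertions: dict[int, set[str]] = {a.id: set() for a in agents}
    spawn_queue: list[tuple[str, str, int]] = []  # (type, compartment, parent)
    for rule in state.config.interaction_rules:
        if rule.name in knockouts:
            continue
        rate = params.get(rule.rate)
        if rate is None:
            raise KeyError(f"interaction rate parameter {rule.rate!r} missing")
        partners_by_comp: dict[Optional[str], list[AgentInstance]] = {}
        for a in agents:
            if a.entity_type == rule.partner_type and set(rule.partner_states) <= snapshot[a.id]:
                key = a.compartment if rule.co_location else None
                partners_by_comp.setdefault(key, []).append(a)
        for actor in agents:
            if actor.entity_type != rule.actor_type:
                continue
            if not set(rule.actor_states) <= snapshot[actor.id]:
                continue
            key = actor.compartment if rule.co_location else None
            pool = [p for p in partners_by_comp.get(key, []) if p.id != actor.id]
            if not pool:
                continue
            partner = pool[int(rng.integers(len(pool)))]
            if rng.random() >= rate:
                continue
            effect = rule.effect
            if effect.kind == "assert_predicate":
                target = actor if effect.on == "actor" else partner
                assertions[target.id].add(effect.predicate)
            elif effect.kind == "kill":
                assertions[partner.id].add(KILLED_PREDICATE)
                state.event_log.append(
                    {
                        "step": state.step,
                        "event": "kill",
                        "rule": rule.name,
                        "actor": actor.id,
                        "victim": partner.id,
                    }
                )
            elif effect.kind == "spawn":
                spawn_queue.append((effect.spawn_type, actor.compartment, actor.id))

    # (iii) machine stepping against the snapshot environment
    emissions: list[tuple[AgentInstance, list[str]]] = []
    for agent in agents:
        machine = state.sim_machines.get(agent.entity_type)
        if machine is None:
            continue
        active = snapshot[agent.id]
        env = {}
        for pred in state.mentioned[agent.entity_type]:
            if pred.startswith("in_"):
                env[pred] = pred[3:] in active
            elif pred.endswith("_present") and pred[: -len("_present")] in state.fields[agent.compartment]:
                molecule = pred[: -len("_present")]
                threshold = params.get(f"threshold_{molecule}", 1.0)
                env[pred] = state.fields[agent.compartment][molecule] >= threshold
            else:
                env[pred] = pred in assertions[agent.id]
        agent.machine_config, emitted = step_machine(
            machine, agent.machine_config, env, params, rng
        )
        if emitted:
            emissions.append((agent, emitted))

    # (iv) emissions: secretion and proliferation
    for agent, emitted in emissions:
        for label in emitted:
            if label.startswith("secrete_"):
                molecule = label[len("secrete_"):]
                if molecule in state.fields[agent.compartment]:
                    state.fields[agent.compartment][molecule] += 1.0
            elif label == "proliferate":
                spawn_queue.append((agent.entity_type, agent.compartment, agent.id))

    for entity_type, comp, parent in spawn_queue:
        machine = model.state_machines.get(entity_type)
        config = initial_config(machine) if machine is not None else MachineConfig({}, {})
        if machine is not None:
            _sync_location(machine, config, comp)
        state.agents.append(
            AgentInstance(state.next_id, entity_type, config, comp, parent_id=parent)
        )
        state.births[entity_type] = state.births.get(entity_type, 0) + 1
        state.event_log.append(
            {"step": state.step, "event": "birth", "entity_type": entity_type,
             "compartment": comp, "parent": parent}
        )
        state.next_id += 1

    # deaths: a death state active for one full step removes the agent
    death_states = state.config.death_states
    for agent in agents:
        active = agent.machine_config.active_leaves()
        for leaf in active & death_states:
            if agent.machine_config.elapsed.get(leaf, 0) >= 1:
                agent.alive = False
                state.deaths[agent.entity_type] = (
                    state.deaths.get(agent.entity_type, 0) + 1
                )
                state.event_log.append(
                    {"step": state.step, "event": "death", "agent": agent.id,
                     "entity_type": agent.entity_type}
                )
                break

    # (v) migration along allowed rules with per-type move probability
    for agent in agents:
        if not agent.alive:
            continue
        labels = agent.machine_config.active_states()
        targets = _allowed_targets(state, agent, labels)
        if not targets:
            continue
        p_move = params.get(
            f"p_migrate_{agent.entity_type}", params.get("p_migrate", 0.0)
        )
        if rng.random() < p_move:
            destination = targets[int(rng.integers(len(targets)))]
            agent.compartment = destination
            machine = model.state_machines.get(agent.entity_type)
            if machine is not None:
                _sync_location(machine, agent.machine_config, destination)

    # (vi) field decay
    for comp, by_mol in state.fields.items():
        for molecule in by_mol:
            decay = params.get(f"decay_{molecule}", 0.0)
            by_mol[molecule] = max(by_mol[molecule] * (1.0 - decay), 0.0)

    state.step += 1
    return state


# --------------------------------------------------------------------------
# Observation layer


@dataclass
class PopulationTimeSeries:
    """Per-step agent counts by (entity type, active leaf states,
    compartment), with cumulative birth/death accounting and the run's
    event log."""

    steps: list[dict[tuple[str, tuple[str, ...], str], int]]
    births: list[dict[str, int]]  # cumulative, per step
    deaths: list[dict[str, int]]
    initial_counts: dict[str, int]
    event_log: list[dict] = field(default_factory=list)

    def totals(self, entity_type: str) -> np.ndarray:
        return np.array(
            [
                sum(n for (etype, _, _), n in row.items() if etype == entity_type)
                for row in self.steps
            ]
        )

    def accounting_holds(self) -> bool:
        """initial + cumulative births == alive + cumulative deaths, for
        every type at every step."""
        types = set(self.initial_counts)
        for row, births, deaths in zip(self.steps, self.births, self.deaths):
            types |= set(births) | set(deaths)
            for entity_type in types:
                alive = sum(
                    n for (etype, _, _), n in row.items() if etype == entity_type
                )
                lhs = self.initial_counts.get(entity_type, 0) + births.get(entity_type, 0)
                if lhs != alive + deaths.get(entity_type, 0):
                    return False
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for step, counts in enumerate(self.steps):
            for (entity_type, states, comp), n in sorted(counts.items()):
                rows.append(
                    {
                        "step": step,
                        "entity_type": entity_type,
                        "state": "+".join(states),
                        "compartment": comp,
                        "count": n,
                    }
                )
        return pd.DataFrame(
            rows, columns=["step", "entity_type", "state", "compartment", "count"]
        )

    def to_csv(self) -> str:
        return self.to_frame().to_csv(index=False)

    def event_log_ndjson(self) -> str:
        return "\n".join(json.dumps(e, sort_keys=True) for e in self.event_log)


def _observe(state: SimState) -> dict[tuple[str, tuple[str, ...], str], int]:
    counts: dict[tuple[str, tuple[str, ...], str], int] = {}
    for agent in state.living():
        key = (
            agent.entity_type,
            tuple(sorted(agent.machine_config.active_leaves())),
            agent.compartment,
        )
        counts[key] = counts.get(key, 0) + 1
    return counts


def run_sim(
    model: DomainModel, sim_config: SimConfig, force: bool = False
) -> PopulationTimeSeries:
    """Run ``n_steps`` of the simulation; deterministic under the config's
    seed.  The returned series includes step 0 (the initial state)."""
    state = init_sim(model, sim_config, force=force)
    initial_counts: dict[str, int] = {}
    for agent in state.agents:
        initial_counts[agent.entity_type] = initial_counts.get(agent.entity_type, 0) + 1
    steps = [_observe(state)]
    births = [dict(state.births)]
    deaths = [dict(state.deaths)]
    for _ in range(sim_config.n_steps):
        state = step_sim(model, state)
        steps.append(_observe(state))
        births.append(dict(state.births))
        deaths.append(dict(state.deaths))
    return PopulationTimeSeries(
        steps=steps,
        births=births,
        deaths=deaths,
        initial_counts=initial_counts,
        event_log=list(state.event_log),
    )
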