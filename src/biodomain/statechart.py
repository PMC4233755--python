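"""Single-entity state machines with guarded, hierarchical, orthogonal regions.

A :class:`StateMachine` describes one entity type's dynamics as a set of
orthogonal *regions*, each a small statechart of atomic, composite, and
isolated states.  Transitions carry guards in the δ/λ/logical language of
:mod:`biodomain.guards`.  Execution is discrete-time and synchronous: each
call to :func:`step_machine` advances one step, firing at most one
transition per region against a start-of-step snapshot of the environment
and configuration, so regions never observe each other's within-step
changes.  Partial orthogonality between regions is expressed through guard
predicates naming other regions' active states (``in_<state>``), never
through shared states.

Isolated states (states with no incident transitions) model standing
capabilities — e.g. a mature antigen-presenting cell that is always capable
of expressing MHC-II.  They live in their own region and simply remain
active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .guards import GuardExpr, TrueGuard, parse_guard

__all__ = [
    "StateNode",
    "Region",
    "Transition",
    "StateMachine",
    "MachineConfig",
    "Environment",
    "MachineDefinitionError",
    "ConfigError",
    "initial_config",
    "step_machine",
]

Environment = Mapping[str, bool]

STATE_KINDS = ("atomic", "composite", "isolated")


class MachineDefinitionError(ValueError):
    """A state machine violates a structural invariant."""


class ConfigError(ValueError):
    """A machine configuration is invalid for its machine."""


@dataclass(frozen=True)
class StateNode:
    """One state: atomic, composite (with substates), or isolated."""

    name: str
    kind: str = "atomic"
    substates: tuple["StateNode", ...] = ()
    initial: Optional[str] = None  # composite only: name of initial substate
    entry_actions: tuple[str, ...] = ()
    exit_actions: tuple[str, ...] = ()
    emissions: tuple[str, ...] = ()  # per-step action labels while active

    def __post_init__(self):
        if not self.name:
            raise MachineDefinitionError("state name must be non-empty")
        if self.kind not in STATE_KINDS:
            raise MachineDefinitionError(
                f"state {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "composite":
            if not self.substates:
                raise MachineDefinitionError(
                    f"composite state {self.name!r} needs >=1 substate"
                )
            names = [s.name for s in self.substates]
            if self.initial not in names:
                raise MachineDefinitionError(
                    f"composite state {self.name!r}: initial {self.initial!r} "
                    "is not one of its substates"
                )
        else:
            if self.substates or self.initial is not None:
                raise MachineDefinitionError(
                    f"non-composite state {self.name!r} cannot carry substates"
                )


@dataclass(frozen=True)
class Transition:
    """Guarded transition between two states of the same region."""

    source: str
    target: str
    guard: GuardExpr = field(default_factory=TrueGuard)
    actions: tuple[str, ...] = ()

    @staticmethod
    def of(source: str, target: str, guard: str = "", actions: Sequence[str] = ()) -> "Transition":
        return Transition(source, target, parse_guard(guard), tuple(actions))


@dataclass(frozen=True)
class Region:
    """An orthogonal region: a set of top-level states and one initial.

    ``location`` tags the region whose states name the spatial compartments
    an entity can occupy; the consistency checker and the population
    simulation treat it specially.
    """

    name: str
    states: tuple[StateNode, ...]
    initial: str
    location: bool = False

    def __post_init__(self):
        if not self.states:
            raise MachineDefinitionError(f"region {self.name!r} has no states")
        if self.initial not in {s.name for s in self.states}:
            raise MachineDefinitionError(
                f"region {self.name!r}: initial {self.initial!r} is not a "
                "top-level state of the region"
            )


def _walk(node: StateNode) -> Iterable[StateNode]:
    yield node
    for sub in node.substates:
        yield from _walk(sub)


@dataclass(frozen=True)
class StateMachine:
    entity_type: str
    regions: tuple[Region, ...]
    transitions: tuple[Transition, ...] = ()

    def __post_init__(self):
        index: dict[str, tuple[Region, StateNode]] = {}
        parent: dict[str, Optional[str]] = {}
        for region in self.regions:
            for top in region.states:
                for node in _walk(top):
                    if node.name in index:
                        raise MachineDefinitionError(
                            f"{self.entity_type}: duplicate state name {node.name!r}"
                        )
                    index[node.name] = (region, node)
                for node in _walk(top):
                    for sub in node.substates:
                        parent[sub.name] = node.name
                parent.setdefault(top.name, None)
        region_names = [r.name for r in self.regions]
        if len(set(region_names)) != len(region_names):
            raise MachineDefinitionError(
                f"{self.entity_type}: duplicate region names"
            )
        for t in self.transitions:
            for endpoint in (t.source, t.target):
                if endpoint not in index:
                    raise MachineDefinitionError(
                        f"{self.entity_type}: transition endpoint {endpoint!r} "
                        "does not resolve"
                    )
            src_region, src_node = index[t.source]
            tgt_region, tgt_node = index[t.target]
            if src_region is not tgt_region:
                raise MachineDefinitionError(
                    f"{self.entity_type}: transition {t.source!r} -> "
                    f"{t.target!r} crosses regions"
                )
            if src_node.kind == "isolated" or tgt_node.kind == "isolated":
                raise MachineDefinitionError(
                    f"{self.entity_type}: isolated state in transition "
                    f"{t.source!r} -> {t.target!r}"
                )
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_parent", parent)

    # -- lookup helpers -----------------------------------------------------

    def state(self, name: str) -> StateNode:
        return self._index[name][1]

    def region_of(self, name: str) -> Region:
        return self._index[name][0]

    def has_state(self, name: str) -> bool:
        return name in self._index

    def path_to(self, name: str) -> tuple[str, ...]:
        """Ancestor chain from the region's top level down to ``name``."""
        chain = [name]
        while self._parent.get(chain[0]) is not None:
            chain.insert(0, self._parent[chain[0]])
        return tuple(chain)

    def descend_initial(self, name: str) -> tuple[str, ...]:
        """Path from ``name`` down through composite initials to a leaf."""
        node = self.state(name)
        path = [name]
        while node.kind == "composite":
            node = next(s for s in node.substates if s.name == node.initial)
            path.append(node.name)
        return tuple(path)

    def leaves(self, name: str) -> tuple[str, ...]:
        """All leaf states under ``name`` (itself, if not composite)."""
        node = self.state(name)
        return tuple(
            n.name for n in _walk(node) if n.kind != "composite"
        )

    def location_region(self) -> Optional[Region]:
        for region in self.regions:
            if region.location:
                return region
        return None

    def transitions_in(self, region: Region) -> tuple[Transition, ...]:
        return tuple(
            t for t in self.transitions if self.region_of(t.source) is region
        )

    def mentioned_predicates(self) -> set[str]:
        preds: set[str] = set()
        for t in self.transitions:
            preds |= t.guard.predicates()
        return preds


@dataclass
class MachineConfig:
    """Live snapshot of one entity: active path and dwell times per region.

    ``active`` maps region name to the chain of active states from the
    region's top level down to the active leaf; ``elapsed`` records, for
    every state on an active path, the number of completed steps since that
    state was entered.
    """

    active: dict[str, tuple[str, ...]]
    elapsed: dict[str, int]

    def copy(self) -> "MachineConfig":
        return MachineConfig(dict(self.active), dict(self.elapsed))

    def active_states(self) -> set[str]:
        out: set[str] = set()
        for path in self.active.values():
            out.update(path)
        return out

    def active_leaves(self) -> set[str]:
        return {path[-1] for path in self.active.values()}


def initial_config(machine: StateMachine) -> MachineConfig:
    """Configuration with each region in its initial state (descending
    through composite initials), all dwell counters at zero."""
    active: dict[str, tuple[str, ...]] = {}
    elapsed: dict[str, int] = {}
    for region in machine.regions:
        path = machine.descend_initial(region.initial)
        active[region.name] = path
        for name in path:
            elapsed[name] = 0
    return MachineConfig(active, elapsed)


def _check_config(machine: StateMachine, config: MachineConfig) -> None:
    if set(config.active) != {r.name for r in machine.regions}:
        raise ConfigError("config regions do not match machine regions")
    for region in machine.regions:
        path = config.active[region.name]
        if not path or not machine.has_state(path[-1]):
            raise ConfigError(f"region {region.name!r}: invalid active path")
        for name in path:
            if config.elapsed.get(name, -1) < 0:
                raise ConfigError(f"state {name!r}: missing/negative elapsed")


def step_machine(
    machine: StateMachine,
    config: MachineConfig,
    env: Environment,
    parameters: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[MachineConfig, list[str]]:
    """Advance the machine by one step.

    Per region, the guards of transitions leaving the active leaf or any of
    its active ancestor composites are evaluated against the start-of-step
    snapshot (``config`` and ``env`` as given).  At most one transition
    fires per region; when several are enabled the choice is uniform at
    random.  Firing runs exit actions (innermost first), the transition's
    own actions, then entry actions (outermost first), and resets dwell
    counters of newly entered states.  A region with no enabled transition
    keeps its states and increments their dwell counters.  The per-step
    emissions of every state active after the step are appended last.

    Returns the new configuration and the list of emitted action labels.
    """
    _check_config(machine, config)
    new_active: dict[str, tuple[str, ...]] = {}
    new_elapsed: dict[str, int] = {}
    emitted: list[str] = []

    for region in machine.regions:
        old_path = config.active[region.name]
        on_path = set(old_path)
        enabled: list[Transition] = []
        for t in machine.transitions_in(region):
            if t.source in on_path:
                dwell = config.elapsed[t.source]
                if t.guard.evaluate(env, dwell, parameters, rng):
                    enabled.append(t)
        if not enabled:
            new_active[region.name] = old_path
            for name in old_path:
                new_elapsed[name] = config.elapsed[name] + 1
            continue
        fired = enabled[0] if len(enabled) == 1 else enabled[int(rng.integers(len(enabled)))]
        # new path: ancestors of the target, the target, then composite initials
        target_chain = machine.path_to(fired.target)
        descent = machine.descend_initial(fired.target)
        new_path = target_chain[:-1] + descent
        # common prefix of old and new paths, never retaining the source
        k = 0
        while (
            k < min(len(old_path), len(new_path))
            and old_path[k] == new_path[k]
        ):
            k += 1
        k = min(k, old_path.index(fired.source))
        exited = old_path[k:]
        entered = new_path[k:]
        for name in reversed(exited):  # innermost first
            emitted.extend(machine.state(name).exit_actions)
        emitted.extend(fired.actions)
        for name in entered:  # outermost first
            emitted.extend(machine.state(name).entry_actions)
        new_active[region.name] = new_path
        for name in new_path[:k]:
            new_elapsed[name] = config.elapsed[name] + 1
        for name in entered:
            new_elapsed[name] = 0

    result = MachineConfig(new_active, new_elapsed)
    for region in machine.regions:
        for name in result.active[region.name]:
            emitted.extend(machine.state(name).emissions)
    return result, emitted
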