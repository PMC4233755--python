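"""Domain-model data types spanning all three modelling levels.

A :class:`DomainModel` aggregates:

* the **system** level — a :class:`ResearchContext` linking real-world
  phenomena, the emergent behaviours expected to produce them, and the
  cellular/molecular components involved, plus the spatial compartment
  graph (:class:`Compartment`, :class:`MigrationRule`);
* the **perspectives** level — activity networks
  (:class:`~biodomain.activity.Perspective`), each expanding one or more
  expected behaviours;
* the **single-entity** level — one guarded state machine
  (:class:`~biodomain.statechart.StateMachine`) per entity type.

Assembly (:func:`assemble_domain_model`) enforces referential integrity:
every cross-reference between the levels must resolve, and an out-of-scope
phenomenon may never acquire incoming links.  All rate and duration values
live in a single flat parameter table referenced by name from guards, so
the absence of published rates stays explicit and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .activity import Perspective
from .guards import Delta, GuardExpr, Lambda, parse_guard
from .statechart import StateMachine

__all__ = [
    "Compartment",
    "MigrationRule",
    "EntityTypeDecl",
    "Phenomenon",
    "ContextLink",
    "ResearchContext",
    "BindingDeclaration",
    "DomainModel",
    "AssemblyError",
    "assemble_domain_model",
    "migration_allowed",
]

LINK_POLARITIES = ("autoimmune", "regulatory", "neutral")
ENTITY_CATEGORIES = ("cell", "molecule")

_NO_RNG = np.random.default_rng(0)  # state conditions contain no δ/λ atoms


class AssemblyError(ValueError):
    """A dangling reference or invariant violation found during assembly."""


@dataclass(frozen=True)
class Compartment:
    name: str
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise AssemblyError("compartment name must be non-empty")


@dataclass(frozen=True)
class MigrationRule:
    """Permission for one entity type to move between two compartments.

    ``state_condition`` optionally restricts the move to agents whose active
    state labels satisfy a predicate-only guard (e.g. naive regulatory T
    cells may enter lymph nodes; effectors may not).
    """

    entity_type: str
    from_compartment: str
    to_compartment: str
    state_condition: Optional[str] = None

    def condition_expr(self) -> GuardExpr:
        expr = parse_guard(self.state_condition)
        for atom in expr.atoms():
            if isinstance(atom, (Delta, Lambda)):
                raise AssemblyError(
                    f"migration rule {self.entity_type}: state_condition may "
                    "only use predicate atoms over state labels"
                )
        return expr

    def condition_satisfied(self, agent_state_labels: Sequence[str]) -> bool:
        labels = set(agent_state_labels)
        expr = self.condition_expr()
        env = {}
        for name in expr.predicates():
            bare = name[3:] if name.startswith("in_") else name
            env[name] = bare in labels or name in labels
        return expr.evaluate(env, 0, {}, _NO_RNG)


@dataclass(frozen=True)
class EntityTypeDecl:
    """A declared entity type; molecules occupy per-compartment fields in
    simulation whereas cells are individual agents."""

    name: str
    category: str  # "cell" | "molecule"
    description: str = ""

    def __post_init__(self):
        if self.category not in ENTITY_CATEGORIES:
            raise AssemblyError(
                f"entity {self.name!r}: category must be one of "
                f"{ENTITY_CATEGORIES}, got {self.category!r}"
            )


@dataclass(frozen=True)
class Phenomenon:
    """A real-world observation the modelling effort addresses.  Declaring
    one with ``in_scope=False`` records its existence while asserting it is
    not explained by this model; it must stay unlinked."""

    name: str
    in_scope: bool = True


@dataclass(frozen=True)
class ContextLink:
    source: str
    target: str
    polarity: str = "neutral"  # autoimmune | regulatory | neutral

    def __post_init__(self):
        if self.polarity not in LINK_POLARITIES:
            raise AssemblyError(
                f"link {self.source!r} -> {self.target!r}: polarity must be "
                f"one of {LINK_POLARITIES}"
            )


@dataclass(frozen=True)
class ResearchContext:
    """Top-level informal diagram: phenomena, expected emergent behaviours,
    components, and polarized links between them."""

    phenomena: tuple[Phenomenon, ...] = ()
    expected_behaviours: tuple[str, ...] = ()
    components: tuple[str, ...] = ()  # entity-type references
    links: tuple[ContextLink, ...] = ()


@dataclass(frozen=True)
class BindingDeclaration:
    """Structural declaration of a binding predicate: the guard predicate
    ``predicate`` means 'a partner of type ``partner_entity`` in state
    ``partner_state`` is bound'.  Declared data (not parsed from predicate
    names) so binding feasibility is statically decidable."""

    predicate: str
    partner_entity: str
    partner_state: str


@dataclass(frozen=True)
class DomainModel:
    """Immutable aggregate of the three modelling levels."""

    research_context: ResearchContext
    compartments: tuple[Compartment, ...]
    migration_rules: tuple[MigrationRule, ...]
    entities: tuple[EntityTypeDecl, ...]
    state_machines: Mapping[str, StateMachine]
    perspectives: tuple[Perspective, ...]
    parameters: Mapping[str, float]
    binding_declarations: tuple[BindingDeclaration, ...] = ()

    # -- lookup helpers -----------------------------------------------------

    def compartment_names(self) -> set[str]:
        return {c.name for c in self.compartments}

    def entity_names(self) -> set[str]:
        return {e.name for e in self.entities}

    def entity(self, name: str) -> EntityTypeDecl:
        for e in self.entities:
            if e.name == name:
                return e
        raise KeyError(f"entity type {name!r} is not declared")

    def machine(self, entity_type: str) -> StateMachine:
        return self.state_machines[entity_type]

    def perspective(self, name: str) -> Perspective:
        for p in self.perspectives:
            if p.name == name:
                return p
        raise KeyError(f"perspective {name!r} is not declared")

    def binding(self, predicate: str) -> Optional[BindingDeclaration]:
        for b in self.binding_declarations:
            if b.predicate == predicate:
                return b
        return None

    def molecules(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entities if e.category == "molecule")


def assemble_domain_model(
    context: ResearchContext,
    compartments: Sequence[Compartment],
    migration_rules: Sequence[MigrationRule],
    entities: Sequence[EntityTypeDecl],
    machines: Mapping[str, StateMachine],
    perspectives: Sequence[Perspective],
    parameters: Mapping[str, float],
    binding_declarations: Sequence[BindingDeclaration] = (),
) -> DomainModel:
    """Assemble and integrity-check a domain model.

    Raises :class:`AssemblyError` naming the missing identifier on any
    dangling cross-reference.  Identifiers are case-sensitive exact-match
    strings.
    """
    comp_names = [c.name for c in compartments]
    if len(set(comp_names)) != len(comp_names):
        raise AssemblyError("compartment names must be unique")
    entity_names = [e.name for e in entities]
    if len(set(entity_names)) != len(entity_names):
        raise AssemblyError("entity type names must be unique")
    comp_set, entity_set = set(comp_names), set(entity_names)

    for rule in migration_rules:
        if rule.entity_type not in entity_set:
            raise AssemblyError(
                f"migration rule references undeclared entity type "
                f"{rule.entity_type!r}"
            )
        for comp in (rule.from_compartment, rule.to_compartment):
            if comp not in comp_set:
                raise AssemblyError(
                    f"migration rule for {rule.entity_type!r} references "
                    f"undeclared compartment {comp!r}"
                )
        if rule.from_compartment == rule.to_compartment:
            raise AssemblyError(
                f"migration rule for {rule.entity_type!r}: from and to "
                f"compartments are both {rule.from_compartment!r}"
            )
        rule.condition_expr()  # validates the restricted guard grammar

    for entity_type, machine in machines.items():
        if entity_type not in entity_set:
            raise AssemblyError(
                f"state machine declared for undeclared entity type "
                f"{entity_type!r}"
            )
        if machine.entity_type != entity_type:
            raise AssemblyError(
                f"state machine for {entity_type!r} labels itself "
                f"{machine.entity_type!r}"
            )

    behaviours = set(context.expected_behaviours)
    persp_names = [p.name for p in perspectives]
    if len(set(persp_names)) != len(persp_names):
        raise AssemblyError("perspective names must be unique")
    for p in perspectives:
        for tag in p.expands:
            if tag not in behaviours:
                raise AssemblyError(
                    f"perspective {p.name!r} expands undeclared expected "
                    f"behaviour {tag!r}"
                )

    phen_names = {ph.name for ph in context.phenomena}
    for comp in context.components:
        if comp not in entity_set:
            raise AssemblyError(
                f"research context component {comp!r} is not a declared "
                "entity type"
            )
    declared = phen_names | behaviours | set(context.components)
    out_of_scope = {ph.name for ph in context.phenomena if not ph.in_scope}
    for link in context.links:
        for endpoint in (link.source, link.target):
            if endpoint not in declared:
                raise AssemblyError(
                    f"research context link endpoint {endpoint!r} is not a "
                    "declared phenomenon, behaviour, or component"
                )
        if link.target in out_of_scope:
            raise AssemblyError(
                f"out-of-scope phenomenon {link.target!r} must not acquire "
                "incoming links"
            )

    for b in binding_declarations:
        if b.partner_entity not in entity_set:
            raise AssemblyError(
                f"binding declaration {b.predicate!r} references undeclared "
                f"entity type {b.partner_entity!r}"
            )
        partner_machine = machines.get(b.partner_entity)
        if partner_machine is not None and not partner_machine.has_state(b.partner_state):
            raise AssemblyError(
                f"binding declaration {b.predicate!r}: partner state "
                f"{b.partner_state!r} is not a state of {b.partner_entity!r}"
            )

    return DomainModel(
        research_context=context,
        compartments=tuple(compartments),
        migration_rules=tuple(migration_rules),
        entities=tuple(entities),
        state_machines=dict(machines),
        perspectives=tuple(perspectives),
        parameters=dict(parameters),
        binding_declarations=tuple(binding_declarations),
    )


def migration_allowed(
    model: DomainModel,
    entity_type: str,
    from_compartment: str,
    to_compartment: str,
    agent_state_labels: Sequence[str] = (),
) -> bool:
    """Whether an agent of ``entity_type`` with the given active state
    labels may move between the two compartments.

    Remaining in place (``from == to``) is always allowed; otherwise some
    :class:`MigrationRule` must match and its state condition (if any) must
    be satisfied by the agent's labels.  Undeclared identifiers raise
    ``LookupError``.
    """
    if entity_type not in model.entity_names():
        raise LookupError(f"entity type {entity_type!r} is not declared")
    for comp in (from_compartment, to_compartment):
        if comp not in model.compartment_names():
            raise LookupError(f"compartment {comp!r} is not declared")
    if from_compartment == to_compartment:
        return True
    for rule in model.migration_rules:
        if (
            rule.entity_type == entity_type
            and rule.from_compartment == from_compartment
            and rule.to_compartment == to_compartment
            and rule.condition_satisfied(agent_state_labels)
        ):
            return True
    return False
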