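"""Cross-diagram consistency checking.

Diagrams at the three modelling levels make claims about each other: a
cell's location region names spatial compartments, its migration
transitions imply compartment-graph edges, and a receptor-binding guard is
only meaningful where the binding partner can actually be co-located.  In
a manual modelling exercise these claims are verified by eye, by
cross-referencing the state machines involved; this module makes the
cross-reference executable as a fixed registry of rules.

Rules
-----
R1  every leaf state of a location region names a declared compartment
R2  every transition between location states has a matching migration rule
R3  binding feasibility: a transition guarded by a declared binding
    predicate must not be satisfiable in a compartment its partner entity
    can never reach (static reachability, no simulation)
R4  every expected behaviour is expanded by at least one perspective
R5  every swim-lane annotation names a declared compartment
R6  every activity subject names a declared entity type
R7  out-of-scope phenomena have no incoming links

Violations are reported as data (warnings); a strict caller treats a
non-empty report as an error, since deliberate abstraction can make some
rules inapplicable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

from .core import DomainModel
from .statechart import Region, StateMachine

__all__ = [
    "Violation",
    "ConsistencyReport",
    "check_model",
    "list_rules",
    "RULE_REGISTRY",
]


@dataclass(frozen=True)
class Violation:
    rule_id: str
    locus: str  # element path, e.g. "state_machines/CD8Treg/naive->effector"
    message: str


@dataclass(frozen=True)
class ConsistencyReport:
    violations: tuple[Violation, ...]
    rule_summary: Mapping[str, bool]  # rule id -> passed
    fingerprint: str

    @property
    def passed(self) -> bool:
        return not self.violations

    def by_rule(self, rule_id: str) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.rule_id == rule_id)

    def render_text(self) -> str:
        lines = [f"model fingerprint: {self.fingerprint}"]
        for rule_id, description in RULE_REGISTRY:
            status = "pass" if self.rule_summary[rule_id] else "FAIL"
            lines.append(f"[{status}] {rule_id}: {description}")
        for v in self.violations:
            lines.append(f"  {v.rule_id} at {v.locus}: {v.message}")
        lines.append(
            "result: clean" if self.passed else f"result: {len(self.violations)} violation(s)"
        )
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "fingerprint": self.fingerprint,
            "passed": self.passed,
            "rules": dict(self.rule_summary),
            "violations": [
                {"rule_id": v.rule_id, "locus": v.locus, "message": v.message}
                for v in self.violations
            ],
        }


RULE_REGISTRY: tuple[tuple[str, str], ...] = (
    ("R1", "location-region leaf states name declared compartments"),
    ("R2", "location transitions are backed by matching migration rules"),
    (
        "R3",
        "binding feasibility: binding-guarded transitions are only "
        "satisfiable in compartments the partner entity can reach",
    ),
    ("R4", "every expected behaviour is expanded by at least one perspective"),
    ("R5", "swim-lane annotations name declared compartments"),
    ("R6", "activity subjects name declared entity types"),
    ("R7", "out-of-scope phenomena have no incoming links"),
)


def list_rules() -> tuple[dict, ...]:
    """The rule registry in its stable, documented order."""
    return tuple(
        {"rule_id": rule_id, "description": desc} for rule_id, desc in RULE_REGISTRY
    )


# --------------------------------------------------------------------------
# Static location analysis


def _location_leaves(machine: StateMachine, region: Region) -> set[str]:
    leaves: set[str] = set()
    for top in region.states:
        leaves.update(machine.leaves(top.name))
    return leaves


def reachable_compartments(model: DomainModel, entity_type: str) -> set[str]:
    """Compartments an entity's location region can reach from its initial
    state, following location transitions and the entity's migration rules.

    Entities without a location region are treated as potentially anywhere
    (the model places no spatial constraint on them).
    """
    machine = model.state_machines.get(entity_type)
    region = machine.location_region() if machine is not None else None
    if machine is None or region is None:
        return set(model.compartment_names())
    edges: dict[str, set[str]] = {}
    for t in machine.transitions_in(region):
        for src in machine.leaves(t.source):
            edges.setdefault(src, set()).update(machine.leaves(t.target))
    for rule in model.migration_rules:
        if rule.entity_type == entity_type:
            edges.setdefault(rule.from_compartment, set()).add(rule.to_compartment)
    frontier = set(machine.descend_initial(region.initial)[-1:])
    reachable = set(frontier)
    while frontier:
        nxt = set()
        for leaf in frontier:
            nxt.update(edges.get(leaf, ()))
        frontier = nxt - reachable
        reachable |= frontier
    return reachable


def _guard_satisfiable_at(
    machine: StateMachine, region: Region, guard, compartment: str
) -> bool:
    """Whether a guard can be true for an agent located in ``compartment``.

    Location predicates ``in_X`` (X a state of the location region) are
    fixed by the compartment; everything else, including δ and λ atoms, is
    treated as potentially true.  The guard grammar has no negation, so
    this maximal assignment decides satisfiability exactly.
    """
    fixed: dict[str, bool] = {}
    for top in region.states:
        for name in _region_state_names(machine, top):
            fixed[f"in_{name}"] = compartment in machine.leaves(name)
    return guard.satisfiable(fixed)


def _region_state_names(machine: StateMachine, top) -> list[str]:
    names = [top.name]
    for sub in top.substates:
        names.extend(_region_state_names(machine, sub))
    return names


# --------------------------------------------------------------------------
# The checker


def check_model(model: DomainModel) -> ConsistencyReport:
    """Run the full rule registry against an assembled model."""
    if not isinstance(model, DomainModel):
        raise TypeError("check_model requires an assembled DomainModel")
    violations: list[Violation] = []
    comps = model.compartment_names()
    entities = model.entity_names()

    # R1: location leaves name compartments
    for entity_type, machine in sorted(model.state_machines.items()):
        region = machine.location_region()
        if region is None:
            continue
        for leaf in sorted(_location_leaves(machine, region)):
            if leaf not in comps:
                violations.append(
                    Violation(
                        "R1",
                        f"state_machines/{entity_type}/{region.name}/{leaf}",
                        f"location state {leaf!r} is not a declared compartment",
                    )
                )

    # R2: location transitions backed by migration rules
    rule_index = {
        (r.entity_type, r.from_compartment, r.to_compartment)
        for r in model.migration_rules
    }
    for entity_type, machine in sorted(model.state_machines.items()):
        region = machine.location_region()
        if region is None:
            continue
        for t in machine.transitions_in(region):
            for src in machine.leaves(t.source):
                for dst in machine.leaves(t.target):
                    if src == dst or {src, dst} - comps:
                        continue  # same leaf, or already flagged by R1
                    if (entity_type, src, dst) not in rule_index:
                        violations.append(
                            Violation(
                                "R2",
                                f"state_machines/{entity_type}/{t.source}->{t.target}",
                                f"location transition implies move {src} -> "
                                f"{dst} but no migration rule for "
                                f"{entity_type} permits it",
                            )
                        )

    # R3: binding feasibility by static reachability
    for entity_type, machine in sorted(model.state_machines.items()):
        region = machine.location_region()
        owner_comps = reachable_compartments(model, entity_type)
        for t in machine.transitions:
            for predicate in sorted(t.guard.predicates()):
                binding = model.binding(predicate)
                if binding is None:
                    continue
                partner_comps = reachable_compartments(model, binding.partner_entity)
                for comp in sorted(owner_comps):
                    if region is not None and not _guard_satisfiable_at(
                        machine, region, t.guard, comp
                    ):
                        continue
                    if comp not in partner_comps:
                        violations.append(
                            Violation(
                                "R3",
                                f"state_machines/{entity_type}/{t.source}->{t.target}",
                                f"binding predicate {predicate!r} is "
                                f"satisfiable in {comp} but "
                                f"{binding.partner_entity} in state "
                                f"{binding.partner_state!r} can never be "
                                f"co-located there",
                            )
                        )

    # R4: behaviours expanded by perspectives
    expanded = {tag for p in model.perspectives for tag in p.expands}
    for behaviour in model.research_context.expected_behaviours:
        if behaviour not in expanded:
            violations.append(
                Violation(
                    "R4",
                    f"research_context/expected_behaviours/{behaviour}",
                    f"expected behaviour {behaviour!r} is not expanded by any "
                    "perspective",
                )
            )

    # R5/R6: perspective annotations resolve
    for p in model.perspectives:
        for node in p.nodes:
            if node.swim_lane is not None and node.swim_lane not in comps:
                violations.append(
                    Violation(
                        "R5",
                        f"perspectives/{p.name}/{node.name}",
                        f"swim lane {node.swim_lane!r} is not a declared "
                        "compartment",
                    )
                )
            if node.subject is not None and node.subject not in entities:
                violations.append(
                    Violation(
                        "R6",
                        f"perspectives/{p.name}/{node.name}",
                        f"subject {node.subject!r} is not a declared entity "
                        "type",
                    )
                )

    # R7: out-of-scope phenomena unlinked
    out_of_scope = {
        ph.name for ph in model.research_context.phenomena if not ph.in_scope
    }
    for link in model.research_context.links:
        if link.target in out_of_scope:
            violations.append(
                Violation(
                    "R7",
                    f"research_context/links/{link.source}->{link.target}",
                    f"out-of-scope phenomenon {link.target!r} has an incoming "
                    f"link from {link.source!r}",
                )
            )

    failed = {v.rule_id for v in violations}
    summary = {rule_id: rule_id not in failed for rule_id, _ in RULE_REGISTRY}
    return ConsistencyReport(
        violations=tuple(violations),
        rule_summary=summary,
        fingerprint=model_fingerprint(model),
    )


def model_fingerprint(model: DomainModel) -> str:
    """Stable content hash of the model's serialized document form."""
    from .model_io import model_to_document  # local import: avoids a cycle

    payload = json.dumps(model_to_document(model), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
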