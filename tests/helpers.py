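"""Shared test utilities: seeded random generators for machines, guards and
whole models, and the seeded-defect builders for the consistency matrix."""

from __future__ import annotations

import dataclasses

import numpy as np

from biodomain.activity import ActivityNode, Perspective, SequentialEdge
from biodomain.core import (
    Compartment,
    ContextLink,
    EntityTypeDecl,
    MigrationRule,
    Phenomenon,
    ResearchContext,
    assemble_domain_model,
)
from biodomain.eae import (
    HARM_BEHAVIOUR,
    PROTECTION_PHENOMENON,
    REGULATION_BEHAVIOUR,
    build_eae_model,
)
from biodomain.model_io import document_to_model, model_to_document
from biodomain.statechart import Region, StateMachine, StateNode, Transition

# --------------------------------------------------------------------------
# Random statecharts

GUARD_POOL = (
    "",
    "p1",
    "p2",
    "p1 & p2",
    "p1 | p3",
    "δ(d1)",
    "δ(d2)",
    "λ(t1)",
    "p1 & δ(d1)",
    "λ(t1) | p2",
    "(p1 | p2) & δ(d2)",
)


def random_machine(rng: np.random.Generator, all_delta_zero: bool = False) -> tuple:
    """A random flat multi-region machine plus a parameter table.

    Returns (machine, parameters).  With ``all_delta_zero`` every δ
    parameter is 0 and each state gets at most one outgoing transition
    (competing always-enabled transitions are resolved by the seeded
    uniform tie-break, which is stochastic by design), making execution
    fully deterministic.
    """
    n_regions = int(rng.integers(1, 4))
    regions = []
    transitions = []
    for r in range(n_regions):
        n_states = int(rng.integers(2, 5))
        names = [f"r{r}s{i}" for i in range(n_states)]
        regions.append(
            Region(f"region{r}", tuple(StateNode(n) for n in names), names[0])
        )
        n_trans = int(rng.integers(1, 2 * n_states))
        used_sources: set[str] = set()
        for _ in range(n_trans):
            src, tgt = (str(s) for s in rng.choice(names, size=2))
            guard = GUARD_POOL[int(rng.integers(len(GUARD_POOL)))]
            if all_delta_zero and src in used_sources:
                continue
            if src != tgt or guard:
                transitions.append(Transition.of(src, tgt, guard))
                used_sources.add(src)
    params = {
        "d1": 0.0 if all_delta_zero else float(rng.random()),
        "d2": 0.0 if all_delta_zero else float(rng.random()),
        "t1": int(rng.integers(0, 5)),
    }
    return StateMachine("Rand", tuple(regions), tuple(transitions)), params


def random_env(rng: np.random.Generator, machine: StateMachine) -> dict:
    return {p: bool(rng.random() < 0.5) for p in machine.mentioned_predicates()}


# --------------------------------------------------------------------------
# Random whole models (for serialization fuzzing)


def random_model(rng: np.random.Generator):
    n_comp = int(rng.integers(1, 4))
    comps = [Compartment(f"C{i}", f"compartment {i}") for i in range(n_comp)]
    entities = [
        EntityTypeDecl("Alpha", "cell", "a cell"),
        EntityTypeDecl("Beta", "cell"),
        EntityTypeDecl("Sig", "molecule", "a signal"),
    ][: int(rng.integers(1, 4))]
    rules = []
    if n_comp >= 2 and entities:
        for _ in range(int(rng.integers(0, 4))):
            a, b = rng.choice(n_comp, size=2, replace=False)
            cond = str(rng.choice(["", "in_active", "in_active | resting"]))
            rules.append(
                MigrationRule(
                    entities[0].name, comps[a].name, comps[b].name, cond or None
                )
            )
    machines = {}
    if entities and rng.random() < 0.8:
        machine, _ = random_machine(rng)
        machines[entities[0].name] = dataclasses.replace(
            machine, entity_type=entities[0].name
        )
    behaviours = ("growth",) if rng.random() < 0.7 else ()
    perspectives = []
    if behaviours:
        perspectives.append(
            Perspective(
                name="expansion",
                expands=behaviours,
                nodes=(
                    ActivityNode("go", "start"),
                    ActivityNode("act", "action", swim_lane=comps[0].name),
                ),
                sequential=(SequentialEdge("go", "act"),),
            )
        )
    context = ResearchContext(
        phenomena=(Phenomenon("swelling"), Phenomenon("immunity", in_scope=False)),
        expected_behaviours=behaviours,
        components=tuple(e.name for e in entities),
        links=(
            (ContextLink(behaviours[0], "swelling", "autoimmune"),)
            if behaviours
            else ()
        ),
    )
    params = {
        "d1": float(np.round(rng.random(), 6)),
        "d2": float(np.round(rng.random(), 6)),
        "t1": int(rng.integers(0, 9)),
    }
    return assemble_domain_model(
        context, comps, rules, entities, machines, perspectives, params
    )


# --------------------------------------------------------------------------
# Seeded defects, one per consistency rule


def eae_document() -> dict:
    return model_to_document(build_eae_model())


def defect_r1():
    """Undeclared location state: a 'Thymus' leaf in the DC location region."""
    doc = eae_document()
    for region in doc["state_machines"]["DC"]["regions"]:
        if region["location"]:
            region["states"].append({"name": "Thymus", "kind": "atomic"})
    return document_to_model(doc), "Thymus"


def defect_r2():
    """Location transition with its backing migration rule deleted."""
    doc = eae_document()
    doc["migration_rules"] = [
        r
        for r in doc["migration_rules"]
        if not (
            r["entity_type"] == "DC"
            and r["from_compartment"] == "CNS"
            and r["to_compartment"] == "CLN"
        )
    ]
    return document_to_model(doc), "CNS->CLN"


def defect_r3():
    """CD8Treg priming guard stripped of its lymphoid restriction: the
    TCR:Qa-1:CDR1/2 binding transition becomes satisfiable in Circulation,
    where Qa-1:CDR1/2-expressing DCs are never found."""
    doc = eae_document()
    for t in doc["state_machines"]["CD8Treg"]["transitions"]:
        t["guard"] = t["guard"].replace("in_Lymphoid & ", "")
    return document_to_model(doc), "Circulation"


def defect_r4():
    """Expansion tags deleted, orphaning the regulation behaviour."""
    doc = eae_document()
    for p in doc["perspectives"]:
        if REGULATION_BEHAVIOUR in p["expands"]:
            p["expands"] = [b for b in p["expands"] if b != REGULATION_BEHAVIOUR]
    return document_to_model(doc), REGULATION_BEHAVIOUR


def defect_r5():
    """Swim lane naming an undeclared compartment."""
    doc = eae_document()
    doc["perspectives"][0]["nodes"][1]["swim_lane"] = "Thymus"
    return document_to_model(doc), "Thymus"


def defect_r6():
    """Activity subject naming an undeclared entity type."""
    doc = eae_document()
    doc["perspectives"][0]["nodes"][2]["subject"] = "Unicorn"
    return document_to_model(doc), "Unicorn"


def defect_r7():
    """A link into the out-of-scope protection phenomenon (assembly forbids
    this, so the defect is injected into the assembled aggregate)."""
    model = build_eae_model()
    ctx = model.research_context
    bad = ContextLink(HARM_BEHAVIOUR, PROTECTION_PHENOMENON, "neutral")
    ctx2 = dataclasses.replace(ctx, links=ctx.links + (bad,))
    return dataclasses.replace(model, research_context=ctx2), PROTECTION_PHENOMENON


DEFECTS = {
    "R1": defect_r1,
    "R2": defect_r2,
    "R3": defect_r3,
    "R4": defect_r4,
    "R5": defect_r5,
    "R6": defect_r6,
    "R7": defect_r7,
}
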