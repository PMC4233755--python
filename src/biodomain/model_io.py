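"""Model-document serialization, schema validation, and DOT rendering.

The interchange format is a versioned JSON document (YAML is accepted as a
1:1 surface syntax) with sections mirroring the three modelling levels:
``compartments``, ``migration_rules``, ``entities``, ``state_machines``,
``perspectives``, ``research_context``, ``parameters`` and
``binding_declarations``.  Guards are stored as text in the δ/λ grammar
(ASCII ``delta``/``lambda`` accepted); loading funnels through
:func:`~biodomain.core.assemble_domain_model`, so integrity errors surface
identically whether a model is built in code or loaded from disk.

Documents are validated against :data:`MODEL_DOCUMENT_SCHEMA` (shipped as
``data/model_schema.json``); violations carry a JSON-pointer path to the
offending element.  Rendering emits deterministic GraphViz DOT text —
byte-identical for identical models — with swim lanes and composite states
as clusters, interrupt relationships drawn through mid-edge anchor points,
propagating edges dashed with an open arrowhead, and contributory edges
dotted with a circle arrowhead (legend comments are embedded in the
output).
"""

from __future__ import annotations

import json
from typing import Any, Mapping, Optional

import yaml

from .activity import (
    ActivityNode,
    ContributoryEdge,
    InterruptEdge,
    Perspective,
    PropagatingEdge,
    SequentialEdge,
)
from .core import (
    BindingDeclaration,
    Compartment,
    ContextLink,
    DomainModel,
    EntityTypeDecl,
    MigrationRule,
    Phenomenon,
    ResearchContext,
    assemble_domain_model,
)
from .statechart import Region, StateMachine, StateNode, Transition

__all__ = [
    "MODEL_DOCUMENT_SCHEMA",
    "DocumentParseError",
    "SchemaViolation",
    "load_model",
    "save_model",
    "model_to_document",
    "document_to_model",
    "validate_document",
    "render_dot",
]

DOCUMENT_VERSION = 1


class DocumentParseError(ValueError):
    """The document text is not parseable; carries a location string."""

    def __init__(self, message: str, location: str = ""):
        super().__init__(f"{message}{f' ({location})' if location else ''}")
        self.location = location


class SchemaViolation(ValueError):
    """The document violates the schema; carries a JSON pointer."""

    def __init__(self, message: str, pointer: str):
        super().__init__(f"{message} (at {pointer or '/'})")
        self.pointer = pointer or "/"


# --------------------------------------------------------------------------
# Schema (a compact JSON-Schema subset, checked by validate_document)

_STATE_SCHEMA: dict = {
    "type": "object",
    "required": {"name": {"type": "string"}},
    "optional": {
        "kind": {"type": "string", "enum": ["atomic", "composite", "isolated"]},
        "initial": {"type": "string"},
        "entry_actions": {"type": "array", "items": {"type": "string"}},
        "exit_actions": {"type": "array", "items": {"type": "string"}},
        "emissions": {"type": "array", "items": {"type": "string"}},
    },
}
_STATE_SCHEMA["optional"]["substates"] = {"type": "array", "items": _STATE_SCHEMA}

MODEL_DOCUMENT_SCHEMA: dict = {
    "type": "object",
    "required": {
        "version": {"type": "integer"},
        "compartments": {
            "type": "array",
            "items": {
                "type": "object",
                "required": {"name": {"type": "string"}},
                "optional": {"description": {"type": "string"}},
            },
        },
        "migration_rules": {
            "type": "array",
            "items": {
                "type": "object",
                "required": {
                    "entity_type": {"type": "string"},
                    "from_compartment": {"type": "string"},
                    "to_compartment": {"type": "string"},
                },
                "optional": {"state_condition": {"type": ["string", "null"]}},
            },
        },
        "entities": {
            "type": "array",
            "items": {
                "type": "object",
                "required": {
                    "name": {"type": "string"},
                    "category": {"type": "string", "enum": ["cell", "molecule"]},
                },
                "optional": {"description": {"type": "string"}},
            },
        },
        "state_machines": {
            "type": "object",
            "values": {
                "type": "object",
                "required": {
                    "regions": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {
                                "name": {"type": "string"},
                                "initial": {"type": "string"},
                                "states": {"type": "array", "items": _STATE_SCHEMA},
                            },
                            "optional": {"location": {"type": "boolean"}},
                        },
                    },
                },
                "optional": {
                    "transitions": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {
                                "source": {"type": "string"},
                                "target": {"type": "string"},
                            },
                            "optional": {
                                "guard": {"type": "string"},
                                "actions": {"type": "array", "items": {"type": "string"}},
                            },
                        },
                    },
                },
            },
        },
        "perspectives": {
            "type": "array",
            "items": {
                "type": "object",
                "required": {
                    "name": {"type": "string"},
                    "nodes": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {"name": {"type": "string"}},
                            "optional": {
                                "kind": {
                                    "type": "string",
                                    "enum": [
                                        "start", "action", "decision", "merge",
                                        "fork", "join", "end",
                                    ],
                                },
                                "swim_lane": {"type": ["string", "null"]},
                                "subject": {"type": ["string", "null"]},
                            },
                        },
                    },
                },
                "optional": {
                    "expands": {"type": "array", "items": {"type": "string"}},
                    "sequential": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {
                                "source": {"type": "string"},
                                "target": {"type": "string"},
                            },
                            "optional": {"dwell": {"type": ["string", "null"]}},
                        },
                    },
                    "propagating": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {
                                "source": {"type": "string"},
                                "target": {"type": "string"},
                                "spawn_rate": {"type": "string"},
                            },
                        },
                    },
                    "interrupts": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {
                                "interrupter": {"type": "string"},
                                "target": {"type": "string"},
                                "degree": {"type": "string"},
                            },
                        },
                    },
                    "contributory": {
                        "type": "array",
                        "items": {
                            "type": "object",
                            "required": {
                                "source": {"type": "string"},
                                "target": {"type": "string"},
                                "weight_shift": {"type": "object", "values": {"type": "number"}},
                            },
                        },
                    },
                },
            },
        },
        "research_context": {
            "type": "object",
            "required": {},
            "optional": {
                "phenomena": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": {"name": {"type": "string"}},
                        "optional": {"in_scope": {"type": "boolean"}},
                    },
                },
                "expected_behaviours": {"type": "array", "items": {"type": "string"}},
                "components": {"type": "array", "items": {"type": "string"}},
                "links": {
                    "type": "array",
                    "items": {
                        "type": "object",
                        "required": {
                            "source": {"type": "string"},
                            "target": {"type": "string"},
                        },
                        "optional": {
                            "polarity": {
                                "type": "string",
                                "enum": ["autoimmune", "regulatory", "neutral"],
                            },
                        },
                    },
                },
            },
        },
        "parameters": {"type": "object", "values": {"type": "number"}},
    },
    "optional": {
        "binding_declarations": {
            "type": "array",
            "items": {
                "type": "object",
                "required": {
                    "predicate": {"type": "string"},
                    "partner_entity": {"type": "string"},
                    "partner_state": {"type": "string"},
                },
            },
        },
    },
}

def schema_as_json() -> str:
    """The schema as JSON text, with the recursive state definition
    expressed as a ``$ref`` (the in-memory dict is self-referential)."""

    def convert(node, expand_state=False):
        if node is _STATE_SCHEMA and not expand_state:
            return {"$ref": "#/definitions/state"}
        if isinstance(node, dict):
            return {k: convert(v) for k, v in node.items()}
        if isinstance(node, list):
            return [convert(v) for v in node]
        return node

    document = {
        "definitions": {"state": convert(_STATE_SCHEMA, expand_state=True)},
        **{k: convert(v) for k, v in MODEL_DOCUMENT_SCHEMA.items()},
    }
    return json.dumps(document, indent=2) + "\n"


_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "string": lambda v: isinstance(v, str),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "null": lambda v: v is None,
}


def _check(value: Any, schema: Mapping, pointer: str, errors: list[SchemaViolation]):
    types = schema.get("type")
    if types is not None:
        allowed = [types] if isinstance(types, str) else list(types)
        if not any(_TYPE_CHECKS[t](value) for t in allowed):
            errors.append(
                SchemaViolation(
                    f"expected {' or '.join(allowed)}, got {type(value).__name__}",
                    pointer,
                )
            )
            return
    if "enum" in schema and value not in schema["enum"]:
        errors.append(
            SchemaViolation(f"value {value!r} not in {schema['enum']}", pointer)
        )
        return
    if isinstance(value, dict):
        for key, sub in schema.get("required", {}).items():
            if key not in value:
                errors.append(
                    SchemaViolation(f"missing required key {key!r}", f"{pointer}/{key}")
                )
            else:
                _check(value[key], sub, f"{pointer}/{key}", errors)
        for key, sub in schema.get("optional", {}).items():
            if key in value:
                _check(value[key], sub, f"{pointer}/{key}", errors)
        if "values" in schema:
            for key, item in value.items():
                _check(item, schema["values"], f"{pointer}/{key}", errors)
    elif isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], f"{pointer}/{i}", errors)


def validate_document(document: Mapping) -> list[SchemaViolation]:
    """All schema violations in the document (empty list iff valid)."""
    errors: list[SchemaViolation] = []
    _check(document, MODEL_DOCUMENT_SCHEMA, "", errors)
    return errors


# --------------------------------------------------------------------------
# DomainModel <-> document


def _state_to_dict(node: StateNode) -> dict:
    out: dict = {"name": node.name, "kind": node.kind}
    if node.kind == "composite":
        out["substates"] = [_state_to_dict(s) for s in node.substates]
        out["initial"] = node.initial
    if node.entry_actions:
        out["entry_actions"] = list(node.entry_actions)
    if node.exit_actions:
        out["exit_actions"] = list(node.exit_actions)
    if node.emissions:
        out["emissions"] = list(node.emissions)
    return out


def _state_from_dict(d: Mapping) -> StateNode:
    return StateNode(
        name=d["name"],
        kind=d.get("kind", "atomic"),
        substates=tuple(_state_from_dict(s) for s in d.get("substates", [])),
        initial=d.get("initial"),
        entry_actions=tuple(d.get("entry_actions", [])),
        exit_actions=tuple(d.get("exit_actions", [])),
        emissions=tuple(d.get("emissions", [])),
    )


def model_to_document(model: DomainModel) -> dict:
    """The model's canonical document form (plain JSON-able dict)."""
    return {
        "version": DOCUMENT_VERSION,
        "compartments": [
            {"name": c.name, "description": c.description} for c in model.compartments
        ],
        "migration_rules": [
            {
                "entity_type": r.entity_type,
                "from_compartment": r.from_compartment,
                "to_compartment": r.to_compartment,
                "state_condition": r.state_condition,
            }
            for r in model.migration_rules
        ],
        "entities": [
            {"name": e.name, "category": e.category, "description": e.description}
            for e in model.entities
        ],
        "state_machines": {
            entity_type: {
                "regions": [
                    {
                        "name": region.name,
                        "initial": region.initial,
                        "location": region.location,
                        "states": [_state_to_dict(s) for s in region.states],
                    }
                    for region in machine.regions
                ],
                "transitions": [
                    {
                        "source": t.source,
                        "target": t.target,
                        "guard": str(t.guard),
                        "actions": list(t.actions),
                    }
                    for t in machine.transitions
                ],
            }
            for entity_type, machine in sorted(model.state_machines.items())
        },
        "perspectives": [
            {
                "name": p.name,
                "expands": list(p.expands),
                "nodes": [
                    {
                        "name": n.name,
                        "kind": n.kind,
                        "swim_lane": n.swim_lane,
                        "subject": n.subject,
                    }
                    for n in p.nodes
                ],
                "sequential": [
                    {"source": e.source, "target": e.target, "dwell": e.dwell}
                    for e in p.sequential
                ],
                "propagating": [
                    {"source": e.source, "target": e.target, "spawn_rate": e.spawn_rate}
                    for e in p.propagating
                ],
                "interrupts": [
                    {"interrupter": e.interrupter, "target": e.target, "degree": e.degree}
                    for e in p.interrupts
                ],
                "contributory": [
                    {
                        "source": e.source,
                        "target": e.target,
                        "weight_shift": dict(e.weight_shift),
                    }
                    for e in p.contributory
                ],
            }
            for p in model.perspectives
        ],
        "research_context": {
            "phenomena": [
                {"name": ph.name, "in_scope": ph.in_scope}
                for ph in model.research_context.phenomena
            ],
            "expected_behaviours": list(model.research_context.expected_behaviours),
            "components": list(model.research_context.components),
            "links": [
                {"source": l.source, "target": l.target, "polarity": l.polarity}
                for l in model.research_context.links
            ],
        },
        "parameters": dict(sorted(model.parameters.items())),
        "binding_declarations": [
            {
                "predicate": b.predicate,
                "partner_entity": b.partner_entity,
                "partner_state": b.partner_state,
            }
            for b in model.binding_declarations
        ],
    }


def document_to_model(document: Mapping) -> DomainModel:
    """Build and assemble a model from a validated document dict."""
    errors = validate_document(document)
    if errors:
        raise errors[0]
    machines = {}
    for entity_type, md in document["state_machines"].items():
        machines[entity_type] = StateMachine(
            entity_type=entity_type,
            regions=tuple(
                Region(
                    name=rd["name"],
                    states=tuple(_state_from_dict(s) for s in rd["states"]),
                    initial=rd["initial"],
                    location=rd.get("location", False),
                )
                for rd in md["regions"]
            ),
            transitions=tuple(
                Transition.of(
                    td["source"], td["target"], td.get("guard", ""),
                    td.get("actions", []),
                )
                for td in md.get("transitions", [])
            ),
        )
    perspectives = tuple(
        Perspective(
            name=pd["name"],
            expands=tuple(pd.get("expands", [])),
            nodes=tuple(
                ActivityNode(
                    nd["name"], nd.get("kind", "action"),
                    nd.get("swim_lane"), nd.get("subject"),
                )
                for nd in pd["nodes"]
            ),
            sequential=tuple(
                SequentialEdge(ed["source"], ed["target"], ed.get("dwell"))
                for ed in pd.get("sequential", [])
            ),
            propagating=tuple(
                PropagatingEdge(ed["source"], ed["target"], ed["spawn_rate"])
                for ed in pd.get("propagating", [])
            ),
            interrupts=tuple(
                InterruptEdge(ed["interrupter"], ed["target"], ed["degree"])
                for ed in pd.get("interrupts", [])
            ),
            contributory=tuple(
                ContributoryEdge(ed["source"], ed["target"], ed["weight_shift"])
                for ed in pd.get("contributory", [])
            ),
        )
        for pd in document["perspectives"]
    )
    ctx = document["research_context"]
    context = ResearchContext(
        phenomena=tuple(
            Phenomenon(pd["name"], pd.get("in_scope", True))
            for pd in ctx.get("phenomena", [])
        ),
        expected_behaviours=tuple(ctx.get("expected_behaviours", [])),
        components=tuple(ctx.get("components", [])),
        links=tuple(
            ContextLink(ld["source"], ld["target"], ld.get("polarity", "neutral"))
            for ld in ctx.get("links", [])
        ),
    )
    return assemble_domain_model(
        context=context,
        compartments=[
            Compartment(cd["name"], cd.get("description", ""))
            for cd in document["compartments"]
        ],
        migration_rules=[
            MigrationRule(
                rd["entity_type"], rd["from_compartment"], rd["to_compartment"],
                rd.get("state_condition"),
            )
            for rd in document["migration_rules"]
        ],
        entities=[
            EntityTypeDecl(ed["name"], ed["category"], ed.get("description", ""))
            for ed in document["entities"]
        ],
        machines=machines,
        perspectives=perspectives,
        parameters=dict(document["parameters"]),
        binding_declarations=[
            BindingDeclaration(bd["predicate"], bd["partner_entity"], bd["partner_state"])
            for bd in document.get("binding_declarations", [])
        ],
    )


def load_model(document_text: str) -> DomainModel:
    """Parse (JSON, or YAML as fallback surface syntax), validate, and
    assemble a model document."""
    try:
        document = json.loads(document_text)
    except json.JSONDecodeError as json_err:
        stripped = document_text.lstrip()
        if stripped.startswith(("{", "[")):
            raise DocumentParseError(
                json_err.msg, f"line {json_err.lineno}, column {json_err.colno}"
            ) from None
        try:
            document = yaml.safe_load(document_text)
        except yaml.YAMLError as yaml_err:
            mark = getattr(yaml_err, "problem_mark", None)
            location = (
                f"line {mark.line + 1}, column {mark.column + 1}" if mark else ""
            )
            raise DocumentParseError(str(yaml_err).splitlines()[0], location) from None
    if not isinstance(document, dict):
        raise DocumentParseError("document root must be an object")
    return document_to_model(document)


def save_model(model: DomainModel) -> str:
    """Canonical JSON text; byte-stable for a given model."""
    return json.dumps(model_to_document(model), indent=2, sort_keys=True) + "\n"


# --------------------------------------------------------------------------
# DOT rendering


def _q(name: str) -> str:
    return '"' + name.replace('"', r"\"") + '"'


def _render_machine(model: DomainModel, entity_type: str) -> str:
    machine = model.state_machines[entity_type]
    lines = [
        f"digraph {_q(entity_type)} {{",
        "  compound=true;",
        "  rankdir=LR;",
        '  node [shape=box, style=rounded];',
    ]
    anchors: dict[str, str] = {}  # composite name -> representative leaf

    def emit_state(node: StateNode, indent: str, cluster_path: str):
        if node.kind == "composite":
            lines.append(f"{indent}subgraph {_q('cluster_' + node.name)} {{")
            lines.append(f"{indent}  label={_q(node.name)};")
            for sub in node.substates:
                emit_state(sub, indent + "  ", cluster_path + "/" + node.name)
            lines.append(f"{indent}}}")
            anchors[node.name] = machine.leaves(node.name)[0]
        else:
            shape = "box" if node.kind == "atomic" else "component"
            lines.append(f"{indent}{_q(node.name)} [shape={shape}];")
            anchors[node.name] = node.name

    for region in machine.regions:
        lines.append(f"  subgraph {_q('cluster_region_' + region.name)} {{")
        label = region.name + (" (location)" if region.location else "")
        lines.append(f"    label={_q(label)};")
        lines.append("    style=dashed;")
        for top in region.states:
            emit_state(top, "    ", region.name)
        lines.append("  }")
    for t in machine.transitions:
        attrs = []
        guard = str(t.guard)
        if guard:
            attrs.append(f"label={_q('[' + guard + ']')}")
        if machine.state(t.source).kind == "composite":
            attrs.append(f"ltail={_q('cluster_' + t.source)}")
        if machine.state(t.target).kind == "composite":
            attrs.append(f"lhead={_q('cluster_' + t.target)}")
        attr_text = f" [{', '.join(attrs)}]" if attrs else ""
        lines.append(
            f"  {_q(anchors[t.source])} -> {_q(anchors[t.target])}{attr_text};"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


_KIND_ATTRS = {
    "start": "shape=circle, style=filled, fillcolor=black, label=\"\", width=0.15",
    "end": "shape=doublecircle, style=filled, fillcolor=black, label=\"\", width=0.12",
    "decision": "shape=diamond",
    "merge": "shape=diamond, style=filled, fillcolor=lightgrey",
    "fork": "shape=box, style=filled, fillcolor=black, height=0.08, label=\"\"",
    "join": "shape=box, style=filled, fillcolor=black, height=0.08, label=\"\"",
    "action": "shape=box, style=rounded",
}


def _render_perspective(model: DomainModel, name: str) -> str:
    p = model.perspective(name)
    lines = [
        f"digraph {_q(name)} {{",
        "  // legend: dashed/vee = propagating (spawns tokens, source",
        "  // continues); tee via anchor dot = interrupting (blocks the",
        "  // anchored edge); dotted/odot = contributory (shifts decision",
        "  // weights)",
        '  node [shape=box, style=rounded];',
    ]
    lanes: dict[Optional[str], list[ActivityNode]] = {}
    for node in p.nodes:
        lanes.setdefault(node.swim_lane, []).append(node)
    for lane in sorted(lanes, key=lambda x: (x is None, x or "")):
        nodes = lanes[lane]
        if lane is not None:
            lines.append(f"  subgraph {_q('cluster_lane_' + lane)} {{")
            lines.append(f"    label={_q(lane)};")
            lines.append("    style=dotted;")
            indent = "    "
        else:
            indent = "  "
        for node in nodes:
            attrs = _KIND_ATTRS.get(node.kind, "shape=box")
            if node.subject and node.kind == "action":
                attrs += f", xlabel={_q(node.subject)}"
            lines.append(f"{indent}{_q(node.name)} [{attrs}];")
        if lane is not None:
            lines.append("  }")
    interrupted = {i.target for i in p.interrupts}
    for e in p.sequential:
        if e.ident in interrupted:
            anchor = f"anchor:{e.ident}"
            lines.append(
                f"  {_q(anchor)} [shape=point, width=0.05, label=\"\"];"
            )
            lines.append(f"  {_q(e.source)} -> {_q(anchor)} [arrowhead=none];")
            lines.append(f"  {_q(anchor)} -> {_q(e.target)};")
        else:
            lines.append(f"  {_q(e.source)} -> {_q(e.target)};")
    for e in p.propagating:
        lines.append(
            f"  {_q(e.source)} -> {_q(e.target)} "
            f"[style=dashed, arrowhead=vee, label={_q(e.spawn_rate)}];"
        )
    for i in p.interrupts:
        anchor = f"anchor:{i.target}"
        lines.append(
            f"  {_q(i.interrupter)} -> {_q(anchor)} "
            f"[arrowhead=tee, color=red, label={_q(i.degree)}];"
        )
    for c in p.contributory:
        lines.append(
            f"  {_q(c.source)} -> {_q(c.target)} [style=dotted, arrowhead=odot];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


_POLARITY_ATTRS = {
    "autoimmune": "color=red",
    "regulatory": "color=blue, style=dashed",
    "neutral": "color=grey",
}


def _render_context(model: DomainModel) -> str:
    ctx = model.research_context
    lines = [
        "digraph research_context {",
        "  // legend: red = interactions leading to autoimmunity; dashed",
        "  // blue = regulatory activity countering it; grey = neutral;",
        "  // dashed phenomenon boxes are declared out of scope (unlinked)",
        "  rankdir=BT;",
        '  node [shape=box];',
    ]
    for ph in ctx.phenomena:
        style = "style=dashed" if not ph.in_scope else "style=solid"
        lines.append(f"  {_q(ph.name)} [{style}, shape=box, peripheries=2];")
    for b in ctx.expected_behaviours:
        lines.append(f"  {_q(b)} [shape=box, style=rounded];")
    for comp in ctx.components:
        lines.append(f"  {_q(comp)} [shape=ellipse];")
    for link in ctx.links:
        lines.append(
            f"  {_q(link.source)} -> {_q(link.target)} "
            f"[{_POLARITY_ATTRS[link.polarity]}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _render_compartments(model: DomainModel) -> str:
    lines = ["digraph compartments {", '  node [shape=box];']
    for comp in model.compartments:
        lines.append(f"  {_q(comp.name)};")
    edges: dict[tuple[str, str], list[str]] = {}
    for rule in model.migration_rules:
        edges.setdefault(
            (rule.from_compartment, rule.to_compartment), []
        ).append(rule.entity_type)
    for (frm, to) in sorted(edges):
        label = ", ".join(sorted(set(edges[(frm, to)])))
        lines.append(f"  {_q(frm)} -> {_q(to)} [label={_q(label)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_dot(model: DomainModel, element_selector: str) -> str:
    """Render one model element as GraphViz DOT text.

    Selectors: ``compartments``, ``context``, ``machine:<EntityType>``,
    ``perspective:<Name>``.  Output is deterministic for a fixed model.
    """
    if element_selector == "compartments":
        return _render_compartments(model)
    if element_selector == "context":
        return _render_context(model)
    if element_selector.startswith("machine:"):
        entity_type = element_selector[len("machine:"):]
        if entity_type not in model.state_machines:
            raise KeyError(f"no state machine for {entity_type!r}")
        return _render_machine(model, entity_type)
    if element_selector.startswith("perspective:"):
        name = element_selector[len("perspective:"):]
        model.perspective(name)  # raises KeyError for unknown names
        return _render_perspective(model, name)
    raise KeyError(f"unknown selector {element_selector!r}")
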