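"""Perspectives: mid-level activity networks and their token-flow execution.

A :class:`Perspective` decomposes one expected system-level behaviour into a
network of cellular activities.  Beyond ordinary sequential edges the
network supports three extended relationships tailored to population
biology:

* **propagating** — a source activity repeatedly spawns new tokens of
  execution at a target (cell proliferation, cytokine secretion) without
  itself terminating; spawning stops the moment the source activity does;
* **interrupting** — an active interrupter partially or fully blocks
  traversal of one sequential edge (regulatory killing, suppression), with
  a blocking degree in [0, 1];
* **contributory** — an active source shifts the branch weights of a
  decision node (cytokine balance biasing antigen-presenting-cell
  polarization) without being consumed by the routings it influences.

Execution is discrete-time.  Each step works from a start-of-step snapshot
of token positions: tokens whose per-edge dwell has elapsed traverse
sequential edges (duplicating along multiple outgoing edges — an implicit
fork), decision nodes route single tokens along weighted branches, join
nodes synchronize, propagating edges add Poisson-distributed spawn counts,
and tokens reaching end nodes are consumed.  Perspectives are typically
cyclic and need no end nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityNode",
    "SequentialEdge",
    "PropagatingEdge",
    "InterruptEdge",
    "ContributoryEdge",
    "Perspective",
    "FlowState",
    "FlowRunResult",
    "FlowEvaluationError",
    "validate_perspective",
    "initial_flow_state",
    "step_flow",
    "run_flow",
]

NODE_KINDS = ("start", "action", "decision", "merge", "fork", "join", "end")


class FlowEvaluationError(KeyError):
    """An execution parameter failed to resolve."""


@dataclass(frozen=True)
class ActivityNode:
    name: str
    kind: str = "action"
    swim_lane: Optional[str] = None  # compartment annotation
    subject: Optional[str] = None  # entity type carrying out the activity


@dataclass(frozen=True)
class SequentialEdge:
    source: str
    target: str
    dwell: Optional[str] = None  # parameter name; default dwell is 1 step

    @property
    def ident(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class PropagatingEdge:
    source: str
    target: str
    spawn_rate: str  # parameter name: expected spawns per source token/step

    @property
    def ident(self) -> str:
        return f"{self.source}~>{self.target}"


@dataclass(frozen=True)
class InterruptEdge:
    interrupter: str  # node whose activity blocks the target edge
    target: str  # a SequentialEdge ident, "source->target"
    degree: str  # parameter name in [0, 1]; 1 blocks fully


@dataclass(frozen=True)
class ContributoryEdge:
    source: str
    target: str  # a decision node
    weight_shift: Mapping[str, float]  # branch-target node -> signed shift

    def __post_init__(self):
        object.__setattr__(self, "weight_shift", dict(self.weight_shift))


@dataclass(frozen=True)
class Perspective:
    name: str
    expands: tuple[str, ...] = ()  # expected-behaviour names
    nodes: tuple[ActivityNode, ...] = ()
    sequential: tuple[SequentialEdge, ...] = ()
    propagating: tuple[PropagatingEdge, ...] = ()
    interrupts: tuple[InterruptEdge, ...] = ()
    contributory: tuple[ContributoryEdge, ...] = ()

    def node(self, name: str) -> ActivityNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def outgoing(self, name: str) -> tuple[SequentialEdge, ...]:
        return tuple(e for e in self.sequential if e.source == name)

    def incoming(self, name: str) -> tuple[SequentialEdge, ...]:
        return tuple(e for e in self.sequential if e.target == name)


def validate_perspective(perspective: Perspective) -> list[str]:
    """Structural validation; returns a list of human-readable issues
    (empty iff the perspective satisfies every type invariant)."""
    issues: list[str] = []
    names = [n.name for n in perspective.nodes]
    known = set(names)
    if len(known) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        issues.append(f"duplicate node names: {', '.join(dupes)}")
    for node in perspective.nodes:
        if node.kind not in NODE_KINDS:
            issues.append(f"node {node.name!r}: unknown kind {node.kind!r}")
    if not any(n.kind == "start" for n in perspective.nodes):
        issues.append(
            f"perspective {perspective.name!r}: no start node (at least one "
            "start state is required to facilitate exploration)"
        )
    for e in perspective.sequential:
        for endpoint in (e.source, e.target):
            if endpoint not in known:
                issues.append(f"sequential edge {e.ident}: unknown node {endpoint!r}")
    for node in perspective.nodes:
        if node.kind == "start" and perspective.incoming(node.name):
            issues.append(f"start node {node.name!r} has incoming sequential edges")
        if node.kind == "end" and perspective.outgoing(node.name):
            issues.append(f"end node {node.name!r} has outgoing edges")
        if node.kind == "decision" and len(perspective.outgoing(node.name)) < 2:
            issues.append(
                f"decision node {node.name!r} has fewer than 2 outgoing "
                "sequential edges"
            )
    seq_ids = {e.ident for e in perspective.sequential}
    for p in perspective.propagating:
        for endpoint in (p.source, p.target):
            if endpoint not in known:
                issues.append(f"propagating edge {p.ident}: unknown node {endpoint!r}")
    for i in perspective.interrupts:
        if i.interrupter not in known:
            issues.append(f"interrupt by {i.interrupter!r}: unknown node")
        if i.target not in seq_ids:
            issues.append(
                f"interrupt by {i.interrupter!r}: target edge {i.target!r} "
                "does not exist"
            )
    for c in perspective.contributory:
        if c.source not in known:
            issues.append(f"contributory edge from {c.source!r}: unknown node")
        if c.target not in known:
            issues.append(f"contributory edge to {c.target!r}: unknown node")
            continue
        target = perspective.node(c.target)
        if target.kind != "decision":
            issues.append(
                f"contributory edge {c.source!r} -> {c.target!r}: target is a "
                f"{target.kind} node, not a decision"
            )
            continue
        branches = {e.target for e in perspective.outgoing(c.target)}
        for branch in c.weight_shift:
            if branch not in branches:
                issues.append(
                    f"contributory edge {c.source!r} -> {c.target!r}: branch "
                    f"{branch!r} is not an outgoing edge of the decision"
                )
    return issues


# --------------------------------------------------------------------------
# Execution


@dataclass
class _Token:
    age: int = 0
    via: Optional[str] = None  # arrival edge ident (joins synchronize on it)


@dataclass
class FlowState:
    """Multiset of execution tokens per node, with per-token ages and
    cumulative firing counts per edge."""

    tokens: dict[str, list[_Token]] = field(default_factory=dict)
    firing_counts: dict[str, int] = field(default_factory=dict)
    step: int = 0

    def counts(self) -> dict[str, int]:
        return {node: len(toks) for node, toks in self.tokens.items() if toks}

    def total_tokens(self) -> int:
        return sum(len(toks) for toks in self.tokens.values())

    def copy(self) -> "FlowState":
        return FlowState(
            {n: [_Token(t.age, t.via) for t in toks] for n, toks in self.tokens.items()},
            dict(self.firing_counts),
            self.step,
        )


def initial_flow_state(initial_tokens: Mapping[str, int]) -> FlowState:
    tokens = {
        node: [_Token() for _ in range(count)]
        for node, count in initial_tokens.items()
        if count
    }
    return FlowState(tokens=tokens)


def _param(parameters: Mapping[str, float], name: Optional[str], default: float) -> float:
    if name is None:
        return default
    try:
        return float(parameters[name])
    except KeyError:
        raise FlowEvaluationError(
            f"parameter {name!r} is not in the parameter table"
        ) from None


def step_flow(
    perspective: Perspective,
    flow_state: FlowState,
    parameters: Mapping[str, float],
    rng: np.random.Generator,
) -> FlowState:
    """Advance the token flow by one step (see module docstring).

    All eligibility, interrupter-activity, and contributory-activity checks
    read the start-of-step snapshot, so within-step movements never
    influence one another.
    """
    state = flow_state.copy()
    state.step += 1
    for toks in state.tokens.values():
        for tok in toks:
            tok.age += 1
    snapshot_counts = state.counts()  # after aging, before any movement

    def edge_pass_probability(edge: SequentialEdge) -> float:
        prob = 1.0
        for interrupt in perspective.interrupts:
            if interrupt.target == edge.ident and snapshot_counts.get(interrupt.interrupter, 0) > 0:
                degree = _param(parameters, interrupt.degree, 0.0)
                prob *= 1.0 - degree
        return prob

    arrivals: list[tuple[str, _Token]] = []

    def traverse(edge: SequentialEdge) -> None:
        state.firing_counts[edge.ident] = state.firing_counts.get(edge.ident, 0) + 1
        arrivals.append((edge.target, _Token(age=0, via=edge.ident)))

    for node in perspective.nodes:
        waiting = state.tokens.get(node.name, [])
        if not waiting:
            continue
        if node.kind == "end":
            continue  # consumed below
        outgoing = perspective.outgoing(node.name)
        if not outgoing:
            continue
        if node.kind == "decision":
            staying: list[_Token] = []
            for tok in waiting:
                branches = [e for e in outgoing if tok.age >= _param(parameters, e.dwell, 1.0)]
                if not branches:
                    staying.append(tok)
                    continue
                weights = []
                for e in branches:
                    w = 1.0
                    for c in perspective.contributory:
                        if c.target == node.name and snapshot_counts.get(c.source, 0) > 0:
                            w += c.weight_shift.get(e.target, 0.0)
                    weights.append(max(w, 0.0))
                total = sum(weights)
                if total <= 0.0:
                    staying.append(tok)
                    continue
                choice = branches[int(rng.choice(len(branches), p=np.asarray(weights) / total))]
                if rng.random() < edge_pass_probability(choice):
                    traverse(choice)
                else:
                    staying.append(tok)
            state.tokens[node.name] = staying
        elif node.kind == "join":
            incoming_ids = [e.ident for e in perspective.incoming(node.name)]
            merged = [tok for tok in waiting if tok.via is None]
            by_branch = {
                ident: [tok for tok in waiting if tok.via == ident]
                for ident in incoming_ids
            }
            n_complete = min((len(v) for v in by_branch.values()), default=0)
            for ident in incoming_ids:
                del by_branch[ident][:n_complete]
            emitted = [_Token(age=0, via=None) for _ in range(n_complete)]
            # merged tokens whose dwell has elapsed move on like an action
            staying = []
            for tok in merged:
                moved = False
                for e in outgoing:
                    if tok.age >= _param(parameters, e.dwell, 1.0) and rng.random() < edge_pass_probability(e):
                        traverse(e)
                        moved = True
                if not moved:
                    staying.append(tok)
            state.tokens[node.name] = (
                staying + [t for toks in by_branch.values() for t in toks] + emitted
            )
        else:  # start, action, merge, fork
            staying = []
            for tok in waiting:
                moved = False
                for e in outgoing:
                    if tok.age >= _param(parameters, e.dwell, 1.0) and rng.random() < edge_pass_probability(e):
                        traverse(e)
                        moved = True
                if not moved:
                    staying.append(tok)
            state.tokens[node.name] = staying

    # propagating edges spawn from the start-of-step snapshot; the source
    # tokens themselves are never moved or consumed by propagation
    for p in perspective.propagating:
        n_source = snapshot_counts.get(p.source, 0)
        if n_source == 0:
            continue
        rate = _param(parameters, p.spawn_rate, 0.0)
        spawned = int(rng.poisson(rate, size=n_source).sum())
        if spawned:
            state.firing_counts[p.ident] = state.firing_counts.get(p.ident, 0) + spawned
            arrivals.extend((p.target, _Token(age=0, via=p.ident)) for _ in range(spawned))

    for target, tok in arrivals:
        state.tokens.setdefault(target, []).append(tok)
    # tokens reaching (or resting at) end nodes are consumed
    for node in perspective.nodes:
        if node.kind == "end":
            state.tokens[node.name] = []
    return state


@dataclass
class FlowRunResult:
    """Occupancy per node per step plus cumulative edge firing counts."""

    occupancy: pd.DataFrame  # index: step; columns: node names
    firing: pd.DataFrame  # index: step; columns: edge idents (cumulative)
    final_state: FlowState

    def to_csv(self) -> str:
        """Long-format CSV: step, node_or_edge, count."""
        rows = ["step,node_or_edge,count"]
        for step, row in self.occupancy.iterrows():
            for name, count in row.items():
                rows.append(f"{step},{name},{int(count)}")
        for step, row in self.firing.iterrows():
            for name, count in row.items():
                rows.append(f"{step},{name},{int(count)}")
        return "\n".join(rows) + "\n"


def run_flow(
    perspective: Perspective,
    n_steps: int,
    parameters: Mapping[str, float],
    seed: int,
    initial_tokens: Mapping[str, int],
) -> FlowRunResult:
    """Run the token flow for ``n_steps`` steps under a fixed seed.

    Step 0 of the occupancy series equals ``initial_tokens``; the run is
    deterministic for a given seed.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be nonnegative")
    issues = validate_perspective(perspective)
    if issues:
        raise ValueError(f"invalid perspective {perspective.name!r}: {issues[0]}")
    rng = np.random.default_rng(seed)
    state = initial_flow_state(initial_tokens)
    node_names = [n.name for n in perspective.nodes]
    edge_ids = [e.ident for e in perspective.sequential] + [
        p.ident for p in perspective.propagating
    ]
    occupancy = [[len(state.tokens.get(n, [])) for n in node_names]]
    firing = [[0] * len(edge_ids)]
    for _ in range(n_steps):
        state = step_flow(perspective, state, parameters, rng)
        occupancy.append([len(state.tokens.get(n, [])) for n in node_names])
        firing.append([state.firing_counts.get(e, 0) for e in edge_ids])
    occ = pd.DataFrame(occupancy, columns=node_names)
    occ.index.name = "step"
    fir = pd.DataFrame(firing, columns=edge_ids)
    fir.index.name = "step"
    return FlowRunResult(occ, fir, state)
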