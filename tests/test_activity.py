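"""Token-flow execution: the three extended relationships and conservation."""

import numpy as np
import pytest

from biodomain.activity import (
    ActivityNode,
    ContributoryEdge,
    FlowEvaluationError,
    InterruptEdge,
    Perspective,
    PropagatingEdge,
    SequentialEdge,
    initial_flow_state,
    run_flow,
    step_flow,
    validate_perspective,
)
from biodomain.eae import build_eae_model

RNG = np.random.default_rng


def chain(*names, kinds=None):
    kinds = kinds or ["start"] + ["action"] * (len(names) - 2) + ["end"]
    return Perspective(
        name="chain",
        nodes=tuple(ActivityNode(n, k) for n, k in zip(names, kinds)),
        sequential=tuple(
            SequentialEdge(a, b) for a, b in zip(names, names[1:])
        ),
    )


# --------------------------------------------------------------------------
# Validation


def test_eae_regulation_perspective_is_valid_cyclic_and_endless():
    p = build_eae_model().perspective("regulation")
    assert validate_perspective(p) == []
    assert not any(n.kind == "end" for n in p.nodes)
    # cyclic: some edge closes a loop back to an earlier activity
    sources = {e.source for e in p.sequential}
    assert "CD8Treg kills CD4Th1" in sources


def test_missing_start_node_is_an_issue():
    p = Perspective(name="p", nodes=(ActivityNode("a"),))
    issues = validate_perspective(p)
    assert any("start" in i for i in issues)


def test_contributory_edge_must_target_a_decision():
    p = Perspective(
        name="p",
        nodes=(ActivityNode("s", "start"), ActivityNode("a"), ActivityNode("c")),
        sequential=(SequentialEdge("s", "a"),),
        contributory=(ContributoryEdge("c", "a", {}),),
    )
    issues = validate_perspective(p)
    assert any("not a decision" in i for i in issues)


def test_interrupt_must_reference_an_existing_edge():
    p = Perspective(
        name="p",
        nodes=(ActivityNode("s", "start"), ActivityNode("i")),
        interrupts=(InterruptEdge("i", "x->y", "deg"),),
    )
    assert any("x->y" in i for i in issues_of(p))


def issues_of(p):
    return validate_perspective(p)


# --------------------------------------------------------------------------
# Sequential flow


def test_single_token_walks_the_chain_and_is_consumed():
    p = chain("start", "A", "B", "end")
    result = run_flow(p, 5, {}, seed=0, initial_tokens={"start": 1})
    occ = result.occupancy
    assert occ.loc[0, "start"] == 1
    assert occ.loc[1, "A"] == 1
    assert occ.loc[2, "B"] == 1
    assert occ.iloc[3:].to_numpy().sum() == 0  # consumed at the end node
    assert occ.sum(axis=1).tolist() == [1, 1, 1, 0, 0, 0]


def test_zero_steps_returns_initial_occupancy_only():
    p = chain("start", "A", "end")
    result = run_flow(p, 0, {}, seed=0, initial_tokens={"A": 3})
    assert len(result.occupancy) == 1
    assert result.occupancy.loc[0, "A"] == 3


def test_same_seed_gives_identical_series():
    p = build_eae_model().perspective("type-2 deviation")
    params = build_eae_model().parameters
    kw = dict(n_steps=40, parameters=params, seed=11,
              initial_tokens={"deviation start": 1, "killing start": 1})
    r1, r2 = run_flow(p, **kw), run_flow(p, **kw)
    assert r1.occupancy.equals(r2.occupancy)
    assert r1.firing.equals(r2.firing)


def test_closed_cycle_conserves_tokens():
    nodes = tuple(
        [ActivityNode("go", "start")] + [ActivityNode(f"n{i}") for i in range(4)]
    )
    p = Perspective(
        name="cycle",
        nodes=nodes,
        sequential=(
            SequentialEdge("go", "n0"),
            SequentialEdge("n0", "n1"),
            SequentialEdge("n1", "n2"),
            SequentialEdge("n2", "n3"),
            SequentialEdge("n3", "n0"),
        ),
    )
    result = run_flow(p, 300, {}, seed=3, initial_tokens={"go": 1, "n2": 2})
    assert (result.occupancy.sum(axis=1) == 3).all()


def test_unresolved_parameter_raises():
    p = Perspective(
        name="p",
        nodes=(ActivityNode("s", "start"), ActivityNode("t")),
        propagating=(PropagatingEdge("s", "t", "missing_rate"),),
    )
    with pytest.raises(FlowEvaluationError, match="missing_rate"):
        step_flow(p, initial_flow_state({"s": 1}), {}, RNG(0))


# --------------------------------------------------------------------------
# Propagating relationship


def _propagation_network():
    return Perspective(
        name="prop",
        nodes=(
            ActivityNode("go", "start"),
            ActivityNode("S"),
            ActivityNode("T"),
            ActivityNode("E"),
        ),
        sequential=(SequentialEdge("go", "S"), SequentialEdge("S", "E", dwell="d_hold")),
        propagating=(PropagatingEdge("S", "T", "rate"),),
    )


def test_propagation_mean_matches_poisson_oracle():
    # one source token held for 100 steps at rate 0.5: total spawns are
    # Poisson(50); check the mean over seeds against the analytic oracle
    p = _propagation_network()
    params = {"rate": 0.5, "d_hold": 1000.0}
    n_seeds, n_steps = 600, 100
    totals = np.empty(n_seeds)
    for seed in range(n_seeds):
        rng = RNG(seed)
        state = initial_flow_state({"S": 1})
        for _ in range(n_steps):
            state = step_flow(p, state, params, rng)
        totals[seed] = state.firing_counts.get("S~>T", 0)
    se = np.sqrt(50.0 / n_seeds)
    assert abs(totals.mean() - 50.0) < 3 * se


def test_propagation_freezes_after_source_departs():
    # the source token leaves after 10 steps; no more spawns are generated
    p = _propagation_network()
    params = {"rate": 2.0, "d_hold": 10.0}
    rng = RNG(42)
    state = initial_flow_state({"S": 1})
    for _ in range(10):
        state = step_flow(p, state, params, rng)
    assert not state.tokens.get("S")  # departed to E
    frozen = state.firing_counts.get("S~>T", 0)
    assert frozen > 0
    for _ in range(30):
        state = step_flow(p, state, params, rng)
    assert state.firing_counts.get("S~>T", 0) == frozen


def test_propagation_never_moves_or_consumes_the_source_token():
    p = _propagation_network()
    params = {"rate": 3.0, "d_hold": 1000.0}
    rng = RNG(1)
    state = initial_flow_state({"S": 2})
    for _ in range(25):
        state = step_flow(p, state, params, rng)
        assert len(state.tokens["S"]) == 2


# --------------------------------------------------------------------------
# Interrupting relationship


def _interrupt_network():
    return Perspective(
        name="intr",
        nodes=(
            ActivityNode("go", "start"),
            ActivityNode("A"),
            ActivityNode("B"),
            ActivityNode("I"),
        ),
        sequential=(SequentialEdge("go", "A"), SequentialEdge("A", "B")),
        interrupts=(InterruptEdge("I", "A->B", "deg"),),
    )


def test_full_interruption_blocks_the_edge_entirely():
    p = _interrupt_network()
    rng = RNG(0)
    state = initial_flow_state({"A": 1, "I": 1})
    for _ in range(50):
        state = step_flow(p, state, {"deg": 1.0}, rng)
    assert state.firing_counts.get("A->B", 0) == 0
    assert len(state.tokens["A"]) == 1  # still waiting


def test_zero_degree_interrupter_is_statistically_inert():
    # compare branch-choice counts of a decision with and without a
    # degree-0 interrupter present: chi-squared homogeneity at alpha=0.01
    from scipy.stats import chi2_contingency

    def network(with_interrupter):
        interrupts = (InterruptEdge("I", "D->X", "deg"),) if with_interrupter else ()
        return Perspective(
            name="p",
            nodes=(
                ActivityNode("go", "start"),
                ActivityNode("D", "decision"),
                ActivityNode("X"),
                ActivityNode("Y"),
                ActivityNode("I"),
            ),
            sequential=(
                SequentialEdge("go", "D"),
                SequentialEdge("D", "X"),
                SequentialEdge("D", "Y"),
            ),
            interrupts=interrupts,
        )

    n = 10_000
    counts = {}
    for with_interrupter in (False, True):
        p = network(with_interrupter)
        rng = RNG(5)
        state = initial_flow_state({"D": n, "I": 1})
        state = step_flow(p, state, {"deg": 0.0}, rng)
        counts[with_interrupter] = (
            len(state.tokens["X"]),
            len(state.tokens["Y"]),
        )
    table = np.array([counts[False], counts[True]])
    _, p_value, _, _ = chi2_contingency(table)
    assert p_value > 0.01


def test_partial_interruption_slows_but_does_not_stop():
    # degree 0.7 leaves a 0.3 pass probability: first-passage time is
    # geometric with mean 1/0.3
    p = _interrupt_network()
    waits = []
    for seed in range(300):
        rng = RNG(seed)
        state = initial_flow_state({"A": 1, "I": 1})
        steps = 0
        while state.firing_counts.get("A->B", 0) == 0:
            state = step_flow(p, state, {"deg": 0.7}, rng)
            steps += 1
            assert steps < 10_000
        waits.append(steps)
    mean = np.mean(waits)
    se = np.sqrt(0.7 / 0.3**2 / len(waits))
    assert abs(mean - 1 / 0.3) < 3 * se


# --------------------------------------------------------------------------
# Contributory relationship


def _decision_network():
    return Perspective(
        name="dec",
        nodes=(
            ActivityNode("go", "start"),
            ActivityNode("D", "decision"),
            ActivityNode("X"),
            ActivityNode("Y"),
            ActivityNode("C"),
        ),
        sequential=(
            SequentialEdge("go", "D"),
            SequentialEdge("D", "X"),
            SequentialEdge("D", "Y"),
        ),
        contributory=(ContributoryEdge("C", "D", {"X": 1.0}),),
    )


def test_contributory_shift_moves_two_branch_split_to_two_thirds():
    # baseline weights 1:1 shift to 2:1 when C is active
    p = _decision_network()
    rng = RNG(9)
    n = 10_000
    state = initial_flow_state({"D": n, "C": 1})
    state = step_flow(p, state, {}, rng)
    frac_x = len(state.tokens["X"]) / n
    se = np.sqrt((2 / 3) * (1 / 3) / n)
    assert abs(frac_x - 2 / 3) < 3 * se


def test_inactive_contributory_source_leaves_split_uniform():
    p = _decision_network()
    rng = RNG(9)
    n = 10_000
    state = initial_flow_state({"D": n})  # C holds no token
    state = step_flow(p, state, {}, rng)
    frac_x = len(state.tokens["X"]) / n
    se = np.sqrt(0.25 / n)
    assert abs(frac_x - 0.5) < 3 * se


def test_contributory_source_is_not_consumed_by_routings():
    p = _decision_network()
    rng = RNG(4)
    state = initial_flow_state({"D": 500, "C": 1})
    for _ in range(5):
        state = step_flow(p, state, {}, rng)
        assert len(state.tokens["C"]) == 1


# --------------------------------------------------------------------------
# Fork / join / firing-count bookkeeping


def test_fork_duplicates_and_join_synchronizes():
    p = Perspective(
        name="fj",
        nodes=(
            ActivityNode("go", "start"),
            ActivityNode("F", "fork"),
            ActivityNode("L"),
            ActivityNode("R"),
            ActivityNode("J", "join"),
            ActivityNode("out"),
        ),
        sequential=(
            SequentialEdge("go", "F"),
            SequentialEdge("F", "L"),
            SequentialEdge("F", "R"),
            SequentialEdge("L", "J"),
            SequentialEdge("R", "J"),
            SequentialEdge("J", "out"),
        ),
    )
    result = run_flow(p, 6, {}, seed=0, initial_tokens={"go": 1})
    occ = result.occupancy
    assert occ.loc[2, "L"] == 1 and occ.loc[2, "R"] == 1  # duplicated
    assert occ.loc[5, "out"] == 1  # merged back to a single token
    assert result.occupancy.loc[6, "out"] == 1  # nowhere to go; stays


def test_firing_counts_are_monotone_nondecreasing():
    p = build_eae_model().perspective("regulation")
    params = build_eae_model().parameters
    result = run_flow(p, 60, params, seed=2, initial_tokens={"regulation start": 1})
    diffs = result.firing.diff().fillna(0).to_numpy()
    assert (diffs >= 0).all()
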