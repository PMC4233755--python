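"""Statechart execution: initial configurations, stepping, orthogonality."""

import numpy as np
import pytest

import helpers
from biodomain.eae import build_eae_model
from biodomain.statechart import (
    MachineDefinitionError,
    Region,
    StateMachine,
    StateNode,
    Transition,
    initial_config,
    step_machine,
)

RNG = np.random.default_rng


def single_region(*states, initial=None, transitions=()):
    return StateMachine(
        "T",
        (Region("r", tuple(StateNode(s) for s in states), initial or states[0]),),
        tuple(transitions),
    )


# --------------------------------------------------------------------------
# Structure


def test_composite_needs_initial_substate():
    with pytest.raises(MachineDefinitionError):
        StateNode("c", "composite", substates=(StateNode("a"),), initial="zz")


def test_isolated_states_admit_no_transitions():
    with pytest.raises(MachineDefinitionError, match="isolated"):
        StateMachine(
            "T",
            (
                Region(
                    "r",
                    (StateNode("iso", "isolated"), StateNode("a")),
                    "iso",
                ),
            ),
            (Transition.of("a", "iso"),),
        )


def test_transitions_may_not_cross_regions():
    with pytest.raises(MachineDefinitionError, match="crosses regions"):
        StateMachine(
            "T",
            (
                Region("r1", (StateNode("a"),), "a"),
                Region("r2", (StateNode("b"),), "b"),
            ),
            (Transition.of("a", "b"),),
        )


# --------------------------------------------------------------------------
# Initial configuration


def test_initial_config_single_region():
    machine = single_region("immature", "mature")
    config = initial_config(machine)
    assert config.active == {"r": ("immature",)}
    assert config.elapsed == {"immature": 0}


def test_initial_config_descends_composite_initials():
    machine = StateMachine(
        "T",
        (
            Region(
                "r",
                (
                    StateNode(
                        "outer",
                        "composite",
                        substates=(StateNode("inner1"), StateNode("inner2")),
                        initial="inner2",
                    ),
                ),
                "outer",
            ),
        ),
    )
    config = initial_config(machine)
    assert config.active["r"] == ("outer", "inner2")


def test_cd8treg_fixture_has_orthogonal_location_and_maturation():
    machine = build_eae_model().machine("CD8Treg")
    config = initial_config(machine)
    assert config.active["maturation"] == ("naive",)
    assert config.active["location"] == ("Circulation",)
    assert all(v == 0 for v in config.elapsed.values())


# --------------------------------------------------------------------------
# Stepping


def test_quiescent_step_increments_elapsed_and_emits():
    machine = StateMachine(
        "T",
        (
            Region(
                "r",
                (StateNode("a", emissions=("hum",)), StateNode("b")),
                "a",
            ),
        ),
        (Transition.of("a", "b", "go"),),
    )
    config = initial_config(machine)
    config2, emitted = step_machine(machine, config, {"go": False}, {}, RNG(0))
    assert config2.active == config.active
    assert config2.elapsed["a"] == 1
    assert emitted == ["hum"]


def test_tie_break_is_uniform():
    machine = single_region(
        "a", "b", "c",
        transitions=(Transition.of("a", "b", "go"), Transition.of("a", "c", "go")),
    )
    rng = RNG(7)
    outcomes = {"b": 0, "c": 0}
    n = 10_000
    for _ in range(n):
        config, _ = step_machine(machine, initial_config(machine), {"go": True}, {}, rng)
        outcomes[config.active["r"][0]] += 1
    se = np.sqrt(0.25 / n)
    assert abs(outcomes["b"] / n - 0.5) < 3 * se


def test_dc_matures_in_one_step_and_isolated_state_persists():
    machine = build_eae_model().machine("DC")
    env = {p: False for p in machine.mentioned_predicates()}
    env["in_CNS"] = True
    params = dict(build_eae_model().parameters)
    params["p_dc_maturation"] = 1.0
    params["p_mbp_presentation"] = 0.0
    config = initial_config(machine)
    assert "MHCII_capable" in config.active_states()
    config, _ = step_machine(machine, config, env, params, RNG(0))
    assert "mature" in config.active_states()
    assert "MHCII_capable" in config.active_states()


def test_leaving_a_composite_exits_its_substate_and_runs_actions():
    machine = StateMachine(
        "T",
        (
            Region(
                "r",
                (
                    StateNode(
                        "outer",
                        "composite",
                        substates=(
                            StateNode("inner", exit_actions=("bye_inner",)),
                        ),
                        initial="inner",
                        exit_actions=("bye_outer",),
                    ),
                    StateNode("solo", entry_actions=("hi_solo",)),
                ),
                "outer",
            ),
        ),
        (Transition.of("outer", "solo", "go", actions=("hop",)),),
    )
    config, emitted = step_machine(
        machine, initial_config(machine), {"go": True}, {}, RNG(0)
    )
    assert config.active["r"] == ("solo",)
    assert emitted == ["bye_inner", "bye_outer", "hop", "hi_solo"]


def test_lambda_fires_exactly_at_dwell_threshold():
    machine = single_region(
        "a", "b", transitions=(Transition.of("a", "b", "λ(t)"),)
    )
    config = initial_config(machine)
    params = {"t": 3}
    history = []
    rng = RNG(0)
    for _ in range(5):
        config, _ = step_machine(machine, config, {}, params, rng)
        history.append(config.active["r"][0])
    # elapsed reaches 3 at the start of the fourth step
    assert history == ["a", "a", "a", "b", "b"]


def test_reentry_resets_elapsed():
    machine = single_region(
        "a", "b",
        transitions=(
            Transition.of("a", "b", "λ(t)"),
            Transition.of("b", "a"),
        ),
    )
    config = initial_config(machine)
    rng = RNG(0)
    params = {"t": 1}
    config, _ = step_machine(machine, config, {}, params, rng)  # a, elapsed 1
    config, _ = step_machine(machine, config, {}, params, rng)  # fires -> b
    assert config.active["r"] == ("b",)
    assert config.elapsed["b"] == 0
    config, _ = step_machine(machine, config, {}, params, rng)  # back to a
    assert config.active["r"] == ("a",)
    assert config.elapsed["a"] == 0  # dwell clock restarted


def test_regions_step_against_start_of_step_snapshot():
    # R2's guard watches R1's start-of-step state: both regions fire in the
    # same step, so R2 saw the snapshot, not R1's post-firing state
    machine = StateMachine(
        "T",
        (
            Region("r1", (StateNode("a"), StateNode("b")), "a"),
            Region("r2", (StateNode("c"), StateNode("d")), "c"),
        ),
        (
            Transition.of("a", "b", "go"),
            Transition.of("c", "d", "in_a"),
        ),
    )
    env = {"go": True, "in_a": True}  # snapshot: a is active
    config, _ = step_machine(machine, initial_config(machine), env, {}, RNG(0))
    assert config.active["r1"] == ("b",)
    assert config.active["r2"] == ("d",)


# --------------------------------------------------------------------------
# Invariants on randomized machines


@pytest.mark.parametrize("seed", range(40))
def test_exactly_one_active_leaf_per_region(seed):
    rng = RNG(seed)
    machine, params = helpers.random_machine(rng)
    config = initial_config(machine)
    for _ in range(25):
        env = helpers.random_env(rng, machine)
        config, _ = step_machine(machine, config, env, params, rng)
        assert set(config.active) == {r.name for r in machine.regions}
        for region in machine.regions:
            path = config.active[region.name]
            leaf = machine.state(path[-1])
            assert leaf.kind != "composite"
            assert machine.path_to(path[-1]) == path


@pytest.mark.parametrize("seed", range(10))
def test_all_delta_zero_machines_are_seed_invariant(seed):
    machine, params = helpers.random_machine(RNG(seed), all_delta_zero=True)
    env_rng = RNG(seed + 1000)
    envs = [helpers.random_env(env_rng, machine) for _ in range(30)]

    def trajectory(exec_seed):
        rng = RNG(exec_seed)
        config = initial_config(machine)
        out = []
        for env in envs:
            config, _ = step_machine(machine, config, env, params, rng)
            out.append(tuple(sorted(config.active.items())))
        return out

    assert trajectory(1) == trajectory(2) == trajectory(31337)
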