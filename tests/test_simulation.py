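"""Multi-agent simulation: initialization, stepping, accounting, knockouts."""

import dataclasses

import numpy as np
import pytest

from biodomain.eae import build_eae_model, default_sim_config
from biodomain.simulation import (
    KnockoutError,
    SimConfig,
    apply_knockout,
    apply_knockouts_to_perspective,
    init_sim,
    run_sim,
    step_sim,
)


def config_with(populations, n_steps=5, seed=0, **kw):
    base = default_sim_config(seed=seed, n_steps=n_steps)
    return dataclasses.replace(base, initial_populations=populations, **kw)


# --------------------------------------------------------------------------
# Initialization


def test_empty_populations_give_a_valid_empty_state(eae_model):
    state = init_sim(eae_model, config_with({}))
    assert state.agents == []
    state = step_sim(eae_model, state)
    assert state.step == 1 and state.agents == []


def test_agents_start_in_their_initial_states(eae_model):
    state = init_sim(eae_model, config_with({"DC": {"SLO": 10}}))
    assert len(state.agents) == 10
    for agent in state.agents:
        active = agent.machine_config.active_states()
        assert {"immature", "unpolarized", "not_presenting_MBP"} <= active
        assert agent.compartment == "SLO"
        assert "SLO" in active  # location region synced to placement


def test_molecule_populations_become_field_levels(eae_model):
    state = init_sim(eae_model, config_with({"Type1Cytokine": {"CNS": 5}}))
    assert state.fields["CNS"]["Type1Cytokine"] == 5.0
    assert state.agents == []


def test_negative_population_and_unknown_compartment_rejected(eae_model):
    with pytest.raises(ValueError):
        config_with({"DC": {"SLO": -1}})
    with pytest.raises(ValueError, match="Ether"):
        init_sim(eae_model, config_with({"DC": {"Ether": 1}}))


def test_inconsistent_models_need_force():
    import helpers

    broken, _ = helpers.defect_r2()
    with pytest.raises(ValueError, match="consistency"):
        init_sim(broken, config_with({}))
    init_sim(broken, config_with({}), force=True)  # explicit override


# --------------------------------------------------------------------------
# Stepping semantics


def test_stimulated_macrophage_kills_colocated_neuron(eae_model):
    config = config_with(
        {
            "CNSMacrophage": {"CNS": 1},
            "Neuron": {"CNS": 1},
            "Type1Cytokine": {"CNS": 10},
        },
        parameter_overrides={
            "p_macrophage_stimulation": 1.0,
            "r_macrophage_kill": 1.0,
            "decay_Type1Cytokine": 0.0,
        },
    )
    state = init_sim(eae_model, config)
    state = step_sim(eae_model, state)  # macrophage becomes stimulated
    macrophage = next(a for a in state.agents if a.entity_type == "CNSMacrophage")
    assert "stimulated" in macrophage.machine_config.active_states()
    state = step_sim(eae_model, state)  # kill fires at rate 1.0
    neuron = next(a for a in state.agents if a.entity_type == "Neuron")
    assert "dead" in neuron.machine_config.active_states()


def test_dead_agents_are_removed_and_stay_inert(eae_model):
    config = config_with(
        {
            "CNSMacrophage": {"CNS": 1},
            "Neuron": {"CNS": 1},
            "Type1Cytokine": {"CNS": 10},
        },
        parameter_overrides={
            "p_macrophage_stimulation": 1.0,
            "r_macrophage_kill": 1.0,
            "decay_Type1Cytokine": 0.0,
        },
    )
    state = init_sim(eae_model, config)
    for _ in range(4):
        state = step_sim(eae_model, state)
    neuron = next(a for a in state.agents if a.entity_type == "Neuron")
    assert not neuron.alive
    assert state.deaths == {"Neuron": 1}
    n_events = len(state.event_log)
    for _ in range(3):
        state = step_sim(eae_model, state)
    later = state.event_log[n_events:]
    assert not any(e.get("victim") == neuron.id for e in later)
    assert not any(e.get("agent") == neuron.id for e in later)


def test_accounting_identity_holds_at_every_step(eae_model, baseline_series):
    assert baseline_series.accounting_holds()


def test_same_seed_gives_bit_identical_series(eae_model):
    config = default_sim_config(seed=5, n_steps=40)
    a = run_sim(eae_model, config)
    b = run_sim(eae_model, config)
    assert a.steps == b.steps
    assert a.event_log == b.event_log
    assert a.to_csv() == b.to_csv()


def test_zero_steps_returns_initial_observation_only(eae_model):
    series = run_sim(eae_model, default_sim_config(seed=1, n_steps=0))
    assert len(series.steps) == 1
    assert series.totals("Neuron")[0] == 40


def test_fields_decay_to_zero_without_secretors(eae_model):
    config = config_with({"Type1Cytokine": {"CNS": 10}}, n_steps=0)
    state = init_sim(eae_model, config)
    for _ in range(40):
        state = step_sim(eae_model, state)
        assert state.fields["CNS"]["Type1Cytokine"] >= 0.0
    assert state.fields["CNS"]["Type1Cytokine"] < 1e-4


def test_daughters_carry_parent_ids(eae_model, baseline_series):
    births = [e for e in baseline_series.event_log if e["event"] == "birth"]
    assert births, "default run should include proliferation"
    assert all(e["parent"] is not None for e in births)


def test_cytokine_fields_stay_nonnegative(eae_model):
    config = default_sim_config(seed=2, n_steps=60)
    state = init_sim(eae_model, config)
    for _ in range(60):
        state = step_sim(eae_model, state)
        for by_mol in state.fields.values():
            assert all(v >= 0.0 for v in by_mol.values())


# --------------------------------------------------------------------------
# Knockouts


def test_unknown_knockout_name_is_rejected(eae_model):
    config = default_sim_config(seed=0)
    with pytest.raises(KnockoutError, match="NoSuchRule"):
        apply_knockout(config, ["NoSuchRule"], model=eae_model)


def test_empty_knockout_is_a_no_op(eae_model):
    config = default_sim_config(seed=0)
    assert apply_knockout(config, [], model=eae_model) == config


def test_knockout_accepts_perspective_edge_names(eae_model):
    config = default_sim_config(seed=0)
    edge = eae_model.perspective("regulation").propagating[0].ident
    out = apply_knockout(config, [edge], model=eae_model)
    assert edge in out.knockouts


def test_perspective_edge_knockout_removes_the_edge(eae_model):
    p = eae_model.perspective("regulation")
    edge = p.propagating[0].ident
    stripped = apply_knockouts_to_perspective(p, [edge])
    assert edge not in {e.ident for e in stripped.propagating}
    assert len(stripped.sequential) == len(p.sequential)


def test_killing_knockout_prevents_cd4th1_decline(eae_model):
    base_cfg = default_sim_config(seed=7, n_steps=150)
    ko_cfg = apply_knockout(base_cfg, ["CD8Treg_kills_CD4Th1"], model=eae_model)
    base = run_sim(eae_model, base_cfg).totals("CD4Th1")
    ko = run_sim(eae_model, ko_cfg).totals("CD4Th1")
    assert ko[-1] / ko.max() > base[-1] / base.max()
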