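"""Model documents: schema validation, round-trips, DOT rendering, CLI."""

import json
import pathlib
import re

import numpy as np
import pytest
from click.testing import CliRunner

import helpers
from biodomain.cli import main as cli_main
from biodomain.guards import GuardSyntaxError
from biodomain.model_io import (
    DocumentParseError,
    SchemaViolation,
    load_model,
    model_to_document,
    render_dot,
    save_model,
    schema_as_json,
    validate_document,
)

DATA = pathlib.Path(__file__).parent.parent / "src" / "biodomain" / "data"


# --------------------------------------------------------------------------
# Round trips


@pytest.mark.parametrize("seed", range(15))
def test_fuzzed_models_round_trip_structurally(seed):
    model = helpers.random_model(np.random.default_rng(seed))
    assert load_model(save_model(model)) == model


def test_yaml_surface_syntax_loads_identically(eae_model):
    import yaml

    document = model_to_document(eae_model)
    as_yaml = yaml.safe_dump(document)
    assert load_model(as_yaml) == eae_model


def test_save_is_byte_stable(eae_model):
    assert save_model(eae_model) == save_model(eae_model)


# --------------------------------------------------------------------------
# Schema rejection corpus

def _drop(key):
    def mutate(doc):
        del doc[key]
    return mutate, f"/{key}"


def _set(path, value):
    def mutate(doc):
        node = doc
        for part in path[:-1]:
            node = node[part]
        node[path[-1]] = value
    return mutate, "/" + "/".join(str(p) for p in path)


_INVALID_DOCUMENTS = [
    _drop("compartments"),
    _drop("version"),
    _drop("entities"),
    _drop("migration_rules"),
    _drop("state_machines"),
    _drop("perspectives"),
    _drop("research_context"),
    _drop("parameters"),
    _set(("version",), "one"),
    _set(("compartments",), {"name": "CNS"}),
    _set(("compartments", 0, "name"), 7),
    _set(("entities", 0, "category"), "tissue"),
    _set(("entities", 0, "name"), None),
    _set(("migration_rules", 0, "from_compartment"), 3),
    _set(("migration_rules", 0, "state_condition"), 1.5),
    _set(("parameters", "p_migrate"), "fast"),
    _set(("perspectives", 0, "nodes", 0, "kind"), "loop"),
    _set(("perspectives", 0, "name"), []),
    _set(("perspectives", 0, "sequential", 0, "target"), 0),
    _set(("research_context", "links"), [{"source": "DC"}]),
    _set(("research_context", "links", 0, "polarity"), "hostile"),
    _set(("research_context", "phenomena", 0, "in_scope"), "yes"),
    _set(("state_machines", "DC", "regions"), {}),
    _set(("state_machines", "DC", "transitions", 0, "source"), False),
    _set(("binding_declarations", 0, "partner_state"), 9),
]


@pytest.mark.parametrize(
    "mutator", _INVALID_DOCUMENTS, ids=[ptr for _, ptr in _INVALID_DOCUMENTS]
)
def test_schema_rejects_invalid_documents_with_a_pointer(eae_model, mutator):
    mutate, pointer = mutator
    document = model_to_document(eae_model)
    mutate(document)
    errors = validate_document(document)
    assert errors, "mutation should be rejected"
    assert any(e.pointer.startswith(pointer) for e in errors)


def test_parse_error_carries_location():
    with pytest.raises(DocumentParseError) as err:
        load_model('{"version": 1,,}')
    assert "line" in str(err.value)


def test_malformed_guard_in_document_raises_with_position(eae_model):
    document = model_to_document(eae_model)
    document["state_machines"]["DC"]["transitions"][0]["guard"] = "δ(p & "
    with pytest.raises(GuardSyntaxError, match="position"):
        load_model(json.dumps(document))


def test_shipped_schema_file_matches_the_library():
    assert (DATA / "model_schema.json").read_text() == schema_as_json()


# --------------------------------------------------------------------------
# DOT rendering

_DOT_LINE = re.compile(
    r'^\s*(digraph\s+.*\{|\}|subgraph\s+.*\{|//.*|'
    r'(compound|rankdir|label|style|node)\s*=.*;|node\s*\[.*\];|'
    r'"(?:[^"\\]|\\.)*"\s*(\[.*\])?\s*;|'
    r'"(?:[^"\\]|\\.)*"\s*->\s*"(?:[^"\\]|\\.)*"\s*(\[.*\])?\s*;)\s*$'
)


def assert_well_formed_dot(text):
    assert text.startswith("digraph")
    assert text.count("{") == text.count("}")
    for line in text.strip().splitlines():
        assert _DOT_LINE.match(line), f"unparseable DOT line: {line!r}"


def all_selectors(model):
    yield "compartments"
    yield "context"
    for entity_type in model.state_machines:
        yield f"machine:{entity_type}"
    for p in model.perspectives:
        yield f"perspective:{p.name}"


def test_every_eae_element_renders_to_well_formed_dot(eae_model):
    for selector in all_selectors(eae_model):
        assert_well_formed_dot(render_dot(eae_model, selector))


def test_dot_output_is_deterministic(eae_model):
    for selector in all_selectors(eae_model):
        assert render_dot(eae_model, selector) == render_dot(eae_model, selector)


def test_cd8treg_machine_shows_the_lymphoid_cluster(eae_model):
    dot = render_dot(eae_model, "machine:CD8Treg")
    assert '"cluster_Lymphoid"' in dot


def test_interrupts_render_via_mid_edge_anchors(eae_model):
    dot = render_dot(eae_model, "perspective:type-2 deviation")
    assert "anchor:" in dot and "arrowhead=tee" in dot
    assert "arrowhead=vee" in dot  # propagating style
    assert "arrowhead=odot" in dot  # contributory style


def test_unknown_selector_raises(eae_model):
    with pytest.raises(KeyError):
        render_dot(eae_model, "machine:Ghost")
    with pytest.raises(KeyError):
        render_dot(eae_model, "banana")


# --------------------------------------------------------------------------
# CLI


def test_validate_clean_fixture_exits_zero(tmp_path):
    runner = CliRunner()
    result = runner.invoke(cli_main, ["validate"])
    assert result.exit_code == 0
    assert "result: clean" in result.output


def test_validate_defective_fixture_exits_one_citing_circulation(tmp_path):
    model, _ = helpers.defect_r3()
    path = tmp_path / "bad.json"
    path.write_text(save_model(model))
    result = CliRunner().invoke(cli_main, ["validate", str(path)])
    assert result.exit_code == 1
    assert "Circulation" in result.output


def test_simulate_zero_steps_writes_a_single_row_group(tmp_path):
    out = tmp_path / "run"
    result = CliRunner().invoke(
        cli_main, ["simulate", "--seed", "7", "--steps", "0", "--out", str(out)]
    )
    assert result.exit_code == 0
    csv = (out / "timeseries.csv").read_text()
    steps = {line.split(",")[0] for line in csv.strip().splitlines()[1:]}
    assert steps == {"0"}


def test_simulate_csv_is_bit_reproducible(tmp_path):
    runner = CliRunner()
    outputs = []
    for name in ("a", "b"):
        out = tmp_path / name
        result = runner.invoke(
            cli_main,
            ["simulate", "--seed", "3", "--steps", "30", "--out", str(out)],
        )
        assert result.exit_code == 0
        outputs.append((out / "timeseries.csv").read_bytes())
    assert outputs[0] == outputs[1]


def test_knockout_command_runs_and_records_names(tmp_path):
    out = tmp_path / "ko"
    result = CliRunner().invoke(
        cli_main,
        ["knockout", "CD8Treg_kills_CD4Th1", "--steps", "10", "--out", str(out)],
    )
    assert result.exit_code == 0
    metadata = json.loads((out / "metadata.json").read_text())
    assert metadata["knockouts"] == ["CD8Treg_kills_CD4Th1"]


def test_unknown_knockout_is_a_usage_error():
    result = CliRunner().invoke(cli_main, ["knockout", "NoSuchRule", "--steps", "1"])
    assert result.exit_code == 2


def test_unknown_subcommand_is_a_usage_error():
    result = CliRunner().invoke(cli_main, ["transmogrify"])
    assert result.exit_code == 2


def test_rules_command_lists_the_registry():
    result = CliRunner().invoke(cli_main, ["rules"])
    assert result.exit_code == 0
    for i in range(1, 8):
        assert f"R{i}:" in result.output


def test_fixture_command_writes_a_loadable_document(tmp_path, eae_model):
    out = tmp_path / "model.json"
    result = CliRunner().invoke(cli_main, ["fixture", "--out", str(out)])
    assert result.exit_code == 0
    assert load_model(out.read_text()) == eae_model
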