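"""Binary coding of raw survey levels, gate logic, and coding invariants."""

import numpy as np
import pandas as pd
import pytest

from fsrasch import (
    CodingError,
    build_binary_matrix,
    code_frequency_item,
    code_how_often,
    code_yes_no,
)
from fsrasch.coding import DEFAULT_ITEM_IDS, GATE_OF, MISSING

ITEMS = list(DEFAULT_ITEM_IDS)


@pytest.mark.parametrize(
    "coder, level, expected",
    [
        (code_frequency_item, "often_true", 1),
        (code_frequency_item, "sometimes_true", 1),
        (code_frequency_item, "never_true", 0),
        (code_frequency_item, "Often true", 1),  # spelling-tolerant
        (code_yes_no, "yes", 1),
        (code_yes_no, "no", 0),
        (code_how_often, "almost_every_month", 1),
        (code_how_often, "some_months", 1),
        (code_how_often, "one_or_two_months", 0),
        (code_how_often, "only 1 or 2 months", 0),
        (code_how_often, "not_applicable", 0),
    ],
)
def test_level_coding(coder, level, expected):
    assert coder(level) == expected


@pytest.mark.parametrize("coder", [code_frequency_item, code_yes_no, code_how_often])
def test_unknown_level_raises(coder):
    with pytest.raises(CodingError) as exc:
        coder("banana", item="E3", row="H1")
    assert "banana" in str(exc.value)


def test_dont_know_policies():
    assert code_yes_no("dont_know", "as_negative") == 0
    assert code_yes_no("don't know", "as_negative") == 0
    assert code_yes_no("dont_know", "as_missing") is MISSING


@pytest.mark.parametrize("coder", [code_frequency_item, code_yes_no, code_how_often])
@pytest.mark.parametrize("binary", [0, 1, "0", "1"])
def test_idempotent_on_binary(coder, binary):
    assert coder(binary) == int(binary)


def _raw_frame(rows, items=ITEMS):
    df = pd.DataFrame(rows, columns=items)
    df.insert(0, "household_id", [f"H{i}" for i in range(len(df))])
    df.insert(1, "district", "tororo")
    return df


# the published data-structure example rows (columns E1-E8 and E18)
STRUCTURE_ROWS = [
    [1, 1, 1, 1, 1, 1, 0, 0, 0],
    [1, 1, 1, 0, 1, 1, 1, 1, 1],
    [1, 1, 0, 0, 0, 0, 1, 1, 0],
    [1, 0, 1, 1, 1, 0, 1, 1, 0],
    [0, 1, 0, 1, 1, 0, 0, 0, 0],
    [1, 1, 1, 1, 1, 1, 1, 0, 1],
    [1, 1, 1, 1, 1, 1, 1, 1, 1],
    [1, 1, 1, 1, 1, 1, 1, 1, 1],
    [1, 1, 0, 1, 0, 0, 0, 0, 0],
    [1, 1, 1, 1, 1, 1, 1, 1, 1],
]


def test_binary_rows_round_trip_unchanged():
    """Already-binary data passes through the coder bit for bit."""
    items = ["E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8", "E18"]
    raw = _raw_frame(STRUCTURE_ROWS, items=items)
    matrix, log = build_binary_matrix(raw, item_ids=items)
    np.testing.assert_array_equal(matrix.X, np.array(STRUCTURE_ROWS, dtype=float))
    assert matrix.item_id == items
    assert not log.warnings


def test_coding_is_idempotent():
    items = ["E1", "E7", "E8"]
    raw = _raw_frame(
        [["often_true", "yes", "some_months"], ["never_true", "no", "not_applicable"]],
        items=items,
    )
    m1, _ = build_binary_matrix(raw, item_ids=items)
    m2, _ = build_binary_matrix(m1.to_frame(), item_ids=items)
    np.testing.assert_array_equal(m1.X, m2.X)


def test_all_negative_household_is_all_zero_row():
    row = []
    for item in ITEMS:
        if item in ("E1", "E2", "E3", "E4", "E5", "E6"):
            row.append("never_true")
        elif item in ("E8", "E13", "E16"):
            row.append("not_applicable")
        else:
            row.append("no")
    matrix, _ = build_binary_matrix(_raw_frame([row]))
    np.testing.assert_array_equal(matrix.X, np.zeros((1, 18)))


def test_affirmative_counts_match_injected_mix(rng):
    """Per-item affirmative totals equal the count of affirmative levels emitted."""
    n = 200
    levels = {
        "E2": (["often_true", "sometimes_true", "never_true"], [1, 1, 0]),
        "E9": (["yes", "no", "dont_know"], [1, 0, 0]),
    }
    counts = {}
    cols = {"household_id": [f"H{i}" for i in range(n)]}
    for item, (lvls, vals) in levels.items():
        draw = rng.integers(0, 3, size=n)
        cols[item] = [lvls[d] for d in draw]
        counts[item] = sum(vals[d] for d in draw)
    raw = pd.DataFrame(cols)
    matrix, log = build_binary_matrix(raw, item_ids=list(levels))
    for j, item in enumerate(levels):
        assert matrix.X[:, j].sum() == counts[item]
        assert sum(log.level_counts[item].values()) == n


def test_gate_forces_follow_up_to_zero():
    items = ["E7", "E8", "E12", "E13", "E15", "E16"]
    raw = _raw_frame(
        [["no", "some_months", "no", "almost_every_month", "yes", "some_months"]],
        items=items,
    )
    matrix, log = build_binary_matrix(raw, item_ids=items)
    np.testing.assert_array_equal(matrix.X[0], [0, 0, 0, 0, 1, 1])
    assert any("forced to 0" in w for w in log.warnings)


def test_gate_consistency_invariant(rng):
    """After coding, X[follow-up] <= X[gate] for every gated pair."""
    n = 100
    pick = {
        "frequency": ["often_true", "sometimes_true", "never_true"],
        "yes_no": ["yes", "no", "dont_know"],
        "how_often": ["almost_every_month", "some_months", "one_or_two_months", "not_applicable"],
    }
    from fsrasch.coding import _coder_for

    cols = {item: [pick[_coder_for(item)][rng.integers(0, len(pick[_coder_for(item)]))]
                   for _ in range(n)] for item in ITEMS}
    matrix, _ = build_binary_matrix(_raw_frame(list(zip(*[cols[i] for i in ITEMS]))))
    pos = {i: j for j, i in enumerate(ITEMS)}
    for fu, gate in GATE_OF.items():
        assert np.all(matrix.X[:, pos[fu]] <= matrix.X[:, pos[gate]])


def test_all_missing_row_dropped_and_logged():
    items = ["E1", "E2"]
    raw = _raw_frame([["often_true", "never_true"], ["", ""]], items=items)
    matrix, log = build_binary_matrix(raw, item_ids=items)
    assert matrix.n == 1
    assert log.dropped_rows == ["H1"]


def test_missing_gate_with_present_follow_up_warns():
    items = ["E7", "E8"]
    raw = _raw_frame([["", "some_months"]], items=items)
    matrix, log = build_binary_matrix(raw, item_ids=items)
    assert matrix.X[0, 1] == 1  # follow-up honored as coded
    assert any("gate E7 is missing" in w for w in log.warnings)


def test_level_map_translates_bespoke_spellings():
    items = ["E1"]
    raw = _raw_frame([["souvent"]], items=items)
    matrix, _ = build_binary_matrix(raw, item_ids=items, level_map={"souvent": "often_true"})
    assert matrix.X[0, 0] == 1


def test_dk_as_missing_produces_nan():
    items = ["E9", "E10"]
    raw = _raw_frame([["dont_know", "yes"]], items=items)
    matrix, _ = build_binary_matrix(raw, dk_policy="as_missing", item_ids=items)
    assert np.isnan(matrix.X[0, 0]) and matrix.X[0, 1] == 1
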