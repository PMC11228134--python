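"""Availability, completeness, accuracy: worked examples and properties."""

import random

import pytest
from hypothesis import given, strategies as st

from esourceflow.crf_model import Module
from esourceflow.errors import InvariantError, MetricUndefinedError, ReportError
from esourceflow.quality_metrics import (
    AccuracyPairs,
    CompletenessInventory,
    FieldInventory,
    accuracy,
    availability_ehr_crf,
    availability_esource_crf,
    build_report,
    completeness,
    round_percent,
)

M = Module.DEMOGRAPHICS  # metric math is module-agnostic


@pytest.mark.parametrize(
    ("ehr", "crf", "expected"),
    [(3, 6, 50.00), (6, 6, 100.00), (6, 9, 66.67), (6, 10, 60.00)],
)
def test_ehr_crf_availability_worked_examples(ehr, crf, expected):
    assert availability_ehr_crf(FieldInventory(M, crf, ehr, 0)) == expected


@pytest.mark.parametrize(
    ("esource", "ehr", "crf", "expected"),
    [(2, 3, 6, 33.33), (9, 10, 10, 90.00), (5, 6, 9, 55.56), (0, 3, 6, 0.00)],
)
def test_esource_crf_availability_worked_examples(esource, ehr, crf, expected):
    assert availability_esource_crf(FieldInventory(M, crf, ehr, esource)) == expected


@pytest.mark.parametrize(
    ("captured", "required", "expected"),
    [(14, 76, 18.42), (24, 1812, 1.32), (12968, 13540, 95.78), (15, 40, 37.50)],
)
def test_completeness_worked_examples(captured, required, expected):
    assert completeness(CompletenessInventory(M, required, captured)) == expected


def test_rounding_is_half_up_not_bankers():
    assert round_percent(5, 9) == 55.56  # banker's rounding would give 55.55...6 -> .56 anyway
    assert round_percent(1, 800) == 0.13  # 0.125 rounds up, not to even
    assert round_percent(3, 800) == 0.38  # 0.375 rounds up


def test_accuracy_worked_examples():
    full_match = AccuracyPairs(M, pairs=[(str(i), str(i)) for i in range(8)])
    assert accuracy(full_match) == 100.00
    assert accuracy(AccuracyPairs(M, pairs=[("a", "b")])) == 0.00


def test_normalized_matching_is_tolerant_of_case_and_space():
    pairs = AccuracyPairs(M, pairs=[("Male", " male "), ("007", "7"), ("36.5", "36.50")])
    assert pairs.matched() == 2  # decimal strings compare exactly, integers numerically


def test_random_pairs_match_brute_force_count():
    rng = random.Random(8)
    pairs = [(str(rng.randrange(5)), str(rng.randrange(5))) for _ in range(400)]
    expected = sum(1 for a, b in pairs if int(a) == int(b))
    ap = AccuracyPairs(M, pairs=pairs)
    assert ap.matched() == expected
    assert accuracy(ap) == round_percent(expected, 400)


def test_undefined_metrics_raise_not_default_to_zero():
    with pytest.raises(MetricUndefinedError):
        availability_ehr_crf(FieldInventory(M, 0, 0, 0))
    with pytest.raises(MetricUndefinedError):
        completeness(CompletenessInventory(M, 0, 0))
    with pytest.raises(MetricUndefinedError):
        accuracy(AccuracyPairs(M, pairs=[]))


def test_inventory_subset_invariant_enforced():
    with pytest.raises(InvariantError):
        FieldInventory(M, crf_total=6, ehr_present=3, esource_transferable=4)
    with pytest.raises(InvariantError):
        CompletenessInventory(M, required_points=10, captured_nonnull=11)


@given(st.data())
def test_esource_availability_never_exceeds_ehr_availability(data):
    crf = data.draw(st.integers(min_value=1, max_value=60))
    ehr = data.draw(st.integers(min_value=0, max_value=crf))
    esource = data.draw(st.integers(min_value=0, max_value=ehr))
    inv = FieldInventory(M, crf, ehr, esource)
    assert availability_esource_crf(inv) <= availability_ehr_crf(inv)


@given(
    st.integers(min_value=1, max_value=500),
    st.integers(min_value=0, max_value=500),
    st.integers(min_value=1, max_value=20),
)
def test_metrics_are_scale_invariant(denominator, numerator, scale):
    numerator = min(numerator, denominator)
    assert round_percent(numerator, denominator) == round_percent(
        numerator * scale, denominator * scale
    )


@given(st.integers(min_value=1, max_value=300), st.integers(min_value=0, max_value=300))
def test_completeness_monotone_in_captured_points(required, captured):
    captured = min(captured, required - 1) if required > 1 else 0
    before = completeness(CompletenessInventory(M, required, captured))
    after = completeness(CompletenessInventory(M, required, captured + 1))
    assert after >= before


@given(st.lists(st.booleans(), min_size=1, max_size=60))
def test_accuracy_never_increases_with_a_mismatching_pair(matches):
    pairs = [("v", "v") if m else ("v", "w") for m in matches]
    before = accuracy(AccuracyPairs(M, pairs=pairs))
    after = accuracy(AccuracyPairs(M, pairs=pairs + [("v", "w")]))
    assert after <= before


# -- report assembly ----------------------------------------------------
def _inventories():
    modules = list(Module)
    field_invs = [FieldInventory(m, 6, 3, 2) for m in modules]
    comp_invs = [CompletenessInventory(m, 12, 12) for m in modules]
    acc = [AccuracyPairs(m, pairs=[("x", "x")] * 12) for m in modules]
    return field_invs, comp_invs, acc


def test_report_row_combines_all_four_metrics():
    field_invs, comp_invs, acc = _inventories()
    report = build_report(field_invs, comp_invs, acc)
    row = report.rows[Module.DEMOGRAPHICS]
    assert row.availability_ehr.fraction() == "3/6 (50.00)"
    assert row.availability_esource.fraction() == "2/6 (33.33)"
    assert row.completeness.fraction() == "12/12 (100.00)"
    assert row.accuracy.fraction() == "12/12 (100.00)"
    assert "Demographics" in report.to_text()


def test_missing_module_is_a_report_error_naming_absentees():
    field_invs, comp_invs, acc = _inventories()
    with pytest.raises(ReportError, match="conmed"):
        build_report(field_invs, comp_invs, [p for p in acc if p.module_id is not Module.CONMED])


def test_report_percents_recompute_from_their_own_fractions(pilot_result):
    for row in pilot_result.report.rows.values():
        for metric in (row.availability_ehr, row.availability_esource,
                       row.completeness, row.accuracy):
            assert metric.percent == round_percent(metric.numerator, metric.denominator)
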