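"""Three-layer deidentification: rules, audit completeness, idempotence."""

import json
import random
from datetime import date, timedelta

import pytest
from hypothesis import given, strategies as st

from esourceflow.crf_model import Module
from esourceflow.deidentify import (
    AuditLog,
    DeidConfig,
    HipaaField,
    IdRule,
    bin_age,
    apply_safe_harbor,
    categorize_id,
    deidentify_study,
    shift_date,
    suppress_low_frequency,
)
from esourceflow.errors import ConfigError, DomainError
from esourceflow.synthetic_ehr import EHRRecord, EHRStore


# -- date shifting ------------------------------------------------------
def test_shift_date_definition():
    base = date(2021, 1, 1)
    assert shift_date(base, base) == 0
    assert shift_date(base + timedelta(days=30), base) == 30
    assert shift_date(base - timedelta(days=5), base) == -5


@given(
    st.dates(min_value=date(1950, 1, 1), max_value=date(2030, 12, 31)),
    st.dates(min_value=date(1950, 1, 1), max_value=date(2030, 12, 31)),
    st.dates(min_value=date(2015, 1, 1), max_value=date(2025, 12, 31)),
)
def test_shift_date_preserves_intervals_and_order(d1, d2, base):
    assert shift_date(d2, base) - shift_date(d1, base) == (d2 - d1).days
    if d1 < d2:
        assert shift_date(d1, base) < shift_date(d2, base)


def test_shift_date_rejects_unparseable_input():
    with pytest.raises(ValueError):
        shift_date("not-a-date", date(2021, 1, 1))


# -- age binning --------------------------------------------------------
def test_every_age_maps_to_exactly_one_bin():
    bins = DeidConfig().age_bins
    for age in range(0, 131):
        hits = [b.label for b in bins if b.lower <= age <= b.upper]
        assert len(hits) == 1
        assert bin_age(age, bins) == hits[0]


def test_age_cap_bin_and_boundaries():
    bins = DeidConfig().age_bins
    assert bin_age(0, bins) == "0-9"
    assert bin_age(95, bins) == ">=90"
    with pytest.raises(DomainError):
        bin_age(131, bins)


def test_overlapping_age_bins_rejected():
    from esourceflow.deidentify import AgeBin

    bad = [AgeBin(lower=0, upper=50, label="young"), AgeBin(lower=40, upper=130, label="old")]
    with pytest.raises((ConfigError, ValueError)):
        DeidConfig(age_bins=bad)


# -- ID categorization --------------------------------------------------
_ID_RULES = [
    IdRule(pattern="^B", label="ACC-BLOOD"),
    IdRule(pattern="^U", label="ACC-URINE"),
    IdRule(pattern="", label="ACC-OTHER"),
]


def test_first_matching_rule_wins_and_fallback_applies():
    assert categorize_id("B2021001", _ID_RULES) == "ACC-BLOOD"
    assert categorize_id("U2021001", _ID_RULES) == "ACC-URINE"
    assert categorize_id("X999", _ID_RULES) == "ACC-OTHER"


def test_category_labels_never_leak_id_substrings():
    rng = random.Random(0)
    for _ in range(500):
        value = "".join(rng.choice("0123456789") for _ in range(10))
        label = categorize_id(value, _ID_RULES)
        for start in range(len(value) - 3):
            assert value[start : start + 4] not in label


# -- low-frequency suppression ------------------------------------------
def test_threshold_one_suppresses_nothing():
    column = ["a", "b", "b", None]
    assert suppress_low_frequency(column, 1) == column


def test_singletons_nulled_at_threshold_two():
    assert suppress_low_frequency(["A", "A", "B"], 2) == ["A", "A", None]


@given(
    st.lists(st.sampled_from("abcde"), max_size=60),
    st.integers(min_value=1, max_value=5),
)
def test_suppression_count_matches_frequency_table(column, k):
    from collections import Counter

    out = suppress_low_frequency(column, k)
    freq = Counter(column)
    assert len(out) == len(column)
    expected_nulled = sum(1 for v in column if freq[v] < k)
    assert sum(1 for v in out if v is None) == expected_nulled
    assert all(o == v for o, v in zip(out, column) if freq[v] >= k)


# -- Safe-Harbor masking ------------------------------------------------
def _record(payload, **kwargs):
    defaults = dict(
        patient_id="PID1",
        domain=Module.DEMOGRAPHICS,
        page_index=0,
        record_date=date(2021, 1, 4),
        provenance="electronic",
    )
    defaults.update(kwargs)
    return EHRRecord(payload=payload, **defaults)


def test_record_without_configured_identifiers_is_unchanged():
    record = _record({"demo.nianling": "61"})
    out = apply_safe_harbor(record, DeidConfig())
    assert out.payload == record.payload


def test_name_and_phone_categories_are_removed():
    config = DeidConfig(
        hipaa_fields=[
            HipaaField(path="demo.xingming", category=1),
            HipaaField(path="demo.dianhua", category=4),
        ]
    )
    record = _record({"demo.xingming": "王伟", "demo.dianhua": "13900001111", "demo.nianling": "61"})
    out = apply_safe_harbor(record, config)
    assert "demo.xingming" not in out.payload
    assert "demo.dianhua" not in out.payload
    assert out.payload["demo.nianling"] == "61"


# -- whole-store deidentification ---------------------------------------
def _store_diff(before: EHRStore, after: EHRStore) -> set[tuple[str, str]]:
    """Brute-force value-level diff as (record_key, field_path) cells."""
    diffs = set()
    for b, a in zip(before.records, after.records):
        rkey = f"{b.domain.value}/{b.patient_id}/{b.page_index}"
        if b.patient_id != a.patient_id:
            diffs.add((rkey, "patient_id"))
        if b.record_date != a.record_date:
            diffs.add((rkey, "record_date"))
        for path in set(b.payload) | set(a.payload):
            if b.payload.get(path) != a.payload.get(path):
                diffs.add((rkey, path))
    return diffs


def test_empty_store_deidentifies_to_empty():
    result = deidentify_study(EHRStore())
    assert result.store.records == [] and len(result.audit) == 0


def test_no_raw_identifier_values_survive(pilot_study):
    store, _ = pilot_study
    result = deidentify_study(store)
    blob = result.store.to_jsonl()
    demo = [r for r in store.records if r.domain is Module.DEMOGRAPHICS]
    for r in demo:
        assert r.patient_id not in blob
        for path in ("demo.xingming", "demo.shenfenzheng", "demo.dianhua", "demo.youxiang"):
            assert r.payload[path] not in blob
        # date of birth is offset (a signed integer), never a calendar date
        assert r.payload["demo.chusheng_riqi"] not in blob
    for record in result.store.records:
        dob = record.payload.get("demo.chusheng_riqi")
        if dob is not None:
            int(dob)


def test_audit_entries_cover_exactly_the_mutated_cells(pilot_study):
    store, _ = pilot_study
    result = deidentify_study(store)
    assert result.store is not store and len(result.store.records) == len(store.records)
    assert result.audit.mutated_cells() == _store_diff(store, result.store)
    seqs = [e.sequence_number for e in result.audit.entries]
    assert seqs == sorted(seqs) and len(set(seqs)) == len(seqs)


def test_second_pass_is_identity_with_empty_audit(pilot_study):
    store, _ = pilot_study
    once = deidentify_study(store)
    twice = deidentify_study(once.store)
    assert twice.store.to_jsonl() == once.store.to_jsonl()
    assert len(twice.audit) == 0


def test_deidentification_is_deterministic(pilot_study):
    store, _ = pilot_study
    a = deidentify_study(store)
    b = deidentify_study(store)
    assert a.store.to_jsonl() == b.store.to_jsonl()


def test_reversal_key_inverts_surrogates(pilot_study):
    store, _ = pilot_study
    result = deidentify_study(store)
    for orig, surrogate in result.subject_map.items():
        assert result.key.invert("subject", surrogate) == orig
    demo_before = next(r for r in store.records if r.domain is Module.DEMOGRAPHICS)
    surrogate_pid = result.subject_map[demo_before.patient_id]
    demo_after = next(
        r for r in result.store.records
        if r.domain is Module.DEMOGRAPHICS and r.patient_id == surrogate_pid
    )
    mrn_surrogate = demo_after.payload["demo.bingli_hao"]
    assert result.key.invert("cat8", mrn_surrogate) == demo_before.payload["demo.bingli_hao"]


def test_reversal_key_never_inside_transfer_artifacts(pilot_result):
    transfer_dir = pilot_result.paths["transfer_dir"]
    names = {p.name for p in transfer_dir.iterdir()}
    assert "reversal_key.json" not in names
    key_text = (pilot_result.output_dir / "keys" / "reversal_key.json").read_text()
    originals = [o for table in json.loads(key_text).values() for o in table]
    manifest_blob = (transfer_dir / "manifest.json").read_text()
    for original in originals:
        assert original not in manifest_blob


def test_audit_log_round_trips_as_jsonl(pilot_study):
    store, _ = pilot_study
    result = deidentify_study(store)
    text = result.audit.to_jsonl()
    again = AuditLog.from_jsonl(text)
    assert again.to_jsonl() == text


def test_date_intervals_preserved_within_patient(pilot_study):
    store, _ = pilot_study
    result = deidentify_study(store)
    surrogate = {pid: s for pid, s in result.subject_map.items()}
    originals = {
        (r.domain, surrogate[r.patient_id], r.page_index): r.record_date
        for r in store.records
        if isinstance(r.record_date, date)
    }
    by_patient: dict[str, list[tuple[date, int]]] = {}
    for r in result.store.records:
        orig = originals[(r.domain, r.patient_id, r.page_index)]
        by_patient.setdefault(r.patient_id, []).append((orig, r.record_date))
    for pairs in by_patient.values():
        (d1, o1), (d2, o2) = pairs[0], pairs[-1]
        assert o2 - o1 == (d2 - d1).days
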