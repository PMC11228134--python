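"""Extraction, translation, CRF mapping, serialization and the one-time push."""

import random

import pytest

from esourceflow.crf_model import CRFPage, Module, Provenance
from esourceflow.deidentify import deidentify_study
from esourceflow.errors import IntegrityError, PolicyError, PushStateError, SchemaError
from esourceflow.etl_transform import (
    TransferDataset,
    builtin_terminology,
    extract,
    map_to_crf,
    push,
    translate_value,
    verify_push,
)
from esourceflow.formats import FORMATS, deserialize, serialize
from esourceflow.synthetic_ehr import EHRStore


@pytest.fixture(scope="module")
def deid_store(pilot_study):
    store, _ = pilot_study
    return deidentify_study(store).store


# -- extraction ---------------------------------------------------------
def test_extraction_requires_deidentified_store(pilot_study, dictionary):
    store, _ = pilot_study
    with pytest.raises(PolicyError):
        extract(store, dictionary)


def test_paper_only_store_extracts_nothing(deid_store, dictionary):
    paper_only = EHRStore(
        records=[r for r in deid_store.records if r.provenance == "paper"],
        patients=deid_store.patients,
        deidentified=True,
    )
    assert extract(paper_only, dictionary) == []


def test_extraction_equals_brute_force_filter(deid_store, dictionary):
    extracted = extract(deid_store, dictionary)
    modules = set(dictionary.modules())
    expected = [
        r for r in deid_store.records
        if r.provenance == "electronic" and r.domain in modules
    ]
    assert extracted == expected


def test_seven_electronic_conmed_pages_extracted(deid_store, dictionary):
    extracted = extract(deid_store, dictionary)
    assert sum(1 for r in extracted if r.domain is Module.CONMED) == 7


# -- translation --------------------------------------------------------
def test_known_token_translates_and_unknown_is_flagged():
    terminology = builtin_terminology()
    assert translate_value("男", terminology) == ("Male", True)
    assert translate_value("不存在的词", terminology) == ("不存在的词", False)


def test_unmapped_fraction_matches_dictionary_miss_rate():
    terminology = builtin_terminology()
    known = list(terminology.entries)
    rng = random.Random(4)
    tokens = [rng.choice(known) if rng.random() < 0.7 else f"junk{rng.randrange(100)}"
              for _ in range(1000)]
    flagged = sum(1 for t in tokens if not translate_value(t, terminology).ok)
    assert flagged == sum(1 for t in tokens if t not in terminology.entries)


# -- mapping ------------------------------------------------------------
def test_empty_record_list_maps_to_no_pages(mapping_rules):
    assert map_to_crf([], mapping_rules) == []


def test_demographics_pages_carry_exactly_two_fields(deid_store, dictionary, mapping_rules):
    pages = map_to_crf(extract(deid_store, dictionary), mapping_rules)
    demo = [p for p in pages if p.module_id is Module.DEMOGRAPHICS]
    assert len(demo) == 6
    for page in demo:
        nonnull = [n for n, v in page.values.items() if v is not None]
        assert sorted(nonnull) == ["Age", "Sex"]
        assert all(page.provenance[n] is Provenance.ESOURCE for n in nonnull)


def test_populated_points_match_study_capture_counts(
    deid_store, dictionary, mapping_rules, pilot_config
):
    pages = map_to_crf(extract(deid_store, dictionary), mapping_rules)
    ds = TransferDataset(pages=pages)
    assert ds.captured_nonnull(Module.DEMOGRAPHICS) == 2 * pilot_config.n_patients
    assert ds.captured_nonnull(Module.VITAL_SIGNS) == pilot_config.vitals_points_captured
    assert ds.captured_nonnull(Module.LOCAL_LAB_BLOOD) == pilot_config.blood_nonnull_points
    assert ds.captured_nonnull(Module.LOCAL_LAB_URINE) == pilot_config.urine_points_captured
    assert ds.captured_nonnull(Module.CONMED) == (
        pilot_config.conmed_pages_electronic * pilot_config.conmed_tracked_fields_per_page
    )


def test_mapping_is_order_independent(deid_store, dictionary, mapping_rules):
    records = extract(deid_store, dictionary)
    shuffled = records.copy()
    random.Random(9).shuffle(shuffled)
    assert map_to_crf(records, mapping_rules) == map_to_crf(shuffled, mapping_rules)


def test_no_source_language_tokens_survive_mapping(deid_store, dictionary, mapping_rules):
    """All transferred values are in the EDC vocabulary (translated)."""
    pages = map_to_crf(extract(deid_store, dictionary), mapping_rules)
    zh_tokens = set(builtin_terminology().entries)
    for page in pages:
        for value in page.values.values():
            assert value not in zh_tokens


# -- serialization ------------------------------------------------------
def _sample_pages():
    return [
        CRFPage(
            Module.DEMOGRAPHICS,
            "SUBJ-01",
            0,
            values={"Sex": "Male", "Age": "60-69"},
            provenance={"Sex": Provenance.ESOURCE, "Age": Provenance.ESOURCE},
        ),
        CRFPage(
            Module.VITAL_SIGNS,
            "SUBJ-01",
            3,
            values={"Weight": None, "Height unit": "", "Pulse": "72"},
            provenance={
                "Weight": Provenance.MISSING,
                "Height unit": Provenance.ESOURCE,
                "Pulse": Provenance.MANUAL,
            },
        ),
        CRFPage(Module.CONMED, "SUBJ-02", 0),  # page with no fields
    ]


@pytest.mark.parametrize("fmt", FORMATS)
def test_round_trip_identity(fmt):
    pages = _sample_pages()
    assert deserialize(serialize(pages, fmt), fmt) == pages


@pytest.mark.parametrize("fmt", FORMATS)
def test_empty_page_list_round_trips(fmt):
    assert deserialize(serialize([], fmt), fmt) == []


@pytest.mark.parametrize("fmt", FORMATS)
def test_null_distinct_from_empty_string_after_round_trip(fmt):
    pages = deserialize(serialize(_sample_pages(), fmt), fmt)
    vitals = pages[1]
    assert vitals.values["Weight"] is None
    assert vitals.values["Height unit"] == ""


def test_cross_format_equality(deid_store, dictionary, mapping_rules):
    pages = map_to_crf(extract(deid_store, dictionary), mapping_rules)[:200]
    via_xml = deserialize(serialize(pages, "xml"), "xml")
    via_csv = deserialize(serialize(pages, "csv"), "csv")
    via_json = deserialize(serialize(pages, "json"), "json")
    assert via_xml == via_json == via_csv == pages


def test_malformed_documents_raise_schema_errors():
    with pytest.raises(SchemaError):
        deserialize(b"not json", "json")
    with pytest.raises(SchemaError):
        deserialize(b"<transfer><bogus/></transfer>", "xml")
    with pytest.raises(SchemaError):
        deserialize(b"wrong,header\n1,2\n", "csv")
    with pytest.raises(SchemaError):
        serialize([], "parquet")


# -- push ---------------------------------------------------------------
def test_push_writes_manifest_with_per_module_counts(deid_store, dictionary, mapping_rules, tmp_path):
    pages = map_to_crf(extract(deid_store, dictionary), mapping_rules)
    ds = TransferDataset(pages=pages)
    manifest = push(ds, tmp_path / "out", formats=("json", "csv"))
    assert ds.pushed is True
    counts = {e["name"]: e["records"] for e in manifest["files"]}
    for module in dictionary.modules():
        expected = len(ds.pages_for(module))
        assert counts[f"{module.value}.json"] == expected
        assert counts[f"{module.value}.csv"] == expected
    assert verify_push(tmp_path / "out") == manifest


def test_second_push_requires_force(tmp_path):
    ds = TransferDataset(pages=_sample_pages())
    push(ds, tmp_path / "a", formats=("json",))
    with pytest.raises(PushStateError):
        push(ds, tmp_path / "b", formats=("json",))
    push(ds, tmp_path / "b", formats=("json",), force=True)


def test_tampering_one_byte_fails_verification(tmp_path):
    ds = TransferDataset(pages=_sample_pages())
    push(ds, tmp_path, formats=("json",))
    target = tmp_path / "demographics.json"
    raw = bytearray(target.read_bytes())
    raw[-2] ^= 0x01
    target.write_bytes(bytes(raw))
    with pytest.raises(IntegrityError):
        verify_push(tmp_path)


def test_transfer_never_contains_paper_provenance(pilot_result):
    """Corpus scan: pushed pages carry only eSource or missing provenance."""
    transfer_dir = pilot_result.paths["transfer_dir"]
    for path in transfer_dir.glob("*.json"):
        if path.name == "manifest.json":
            continue
        for page in deserialize(path.read_bytes(), "json"):
            assert set(page.provenance.values()) <= {Provenance.ESOURCE, Provenance.MISSING}
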