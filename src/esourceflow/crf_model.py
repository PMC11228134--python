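"""CRF schema model: the trial's data-collection fields and their EHR mapping.

The study collects four case-report-form (CRF) domains — demographics, vital
signs, local laboratory results (blood and urine panels, scored separately)
and concomitant medication.  Each field carries two flags that drive the
availability metrics:

``ehr_available``
    the hospital EHR/LIMS holds the field as structured data at all;
``esource_transferable``
    the field can additionally be transferred electronically (a field may be
    present but unstructured, or excluded by deidentification policy, and
    hence not transferable).

Availability is decided at schema level: a field is counted as available if
the EHR schema declares it, independent of any particular patient's records.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field as dc_field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InvariantError, SchemaError

__all__ = [
    "Module",
    "ValueKind",
    "Provenance",
    "CRFFieldSpec",
    "FieldDictionary",
    "MappingRule",
    "CRFPage",
    "CORE_FIELD_NAMES",
    "canonical_dictionary",
    "canonical_mapping_rules",
    "load_field_dictionary",
    "validate_crf_page",
]


class Module(str, Enum):
    """The four CRF domains; the lab panels are distinct modules because they
    are scored separately."""

    DEMOGRAPHICS = "demographics"
    VITAL_SIGNS = "vital_signs"
    LOCAL_LAB_BLOOD = "local_lab_blood"
    LOCAL_LAB_URINE = "local_lab_urine"
    CONMED = "conmed"


class ValueKind(str, Enum):
    TEXT = "text"
    DATE = "date"
    INTEGER = "integer"
    DECIMAL = "decimal"
    CODED = "coded"


class Provenance(str, Enum):
    """How a CRF page value was obtained."""

    ESOURCE = "esource"
    MANUAL = "manual"
    MISSING = "missing"


@dataclass(frozen=True)
class CRFFieldSpec:
    """One CRF field and its EHR-side availability flags."""

    module_id: Module
    field_name: str
    value_kind: ValueKind
    unit: str = ""
    ehr_available: bool = False
    esource_transferable: bool = False
    requires_investigator_interpretation: bool = False

    def __post_init__(self) -> None:
        if not self.field_name:
            raise SchemaError("field_name must be non-empty")
        if self.esource_transferable and not self.ehr_available:
            raise InvariantError(
                f"{self.module_id.value}.{self.field_name}: a field cannot be "
                "electronically transferable if absent from the EHR"
            )


#: The 29 distinct collection-field names of the trial's field list.  The
#: canonical dictionary contains all of them; additional per-module slots are
#: standard CRF fields absent from the hospital systems (see docs/methods.md).
CORE_FIELD_NAMES: frozenset[str] = frozenset(
    {
        # demographics
        "Subject ID",
        "Date of birth",
        "Sex",
        "Ethnicity",
        "Race",
        "Age",
        # concomitant medication
        "Combined drug name",
        "Whether for the treatment of adverse reactions",
        "Adverse event number",
        "Combined drug start date",
        "Combined drug end date",
        "Currently still in use",
        # vital signs
        "Date of vital signs collection",
        "Weight",
        "Weight unit",
        "Body temperature",
        "Height",
        "Height unit",
        "Location of temperature measurement",
        "Systolic blood pressure",
        "Diastolic blood pressure",
        "Pulse",
        # local lab
        "Laboratory inspection name",
        "Laboratory name and address",
        "Sponsor number",
        "Laboratory number",
        "Incomplete laboratory inspection",
        "Sample collection data",
        "Inspection results",
    }
)


class FieldDictionary:
    """Ordered collection of :class:`CRFFieldSpec`, keyed by (module, name).

    Field order within a module is meaningful: it defines the tracked-cell
    order used by the synthetic study generator and the serializers.
    """

    def __init__(self, specs: Iterable[CRFFieldSpec] = ()) -> None:
        self._modules: dict[Module, dict[str, CRFFieldSpec]] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: CRFFieldSpec) -> None:
        fields = self._modules.setdefault(spec.module_id, {})
        if spec.field_name in fields:
            raise SchemaError(
                f"duplicate field {spec.field_name!r} in module {spec.module_id.value}"
            )
        fields[spec.field_name] = spec

    # -- access ---------------------------------------------------------
    def modules(self) -> list[Module]:
        return list(self._modules)

    def fields(self, module: Module) -> list[CRFFieldSpec]:
        if module not in self._modules:
            raise KeyError(f"unknown module {module!r}")
        return list(self._modules[module].values())

    def field(self, module: Module, name: str) -> CRFFieldSpec:
        return self._modules[module][name]

    def field_names(self, module: Module) -> list[str]:
        return [s.field_name for s in self.fields(module)]

    def transferable_fields(self, module: Module) -> list[str]:
        return [s.field_name for s in self.fields(module) if s.esource_transferable]

    def distinct_field_names(self) -> frozenset[str]:
        return frozenset(
            s.field_name for fields in self._modules.values() for s in fields.values()
        )

    def counts(self, module: Module) -> tuple[int, int, int]:
        """(CRF total, EHR-available, eSource-transferable) for one module."""
        specs = self.fields(module)
        return (
            len(specs),
            sum(s.ehr_available for s in specs),
            sum(s.esource_transferable for s in specs),
        )

    def __len__(self) -> int:
        return sum(len(f) for f in self._modules.values())

    def __contains__(self, module: object) -> bool:
        return module in self._modules

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FieldDictionary):
            return NotImplemented
        return self._modules == other._modules

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "modules": {
                m.value: [
                    {
                        "field_name": s.field_name,
                        "value_kind": s.value_kind.value,
                        "unit": s.unit,
                        "ehr_available": s.ehr_available,
                        "esource_transferable": s.esource_transferable,
                        "requires_investigator_interpretation": s.requires_investigator_interpretation,
                    }
                    for s in fields.values()
                ]
                for m, fields in self._modules.items()
            }
        }
        return json.dumps(doc, indent=2, sort_keys=False)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(
            [
                "module_id",
                "field_name",
                "value_kind",
                "unit",
                "ehr_available",
                "esource_transferable",
                "requires_investigator_interpretation",
            ]
        )
        for module, fields in self._modules.items():
            for s in fields.values():
                writer.writerow(
                    [
                        module.value,
                        s.field_name,
                        s.value_kind.value,
                        s.unit,
                        int(s.ehr_available),
                        int(s.esource_transferable),
                        int(s.requires_investigator_interpretation),
                    ]
                )
        return buf.getvalue()

    @classmethod
    def from_json(cls, text: str) -> "FieldDictionary":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"field dictionary is not valid JSON: {exc}") from exc
        if not isinstance(doc, Mapping) or "modules" not in doc:
            raise SchemaError("field dictionary JSON must have a 'modules' mapping")
        out = cls()
        for module_name, entries in doc["modules"].items():
            module = _parse_module(module_name)
            for entry in entries:
                out.add(
                    CRFFieldSpec(
                        module_id=module,
                        field_name=entry["field_name"],
                        value_kind=ValueKind(entry["value_kind"]),
                        unit=entry.get("unit", ""),
                        ehr_available=bool(entry["ehr_available"]),
                        esource_transferable=bool(entry["esource_transferable"]),
                        requires_investigator_interpretation=bool(
                            entry.get("requires_investigator_interpretation", False)
                        ),
                    )
                )
        return out

    @classmethod
    def from_csv(cls, text: str) -> "FieldDictionary":
        reader = csv.DictReader(io.StringIO(text))
        out = cls()
        for row in reader:
            if not row.get("field_name"):
                raise SchemaError("CSV row with empty field_name")
            out.add(
                CRFFieldSpec(
                    module_id=_parse_module(row["module_id"]),
                    field_name=row["field_name"],
                    value_kind=ValueKind(row["value_kind"]),
                    unit=row.get("unit", "") or "",
                    ehr_available=_parse_bool(row["ehr_available"]),
                    esource_transferable=_parse_bool(row["esource_transferable"]),
                    requires_investigator_interpretation=_parse_bool(
                        row.get("requires_investigator_interpretation", "0")
                    ),
                )
            )
        return out


def _parse_module(name: str) -> Module:
    try:
        return Module(name)
    except ValueError as exc:
        raise SchemaError(f"unknown module {name!r}") from exc


def _parse_bool(token: str) -> bool:
    token = str(token).strip().lower()
    if token in {"1", "true", "yes"}:
        return True
    if token in {"0", "false", "no", ""}:
        return False
    raise SchemaError(f"cannot parse boolean {token!r}")


def load_field_dictionary(source: str | Path | Mapping | None) -> FieldDictionary:
    """Load a field dictionary from JSON text, a CSV table, a mapping, or a path.

    An empty source yields an empty dictionary.  Strings are sniffed: JSON if
    they parse as JSON, otherwise CSV.
    """
    if source is None:
        return FieldDictionary()
    if isinstance(source, Mapping):
        return FieldDictionary.from_json(json.dumps(source))
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
        if source.suffix.lower() == ".csv":
            return FieldDictionary.from_csv(text)
        return FieldDictionary.from_json(text)
    text = str(source)
    if not text.strip():
        return FieldDictionary()
    try:
        json.loads(text)
    except json.JSONDecodeError:
        return FieldDictionary.from_csv(text)
    return FieldDictionary.from_json(text)


def canonical_dictionary() -> FieldDictionary:
    """The study's built-in CRF field dictionary.

    Per-module (CRF, EHR-available, eSource-transferable) counts are
    (6, 3, 2), (10, 10, 9), (10, 6, 5), (9, 6, 5) and (10, 10, 9) for
    demographics, vital signs, blood panel, urine panel and concomitant
    medication respectively.  Flag choices follow the hospital systems'
    documented gaps: trial-specific identifiers and fields needing an
    investigator's interpretation are absent from the EHR/LIMS, and the
    laboratory name-and-address is held only as unstructured text (present
    but not transferable).  Date of birth is EHR-available but excluded from
    electronic transfer by deidentification policy.
    """
    d = FieldDictionary()
    M, K = Module, ValueKind

    def add(module, name, kind, unit="", avail=False, transf=False, interp=False):
        d.add(
            CRFFieldSpec(
                module_id=module,
                field_name=name,
                value_kind=kind,
                unit=unit,
                ehr_available=avail,
                esource_transferable=transf,
                requires_investigator_interpretation=interp,
            )
        )

    # demographics: 6 / 3 / 2
    add(M.DEMOGRAPHICS, "Subject ID", K.TEXT)
    add(M.DEMOGRAPHICS, "Date of birth", K.DATE, avail=True)
    add(M.DEMOGRAPHICS, "Sex", K.CODED, avail=True, transf=True)
    add(M.DEMOGRAPHICS, "Ethnicity", K.CODED)
    add(M.DEMOGRAPHICS, "Race", K.CODED)
    add(M.DEMOGRAPHICS, "Age", K.INTEGER, unit="years", avail=True, transf=True)

    # vital signs: 10 / 10 / 9 (measurement location is free text, not transferable)
    add(M.VITAL_SIGNS, "Date of vital signs collection", K.DATE, avail=True, transf=True)
    add(M.VITAL_SIGNS, "Weight", K.DECIMAL, unit="kg", avail=True, transf=True)
    add(M.VITAL_SIGNS, "Weight unit", K.CODED, avail=True, transf=True)
    add(M.VITAL_SIGNS, "Body temperature", K.DECIMAL, unit="C", avail=True, transf=True)
    add(M.VITAL_SIGNS, "Height", K.DECIMAL, unit="cm", avail=True, transf=True)
    add(M.VITAL_SIGNS, "Height unit", K.CODED, avail=True, transf=True)
    add(M.VITAL_SIGNS, "Location of temperature measurement", K.CODED, avail=True)
    add(M.VITAL_SIGNS, "Systolic blood pressure", K.INTEGER, unit="mmHg", avail=True, transf=True)
    add(M.VITAL_SIGNS, "Diastolic blood pressure", K.INTEGER, unit="mmHg", avail=True, transf=True)
    add(M.VITAL_SIGNS, "Pulse", K.INTEGER, unit="bpm", avail=True, transf=True)

    # local lab, blood panel: 10 / 6 / 5
    for module in (M.LOCAL_LAB_BLOOD, M.LOCAL_LAB_URINE):
        add(module, "Laboratory inspection name", K.CODED, avail=True, transf=True)
        add(module, "Laboratory name and address", K.TEXT, avail=True)
        add(module, "Sponsor number", K.TEXT)
        add(module, "Laboratory number", K.TEXT, avail=True, transf=True)
        add(module, "Incomplete laboratory inspection", K.CODED, avail=True, transf=True)
        add(module, "Sample collection data", K.DATE, avail=True, transf=True)
        add(module, "Inspection results", K.DECIMAL, avail=True, transf=True)
        add(module, "Lab ID", K.TEXT)
        add(module, "Clinically Significant", K.CODED, interp=True)
    add(M.LOCAL_LAB_BLOOD, "Not Done", K.CODED, interp=True)  # blood only: 10 vs 9 fields

    # concomitant medication: 10 / 10 / 9 (AE-relatedness needs investigator judgment)
    add(M.CONMED, "Combined drug name", K.CODED, avail=True, transf=True)
    add(
        M.CONMED,
        "Whether for the treatment of adverse reactions",
        K.CODED,
        avail=True,
        interp=True,
    )
    add(M.CONMED, "Adverse event number", K.TEXT, avail=True, transf=True)
    add(M.CONMED, "Combined drug start date", K.DATE, avail=True, transf=True)
    add(M.CONMED, "Combined drug end date", K.DATE, avail=True, transf=True)
    add(M.CONMED, "Currently still in use", K.CODED, avail=True, transf=True)
    add(M.CONMED, "Dose", K.DECIMAL, avail=True, transf=True)
    add(M.CONMED, "Dose unit", K.CODED, avail=True, transf=True)
    add(M.CONMED, "Frequency", K.CODED, avail=True, transf=True)
    add(M.CONMED, "Route", K.CODED, avail=True, transf=True)

    missing = CORE_FIELD_NAMES - d.distinct_field_names()
    if missing:  # pragma: no cover - construction bug guard
        raise InvariantError(f"canonical dictionary missing core names: {sorted(missing)}")
    return d


@dataclass(frozen=True)
class MappingRule:
    """Maps one structured EHR field path onto one transferable CRF field."""

    ehr_field_path: str
    module_id: Module
    crf_field: str
    transform_kind: str = "copy"  # copy | dictionary_translate | unit_convert | derive
    dictionary_ref: str = ""

    def __post_init__(self) -> None:
        if self.transform_kind not in {"copy", "dictionary_translate", "unit_convert", "derive"}:
            raise SchemaError(f"unknown transform_kind {self.transform_kind!r}")
        if self.transform_kind == "dictionary_translate" and not self.dictionary_ref:
            raise InvariantError(
                f"rule for {self.crf_field!r}: dictionary_translate requires dictionary_ref"
            )


#: EHR-side structured field paths for every transferable CRF field, in the
#: hospital system's own (romanized) vocabulary.
EHR_FIELD_PATHS: dict[tuple[Module, str], str] = {
    (Module.DEMOGRAPHICS, "Sex"): "demo.xingbie",
    (Module.DEMOGRAPHICS, "Age"): "demo.nianling",
    (Module.VITAL_SIGNS, "Date of vital signs collection"): "vs.celiang_riqi",
    (Module.VITAL_SIGNS, "Weight"): "vs.tizhong",
    (Module.VITAL_SIGNS, "Weight unit"): "vs.tizhong_danwei",
    (Module.VITAL_SIGNS, "Body temperature"): "vs.tiwen",
    (Module.VITAL_SIGNS, "Height"): "vs.shengao",
    (Module.VITAL_SIGNS, "Height unit"): "vs.shengao_danwei",
    (Module.VITAL_SIGNS, "Systolic blood pressure"): "vs.shousuoya",
    (Module.VITAL_SIGNS, "Diastolic blood pressure"): "vs.shuzhangya",
    (Module.VITAL_SIGNS, "Pulse"): "vs.maibo",
    (Module.LOCAL_LAB_BLOOD, "Laboratory inspection name"): "lab.jiancha_mingcheng",
    (Module.LOCAL_LAB_BLOOD, "Laboratory number"): "lab.huayan_hao",
    (Module.LOCAL_LAB_BLOOD, "Incomplete laboratory inspection"): "lab.weiwancheng",
    (Module.LOCAL_LAB_BLOOD, "Sample collection data"): "lab.caiyang_riqi",
    (Module.LOCAL_LAB_BLOOD, "Inspection results"): "lab.jiancha_jieguo",
    (Module.LOCAL_LAB_URINE, "Laboratory inspection name"): "lab.jiancha_mingcheng",
    (Module.LOCAL_LAB_URINE, "Laboratory number"): "lab.huayan_hao",
    (Module.LOCAL_LAB_URINE, "Incomplete laboratory inspection"): "lab.weiwancheng",
    (Module.LOCAL_LAB_URINE, "Sample collection data"): "lab.caiyang_riqi",
    (Module.LOCAL_LAB_URINE, "Inspection results"): "lab.jiancha_jieguo",
    (Module.CONMED, "Combined drug name"): "cm.yaopin_mingcheng",
    (Module.CONMED, "Adverse event number"): "cm.buliang_shijian_hao",
    (Module.CONMED, "Combined drug start date"): "cm.kaishi_riqi",
    (Module.CONMED, "Combined drug end date"): "cm.jieshu_riqi",
    (Module.CONMED, "Currently still in use"): "cm.shifou_shiyong",
    (Module.CONMED, "Dose"): "cm.jiliang",
    (Module.CONMED, "Dose unit"): "cm.jiliang_danwei",
    (Module.CONMED, "Frequency"): "cm.pinci",
    (Module.CONMED, "Route"): "cm.geiyao_tujing",
}

#: Transferable coded fields whose source tokens need terminology translation.
_TRANSLATED_FIELDS = {
    "Sex",
    "Weight unit",
    "Height unit",
    "Laboratory inspection name",
    "Incomplete laboratory inspection",
    "Combined drug name",
    "Currently still in use",
    "Dose unit",
    "Frequency",
    "Route",
}


def canonical_mapping_rules(dictionary: FieldDictionary | None = None) -> list[MappingRule]:
    """One rule per transferable field of the canonical dictionary."""
    dictionary = dictionary or canonical_dictionary()
    rules: list[MappingRule] = []
    for module in dictionary.modules():
        for name in dictionary.transferable_fields(module):
            path = EHR_FIELD_PATHS[(module, name)]
            if name in _TRANSLATED_FIELDS:
                rules.append(
                    MappingRule(path, module, name, "dictionary_translate", "zh2edc")
                )
            else:
                rules.append(MappingRule(path, module, name, "copy"))
    return rules


@dataclass
class CRFPage:
    """One filled CRF page: a (module, subject, page-index) cell map.

    ``page_index`` is the visit number, lab-test number or medication entry
    number within the module.  ``values`` maps field names to value-or-null;
    ``provenance`` records per field whether the value arrived through
    eSource, manual entry, or is missing.
    """

    module_id: Module
    subject_id: str
    page_index: int
    values: dict[str, str | None] = dc_field(default_factory=dict)
    provenance: dict[str, Provenance] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.page_index < 0:
            raise InvariantError("page_index must be non-negative")
        for key in self.values:
            self.provenance.setdefault(
                key, Provenance.MISSING if self.values[key] is None else Provenance.MANUAL
            )

    def sort_key(self) -> tuple:
        return (self.module_id.value, self.subject_id, self.page_index)


def _value_type_ok(value: str, kind: ValueKind) -> bool:
    if kind is ValueKind.TEXT:
        return True
    if kind is ValueKind.CODED:
        return bool(value.strip())
    if kind is ValueKind.INTEGER:
        try:
            int(value)
            return True
        except ValueError:
            return False
    if kind is ValueKind.DECIMAL:
        try:
            float(value)
            return True
        except ValueError:
            return False
    if kind is ValueKind.DATE:
        # calendar date pre-deidentification, or a signed day offset after
        try:
            int(value)
            return True
        except ValueError:
            pass
        try:
            date.fromisoformat(value)
            return True
        except ValueError:
            return False
    return False  # pragma: no cover


def validate_crf_page(page: CRFPage, dictionary: FieldDictionary) -> list[str]:
    """Type-check a page against the dictionary; returns human-readable violations."""
    if page.module_id not in dictionary:
        raise KeyError(f"unknown module {page.module_id!r}")
    known = set(dictionary.field_names(page.module_id))
    violations: list[str] = []
    for name, value in page.values.items():
        if name not in known:
            violations.append(f"unknown field {name!r} for module {page.module_id.value}")
            continue
        if value is None:
            continue
        kind = dictionary.field(page.module_id, name).value_kind
        if not _value_type_ok(value, kind):
            violations.append(
                f"field {name!r}: value {value!r} does not parse as {kind.value}"
            )
    for name in page.values:
        if name not in page.provenance:
            violations.append(f"field {name!r}: provenance undefined")
    return violations
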