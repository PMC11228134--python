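"""Deterministic synthetic study generator.

Generates a hospital EHR store together with the parallel manually-entered
EDC truth set the quality evaluation compares against.  The generator is a
pure function of its :class:`StudyConfig`: the same config (including the
seed) yields byte-identical serialized output.

The study's value-level denominators (how many vital-sign points a visit
schedule requires, how many blood tests were run, how many medication pages
exist) are opaque design counts taken directly from the configuration rather
than derived from a visit calendar — the generator distributes them over
patients and pages.  Electronic-versus-paper provenance is assigned so that
exactly the configured number of points is capturable through eSource:

* demographics — one electronic record per patient (2 tracked fields);
* vital signs / urine panel — the first ``*_captured`` cells (in patient,
  page, field order) live in electronic records; the rest exist only on
  paper forms (paper-provenance records);
* blood panel — every test record is electronic, but only
  ``blood_nonnull_points`` of the ``tests × 5`` cells are nonnull in the
  EHR (laboratory feeds are the one fully electronic source);
* concomitant medication — the first ``conmed_pages_electronic`` pages are
  electronic, the rest are paper tracking forms.

With ``corruption_rate > 0`` each electronic cell is independently replaced
by a gross transcription error (a value guaranteed to mismatch the truth
even after categorical coarsening by the deidentification layer).
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

from .crf_model import CRFPage, Module, Provenance
from .errors import ConfigError, SchemaError
from . import terminology as term

__all__ = [
    "StudyConfig",
    "EHRRecord",
    "EHRStore",
    "EDCTruth",
    "generate_study",
    "pilot_study_config",
    "TRACKED_FIELDS",
    "LAB_PANEL_WIDTH",
]

#: Number of transferable cells per laboratory test record.
LAB_PANEL_WIDTH = 5

#: Tracked (value-level) fields per module, in cell order.  These are the
#: fields whose points the completeness denominator counts.
TRACKED_FIELDS: dict[Module, list[str]] = {
    Module.DEMOGRAPHICS: ["Sex", "Age"],
    Module.VITAL_SIGNS: [
        "Date of vital signs collection",
        "Weight",
        "Weight unit",
        "Body temperature",
        "Height",
        "Height unit",
        "Systolic blood pressure",
        "Diastolic blood pressure",
        "Pulse",
    ],
    Module.LOCAL_LAB_BLOOD: [
        "Laboratory inspection name",
        "Laboratory number",
        "Incomplete laboratory inspection",
        "Sample collection data",
        "Inspection results",
    ],
    Module.LOCAL_LAB_URINE: [
        "Laboratory inspection name",
        "Laboratory number",
        "Incomplete laboratory inspection",
        "Sample collection data",
        "Inspection results",
    ],
    Module.CONMED: [
        "Combined drug name",
        "Combined drug start date",
        "Combined drug end date",
        "Currently still in use",
        "Adverse event number",
        "Dose",
        "Dose unit",
        "Frequency",
        "Route",
    ],
}

#: EHR payload path for every tracked field (tracked fields are a subset of
#: the transferable fields, whose paths the CRF model declares).
from .crf_model import EHR_FIELD_PATHS as _FIELD_PATHS  # noqa: E402


class StudyConfig(BaseModel):
    """Design counts and noise parameters of one synthetic study."""

    n_patients: int = Field(ge=0)
    n_visits: int | None = Field(default=None, description="informational only")
    blood_tests_total: int = Field(default=0, ge=0)
    blood_nonnull_points: int = Field(default=0, ge=0)
    urine_points_required: int = Field(default=0, ge=0)
    urine_points_captured: int = Field(default=0, ge=0)
    vitals_points_required: int = Field(default=0, ge=0)
    vitals_points_captured: int = Field(default=0, ge=0)
    conmed_pages: int = Field(default=0, ge=0)
    conmed_pages_electronic: int = Field(default=0, ge=0)
    conmed_tracked_fields_per_page: int = Field(default=2, ge=1, le=9)
    corruption_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0
    base_date: date = date(2020, 12, 15)

    @model_validator(mode="after")
    def _captured_within_required(self) -> "StudyConfig":
        checks = [
            ("vitals_points_captured", self.vitals_points_captured, self.vitals_points_required),
            ("urine_points_captured", self.urine_points_captured, self.urine_points_required),
            ("conmed_pages_electronic", self.conmed_pages_electronic, self.conmed_pages),
            (
                "blood_nonnull_points",
                self.blood_nonnull_points,
                self.blood_tests_total * LAB_PANEL_WIDTH,
            ),
        ]
        for name, captured, required in checks:
            if captured > required:
                raise ConfigError(f"{name}={captured} exceeds its required total {required}")
        return self


def pilot_study_config(seed: int = 0) -> StudyConfig:
    """Configuration reproducing the pilot study's published counts.

    Six patients; vital signs 1812 required / 24 captured points; 2708 blood
    tests (13,540 points, 12,968 nonnull); urine 40 / 15; 38 concomitant-
    medication pages with 2 tracked fields each, 7 pages electronic (the
    remaining ~80% are paper tracking forms); no transcription noise.
    """
    return StudyConfig(
        n_patients=6,
        blood_tests_total=2708,
        blood_nonnull_points=12968,
        urine_points_required=40,
        urine_points_captured=15,
        vitals_points_required=1812,
        vitals_points_captured=24,
        conmed_pages=38,
        conmed_pages_electronic=7,
        conmed_tracked_fields_per_page=2,
        corruption_rate=0.0,
        seed=seed,
        base_date=date(2020, 12, 15),
    )


@dataclass
class EHRRecord:
    """One structured source record with its provenance."""

    patient_id: str
    domain: Module
    page_index: int
    record_date: date | int
    provenance: str  # "electronic" | "paper"
    payload: dict[str, str]

    def to_json(self) -> str:
        rd = self.record_date
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "domain": self.domain.value,
                "page_index": self.page_index,
                "record_date": rd.isoformat() if isinstance(rd, date) else rd,
                "provenance": self.provenance,
                "payload": self.payload,
            },
            ensure_ascii=False,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "EHRRecord":
        doc = json.loads(line)
        rd = doc["record_date"]
        return cls(
            patient_id=doc["patient_id"],
            domain=Module(doc["domain"]),
            page_index=doc["page_index"],
            record_date=rd if isinstance(rd, int) else date.fromisoformat(rd),
            provenance=doc["provenance"],
            payload=doc["payload"],
        )


@dataclass
class EHRStore:
    """A set of EHR records plus the patient roster (in enrolment order)."""

    records: list[EHRRecord] = dc_field(default_factory=list)
    patients: list[str] = dc_field(default_factory=list)
    deidentified: bool = False

    def electronic(self) -> list[EHRRecord]:
        return [r for r in self.records if r.provenance == "electronic"]

    def to_jsonl(self) -> str:
        header = json.dumps(
            {
                "kind": "esourceflow_ehr_store",
                "version": 1,
                "deidentified": self.deidentified,
                "patients": self.patients,
            },
            ensure_ascii=False,
            sort_keys=True,
        )
        return "\n".join([header] + [r.to_json() for r in self.records]) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "EHRStore":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            return cls()
        header = json.loads(lines[0])
        if header.get("kind") != "esourceflow_ehr_store":
            raise SchemaError("not an EHR store JSON-lines file (missing header)")
        return cls(
            records=[EHRRecord.from_json(ln) for ln in lines[1:]],
            patients=list(header.get("patients", [])),
            deidentified=bool(header.get("deidentified", False)),
        )


@dataclass
class EDCTruth:
    """The manually-entered EDC counterpart: every required data point,
    nonnull, in the sponsor's vocabulary."""

    pages: list[CRFPage] = dc_field(default_factory=list)

    def pages_for(self, module: Module) -> list[CRFPage]:
        return [p for p in self.pages if p.module_id == module]

    def required_points(self, module: Module) -> int:
        return sum(len(p.values) for p in self.pages_for(module))

    def cell_map(self) -> dict[tuple[Module, str, int, str], str | None]:
        return {
            (p.module_id, p.subject_id, p.page_index, name): value
            for p in self.pages
            for name, value in p.values.items()
        }

    def to_module_csv(self, module: Module) -> bytes:
        from .formats import serialize

        return serialize(self.pages_for(module), "csv")

    @classmethod
    def from_module_csvs(cls, blobs: list[bytes]) -> "EDCTruth":
        from .formats import deserialize

        pages: list[CRFPage] = []
        for blob in blobs:
            pages.extend(deserialize(blob, "csv"))
        return cls(pages=pages)


# -- identity synthesis -------------------------------------------------
_SURNAMES = ["王", "李", "张", "刘", "陈", "杨", "赵", "黄", "周", "吴"]
_GIVEN = ["伟", "芳", "娜", "敏", "静", "磊", "军", "洋", "勇", "艳"]
_OCCUPATIONS = ["教师", "工人", "医生", "农民", "职员"]
_LOCATIONS = ["腋下", "口腔", "耳温"]


@dataclass
class _Patient:
    index: int
    patient_id: str
    subject_id: str
    name: str
    national_id: str
    phone: str
    address: str
    mrn: str
    email: str
    sex_zh: str
    sex_en: str
    age: int
    dob: date
    occupation: str
    start: date


def _rng(config: StudyConfig, label: str) -> random.Random:
    return random.Random(f"{config.seed}:{label}")


def _make_patients(config: StudyConfig) -> list[_Patient]:
    rng = _rng(config, "identity")
    patients = []
    for i in range(config.n_patients):
        sex_zh, sex_en = term.SEX_TOKENS[rng.randrange(2)]
        age = rng.randint(28, 79)
        dob = config.base_date - timedelta(days=age * 365 + rng.randint(0, 364))
        patients.append(
            _Patient(
                index=i,
                patient_id=f"PID{rng.randint(10**6, 10**7 - 1)}",
                subject_id=f"S{i + 1:02d}",
                name=rng.choice(_SURNAMES) + rng.choice(_GIVEN),
                national_id="".join(str(rng.randrange(10)) for _ in range(18)),
                phone="13" + "".join(str(rng.randrange(10)) for _ in range(9)),
                address=f"北京市海淀区学院路{rng.randint(1, 99)}号",
                mrn=f"MRN{rng.randint(10**5, 10**6 - 1)}",
                email=f"patient{i + 1}@example.org",
                sex_zh=sex_zh,
                sex_en=sex_en,
                age=age,
                dob=dob,
                occupation=rng.choice(_OCCUPATIONS),
                start=config.base_date + timedelta(days=rng.randint(0, 30)),
            )
        )
    return patients


def _split_counts(total: int, n: int) -> list[int]:
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


# -- corruption ---------------------------------------------------------
def _corrupt(path: str, value: str, rng: random.Random) -> str:
    """Replace a source value by a gross transcription error that still
    mismatches after date shifting, age binning or ID categorization."""
    if path.endswith("_riqi"):  # any date field
        return (date.fromisoformat(value) + timedelta(days=997)).isoformat()
    if path == "demo.nianling":  # lands in a different 10-year bin, stays in [0, 89]
        return str((int(value) + 23) % 90)
    if path == "demo.xingbie":
        return "女" if value == "男" else "男"
    if path == "lab.huayan_hao":  # flips the accession prefix, hence the category
        return ("U" if value.startswith("B") else "B") + value[1:]
    for vocab in (
        term.BLOOD_TEST_TOKENS,
        term.URINE_TEST_TOKENS,
        term.DRUG_TOKENS,
        term.YES_NO_TOKENS,
        term.UNIT_TOKENS,
        term.FREQUENCY_TOKENS,
        term.ROUTE_TOKENS,
    ):
        tokens = [src for src, _ in vocab]
        if value in tokens:
            others = [t for t in tokens if t != value]
            return rng.choice(others)
    try:
        iv = int(value)
        return str(iv + rng.randint(100, 999))
    except ValueError:
        pass
    try:
        fv = float(value)
        return f"{fv + rng.randint(100, 999):.2f}"
    except ValueError:
        return value + "X"


class _Corruptor:
    def __init__(self, config: StudyConfig) -> None:
        self.rate = config.corruption_rate
        self.rng = _rng(config, "corruption")

    def __call__(self, path: str, value: str) -> str:
        if self.rate > 0 and self.rng.random() < self.rate:
            return _corrupt(path, value, self.rng)
        return value


# -- per-module generation ----------------------------------------------
def _gen_demographics(config, patients, corrupt, store, truth) -> None:
    for p in patients:
        truth.pages.append(
            CRFPage(
                Module.DEMOGRAPHICS,
                p.subject_id,
                0,
                values={"Sex": p.sex_en, "Age": str(p.age)},
                provenance={"Sex": Provenance.MANUAL, "Age": Provenance.MANUAL},
            )
        )
        payload = {
            "demo.xingming": p.name,
            "demo.shenfenzheng": p.national_id,
            "demo.dianhua": p.phone,
            "demo.dizhi": p.address,
            "demo.youxiang": p.email,
            "demo.bingli_hao": p.mrn,
            "demo.chusheng_riqi": p.dob.isoformat(),
            "demo.xingbie": corrupt("demo.xingbie", p.sex_zh),
            "demo.nianling": corrupt("demo.nianling", str(p.age)),
            "demo.zhiye": p.occupation,
        }
        store.records.append(
            EHRRecord(p.patient_id, Module.DEMOGRAPHICS, 0, p.start, "electronic", payload)
        )


def _gen_vitals(config, patients, corrupt, store, truth) -> None:
    fields = TRACKED_FIELDS[Module.VITAL_SIGNS]
    rng = _rng(config, "vitals")
    per_patient = _split_counts(config.vitals_points_required, len(patients))
    captured_left = config.vitals_points_captured
    for p, n_cells in zip(patients, per_patient):
        height = round(rng.uniform(150, 185), 1)
        n_pages = math.ceil(n_cells / len(fields))
        remaining = n_cells
        for page_idx in range(n_pages):
            page_fields = fields[: min(len(fields), remaining)]
            remaining -= len(page_fields)
            page_date = p.start + timedelta(days=7 * page_idx)
            cells = {}
            for name in page_fields:
                if name == "Date of vital signs collection":
                    cells[name] = page_date.isoformat()
                elif name == "Weight":
                    cells[name] = str(round(rng.uniform(45, 90), 1))
                elif name == "Weight unit":
                    cells[name] = "kg"
                elif name == "Body temperature":
                    cells[name] = str(round(rng.uniform(36.0, 37.5), 1))
                elif name == "Height":
                    cells[name] = str(height)
                elif name == "Height unit":
                    cells[name] = "cm"
                elif name == "Systolic blood pressure":
                    cells[name] = str(rng.randint(95, 140))
                elif name == "Diastolic blood pressure":
                    cells[name] = str(rng.randint(60, 90))
                else:  # Pulse
                    cells[name] = str(rng.randint(55, 100))
            truth.pages.append(
                CRFPage(
                    Module.VITAL_SIGNS,
                    p.subject_id,
                    page_idx,
                    values=dict(cells),
                    provenance={k: Provenance.MANUAL for k in cells},
                )
            )
            n_electronic = min(captured_left, len(page_fields))
            captured_left -= n_electronic
            if n_electronic > 0:
                payload = {}
                for name in page_fields[:n_electronic]:
                    path = _FIELD_PATHS[(Module.VITAL_SIGNS, name)]
                    src = _to_source_token(name, cells[name])
                    payload[path] = corrupt(path, src)
                store.records.append(
                    EHRRecord(p.patient_id, Module.VITAL_SIGNS, page_idx, page_date, "electronic", payload)
                )
            else:
                payload = {
                    _FIELD_PATHS[(Module.VITAL_SIGNS, name)]: _to_source_token(name, cells[name])
                    for name in page_fields
                }
                payload["vs.celiang_buwei"] = rng.choice(_LOCATIONS)
                store.records.append(
                    EHRRecord(p.patient_id, Module.VITAL_SIGNS, page_idx, page_date, "paper", payload)
                )


_UNIT_TO_SOURCE = {en: zh for zh, en in term.UNIT_TOKENS}


def _to_source_token(field_name: str, edc_value: str) -> str:
    """Source-system representation of a truth value (reverse translation)."""
    if field_name in {"Weight unit", "Height unit", "Dose unit"}:
        return _UNIT_TO_SOURCE[edc_value]
    return edc_value


def _gen_lab(config, patients, corrupt, store, truth, module: Module) -> None:
    fields = TRACKED_FIELDS[module]
    if module is Module.LOCAL_LAB_BLOOD:
        rng = _rng(config, "blood")
        tokens = term.BLOOD_TEST_TOKENS
        prefix = "B"
        n_tests = config.blood_tests_total
        total_cells = n_tests * LAB_PANEL_WIDTH
        null_cells = set(
            rng.sample(range(total_cells), total_cells - config.blood_nonnull_points)
        ) if n_tests else set()
        electronic_cells = None  # all tests electronic; nulls carve out completeness
    else:
        rng = _rng(config, "urine")
        tokens = term.URINE_TEST_TOKENS
        prefix = "U"
        n_tests = math.ceil(config.urine_points_required / LAB_PANEL_WIDTH)
        null_cells = set()
        electronic_cells = config.urine_points_captured

    per_patient_pages: list[list[int]] = [[] for _ in patients]
    for g in range(n_tests):
        per_patient_pages[g % len(patients)].append(g)

    cell_index = 0
    remaining_points = config.urine_points_required if module is Module.LOCAL_LAB_URINE else None
    for p, global_pages in zip(patients, per_patient_pages):
        for local_idx, g in enumerate(global_pages):
            zh_name, en_name = tokens[g % len(tokens)]
            accession = f"{prefix}2021{g:05d}"
            sample_date = p.start + timedelta(days=local_idx)
            result = str(round(rng.uniform(0.5, 200.0), 2))
            cells = {
                "Laboratory inspection name": en_name,
                "Laboratory number": accession,
                "Incomplete laboratory inspection": "No",
                "Sample collection data": sample_date.isoformat(),
                "Inspection results": result,
            }
            page_fields = fields
            if remaining_points is not None:
                page_fields = fields[: min(len(fields), remaining_points)]
                remaining_points -= len(page_fields)
            truth.pages.append(
                CRFPage(
                    module,
                    p.subject_id,
                    local_idx,
                    values={k: cells[k] for k in page_fields},
                    provenance={k: Provenance.MANUAL for k in page_fields},
                )
            )
            src = {
                "lab.jiancha_mingcheng": zh_name,
                "lab.huayan_hao": accession,
                "lab.weiwancheng": "否",
                "lab.caiyang_riqi": sample_date.isoformat(),
                "lab.jiancha_jieguo": result,
            }
            path_of = {name: _FIELD_PATHS[(module, name)] for name in page_fields}
            if module is Module.LOCAL_LAB_BLOOD:
                payload = {}
                for k, name in enumerate(page_fields):
                    if cell_index + k in null_cells:
                        continue
                    path = path_of[name]
                    payload[path] = corrupt(path, src[path])
                cell_index += len(page_fields)
                store.records.append(
                    EHRRecord(p.patient_id, module, local_idx, sample_date, "electronic", payload)
                )
            else:
                n_elec = min(electronic_cells, len(page_fields))
                electronic_cells -= n_elec
                if n_elec > 0:
                    payload = {}
                    for name in page_fields[:n_elec]:
                        path = path_of[name]
                        payload[path] = corrupt(path, src[path])
                    store.records.append(
                        EHRRecord(p.patient_id, module, local_idx, sample_date, "electronic", payload)
                    )
                else:
                    payload = {path_of[name]: src[path_of[name]] for name in page_fields}
                    store.records.append(
                        EHRRecord(p.patient_id, module, local_idx, sample_date, "paper", payload)
                    )


def _gen_conmed(config, patients, corrupt, store, truth) -> None:
    tracked = TRACKED_FIELDS[Module.CONMED][: config.conmed_tracked_fields_per_page]
    rng = _rng(config, "conmed")
    per_patient_pages: list[list[int]] = [[] for _ in patients]
    for g in range(config.conmed_pages):
        per_patient_pages[g % len(patients)].append(g)
    for p, global_pages in zip(patients, per_patient_pages):
        for local_idx, g in enumerate(global_pages):
            zh_drug, en_drug = term.DRUG_TOKENS[g % len(term.DRUG_TOKENS)]
            start_date = p.start + timedelta(days=rng.randint(0, 200))
            zh_freq, en_freq = rng.choice(term.FREQUENCY_TOKENS)
            zh_route, en_route = rng.choice(term.ROUTE_TOKENS)
            dose = str(rng.choice([5, 10, 20, 50, 100, 200, 500]))
            edc = {
                "Combined drug name": en_drug,
                "Combined drug start date": start_date.isoformat(),
                "Combined drug end date": (start_date + timedelta(days=rng.randint(1, 60))).isoformat(),
                "Currently still in use": "No",
                "Adverse event number": f"AE{g + 1:03d}",
                "Dose": dose,
                "Dose unit": "mg",
                "Frequency": en_freq,
                "Route": en_route,
            }
            src = {
                "cm.yaopin_mingcheng": zh_drug,
                "cm.kaishi_riqi": edc["Combined drug start date"],
                "cm.jieshu_riqi": edc["Combined drug end date"],
                "cm.shifou_shiyong": "否",
                "cm.buliang_shijian_hao": edc["Adverse event number"],
                "cm.jiliang": dose,
                "cm.jiliang_danwei": "毫克",
                "cm.pinci": zh_freq,
                "cm.geiyao_tujing": zh_route,
            }
            truth.pages.append(
                CRFPage(
                    Module.CONMED,
                    p.subject_id,
                    local_idx,
                    values={k: edc[k] for k in tracked},
                    provenance={k: Provenance.MANUAL for k in tracked},
                )
            )
            electronic = g < config.conmed_pages_electronic
            path_of = {name: _FIELD_PATHS[(Module.CONMED, name)] for name in tracked}
            if electronic:
                payload = {path_of[n]: corrupt(path_of[n], src[path_of[n]]) for n in tracked}
                store.records.append(
                    EHRRecord(p.patient_id, Module.CONMED, local_idx, start_date, "electronic", payload)
                )
            else:
                payload = {path_of[n]: src[path_of[n]] for n in tracked}
                store.records.append(
                    EHRRecord(p.patient_id, Module.CONMED, local_idx, start_date, "paper", payload)
                )


def generate_study(config: StudyConfig) -> tuple[EHRStore, EDCTruth]:
    """Generate the EHR store and parallel EDC truth for one study design.

    Deterministic: all randomness flows from ``config.seed`` through
    per-section generators drawn in a fixed order (identity, corruption,
    vitals, blood, urine, conmed).
    """
    store = EHRStore()
    truth = EDCTruth()
    if config.n_patients == 0:
        return store, truth
    patients = _make_patients(config)
    store.patients = [p.patient_id for p in patients]
    corrupt = _Corruptor(config)
    _gen_demographics(config, patients, corrupt, store, truth)
    if config.vitals_points_required:
        _gen_vitals(config, patients, corrupt, store, truth)
    if config.blood_tests_total:
        _gen_lab(config, patients, corrupt, store, truth, Module.LOCAL_LAB_BLOOD)
    if config.urine_points_required:
        _gen_lab(config, patients, corrupt, store, truth, Module.LOCAL_LAB_URINE)
    if config.conmed_pages:
        _gen_conmed(config, patients, corrupt, store, truth)
    return store, truth
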