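"""Three-layer deidentification with an append-only audit trail.

Layer 1 drops configured direct-identifier columns before anything else is
processed.  Layer 2 masks the 18 HIPAA Safe-Harbor identifier categories at
field level (dates become signed day offsets from a base date, record
numbers become surrogates, contact details are removed).  Layer 3 applies
the project rules: ID values are reduced to categories, ages to bins, and
low-frequency values — quasi-identifiers by rarity — are set to null.

Every mutation appends one audit entry per layer that touched the value.
Audit entries carry SHA-256 digests of the before/after values, never the
values themselves, so the log leaks nothing.  When ``reversible`` is set, a
:class:`ReversalKey` mapping originals to surrogates is returned; it is
stored separately and never serialized into a transfer dataset.
"""

from __future__ import annotations

import copy
import hashlib
import json
import re
from collections import Counter
from dataclasses import dataclass, field as dc_field
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Callable, Literal, Sequence

from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError, DomainError
from .synthetic_ehr import EHRRecord, EHRStore

__all__ = [
    "DeidConfig",
    "HipaaField",
    "IdRule",
    "AgeBin",
    "AuditEntry",
    "AuditLog",
    "ReversalKey",
    "DeidResult",
    "shift_date",
    "bin_age",
    "categorize_id",
    "suppress_low_frequency",
    "apply_safe_harbor",
    "deidentify_study",
    "default_deid_config",
]

# Default masking action for each HIPAA Safe-Harbor category (1..18):
# dates are shifted; record/account-style identifiers get surrogates;
# everything else is removed outright.
_CATEGORY_ACTIONS: dict[int, str] = {
    **{c: "remove" for c in range(1, 19)},
    3: "shift",
    7: "surrogate",
    8: "surrogate",
    9: "surrogate",
    10: "surrogate",
    11: "surrogate",
    18: "surrogate",
}


class HipaaField(BaseModel):
    path: str
    category: int = Field(ge=1, le=18)
    action: Literal["auto", "remove", "surrogate", "shift"] = "auto"

    def resolved_action(self) -> str:
        return self.action if self.action != "auto" else _CATEGORY_ACTIONS[self.category]


class IdRule(BaseModel):
    pattern: str  # regular expression, searched; "" matches everything
    label: str


class AgeBin(BaseModel):
    lower: int
    upper: int  # inclusive
    label: str


def _default_age_bins() -> list[AgeBin]:
    bins = [AgeBin(lower=lo, upper=lo + 9, label=f"{lo}-{lo + 9}") for lo in range(0, 90, 10)]
    bins.append(AgeBin(lower=90, upper=130, label=">=90"))
    return bins


class DeidConfig(BaseModel):
    """Rules for the three deidentification layers."""

    layer1_drop: list[str] = Field(
        default_factory=lambda: [
            "demo.xingming",
            "demo.shenfenzheng",
            "demo.dianhua",
            "demo.dizhi",
        ]
    )
    pseudonymize_patient_id: bool = True
    hipaa_fields: list[HipaaField] = Field(
        default_factory=lambda: [
            HipaaField(path="demo.youxiang", category=6),
            HipaaField(path="demo.bingli_hao", category=8),
            HipaaField(path="demo.chusheng_riqi", category=3),
            HipaaField(path="vs.celiang_riqi", category=3),
            HipaaField(path="lab.caiyang_riqi", category=3),
            HipaaField(path="cm.kaishi_riqi", category=3),
            HipaaField(path="cm.jieshu_riqi", category=3),
        ]
    )
    base_date_policy: Literal["study_fixed", "per_patient_first_record"] = (
        "per_patient_first_record"
    )
    study_base_date: date | None = None
    id_fields: dict[str, str] = Field(default_factory=lambda: {"lab.huayan_hao": "accession"})
    id_category_maps: dict[str, list[IdRule]] = Field(
        default_factory=lambda: {
            "accession": [
                IdRule(pattern="^B", label="ACC-BLOOD"),
                IdRule(pattern="^U", label="ACC-URINE"),
                IdRule(pattern="", label="ACC-OTHER"),
            ]
        }
    )
    age_fields: list[str] = Field(default_factory=lambda: ["demo.nianling"])
    age_bins: list[AgeBin] = Field(default_factory=_default_age_bins)
    low_freq_fields: list[str] = Field(default_factory=lambda: ["demo.zhiye"])
    low_freq_threshold: int = Field(default=2, ge=1)
    reversible: bool = True

    @model_validator(mode="after")
    def _validate(self) -> "DeidConfig":
        bins = sorted(self.age_bins, key=lambda b: b.lower)
        if not bins or bins[0].lower != 0 or bins[-1].upper < 130:
            raise ConfigError("age_bins must cover [0, 130]")
        for a, b in zip(bins, bins[1:]):
            if b.lower != a.upper + 1:
                raise ConfigError(f"age_bins overlap or leave a gap at {a.upper}/{b.lower}")
        for name in set(self.id_fields.values()):
            if name not in self.id_category_maps:
                raise ConfigError(f"id_fields references unknown category map {name!r}")
            rules = self.id_category_maps[name]
            if not rules or rules[-1].pattern not in ("", ".*"):
                raise ConfigError(
                    f"id_category_map {name!r} needs a catch-all fallback rule last"
                )
        if self.base_date_policy == "study_fixed" and self.study_base_date is None:
            raise ConfigError("study_fixed base_date_policy requires study_base_date")
        return self


def default_deid_config(**overrides) -> DeidConfig:
    return DeidConfig(**overrides)


# -- primitive rules ----------------------------------------------------
def shift_date(d: date | str, base: date | str) -> int:
    """Signed day difference ``d - base``; order- and interval-preserving."""
    if isinstance(d, str):
        d = date.fromisoformat(d)
    if isinstance(base, str):
        base = date.fromisoformat(base)
    return (d - base).days


def bin_age(age: int, bins: Sequence[AgeBin]) -> str:
    """The unique bin label containing ``age``."""
    for b in bins:
        if b.lower <= age <= b.upper:
            return b.label
    raise DomainError(f"age {age} outside all configured bins")


def categorize_id(value: str, rules: Sequence[IdRule]) -> str:
    """First matching rule wins; the configured fallback guarantees a label."""
    for rule in rules:
        if rule.pattern == "" or re.search(rule.pattern, value):
            return rule.label
    raise ConfigError("id_category_map is not exhaustive (no fallback rule)")


def suppress_low_frequency(column: Sequence[str | None], k: int) -> list[str | None]:
    """Null every value whose frequency in the column is below ``k``."""
    if k < 1:
        raise ConfigError("low-frequency threshold k must be >= 1")
    freq = Counter(v for v in column if v is not None)
    return [None if v is not None and freq[v] < k else v for v in column]


# -- audit trail --------------------------------------------------------
def _digest(value) -> str:
    if value is None:
        return ""
    return hashlib.sha256(json.dumps(value, ensure_ascii=False).encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class AuditEntry:
    sequence_number: int
    wall_time: str
    layer: int
    rule_id: str
    record_key: str
    field_path: str
    before_digest: str
    after_digest: str


class AuditLog:
    """Append-only mutation log with strictly increasing sequence numbers."""

    def __init__(self, clock: Callable[[], datetime] | None = None) -> None:
        self.entries: list[AuditEntry] = []
        self._clock = clock or (lambda: datetime.now(timezone.utc))

    def append(self, layer: int, rule_id: str, record_key: str, field_path: str,
               before, after) -> None:
        self.entries.append(
            AuditEntry(
                sequence_number=len(self.entries) + 1,
                wall_time=self._clock().isoformat(),
                layer=layer,
                rule_id=rule_id,
                record_key=record_key,
                field_path=field_path,
                before_digest=_digest(before),
                after_digest=_digest(after),
            )
        )

    def mutated_cells(self) -> set[tuple[str, str]]:
        return {(e.record_key, e.field_path) for e in self.entries}

    def to_jsonl(self) -> str:
        return "".join(json.dumps(vars(e), sort_keys=True) + "\n" for e in self.entries)

    @classmethod
    def from_jsonl(cls, text: str) -> "AuditLog":
        log = cls()
        for line in text.splitlines():
            if line.strip():
                log.entries.append(AuditEntry(**json.loads(line)))
        return log

    def __len__(self) -> int:
        return len(self.entries)


class ReversalKey:
    """Original-to-surrogate mapping, kept apart from any transfer output.

    Persisted with :meth:`save`; a ``codec`` (encrypt, decrypt) pair can be
    supplied to keep the file encrypted at rest — the package itself stores
    plain JSON and leaves cipher choice to the deployment.
    """

    def __init__(self) -> None:
        self._forward: dict[str, dict[str, str]] = {}

    def surrogate(self, kind: str, original: str) -> str:
        table = self._forward.setdefault(kind, {})
        if original not in table:
            table[original] = f"{kind.upper()}-{len(table) + 1:03d}"
        return table[original]

    def invert(self, kind: str, surrogate: str) -> str:
        for original, s in self._forward.get(kind, {}).items():
            if s == surrogate:
                return original
        raise KeyError(f"no original recorded for {kind}:{surrogate}")

    def to_json(self) -> str:
        return json.dumps(self._forward, ensure_ascii=False, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReversalKey":
        key = cls()
        key._forward = json.loads(text)
        return key

    def save(self, path: Path, codec: Callable[[bytes], bytes] | None = None) -> None:
        data = self.to_json().encode("utf-8")
        if codec is not None:
            data = codec(data)
        Path(path).write_bytes(data)

    @classmethod
    def load(cls, path: Path, codec: Callable[[bytes], bytes] | None = None) -> "ReversalKey":
        data = Path(path).read_bytes()
        if codec is not None:
            data = codec(data)
        return cls.from_json(data.decode("utf-8"))


# -- layer 2 ------------------------------------------------------------
def apply_safe_harbor(
    record: EHRRecord,
    config: DeidConfig,
    base: date | None = None,
    key: ReversalKey | None = None,
    audit: AuditLog | None = None,
    record_key: str = "",
) -> EHRRecord:
    """Mask every configured HIPAA field of one record; others untouched."""
    out = copy.deepcopy(record)
    key = key if key is not None else ReversalKey()
    for hf in config.hipaa_fields:
        if hf.path not in out.payload or out.payload[hf.path] is None:
            continue
        before = out.payload[hf.path]
        action = hf.resolved_action()
        if action == "remove":
            del out.payload[hf.path]
            after = None
        elif action == "surrogate":
            after = key.surrogate(f"cat{hf.category}", before)
            out.payload[hf.path] = after
        else:  # shift
            effective_base = base or config.study_base_date
            if effective_base is None:
                raise ConfigError(
                    f"date field {hf.path} needs a base date (none resolved)"
                )
            try:
                after = str(shift_date(before, effective_base))
            except ValueError as exc:
                raise ConfigError(f"field {hf.path}: bad date {before!r}") from exc
            out.payload[hf.path] = after
        if audit is not None:
            audit.append(2, f"hipaa.cat{hf.category}.{action}", record_key, hf.path, before, after)
    return out


@dataclass
class DeidResult:
    """Deidentified store plus the side artifacts the pipeline needs."""

    store: EHRStore
    audit: AuditLog
    key: ReversalKey | None
    base_dates: dict[str, date] = dc_field(default_factory=dict)  # original pid -> base
    subject_map: dict[str, str] = dc_field(default_factory=dict)  # original pid -> surrogate


def _resolve_bases(store: EHRStore, config: DeidConfig, roster: list[str]) -> dict[str, date]:
    if config.base_date_policy == "study_fixed":
        return {pid: config.study_base_date for pid in roster}
    bases: dict[str, date] = {}
    for r in store.records:
        if isinstance(r.record_date, date):
            prev = bases.get(r.patient_id)
            if prev is None or r.record_date < prev:
                bases[r.patient_id] = r.record_date
    missing = [pid for pid in roster if pid not in bases]
    if missing:
        raise ConfigError(f"no dated records to anchor base dates for patients {missing}")
    return bases


def deidentify_study(
    store: EHRStore,
    config: DeidConfig | None = None,
    clock: Callable[[], datetime] | None = None,
) -> DeidResult:
    """Run the three layers in order over a whole store.

    Idempotent: a store already flagged deidentified is returned unchanged
    with an empty audit log.
    """
    config = config or default_deid_config()
    audit = AuditLog(clock)
    if store.deidentified:
        return DeidResult(store=store, audit=audit, key=None)

    roster = list(store.patients) or list(dict.fromkeys(r.patient_id for r in store.records))
    bases = _resolve_bases(store, config, roster)
    key = ReversalKey()
    subject_map = {pid: f"SUBJ-{i + 1:02d}" for i, pid in enumerate(roster)}
    for pid in roster:  # register in roster order so surrogates are stable
        key._forward.setdefault("subject", {})[pid] = subject_map[pid]

    new_records: list[EHRRecord] = []
    for r in store.records:
        orig_pid = r.patient_id
        rkey = f"{r.domain.value}/{orig_pid}/{r.page_index}"
        out = copy.deepcopy(r)

        # layer 1: schema-level drop of direct identifiers
        for path in config.layer1_drop:
            if path in out.payload:
                audit.append(1, "direct_identifier.drop", rkey, path, out.payload[path], None)
                del out.payload[path]

        # layer 2: HIPAA Safe-Harbor masking
        base = bases[orig_pid]
        out = apply_safe_harbor(out, config, base=base, key=key, audit=audit, record_key=rkey)
        if config.pseudonymize_patient_id:
            audit.append(2, "hipaa.cat18.surrogate", rkey, "patient_id",
                         orig_pid, subject_map[orig_pid])
            out.patient_id = subject_map[orig_pid]
        if isinstance(out.record_date, date):
            shifted = shift_date(out.record_date, base)
            audit.append(2, "hipaa.cat3.shift", rkey, "record_date",
                         out.record_date.isoformat(), str(shifted))
            out.record_date = shifted

        # layer 3: project rules (ID categories, age bins)
        for path, map_name in config.id_fields.items():
            value = out.payload.get(path)
            if value is None:
                continue
            label = categorize_id(value, config.id_category_maps[map_name])
            if label != value:
                audit.append(3, f"id_categorize.{map_name}", rkey, path, value, label)
                out.payload[path] = label
        for path in config.age_fields:
            value = out.payload.get(path)
            if value is None:
                continue
            label = bin_age(int(value), config.age_bins)
            if label != value:
                audit.append(3, "age_bin", rkey, path, value, label)
                out.payload[path] = label
        new_records.append(out)

    # layer 3: corpus-wide low-frequency suppression
    for path in config.low_freq_fields:
        holders = [r for r in new_records if path in r.payload]
        column = [r.payload[path] for r in holders]
        suppressed = suppress_low_frequency(column, config.low_freq_threshold)
        for r, before, after in zip(holders, column, suppressed):
            if after is None and before is not None:
                rkey = f"{r.domain.value}/{key.invert('subject', r.patient_id) if config.pseudonymize_patient_id else r.patient_id}/{r.page_index}"
                audit.append(3, "low_frequency.null", rkey, path, before, None)
                r.payload[path] = None

    out_store = EHRStore(
        records=new_records,
        patients=[subject_map[pid] for pid in roster],
        deidentified=True,
    )
    return DeidResult(
        store=out_store,
        audit=audit,
        key=key if config.reversible else None,
        base_dates=bases,
        subject_map=subject_map,
    )
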