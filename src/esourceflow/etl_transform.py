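"""Extraction, terminology translation, CRF mapping and the one-time push.

Only deidentified, electronic-provenance records in the four CRF domains are
extracted.  Mapping produces one CRF page per (subject, module, page index)
with values populated for every transferable field a mapping rule covers;
coded source tokens go through the terminology dictionary, and tokens the
dictionary does not know are flagged unmapped and excluded from transfer
(they count against completeness, never against accuracy).

The push writes one file per module and format plus a manifest of record
counts and SHA-256 checksums; a dataset can be pushed exactly once unless
explicitly forced, and the manifest can be re-verified against the files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .crf_model import CRFPage, FieldDictionary, MappingRule, Module, Provenance, canonical_dictionary
from .errors import IntegrityError, PolicyError, PushStateError, SchemaError
from .formats import FORMATS, deserialize, serialize
from .synthetic_ehr import EHRRecord, EHRStore
from .terminology import TerminologyDictionary, TranslationResult, builtin_terminology, translate_value

__all__ = [
    "TerminologyDictionary",
    "TranslationResult",
    "builtin_terminology",
    "translate_value",
    "serialize",
    "deserialize",
    "extract",
    "map_to_crf",
    "TransferDataset",
    "push",
    "verify_push",
]

logger = logging.getLogger(__name__)

#: Functions available to ``derive``-kind mapping rules.
DERIVE_REGISTRY: dict[str, callable] = {}


def extract(store: EHRStore, dictionary: FieldDictionary | None = None) -> list[EHRRecord]:
    """Electronic records of the four CRF domains, from a deidentified store."""
    dictionary = dictionary or canonical_dictionary()
    if not store.deidentified:
        raise PolicyError("extraction requires a deidentified store (flag not set)")
    modules = set(dictionary.modules())
    return [
        r
        for r in store.records
        if r.provenance == "electronic" and r.domain in modules
    ]


def _apply_rule(rule: MappingRule, value: str, terminology: TerminologyDictionary):
    """Returns (value-or-None, ok).  None means excluded from transfer."""
    if rule.transform_kind == "copy":
        return value, True
    if rule.transform_kind == "dictionary_translate":
        result = translate_value(value, terminology)
        if not result.ok:
            return None, False
        return result.value, True
    if rule.transform_kind == "unit_convert":
        try:
            factor = float(rule.dictionary_ref)
            return str(float(value) * factor), True
        except ValueError:
            return None, False
    # derive
    fn = DERIVE_REGISTRY.get(rule.dictionary_ref)
    if fn is None:
        raise SchemaError(f"derive rule references unknown function {rule.dictionary_ref!r}")
    return fn(value), True


def map_to_crf(
    records: list[EHRRecord],
    rules: list[MappingRule],
    terminology: TerminologyDictionary | None = None,
) -> list[CRFPage]:
    """Map extracted records onto CRF pages.

    One page per (subject, module, page index), values populated only for
    fields a rule covers; populated values get eSource provenance, the rest
    are missing.  Deterministic and order-independent: groups and fields are
    emitted in sorted/rule order regardless of the input record order.
    """
    terminology = terminology or builtin_terminology()
    rules_by_module: dict[Module, list[MappingRule]] = {}
    for rule in rules:
        rules_by_module.setdefault(rule.module_id, []).append(rule)

    merged: dict[tuple[str, str, int], dict[str, str]] = {}
    for r in records:
        key = (r.domain.value, r.patient_id, r.page_index)
        payload = merged.setdefault(key, {})
        for path, value in r.payload.items():
            if value is not None:
                payload[path] = value

    pages: list[CRFPage] = []
    warned_paths: set[tuple[str, str]] = set()
    for (module_name, subject, index) in sorted(merged):
        module = Module(module_name)
        payload = merged[(module_name, subject, index)]
        module_rules = rules_by_module.get(module, [])
        covered_paths = {rule.ehr_field_path for rule in module_rules}
        for path in payload:
            if path not in covered_paths and (module_name, path) not in warned_paths:
                warned_paths.add((module_name, path))
                logger.warning("dropping EHR field %s with no %s mapping rule", path, module_name)
        values: dict[str, str | None] = {}
        provenance: dict[str, Provenance] = {}
        for rule in module_rules:
            raw = payload.get(rule.ehr_field_path)
            if raw is None:
                values[rule.crf_field] = None
                provenance[rule.crf_field] = Provenance.MISSING
                continue
            mapped, ok = _apply_rule(rule, raw, terminology)
            if not ok or mapped is None:
                logger.warning(
                    "unmapped token %r for %s.%s excluded from transfer",
                    raw, module_name, rule.crf_field,
                )
                values[rule.crf_field] = None
                provenance[rule.crf_field] = Provenance.MISSING
                continue
            values[rule.crf_field] = mapped
            provenance[rule.crf_field] = Provenance.ESOURCE
        pages.append(CRFPage(module, subject, index, values=values, provenance=provenance))
    return pages


@dataclass
class TransferDataset:
    """Pages ready for the sponsor, plus one-time push state and manifest."""

    pages: list[CRFPage] = dc_field(default_factory=list)
    manifest: dict | None = None
    pushed: bool = False

    def pages_for(self, module: Module) -> list[CRFPage]:
        return [p for p in self.pages if p.module_id == module]

    def captured_nonnull(self, module: Module) -> int:
        return sum(
            1
            for p in self.pages_for(module)
            for name, v in p.values.items()
            if v is not None and p.provenance[name] is Provenance.ESOURCE
        )


def push(
    ds: TransferDataset,
    destination: Path,
    formats: tuple[str, ...] = FORMATS,
    force: bool = False,
) -> dict:
    """Write per-module files and a checksummed manifest; one-time semantics."""
    if ds.pushed and not force:
        raise PushStateError("dataset already pushed; pass force=True to push again")
    unknown = [f for f in formats if f not in FORMATS]
    if unknown:
        raise SchemaError(f"unsupported formats {unknown}")
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    files = []
    modules = sorted({p.module_id for p in ds.pages}, key=lambda m: m.value)
    for module in modules:
        pages = sorted(ds.pages_for(module), key=lambda p: p.sort_key())
        for fmt in formats:
            name = f"{module.value}.{fmt}"
            data = serialize(pages, fmt)
            (destination / name).write_bytes(data)
            files.append(
                {
                    "name": name,
                    "records": len(pages),
                    "sha256": hashlib.sha256(data).hexdigest(),
                }
            )
    manifest = {"algorithm": "sha256", "files": files}
    (destination / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    ds.manifest = manifest
    ds.pushed = True
    return manifest


def verify_push(destination: Path) -> dict:
    """Recompute checksums of a pushed directory against its manifest."""
    destination = Path(destination)
    manifest = json.loads((destination / "manifest.json").read_text(encoding="utf-8"))
    if manifest.get("algorithm") != "sha256":
        raise IntegrityError(f"unknown checksum algorithm {manifest.get('algorithm')!r}")
    for entry in manifest["files"]:
        path = destination / entry["name"]
        if not path.exists():
            raise IntegrityError(f"manifest file missing: {entry['name']}")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        if digest != entry["sha256"]:
            raise IntegrityError(f"checksum mismatch for {entry['name']}")
    return manifest
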