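"""End-to-end orchestration: generate → deidentify → transform → push → evaluate.

Every stage reads and writes the documented file formats, so the stages are
independently runnable (see :mod:`esourceflow.cli`).  The whole run is a
pure function of the pipeline configuration: rerunning with the same config
and seed reproduces the transfer files, manifest checksums and report bytes.

Accuracy is evaluated in transfer coordinates: the manual-EDC truth values
are projected through the same deidentification rules applied to the source
(dates to day offsets from the patient's base date, ages to bins, accession
IDs to categories) before pairing with the transferred values.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field as dc_field
from datetime import date
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .crf_model import (
    EHR_FIELD_PATHS,
    FieldDictionary,
    Module,
    Provenance,
    ValueKind,
    canonical_dictionary,
    canonical_mapping_rules,
    load_field_dictionary,
)
from .deidentify import (
    DeidConfig,
    DeidResult,
    bin_age,
    categorize_id,
    deidentify_study,
    shift_date,
)
from .errors import ConfigError, EsourceError, MetricUndefinedError, ReportError
from .etl_transform import TransferDataset, extract, map_to_crf, push
from .formats import FORMATS
from .quality_metrics import (
    AccuracyPairs,
    CompletenessInventory,
    QualityReport,
    build_report,
    inventories_from_dictionary,
    round_percent,
)
from .synthetic_ehr import EDCTruth, EHRStore, StudyConfig, generate_study, pilot_study_config

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "EvaluationResult",
    "run_pipeline",
    "evaluate_study",
    "load_pipeline_config",
    "validate_config",
]

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    study: StudyConfig
    deid: DeidConfig = Field(default_factory=DeidConfig)
    output_dir: Path
    formats: list[str] = Field(default_factory=lambda: list(FORMATS))
    dictionary_path: Path | None = None
    force_push: bool = False
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _validate(self) -> "PipelineConfig":
        unknown = [f for f in self.formats if f not in FORMATS]
        if unknown:
            raise ConfigError(f"unsupported formats {unknown}; choose from {list(FORMATS)}")
        if self.dictionary_path is not None and not Path(self.dictionary_path).exists():
            raise ConfigError(f"dictionary file not found: {self.dictionary_path}")
        return self

    def dictionary(self) -> FieldDictionary:
        if self.dictionary_path is None:
            return canonical_dictionary()
        return load_field_dictionary(Path(self.dictionary_path))


def load_pipeline_config(
    source: str | Path | dict,
    seed: int | None = None,
    output_dir: str | Path | None = None,
    formats: list[str] | None = None,
) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file or mapping.

    ``study: pilot`` selects the built-in pilot-study configuration and
    ``deid: default`` the default deidentification rules.  ``seed`` and
    ``output_dir`` arguments override the file.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    else:
        doc = dict(source)
    study = doc.get("study", "pilot")
    study = pilot_study_config() if study == "pilot" else StudyConfig(**study)
    if "seed" in doc:
        study = study.model_copy(update={"seed": int(doc["seed"])})
    if seed is not None:
        study = study.model_copy(update={"seed": int(seed)})
    deid = doc.get("deid", "default")
    deid = DeidConfig() if deid == "default" else DeidConfig(**deid)
    return PipelineConfig(
        study=study,
        deid=deid,
        output_dir=Path(output_dir or doc.get("output_dir", "esourceflow-out")),
        formats=formats or doc.get("formats", list(FORMATS)),
        dictionary_path=doc.get("dictionary_path"),
        force_push=bool(doc.get("force_push", False)),
        log_level=doc.get("log_level", "INFO"),
    )


def validate_config(path: str | Path) -> list[str]:
    """Parse and cross-check a pipeline config file; returns violations ([] = ok)."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        return [f"cannot read config file: {exc}"]
    try:
        yaml.safe_load(text)
    except yaml.YAMLError as exc:
        return [f"config file does not parse: {exc}"]
    try:
        load_pipeline_config(path)
    except ValidationError as exc:
        return [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
    except EsourceError as exc:
        return [str(exc)]
    return []


@dataclass
class EvaluationResult:
    report: QualityReport
    completeness_inventories: list[CompletenessInventory]
    accuracy_pairs: list[AccuracyPairs]

    def pooled_accuracy(self) -> float:
        matched = sum(p.matched() for p in self.accuracy_pairs)
        total = sum(len(p.pairs) for p in self.accuracy_pairs)
        if total == 0:
            raise MetricUndefinedError("no transferred points to pool accuracy over")
        return round_percent(matched, total)

    def pooled_pair_count(self) -> int:
        return sum(len(p.pairs) for p in self.accuracy_pairs)


def _project_truth_value(
    module: Module,
    field_name: str,
    value: str,
    dictionary: FieldDictionary,
    deid: DeidConfig,
    base: date,
) -> str:
    """Truth value in transfer coordinates (same deidentification rules)."""
    kind = dictionary.field(module, field_name).value_kind
    if kind is ValueKind.DATE:
        return str(shift_date(value, base))
    path = EHR_FIELD_PATHS.get((module, field_name))
    if path in deid.age_fields:
        return bin_age(int(value), deid.age_bins)
    if path in deid.id_fields:
        return categorize_id(value, deid.id_category_maps[deid.id_fields[path]])
    return value


def evaluate_study(
    dictionary: FieldDictionary,
    truth: EDCTruth,
    transfer: TransferDataset,
    deid: DeidConfig,
    base_by_subject: dict[str, date],
    surrogate_to_subject: dict[str, str] | None = None,
) -> EvaluationResult:
    """Score availability, completeness and accuracy for every module.

    ``base_by_subject`` maps truth subject IDs to the per-patient base dates
    used during deidentification; ``surrogate_to_subject`` maps the
    transfer-side subject surrogates back to truth subject IDs (identity if
    omitted).
    """
    surrogate_to_subject = surrogate_to_subject or {}
    field_inventories = inventories_from_dictionary(dictionary)
    modules = dictionary.modules()

    completeness_inventories = [
        CompletenessInventory(
            module_id=m,
            required_points=truth.required_points(m),
            captured_nonnull=transfer.captured_nonnull(m),
        )
        for m in modules
    ]

    truth_cells = truth.cell_map()
    pairs_by_module: dict[Module, AccuracyPairs] = {m: AccuracyPairs(module_id=m) for m in modules}
    for page in transfer.pages:
        subject = surrogate_to_subject.get(page.subject_id, page.subject_id)
        base = base_by_subject.get(subject)
        for name, transferred in page.values.items():
            if transferred is None or page.provenance[name] is not Provenance.ESOURCE:
                continue
            raw_truth = truth_cells.get((page.module_id, subject, page.page_index, name))
            if raw_truth is None or base is None:
                projected = None
            else:
                projected = _project_truth_value(
                    page.module_id, name, raw_truth, dictionary, deid, base
                )
            pairs_by_module[page.module_id].pairs.append((transferred, projected))

    report = build_report(
        field_inventories,
        completeness_inventories,
        list(pairs_by_module.values()),
        modules=modules,
    )
    return EvaluationResult(report, completeness_inventories, list(pairs_by_module.values()))


@dataclass
class PipelineResult:
    output_dir: Path
    report: QualityReport | None
    evaluation: EvaluationResult | None
    manifest: dict | None
    metric_error: str | None = None
    paths: dict[str, Path] = dc_field(default_factory=dict)


@contextmanager
def _stage(name: str):
    logger.info("stage=%s status=start", name)
    try:
        yield
    except Exception:
        logger.exception("stage=%s status=failed", name)
        raise
    logger.info("stage=%s status=done", name)


def run_pipeline(config: PipelineConfig, clock=None) -> PipelineResult:
    """Run all stages, writing the documented artifacts under ``output_dir``."""
    out = Path(config.output_dir)
    dictionary = config.dictionary()
    rules = canonical_mapping_rules(dictionary)
    paths: dict[str, Path] = {}

    with _stage("generate"):
        store, truth = generate_study(config.study)
        raw_dir = out / "raw"
        raw_dir.mkdir(parents=True, exist_ok=True)
        paths["raw_store"] = raw_dir / "ehr_store.jsonl"
        paths["raw_store"].write_text(store.to_jsonl(), encoding="utf-8")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for module in dictionary.modules():
            p = truth_dir / f"{module.value}.csv"
            p.write_bytes(truth.to_module_csv(module))
            paths[f"truth_{module.value}"] = p

    with _stage("deidentify"):
        deid_result = deidentify_study(store, config.deid, clock=clock)
        deid_dir = out / "deid"
        deid_dir.mkdir(exist_ok=True)
        paths["deid_store"] = deid_dir / "store.jsonl"
        paths["deid_store"].write_text(deid_result.store.to_jsonl(), encoding="utf-8")
        paths["audit_log"] = deid_dir / "audit.jsonl"
        paths["audit_log"].write_text(deid_result.audit.to_jsonl(), encoding="utf-8")
        keys_dir = out / "keys"
        keys_dir.mkdir(exist_ok=True)
        if deid_result.key is not None:
            paths["reversal_key"] = keys_dir / "reversal_key.json"
            deid_result.key.save(paths["reversal_key"])
        paths["deid_meta"] = keys_dir / "deid_meta.json"
        paths["deid_meta"].write_text(
            json.dumps(
                {
                    "base_dates": {
                        pid: d.isoformat() for pid, d in deid_result.base_dates.items()
                    },
                    "subject_map": deid_result.subject_map,
                },
                sort_keys=True,
                indent=1,
            ),
            encoding="utf-8",
        )

    with _stage("transform"):
        records = extract(deid_result.store, dictionary)
        pages = map_to_crf(records, rules)
        transfer = TransferDataset(pages=pages)

    with _stage("push"):
        transfer_dir = out / "transfer"
        manifest = push(transfer, transfer_dir, tuple(config.formats), force=config.force_push)
        paths["transfer_dir"] = transfer_dir
        paths["manifest"] = transfer_dir / "manifest.json"

    with _stage("evaluate"):
        roster = store.patients
        subjects = [f"S{i + 1:02d}" for i in range(len(roster))]
        surrogate_to_subject = {
            deid_result.subject_map[pid]: subj for pid, subj in zip(roster, subjects)
        }
        base_by_subject = {
            subj: deid_result.base_dates[pid] for pid, subj in zip(roster, subjects)
        }
        try:
            evaluation = evaluate_study(
                dictionary, truth, transfer, config.deid, base_by_subject, surrogate_to_subject
            )
        except (MetricUndefinedError, ReportError) as exc:
            logger.warning("stage=evaluate metrics undefined: %s", exc)
            return PipelineResult(
                output_dir=out,
                report=None,
                evaluation=None,
                manifest=manifest,
                metric_error=str(exc),
                paths=paths,
            )
        paths["report_csv"] = out / "report.csv"
        paths["report_csv"].write_text(evaluation.report.to_csv(), encoding="utf-8")
        paths["report_txt"] = out / "report.txt"
        paths["report_txt"].write_text(evaluation.report.to_text() + "\n", encoding="utf-8")
        paths["summary"] = out / "summary.json"
        summary = {
            "pooled_accuracy_percent": evaluation.pooled_accuracy(),
            "pooled_pair_count": evaluation.pooled_pair_count(),
            "modules": {
                m.value: {
                    "availability_ehr": evaluation.report.percent(m, "availability_ehr"),
                    "availability_esource": evaluation.report.percent(m, "availability_esource"),
                    "completeness": evaluation.report.percent(m, "completeness"),
                    "accuracy": evaluation.report.percent(m, "accuracy"),
                }
                for m in evaluation.report.rows
            },
        }
        paths["summary"].write_text(json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8")

    return PipelineResult(
        output_dir=out,
        report=evaluation.report,
        evaluation=evaluation,
        manifest=manifest,
        paths=paths,
    )
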