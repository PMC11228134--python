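"""Data-quality statistics: availability, completeness and accuracy.

Four ratio metrics, all reported as percentages rounded half-up to two
decimals (half-up, not banker's: 5/9 must print 55.56):

* EHR-CRF availability — fields present in the hospital EHR over fields the
  CRF requests (field dimension, decided at schema level);
* eSource-CRF availability — fields electronically transferable over fields
  requested; transferable fields are a subset of EHR-present fields;
* completeness — nonnull data points captured and sent through eSource over
  the study's required data points (value dimension, per-module
  denominators are explicit design counts);
* accuracy — transferred nonnull points matching the manually entered EDC
  value, over transferred nonnull points.  Accuracy of nothing is
  undefined, not 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

import pandas as pd

from .crf_model import FieldDictionary, Module
from .errors import InvariantError, MetricUndefinedError, ReportError

__all__ = [
    "FieldInventory",
    "CompletenessInventory",
    "AccuracyPairs",
    "QualityReport",
    "availability_ehr_crf",
    "availability_esource_crf",
    "completeness",
    "accuracy",
    "build_report",
    "inventories_from_dictionary",
    "round_percent",
]


def round_percent(numerator: int, denominator: int) -> float:
    """100·n/N rounded half-up to 2 decimals."""
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FieldInventory:
    """Field-dimension counts for one module (CRF ⊇ EHR ⊇ eSource)."""

    module_id: Module
    crf_total: int
    ehr_present: int
    esource_transferable: int

    def __post_init__(self) -> None:
        if not 0 <= self.esource_transferable <= self.ehr_present <= self.crf_total:
            raise InvariantError(
                f"{self.module_id.value}: need 0 <= eSource <= EHR <= CRF, got "
                f"{self.esource_transferable}/{self.ehr_present}/{self.crf_total}"
            )


@dataclass(frozen=True)
class CompletenessInventory:
    """Value-dimension counts for one module."""

    module_id: Module
    required_points: int
    captured_nonnull: int

    def __post_init__(self) -> None:
        if not 0 <= self.captured_nonnull <= self.required_points:
            raise InvariantError(
                f"{self.module_id.value}: captured_nonnull {self.captured_nonnull} "
                f"outside [0, {self.required_points}]"
            )


class Normalization(str, Enum):
    EXACT = "exact"
    NORMALIZED = "normalized"


@dataclass
class AccuracyPairs:
    """(transferred, EDC-truth) value pairs over captured nonnull points."""

    module_id: Module
    pairs: list[tuple[str, str | None]] = dc_field(default_factory=list)
    normalization: Normalization = Normalization.NORMALIZED

    def matched(self) -> int:
        return sum(1 for a, b in self.pairs if _values_match(a, b, self.normalization))


def _values_match(a: str, b: str | None, normalization: Normalization) -> bool:
    if b is None:
        return False
    if normalization is Normalization.EXACT:
        return a == b
    a, b = a.strip(), b.strip()
    try:
        return int(a) == int(b)
    except ValueError:
        pass
    return a.casefold() == b.casefold()


# -- the four metrics ---------------------------------------------------
def availability_ehr_crf(inv: FieldInventory) -> float:
    if inv.crf_total == 0:
        raise MetricUndefinedError(f"{inv.module_id.value}: availability undefined for 0 CRF fields")
    return round_percent(inv.ehr_present, inv.crf_total)


def availability_esource_crf(inv: FieldInventory) -> float:
    if inv.crf_total == 0:
        raise MetricUndefinedError(f"{inv.module_id.value}: availability undefined for 0 CRF fields")
    return round_percent(inv.esource_transferable, inv.crf_total)


def completeness(inv: CompletenessInventory) -> float:
    if inv.required_points == 0:
        raise MetricUndefinedError(
            f"{inv.module_id.value}: completeness undefined for 0 required points"
        )
    return round_percent(inv.captured_nonnull, inv.required_points)


def accuracy(pairs: AccuracyPairs) -> float:
    if not pairs.pairs:
        raise MetricUndefinedError(
            f"{pairs.module_id.value}: accuracy of zero transferred points is undefined"
        )
    return round_percent(pairs.matched(), len(pairs.pairs))


def inventories_from_dictionary(dictionary: FieldDictionary) -> list[FieldInventory]:
    """Schema-level field inventories for every module of a dictionary."""
    out = []
    for module in dictionary.modules():
        crf, ehr, esrc = dictionary.counts(module)
        out.append(FieldInventory(module, crf, ehr, esrc))
    return out


# -- the report ---------------------------------------------------------
@dataclass(frozen=True)
class Metric:
    numerator: int
    denominator: int
    percent: float

    def fraction(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent:.2f})"


@dataclass(frozen=True)
class ReportRow:
    module_id: Module
    availability_ehr: Metric
    availability_esource: Metric
    completeness: Metric
    accuracy: Metric


#: Module display order and labels for rendered reports.
_MODULE_LABELS = {
    Module.DEMOGRAPHICS: "Demographics",
    Module.VITAL_SIGNS: "Vital signs",
    Module.LOCAL_LAB_BLOOD: "Blood biochemical tests",
    Module.LOCAL_LAB_URINE: "Urine sample tests",
    Module.CONMED: "Concomitant medication",
}

_COLUMNS = [
    "CRF-EHR data availability",
    "CRF-eSource data availability",
    "Data completeness",
    "Data accuracy",
]


class QualityReport:
    """Per-module metric rows, renderable as CSV or an aligned text table."""

    def __init__(self, rows: dict[Module, ReportRow]) -> None:
        self.rows = rows

    def to_frame(self) -> pd.DataFrame:
        data = {
            _MODULE_LABELS[m]: [
                row.availability_ehr.fraction(),
                row.availability_esource.fraction(),
                row.completeness.fraction(),
                row.accuracy.fraction(),
            ]
            for m, row in self.rows.items()
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=_COLUMNS)

    def to_csv(self) -> str:
        frame = self.to_frame()
        frame.index.name = "CRF domain"
        return frame.to_csv(lineterminator="\n")

    def to_text(self) -> str:
        frame = self.to_frame()
        frame.index.name = "CRF domain"
        return frame.reset_index().to_string(index=False)

    def percent(self, module: Module, metric: str) -> float:
        return getattr(self.rows[module], metric).percent


def build_report(
    field_inventories: list[FieldInventory],
    completeness_inventories: list[CompletenessInventory],
    accuracy_pairs: list[AccuracyPairs],
    modules: list[Module] | None = None,
) -> QualityReport:
    """Assemble the per-module report; every requested module must be present."""
    modules = modules or list(_MODULE_LABELS)
    field_by = {inv.module_id: inv for inv in field_inventories}
    comp_by = {inv.module_id: inv for inv in completeness_inventories}
    acc_by = {p.module_id: p for p in accuracy_pairs}
    absent = [
        m.value
        for m in modules
        if m not in field_by or m not in comp_by or m not in acc_by
    ]
    if absent:
        raise ReportError(f"report is missing modules: {absent}")
    rows: dict[Module, ReportRow] = {}
    for m in modules:
        finv, cinv, apairs = field_by[m], comp_by[m], acc_by[m]
        rows[m] = ReportRow(
            module_id=m,
            availability_ehr=Metric(finv.ehr_present, finv.crf_total, availability_ehr_crf(finv)),
            availability_esource=Metric(
                finv.esource_transferable, finv.crf_total, availability_esource_crf(finv)
            ),
            completeness=Metric(cinv.captured_nonnull, cinv.required_points, completeness(cinv)),
            accuracy=Metric(apairs.matched(), len(apairs.pairs), accuracy(apairs)),
        )
    return QualityReport(rows)
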