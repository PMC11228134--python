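"""Source-to-EDC terminology dictionary.

The hospital records coded values in Chinese; the sponsor's EDC standard is
English.  Translation is a plain dictionary lookup: a token either maps, or
is flagged unmapped (and the value is then excluded from transfer, which
counts against completeness — translation never fails hard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "TerminologyDictionary",
    "TranslationResult",
    "builtin_terminology",
    "translate_value",
]


class TranslationResult(NamedTuple):
    value: str
    ok: bool


@dataclass
class TerminologyDictionary:
    """Token map from source-system vocabulary to EDC vocabulary."""

    entries: dict[str, str] = field(default_factory=dict)
    scope: str = ""

    def translate(self, token: str) -> TranslationResult:
        if token in self.entries:
            return TranslationResult(self.entries[token], True)
        return TranslationResult(token, False)

    def __contains__(self, token: str) -> bool:
        return token in self.entries


def translate_value(value: str, dictionary: TerminologyDictionary) -> TranslationResult:
    """Translate one token; unmapped tokens come back unchanged with ok=False."""
    return dictionary.translate(value)


# Paired (source token, EDC token) vocabularies.  The synthetic generator
# draws source tokens from these lists, so the ETL layer's dictionary lookup
# does real work on every coded field.
SEX_TOKENS = [("男", "Male"), ("女", "Female")]
YES_NO_TOKENS = [("是", "Yes"), ("否", "No")]
UNIT_TOKENS = [("千克", "kg"), ("厘米", "cm"), ("毫克", "mg"), ("克", "g")]
FREQUENCY_TOKENS = [("每日一次", "QD"), ("每日两次", "BID"), ("每日三次", "TID")]
ROUTE_TOKENS = [("口服", "Oral"), ("静脉注射", "Intravenous"), ("皮下注射", "Subcutaneous")]
BLOOD_TEST_TOKENS = [
    ("血红蛋白", "Hemoglobin"),
    ("白细胞计数", "White blood cell count"),
    ("血小板计数", "Platelet count"),
    ("丙氨酸氨基转移酶", "Alanine aminotransferase"),
    ("天冬氨酸氨基转移酶", "Aspartate aminotransferase"),
    ("肌酐", "Creatinine"),
    ("血糖", "Glucose"),
    ("总胆红素", "Total bilirubin"),
]
URINE_TEST_TOKENS = [
    ("尿蛋白", "Urine protein"),
    ("尿葡萄糖", "Urine glucose"),
    ("尿潜血", "Urine occult blood"),
    ("尿比重", "Urine specific gravity"),
    ("尿酸碱度", "Urine pH"),
]
DRUG_TOKENS = [
    ("阿司匹林", "Aspirin"),
    ("对乙酰氨基酚", "Paracetamol"),
    ("奥美拉唑", "Omeprazole"),
    ("布洛芬", "Ibuprofen"),
    ("氯雷他定", "Loratadine"),
    ("地塞米松", "Dexamethasone"),
]

_ALL_PAIRS = (
    SEX_TOKENS
    + YES_NO_TOKENS
    + UNIT_TOKENS
    + FREQUENCY_TOKENS
    + ROUTE_TOKENS
    + BLOOD_TEST_TOKENS
    + URINE_TEST_TOKENS
    + DRUG_TOKENS
)


def builtin_terminology() -> TerminologyDictionary:
    """The built-in Chinese-to-EDC dictionary covering the study vocabulary."""
    return TerminologyDictionary(entries=dict(_ALL_PAIRS), scope="zh2edc")
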