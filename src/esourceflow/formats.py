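"""Lossless CRF-page serialization: JSON, XML and CSV.

All three formats round-trip ``deserialize(serialize(pages)) == pages`` and
distinguish a null value from an empty string:

* JSON — ``null`` vs ``""``;
* XML — ``nil="true"`` on an empty element vs an empty element without it
  (schema shipped as ``schemas/transfer.xsd``; documents are validated on
  both write and read);
* CSV — an explicit ``is_null`` column, because no CSV dialect preserves a
  quoting distinction through standard readers.  Columns are
  ``module_id,subject_id,page_index,field_name,value,is_null,provenance``;
  a page without any fields is represented by a single row with an empty
  ``field_name``.  UTF-8, comma-separated, quote-doubling, ``\\n`` line ends.

Dates are serialized as whatever string the page carries — post-
deidentification that is a signed integer day offset, never a calendar date.
"""

from __future__ import annotations

import csv
import io
import json
from functools import lru_cache
from importlib import resources

from lxml import etree

from .crf_model import CRFPage, Module, Provenance
from .errors import SchemaError

__all__ = ["serialize", "deserialize", "FORMATS"]

FORMATS = ("json", "xml", "csv")


@lru_cache(maxsize=1)
def _xml_schema() -> etree.XMLSchema:
    text = resources.files("esourceflow.schemas").joinpath("transfer.xsd").read_text()
    return etree.XMLSchema(etree.fromstring(text.encode()))


def serialize(pages: list[CRFPage], fmt: str) -> bytes:
    """Serialize pages to one of the supported formats, preserving order."""
    if fmt == "json":
        return _to_json(pages)
    if fmt == "xml":
        return _to_xml(pages)
    if fmt == "csv":
        return _to_csv(pages)
    raise SchemaError(f"unsupported format {fmt!r}")


def deserialize(data: bytes | str, fmt: str) -> list[CRFPage]:
    if isinstance(data, str):
        data = data.encode("utf-8")
    if fmt == "json":
        return _from_json(data)
    if fmt == "xml":
        return _from_xml(data)
    if fmt == "csv":
        return _from_csv(data)
    raise SchemaError(f"unsupported format {fmt!r}")


# -- JSON ---------------------------------------------------------------
def _to_json(pages: list[CRFPage]) -> bytes:
    doc = {
        "pages": [
            {
                "module_id": p.module_id.value,
                "subject_id": p.subject_id,
                "page_index": p.page_index,
                "fields": [
                    {
                        "name": name,
                        "value": p.values[name],
                        "provenance": p.provenance[name].value,
                    }
                    for name in p.values
                ],
            }
            for p in pages
        ]
    }
    return json.dumps(doc, ensure_ascii=False, indent=1).encode("utf-8")


def _from_json(data: bytes) -> list[CRFPage]:
    try:
        doc = json.loads(data.decode("utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SchemaError(f"malformed JSON transfer document: {exc}") from exc
    if not isinstance(doc, dict) or "pages" not in doc:
        raise SchemaError("JSON transfer document must contain a 'pages' list")
    pages = []
    for entry in doc["pages"]:
        pages.append(
            CRFPage(
                module_id=Module(entry["module_id"]),
                subject_id=entry["subject_id"],
                page_index=int(entry["page_index"]),
                values={f["name"]: f["value"] for f in entry["fields"]},
                provenance={f["name"]: Provenance(f["provenance"]) for f in entry["fields"]},
            )
        )
    return pages


# -- XML ----------------------------------------------------------------
def _to_xml(pages: list[CRFPage]) -> bytes:
    root = etree.Element("transfer")
    for p in pages:
        page_el = etree.SubElement(
            root,
            "page",
            module=p.module_id.value,
            subject=p.subject_id,
            index=str(p.page_index),
        )
        for name in p.values:
            attrs = {"name": name, "provenance": p.provenance[name].value}
            value = p.values[name]
            if value is None:
                attrs["nil"] = "true"
            field_el = etree.SubElement(page_el, "field", **attrs)
            if value is not None:
                field_el.text = value
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    _xml_schema().assertValid(etree.fromstring(data))
    return data


def _from_xml(data: bytes) -> list[CRFPage]:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"malformed XML transfer document: {exc}") from exc
    schema = _xml_schema()
    if not schema.validate(root):
        raise SchemaError(f"XML transfer document violates schema: {schema.error_log}")
    pages = []
    for page_el in root.iter("page"):
        values: dict[str, str | None] = {}
        provenance: dict[str, Provenance] = {}
        for field_el in page_el.iter("field"):
            name = field_el.get("name")
            if field_el.get("nil") == "true":
                values[name] = None
            else:
                values[name] = field_el.text or ""
            provenance[name] = Provenance(field_el.get("provenance"))
        pages.append(
            CRFPage(
                module_id=Module(page_el.get("module")),
                subject_id=page_el.get("subject"),
                page_index=int(page_el.get("index")),
                values=values,
                provenance=provenance,
            )
        )
    return pages


# -- CSV ----------------------------------------------------------------
_CSV_HEADER = [
    "module_id",
    "subject_id",
    "page_index",
    "field_name",
    "value",
    "is_null",
    "provenance",
]


def _to_csv(pages: list[CRFPage]) -> bytes:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_HEADER)
    for p in pages:
        if not p.values:
            writer.writerow([p.module_id.value, p.subject_id, p.page_index, "", "", "1", ""])
            continue
        for name in p.values:
            value = p.values[name]
            writer.writerow(
                [
                    p.module_id.value,
                    p.subject_id,
                    p.page_index,
                    name,
                    "" if value is None else value,
                    "1" if value is None else "0",
                    p.provenance[name].value,
                ]
            )
    return buf.getvalue().encode("utf-8")


def _from_csv(data: bytes) -> list[CRFPage]:
    text = data.decode("utf-8")
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration as exc:
        raise SchemaError("empty CSV transfer document") from exc
    if header != _CSV_HEADER:
        raise SchemaError(f"unexpected CSV header {header!r} (line 1)")
    pages: list[CRFPage] = []
    current_key: tuple | None = None
    for lineno, row in enumerate(reader, start=2):
        if len(row) != len(_CSV_HEADER):
            raise SchemaError(f"CSV row with {len(row)} columns (line {lineno})")
        module, subject, index, name, value, is_null, prov = row
        key = (module, subject, index)
        if key != current_key:
            try:
                pages.append(CRFPage(Module(module), subject, int(index)))
            except ValueError as exc:
                raise SchemaError(f"bad CSV page key {key!r} (line {lineno})") from exc
            current_key = key
        if name == "":
            continue  # marker row for an empty page
        page = pages[-1]
        page.values[name] = None if is_null == "1" else value
        page.provenance[name] = Provenance(prov)
    return pages
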