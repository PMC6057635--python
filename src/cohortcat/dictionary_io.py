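"""Data-dictionary import/export: CSV variable/category tables and a
DDI-flavoured XML codebook.

Dictionaries arrive as two CSV tables — one row per variable, one row per
category — in one of three *dialects* that emulate the column naming and
missing-value conventions of CSV, SPSS and SAS dictionary exports. Native
``.sav``/``.sas7bdat`` parsing is out of scope; only the CSV shapes differ.
"""

from __future__ import annotations

import csv
import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .model import Category, Dataset, DatasetLink, Variable, VALUE_TYPES

__all__ = [
    "Dialect",
    "DIALECTS",
    "DictionaryError",
    "read_dictionary",
    "write_dictionary",
    "export_ddi_lite",
]

# canonical logical column names
_VAR_COLUMNS = ("name", "label", "value_type", "unit", "question")
_CAT_COLUMNS = ("categories_variable", "code", "category_label", "missing")

_TRUTHY = {"true", "1", "yes", "y", "t"}


class DictionaryError(ValueError):
    """Malformed dictionary table (duplicate names, dangling categories, ...)."""


@dataclass(frozen=True)
class Dialect:
    """Column naming + missing-code convention of one dictionary flavour.

    ``column_map`` maps canonical names (``name``, ``label``, ``value_type``,
    ``unit``, ``question``, ``categories_variable``, ``code``,
    ``category_label``, ``missing``) to the dialect's CSV headers. Missing
    categories are declared either by a flag column (``flag_column``) or by
    membership of the code in ``missing_codes`` (``code_list``).
    """

    name: str
    column_map: Mapping[str, str]
    missing_code_convention: str = "flag_column"  # or "code_list"
    missing_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not {"name", "label"} <= set(self.column_map):
            raise ValueError("column_map must cover at least {name, label}")
        if self.missing_code_convention not in ("flag_column", "code_list"):
            raise ValueError(f"unknown missing_code_convention {self.missing_code_convention!r}")

    def header(self, canonical: str) -> Optional[str]:
        return self.column_map.get(canonical)


DIALECTS: dict[str, Dialect] = {
    "plain_csv": Dialect(
        name="plain_csv",
        column_map={
            "name": "name",
            "label": "label",
            "value_type": "valueType",
            "unit": "unit",
            "question": "question",
            "categories_variable": "variable",
            "code": "code",
            "category_label": "label",
            "missing": "missing",
        },
    ),
    "spss_export": Dialect(
        name="spss_export",
        column_map={
            "name": "Variable",
            "label": "Label",
            "value_type": "Type",
            "unit": "Unit",
            "question": "Question",
            "categories_variable": "Variable",
            "code": "Value",
            "category_label": "Label",
            "missing": "Missing",
        },
    ),
    "sas_export": Dialect(
        name="sas_export",
        column_map={
            "name": "NAME",
            "label": "LABEL",
            "value_type": "TYPE",
            "unit": "UNIT",
            "question": "QUESTION",
            "categories_variable": "NAME",
            "code": "VALUE",
            "category_label": "LABEL",
        },
        missing_code_convention="code_list",
        missing_codes=frozenset({".", ".M", "-9", "-99"}),
    ),
}


def _rows(table: str, what: str) -> tuple[list[str], list[dict[str, str]]]:
    reader = csv.reader(io.StringIO(table))
    try:
        header = next(reader)
    except StopIteration:
        raise DictionaryError(f"{what} table is empty (no header row)")
    rows = []
    for cells in reader:
        if not cells:
            continue
        cells += [""] * (len(header) - len(cells))
        rows.append(dict(zip(header, cells)))
    return header, rows


def _is_integer(code: str) -> bool:
    try:
        int(code)
        return True
    except ValueError:
        return False


def read_dictionary(
    variables_table: str,
    categories_table: Optional[str] = None,
    dialect: Dialect = DIALECTS["plain_csv"],
    *,
    dataset_id: str = "dataset",
    dataset_name: str = "",
    description: str = "",
    link: Optional[DatasetLink] = None,
) -> Dataset:
    """Parse variable + category CSV tables into a Dataset.

    Variables keep file row order; categories attach to their variable by
    name, in file order. When the dialect's value-type column is absent or a
    cell is empty, the type is inferred: ``integer`` if the variable has
    categories whose codes all parse as integers, else ``text``.
    """
    header, var_rows = _rows(variables_table, "variables")
    name_col = dialect.header("name")
    label_col = dialect.header("label")
    if name_col not in header:
        raise DictionaryError(f"variables table is missing mandatory column {name_col!r}")
    if label_col not in header:
        raise DictionaryError(f"variables table is missing mandatory column {label_col!r}")

    type_col = dialect.header("value_type")
    unit_col = dialect.header("unit")
    question_col = dialect.header("question")

    order: list[str] = []
    parsed: dict[str, dict] = {}
    for i, row in enumerate(var_rows, start=2):  # header is row 1
        name = row.get(name_col, "").strip()
        if not name:
            raise DictionaryError(f"variables table row {i}: empty variable name")
        if name in parsed:
            raise DictionaryError(f"variables table row {i}: duplicate variable name {name!r}")
        order.append(name)
        parsed[name] = {
            "label": row.get(label_col, ""),
            "value_type": (row.get(type_col) or "").strip() if type_col in header else "",
            "unit": (row.get(unit_col) or "").strip() or None if unit_col in header else None,
            "question": (row.get(question_col) or "").strip() or None
            if question_col in header
            else None,
            "categories": [],
        }

    if categories_table is not None and categories_table.strip():
        cheader, cat_rows = _rows(categories_table, "categories")
        cvar_col = dialect.header("categories_variable")
        code_col = dialect.header("code")
        clabel_col = dialect.header("category_label")
        missing_col = dialect.header("missing")
        for col, logical in ((cvar_col, "variable"), (code_col, "code")):
            if col not in cheader:
                raise DictionaryError(f"categories table is missing mandatory column {col!r}")
        for i, row in enumerate(cat_rows, start=2):
            vname = row.get(cvar_col, "").strip()
            if vname not in parsed:
                raise DictionaryError(
                    f"categories table row {i}: unknown variable {vname!r}"
                )
            code = row.get(code_col, "").strip()
            if not code:
                raise DictionaryError(f"categories table row {i}: empty category code")
            if dialect.missing_code_convention == "flag_column":
                is_missing = (
                    (row.get(missing_col) or "").strip().lower() in _TRUTHY
                    if missing_col in cheader
                    else False
                )
            else:
                is_missing = code in dialect.missing_codes
            parsed[vname]["categories"].append(
                Category(code=code, label=row.get(clabel_col, ""), is_missing=is_missing)
            )

    variables = []
    for name in order:
        p = parsed[name]
        value_type = p["value_type"]
        if not value_type:
            codes = [c.code for c in p["categories"]]
            value_type = "integer" if codes and all(_is_integer(c) for c in codes) else "text"
        if value_type not in VALUE_TYPES:
            raise DictionaryError(f"variable {name!r}: unknown value type {value_type!r}")
        variables.append(
            Variable(
                name=name,
                label=p["label"],
                value_type=value_type,
                unit=p["unit"],
                question_text=p["question"],
                categories=tuple(p["categories"]),
            )
        )
    return Dataset(
        id=dataset_id,
        name=dataset_name,
        description=description,
        link=link,
        variables=tuple(variables),
    )


def write_dictionary(dataset: Dataset, dialect: Dialect = DIALECTS["plain_csv"]) -> tuple[str, str]:
    """Serialize a dataset to (variables_table, categories_table) CSV text.

    Canonical column order; ``read_dictionary(*write_dictionary(d))``
    recovers *d* structurally (for code_list dialects the missing flags must
    be consistent with the dialect's code list, by construction of any
    dataset previously read with that dialect).
    """
    var_buf = io.StringIO()
    var_cols = [dialect.header(c) for c in _VAR_COLUMNS if dialect.header(c)]
    w = csv.writer(var_buf, lineterminator="\n")
    w.writerow(var_cols)
    for v in dataset.variables:
        values = {
            "name": v.name,
            "label": v.label,
            "value_type": v.value_type,
            "unit": v.unit or "",
            "question": v.question_text or "",
        }
        w.writerow([values[c] for c in _VAR_COLUMNS if dialect.header(c)])

    cat_buf = io.StringIO()
    use_flag = dialect.missing_code_convention == "flag_column"
    cat_cols = ["categories_variable", "code", "category_label"] + (["missing"] if use_flag else [])
    w = csv.writer(cat_buf, lineterminator="\n")
    w.writerow([dialect.header(c) for c in cat_cols])
    for v in dataset.variables:
        for c in v.categories:
            row = [v.name, c.code, c.label]
            if use_flag:
                row.append("true" if c.is_missing else "false")
            w.writerow(row)
    return var_buf.getvalue(), cat_buf.getvalue()


def export_ddi_lite(dataset: Dataset) -> str:
    """Render the dataset as a minimal DDI-flavoured XML codebook.

    Element vocabulary is fixed in ``cohortcat/data/ddi_lite_schema.md``; one
    ``variable`` element per variable, one ``category`` element per category,
    in dataset order.
    """
    root = ET.Element("codebook", attrib={"dataset": dataset.id})
    if dataset.name:
        root.set("name", dataset.name)
    for v in dataset.variables:
        var_el = ET.SubElement(root, "variable")
        ET.SubElement(var_el, "name").text = v.name
        ET.SubElement(var_el, "label").text = v.label
        if v.unit:
            ET.SubElement(var_el, "units").text = v.unit
        if v.question_text:
            ET.SubElement(var_el, "question").text = v.question_text
        for c in v.categories:
            cat_el = ET.SubElement(
                var_el,
                "category",
                attrib={"code": c.code, "missing": "true" if c.is_missing else "false"},
            )
            ET.SubElement(cat_el, "label").text = c.label
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
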