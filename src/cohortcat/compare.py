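"""Harmonization-potential comparison tables.

A comparison table is a grid of variable counts with one row per
(study, population, data-collection event) — rows grouped by study then
population, events in declared order, all-zero rows kept — and one column
per selected taxonomy term. A variable annotated with two selected terms
counts once in each of those columns (no cross-column deduplication).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .search import Catalogue
from .taxonomy import TermRef

__all__ = ["RowKey", "ComparisonTable", "harmonization_table", "render_comparison", "parse_comparison_csv"]


class RowKey(NamedTuple):
    study_id: str
    population_id: str
    dce_id: str


@dataclass(frozen=True)
class ComparisonTable:
    columns: tuple[TermRef, ...]
    rows: tuple[RowKey, ...]
    cells: tuple[tuple[int, ...], ...]  # rows x columns
    # display names, parallel to rows, for rendering
    row_names: tuple[tuple[str, str, str], ...] = ()

    def cell(self, row: RowKey, column: TermRef) -> int:
        return self.cells[self.rows.index(RowKey(*row))][self.columns.index(TermRef(*column))]


def harmonization_table(
    catalogue: Catalogue, columns: Sequence[TermRef], study_ids: Sequence[str]
) -> ComparisonTable:
    """Count annotated variables per (study, population, DCE) x term.

    One row per DCE of every population of every selected study, including
    all-zero rows; datasets not linked to a selected DCE are ignored.
    """
    cols = tuple(TermRef(*c) for c in columns)
    for ref in cols:
        if catalogue.taxonomy.resolve(ref) is None:
            raise ValueError(f"unresolvable term reference {ref}")
    for sid in study_ids:
        if sid not in catalogue.studies:
            raise ValueError(f"unknown study {sid!r}")

    rows: list[RowKey] = []
    row_names: list[tuple[str, str, str]] = []
    for sid in study_ids:
        study = catalogue.studies[sid]
        for pop in study.populations:
            for dce in pop.data_collection_events:
                rows.append(RowKey(sid, pop.id, dce.id))
                row_names.append((study.name or sid, pop.name or pop.id, dce.name or dce.id))

    counts = {rk: [0] * len(cols) for rk in rows}
    col_pos = {ref: i for i, ref in enumerate(cols)}
    for ds in catalogue.datasets.values():
        if ds.link is None:
            continue
        rk = RowKey(ds.link.study_id, ds.link.population_id, ds.link.dce_id)
        if rk not in counts:
            continue
        for var in ds.variables:
            for ref in var.annotations:
                pos = col_pos.get(TermRef(*ref))
                if pos is not None:
                    counts[rk][pos] += 1

    return ComparisonTable(
        columns=cols,
        rows=tuple(rows),
        cells=tuple(tuple(counts[rk]) for rk in rows),
        row_names=tuple(row_names),
    )


def render_comparison(table: ComparisonTable, format: str = "csv") -> str:
    """Render as flat CSV (one line per DCE row) or a grouped markdown table."""
    if format == "csv":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["study", "population", "dce"] + [str(c) for c in table.columns])
        for rk, row in zip(table.rows, table.cells):
            w.writerow(list(rk) + [str(n) for n in row])
        return buf.getvalue()
    if format == "markdown":
        header = ["Study / Population / Data collection event"] + [
            c.term_name for c in table.columns
        ]
        lines = [
            "| " + " | ".join(header) + " |",
            "| " + " | ".join("---" for _ in header) + " |",
        ]
        blanks = [""] * len(table.columns)
        current_study = current_pop = None
        names = table.row_names or tuple((rk.study_id, rk.population_id, rk.dce_id) for rk in table.rows)
        for rk, name3, row in zip(table.rows, names, table.cells):
            study_name, pop_name, dce_name = name3
            if rk.study_id != current_study:
                lines.append("| " + " | ".join([f"**{study_name}**"] + blanks) + " |")
                current_study, current_pop = rk.study_id, None
            if rk.population_id != current_pop:
                lines.append("| " + " | ".join([f"*{pop_name}*"] + blanks) + " |")
                current_pop = rk.population_id
            lines.append("| " + " | ".join([dce_name] + [str(n) for n in row]) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def parse_comparison_csv(text: str) -> ComparisonTable:
    """Inverse of the CSV rendering (column headers are ``Domain/Term``)."""
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    columns = tuple(TermRef(*h.split("/", 1)) for h in header[3:])
    rows, cells = [], []
    for rec in reader:
        if not rec:
            continue
        rows.append(RowKey(rec[0], rec[1], rec[2]))
        cells.append(tuple(int(x) for x in rec[3:]))
    return ComparisonTable(columns=columns, rows=tuple(rows), cells=tuple(cells))
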