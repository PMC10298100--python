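"""Descriptive patient-centered and cohort workflows over the relational store.

Five workflows, each returning a labeled count table:

* ``gender_distribution`` — registered patients per gender value;
* ``registrations_by_year`` — patients per year over a range, the year taken
  from the stored date's first four characters (FHIR permits partial dates);
* ``allergy_cohorts`` — distinct patients per allergy label, through the
  allergy→patient join;
* ``test_order_distribution`` — orders per test label with integer
  percentages (largest-remainder apportionment), validated against the
  patient and practitioner joins;
* ``test_orders_by_year`` — orders per authored year over a range.

Zero-count years are omitted by default (sparse presentation); a flag
restores them.  Gender labels are reported lowercase as stored by FHIR;
capitalization belongs to the presentation layer.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .store import SchemaHandle

WORKFLOW_IDS = (
    "gender_distribution",
    "registrations_by_year",
    "allergy_cohorts",
    "test_order_distribution",
    "test_orders_by_year",
)


@dataclass
class WorkflowRow:
    label: str
    count: int
    percent: int | None = None


@dataclass
class WorkflowResult:
    """Labeled count (and optional percentage) table from one workflow."""

    workflow_id: str
    dimension_name: str
    rows: list[WorkflowRow]
    total: int
    parameters: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int]:
        return {r.label: r.count for r in self.rows}

    def percents(self) -> dict[str, int]:
        return {r.label: r.percent for r in self.rows if r.percent is not None}

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "workflow_id": self.workflow_id,
            "dimension": self.dimension_name,
            "total": self.total,
            "parameters": self.parameters,
            "rows": [
                {"label": r.label, "count": r.count}
                | ({"percent": r.percent} if r.percent is not None else {})
                for r in self.rows
            ],
        }

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "count", "percent"])
            for r in self.rows:
                writer.writerow(
                    [r.label, r.count, "" if r.percent is None else r.percent]
                )

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")


def apportion_percentages(counts: list[int]) -> list[int]:
    """Integer percentages summing to exactly 100 (largest-remainder method).

    Quotas are ``count * 100 / total``; each label gets the floor of its
    quota, and the leftover points go to the largest fractional remainders,
    ties broken by earlier index.  When the counts already sum to 100 the
    output equals the input.
    """
    total = sum(counts)
    if total <= 0:
        raise ValueError("apportionment requires a positive total")
    floors = [c * 100 // total for c in counts]
    remainders = [(c * 100) % total for c in counts]
    leftover = 100 - sum(floors)
    order = sorted(range(len(counts)), key=lambda i: (-remainders[i], i))
    out = list(floors)
    for i in order[:leftover]:
        out[i] += 1
    return out


def patients_by_gender(schema: SchemaHandle) -> WorkflowResult:
    """Count registered patients per gender value (null reported as unknown)."""
    rows = schema.conn.execute(
        "SELECT COALESCE(gender, 'unknown') AS g, COUNT(*) FROM patient "
        "GROUP BY g ORDER BY COUNT(*) DESC, g"
    ).fetchall()
    result_rows = [WorkflowRow(label=g, count=n) for g, n in rows]
    return WorkflowResult(
        workflow_id="gender_distribution",
        dimension_name="gender",
        rows=result_rows,
        total=sum(r.count for r in result_rows),
    )


def _year_rows(
    schema: SchemaHandle,
    table: str,
    date_column: str,
    start_year: int,
    end_year: int,
    include_empty_years: bool,
    include_undated: bool,
) -> tuple[list[WorkflowRow], int]:
    if start_year > end_year:
        raise ValueError("start_year must not exceed end_year")
    pairs = schema.conn.execute(
        f'SELECT CAST(substr("{date_column}", 1, 4) AS INTEGER) AS y, COUNT(*) '
        f'FROM "{table}" WHERE "{date_column}" IS NOT NULL '
        f"AND length(\"{date_column}\") >= 4 GROUP BY y"
    ).fetchall()
    counts = {y: n for y, n in pairs if start_year <= y <= end_year}
    rows = []
    for year in range(start_year, end_year + 1):
        n = counts.get(year, 0)
        if n or include_empty_years:
            rows.append(WorkflowRow(label=str(year), count=n))
    undated = schema.conn.execute(
        f'SELECT COUNT(*) FROM "{table}" WHERE "{date_column}" IS NULL '
        f'OR length("{date_column}") < 4'
    ).fetchone()[0]
    if include_undated and undated:
        rows.append(WorkflowRow(label="undated", count=undated))
    return rows, undated


def patients_by_year(
    schema: SchemaHandle,
    start_year: int,
    end_year: int,
    date_basis: str = "birth_date",
    include_empty_years: bool = False,
    include_undated: bool = False,
) -> WorkflowResult:
    """Count registered patients per year within [start_year, end_year].

    ``date_basis`` selects the realization of "registration year": the
    patient's birth date (default) or an explicit registration-date
    extension, when the dataset carries one.
    """
    if date_basis not in ("birth_date", "registration_extension"):
        raise ValueError(f"unknown date_basis {date_basis!r}")
    column = "birth_date" if date_basis == "birth_date" else "registration_date"
    rows, undated = _year_rows(
        schema, "patient", column, start_year, end_year,
        include_empty_years, include_undated,
    )
    params: dict[str, Any] = {
        "start_year": start_year,
        "end_year": end_year,
        "date_basis": date_basis,
    }
    if not include_undated and undated:
        params["undated_excluded"] = undated
    return WorkflowResult(
        workflow_id="registrations_by_year",
        dimension_name="year",
        rows=rows,
        total=sum(r.count for r in rows),
        parameters=params,
    )


def allergy_cohort_counts(schema: SchemaHandle) -> WorkflowResult:
    """Distinct patients per allergy label through the allergy→patient join.

    A patient recorded twice with the same label counts once; orphan allergy
    rows (unresolved patient reference) are excluded and reported.
    """
    rows = schema.conn.execute(
        "SELECT code_display, COUNT(DISTINCT patient_key) FROM allergy "
        "WHERE patient_key IS NOT NULL AND code_display IS NOT NULL "
        "GROUP BY code_display ORDER BY 2 DESC, code_display"
    ).fetchall()
    orphans = schema.conn.execute(
        "SELECT COUNT(*) FROM allergy "
        "WHERE patient_ref_id IS NOT NULL AND patient_key IS NULL"
    ).fetchone()[0]
    result_rows = [WorkflowRow(label=label, count=n) for label, n in rows]
    params: dict[str, Any] = {}
    if orphans:
        params["orphans_excluded"] = orphans
    return WorkflowResult(
        workflow_id="allergy_cohorts",
        dimension_name="allergy",
        rows=result_rows,
        total=sum(r.count for r in result_rows),
        parameters=params,
    )


def test_order_distribution(schema: SchemaHandle) -> WorkflowResult:
    """Orders per test label with integer percentages summing to 100.

    The patient and practitioner joins validate linkage; orders failing
    either join are excluded and their count reported.
    """
    rows = schema.conn.execute(
        "SELECT sr.code_display, COUNT(*) FROM service_request sr "
        "JOIN patient p ON sr.patient_key = p.pk "
        "JOIN practitioner pr ON sr.requester_key = pr.pk "
        "WHERE sr.code_display IS NOT NULL "
        "GROUP BY sr.code_display ORDER BY 2 DESC, sr.code_display"
    ).fetchall()
    total_orders = schema.conn.execute(
        "SELECT COUNT(*) FROM service_request"
    ).fetchone()[0]
    joined = sum(n for _, n in rows)
    result_rows = [WorkflowRow(label=label, count=n) for label, n in rows]
    if result_rows:
        for row, pct in zip(
            result_rows, apportion_percentages([r.count for r in result_rows])
        ):
            row.percent = pct
    params: dict[str, Any] = {}
    if total_orders - joined:
        params["excluded"] = total_orders - joined
    return WorkflowResult(
        workflow_id="test_order_distribution",
        dimension_name="test_name",
        rows=result_rows,
        total=joined,
        parameters=params,
    )


def test_orders_by_year(
    schema: SchemaHandle,
    start_year: int,
    end_year: int,
    include_empty_years: bool = False,
    include_undated: bool = False,
) -> WorkflowResult:
    """Orders per authored year within [start_year, end_year]."""
    rows, undated = _year_rows(
        schema, "service_request", "authored_on", start_year, end_year,
        include_empty_years, include_undated,
    )
    params: dict[str, Any] = {"start_year": start_year, "end_year": end_year}
    if not include_undated and undated:
        params["undated_excluded"] = undated
    return WorkflowResult(
        workflow_id="test_orders_by_year",
        dimension_name="year",
        rows=rows,
        total=sum(r.count for r in rows),
        parameters=params,
    )


def run_workflow(
    schema: SchemaHandle,
    workflow_id: str,
    start_year: int = 1950,
    end_year: int = 2021,
    **kwargs,
) -> WorkflowResult:
    """Dispatch a workflow by id."""
    if workflow_id == "gender_distribution":
        return patients_by_gender(schema)
    if workflow_id == "registrations_by_year":
        return patients_by_year(schema, start_year, end_year, **kwargs)
    if workflow_id == "allergy_cohorts":
        return allergy_cohort_counts(schema)
    if workflow_id == "test_order_distribution":
        return test_order_distribution(schema)
    if workflow_id == "test_orders_by_year":
        return test_orders_by_year(schema, start_year, end_year, **kwargs)
    raise ValueError(f"unknown workflow {workflow_id!r}")


def plot_result(result: WorkflowResult, path: str | Path) -> None:
    """Export a bar chart for a workflow result (cosmetic; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [r.label for r in result.rows]
    counts = [r.count for r in result.rows]
    fig, ax = plt.subplots(figsize=(max(6, len(labels) * 0.5), 4))
    ax.bar(labels, counts, color="#4878a8")
    ax.set_title(result.workflow_id.replace("_", " "))
    ax.set_ylabel("count")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
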