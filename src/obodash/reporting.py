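"""Dashboard assembly and rendering.

Rows (one per ontology) are assembled into a :class:`DashboardGrid` and
rendered as a static HTML matrix, a lossless JSON document, or a compact
TSV of statuses, plus one standalone HTML detail page per ontology.  All
renderings are pure functions of (rows, run metadata): rendering the same
grid twice is byte-identical.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path

from .checks import (
    PRINCIPLE_DOCS,
    PRINCIPLE_IDS,
    PRINCIPLE_NAMES,
    CheckResult,
    CheckStatus,
    DashboardRow,
    summarize,
)

__all__ = [
    "DashboardGrid",
    "DashboardRow",
    "assemble_grid",
    "parse_grid_json",
    "render_detail",
    "render_grid",
    "write_dashboard",
]


@dataclass
class DashboardGrid:
    """Ontology rows x principle columns, with run metadata."""

    rows: list[DashboardRow] = field(default_factory=list)
    run_metadata: dict = field(default_factory=dict)


def assemble_grid(rows: list[DashboardRow], meta: dict | None = None) -> DashboardGrid:
    """Sort rows by ontology id and recompute every summary (never trusted
    from input).  Duplicate ontology ids are an error."""
    ids = [row.ontology_id for row in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate ontology ids in grid: {sorted(dupes)}")
    ordered = sorted(rows, key=lambda r: r.ontology_id)
    for row in ordered:
        missing = [pid for pid in PRINCIPLE_IDS if pid not in row.results]
        if missing:
            raise ValueError(f"row {row.ontology_id!r} lacks results for {missing}")
        row.results = {pid: row.results[pid] for pid in PRINCIPLE_IDS}
        row.summary = summarize(row.results)
    return DashboardGrid(rows=ordered, run_metadata=dict(meta or {}))


# ---------------------------------------------------------------------------
# Rendering

_STATUS_CLASS = {
    CheckStatus.PASS: "status-pass",
    CheckStatus.INFO: "status-info",
    CheckStatus.WARN: "status-warn",
    CheckStatus.ERROR: "status-error",
    CheckStatus.NA: "status-na",
}

_CSS = """\
body { font-family: sans-serif; margin: 1.5em; }
table { border-collapse: collapse; }
th, td { border: 1px solid #999; padding: 0.3em 0.6em; text-align: center; }
td.ontology-id { text-align: left; font-weight: bold; }
.status-pass { background: #c8e6c9; }
.status-info { background: #bbdefb; }
.status-warn { background: #ffe0b2; }
.status-error { background: #ffcdd2; }
.status-na { background: #eeeeee; color: #777; }
section.problem { border-left: 4px solid #c62828; padding-left: 0.8em; margin: 1em 0; }
section.ok { color: #2e7d32; }
"""


def _grid_to_payload(grid: DashboardGrid) -> dict:
    return {
        "run_metadata": grid.run_metadata,
        "principles": [
            {"id": pid, "name": PRINCIPLE_NAMES[pid], "doc": PRINCIPLE_DOCS[pid]}
            for pid in PRINCIPLE_IDS
        ],
        "rows": [
            {
                "ontology_id": row.ontology_id,
                "summary": row.summary.name,
                "results": {
                    pid: {
                        "status": res.status.name,
                        "messages": list(res.messages),
                        "metrics": dict(res.metrics),
                    }
                    for pid, res in row.results.items()
                },
            }
            for row in grid.rows
        ],
    }


def render_grid(grid: DashboardGrid, format: str = "html") -> str:
    """Render the grid as ``html`` (linked matrix), ``json`` (lossless) or
    ``tsv`` (statuses only)."""
    if format == "json":
        return json.dumps(_grid_to_payload(grid), indent=2, sort_keys=True) + "\n"

    if format == "tsv":
        header = ["ontology_id", *PRINCIPLE_IDS, "summary"]
        lines = ["\t".join(header)]
        for row in grid.rows:
            lines.append(
                "\t".join(
                    [
                        row.ontology_id,
                        *(row.results[pid].status.name for pid in PRINCIPLE_IDS),
                        row.summary.name,
                    ]
                )
            )
        return "\n".join(lines) + "\n"

    if format == "html":
        head_cells = "".join(
            f'<th><a href="{html.escape(PRINCIPLE_DOCS[pid])}">'
            f"{html.escape(PRINCIPLE_NAMES[pid])}</a></th>"
            for pid in PRINCIPLE_IDS
        )
        body_rows = []
        for row in grid.rows:
            cells = [
                f'<td class="ontology-id"><a href="reports/{html.escape(row.ontology_id)}.html">'
                f"{html.escape(row.ontology_id)}</a></td>"
            ]
            for pid in PRINCIPLE_IDS:
                status = row.results[pid].status
                cells.append(
                    f'<td class="{_STATUS_CLASS[status]}">{status.name}</td>'
                )
            cells.append(
                f'<td class="{_STATUS_CLASS[row.summary]}">{row.summary.name}</td>'
            )
            body_rows.append("<tr>" + "".join(cells) + "</tr>")
        meta = html.escape(
            ", ".join(f"{k}: {v}" for k, v in sorted(grid.run_metadata.items()))
        )
        return (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            f"<title>Ontology principles dashboard</title><style>{_CSS}</style></head>\n"
            "<body>\n<h1>Ontology principles dashboard</h1>\n"
            f"<p class='meta'>{meta}</p>\n"
            "<table>\n<thead><tr><th>Ontology</th>"
            f"{head_cells}<th>Summary</th></tr></thead>\n<tbody>\n"
            + "\n".join(body_rows)
            + "\n</tbody>\n</table>\n</body></html>\n"
        )

    raise ValueError(f"unknown format {format!r} (expected html, json or tsv)")


def parse_grid_json(text: str) -> DashboardGrid:
    """Inverse of the JSON rendering (statuses, messages and metrics)."""
    payload = json.loads(text)
    rows = []
    for raw in payload["rows"]:
        results = {
            pid: CheckResult(
                principle_id=pid,
                status=CheckStatus[raw["results"][pid]["status"]],
                messages=list(raw["results"][pid]["messages"]),
                metrics={k: int(v) for k, v in raw["results"][pid]["metrics"].items()},
            )
            for pid in PRINCIPLE_IDS
        }
        rows.append(
            DashboardRow(
                ontology_id=raw["ontology_id"],
                results=results,
                summary=CheckStatus[raw["summary"]],
            )
        )
    return DashboardGrid(rows=rows, run_metadata=payload.get("run_metadata", {}))


def render_detail(row: DashboardRow) -> str:
    """Standalone detail page for one ontology: a section per non-PASS
    check with its findings and metrics, passing checks listed compactly."""
    sections: list[str] = []
    passing: list[str] = []
    for pid in PRINCIPLE_IDS:
        res = row.results[pid]
        title = f"{pid} {PRINCIPLE_NAMES[pid]}"
        if res.status in (CheckStatus.PASS, CheckStatus.NA):
            passing.append(f"{title}: {res.status.name}")
            continue
        items = "".join(f"<li>{html.escape(m)}</li>" for m in res.messages)
        metrics = ", ".join(f"{k}={v}" for k, v in sorted(res.metrics.items()))
        sections.append(
            f'<section class="problem {_STATUS_CLASS[res.status]}">'
            f'<h2><a href="{html.escape(PRINCIPLE_DOCS[pid])}">{html.escape(title)}</a>'
            f" &mdash; {res.status.name}</h2>"
            f"<ul>{items}</ul>"
            f"<p class='metrics'>{html.escape(metrics)}</p></section>"
        )
    ok = "".join(f"<li>{html.escape(p)}</li>" for p in passing)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(row.ontology_id)} report</title><style>{_CSS}</style></head>\n"
        f"<body>\n<h1>Report for {html.escape(row.ontology_id)} "
        f"(summary: {row.summary.name})</h1>\n"
        + "\n".join(sections)
        + f"\n<section class='ok'><h2>Passing checks</h2><ul>{ok}</ul></section>\n"
        "</body></html>\n"
    )


def write_dashboard(
    grid: DashboardGrid, out_dir: str | Path, formats: tuple[str, ...] = ("html", "json", "tsv")
) -> list[Path]:
    """Write dashboard.{html,json,tsv} and reports/<id>.html under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt in formats:
        path = out / f"dashboard.{fmt}"
        path.write_text(render_grid(grid, fmt))
        written.append(path)
    reports = out / "reports"
    reports.mkdir(exist_ok=True)
    for row in grid.rows:
        path = reports / f"{row.ontology_id}.html"
        path.write_text(render_detail(row))
        written.append(path)
    return written
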