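"""Deterministic rendering of engine results to JSON, CSV and markdown.

JSON is the canonical output: every result object serializes to the same
structure regardless of format, and markdown/CSV are renderings of that
structure with no format-only fields.  Rendering the same object twice
yields identical bytes.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import json
from datetime import date, datetime
from typing import Any

import pandas as pd
from pydantic import BaseModel

from .datamodel import MUReport

__all__ = ["to_plain", "render_report"]


def to_plain(obj: Any) -> Any:
    """Recursively convert result objects to JSON-serializable structures."""
    if isinstance(obj, BaseModel):
        return to_plain(obj.model_dump())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [to_plain(v) for v in obj]
    if isinstance(obj, (datetime, date, pd.Timestamp)):
        return obj.isoformat()
    if isinstance(obj, pd.DataFrame):
        return to_plain(obj.to_dict("records"))
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    return obj


def render_report(result: Any, fmt: str = "json") -> str:
    """Render a result object as a document in the requested format.

    ``json`` works for any serializable result; ``csv`` requires a list of
    flat records (or a DataFrame); ``markdown`` is implemented for
    :class:`MUReport` (the uncertainty report) and falls back to a fenced
    JSON block otherwise.
    """
    if fmt == "json":
        return json.dumps(to_plain(result), indent=2, sort_keys=True) + "\n"
    if fmt == "csv":
        plain = to_plain(result)
        if isinstance(plain, dict):
            plain = [plain]
        if not isinstance(plain, list):
            raise ValueError("csv rendering needs a record or list of records")
        buf = io.StringIO()
        pd.json_normalize(plain).to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "markdown":
        if isinstance(result, MUReport):
            return _mu_markdown(result)
        return "```json\n" + json.dumps(to_plain(result), indent=2, sort_keys=True) + "\n```\n"
    raise ValueError(f"unknown format: {fmt!r}")


def _mu_markdown(report: MUReport) -> str:
    """Measurement-uncertainty report in the standard four-section order:
    experimental information, EQA statistics, MU statistics, conclusion."""
    lines = [f"# Measurement uncertainty report: {report.analyte}", ""]

    lines += ["## Experimental information", ""]
    lines.append(f"- Analyte: {report.analyte} ({report.unit})" if report.unit
                 else f"- Analyte: {report.analyte}")
    lines.append(f"- Concentration levels: {len(report.levels)}")
    lines.append(f"- Coverage factor k: {report.k:g}")
    lines.append(f"- Quality goal (allowable expanded uncertainty): {report.quality_goal:.2f}%")
    lines.append("")

    lines += ["## EQA statistics", ""]
    lines.append(f"- EQA results used: {len(report.eqa_biases)}")
    biases = ", ".join(f"{b:+.2f}%" for b in report.eqa_biases)
    lines.append(f"- Percent deviations: {biases}")
    lines.append(f"- Assigned-value uncertainty u_cref: {report.u_cref:.2f}%")
    lines.append("")

    lines += ["## MU statistics", ""]
    lines.append("| Level | Mean | u_Rw (%) | u_bias (%) | u_c (%) | U (%) | Goal met |")
    lines.append("|---|---|---|---|---|---|---|")
    for lvl in report.levels:
        lines.append(
            f"| {lvl.level} | {lvl.iqc_mean:.2f} | {lvl.u_rw:.2f} | {lvl.u_bias:.2f} "
            f"| {lvl.u_c:.2f} | {lvl.u_expanded:.2f} | {'yes' if lvl.goal_met else 'no'} |"
        )
    lines.append("")

    lines += ["## Conclusion", ""]
    if report.all_goals_met:
        lines.append(
            f"The measurement uncertainty at all {len(report.levels)} concentration "
            f"level(s) meets the quality objective of {report.quality_goal:.2f}%."
        )
    else:
        failing = [str(l.level) for l in report.levels if not l.goal_met]
        lines.append(
            f"The expanded uncertainty exceeds the quality objective of "
            f"{report.quality_goal:.2f}% at level(s) {', '.join(failing)}; "
            "corrective action is required."
        )
    lines.append("")
    return "\n".join(lines)
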