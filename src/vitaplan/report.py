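"""Report tables and run manifests.

Monetary reporting follows the source conventions: '000s of 2013 USD for
totals, cents for cost per child-year effectively covered and per child
reached, whole dollars per death averted.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .costs import cost_effectiveness

__all__ = ["summarize_programs", "write_manifest"]


def summarize_programs(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Cost-effectiveness summary from a tidy outcome table.

    ``outcomes`` needs columns ``label``, ``total_cost`` ('000s USD),
    ``reach_cy`` ('000s), ``effective_coverage_cy`` ('000s) and optionally
    ``deaths_averted``.  Returns the three conventional ratios per row.
    """
    rows = []
    for rec in outcomes.to_dict("records"):
        row = dict(rec)
        row["cost_per_child_reached"] = cost_effectiveness(
            rec["total_cost"], rec["reach_cy"], "per_child")
        row["cost_per_cy_covered"] = cost_effectiveness(
            rec["total_cost"], rec["effective_coverage_cy"], "per_cy")
        if rec.get("deaths_averted"):
            row["cost_per_death_averted"] = cost_effectiveness(
                rec["total_cost"], rec["deaths_averted"], "per_death")
        rows.append(row)
    return pd.DataFrame(rows)


def write_manifest(path: str | Path, pipeline_manifest: dict, outputs: list | None = None,
                   extra: dict | None = None) -> Path:
    """Write a JSON manifest describing one pipeline run."""
    manifest = dict(pipeline_manifest)
    manifest["timestamp"] = datetime.now(timezone.utc).isoformat()
    manifest["outputs"] = [str(p) for p in (outputs or [])]
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
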