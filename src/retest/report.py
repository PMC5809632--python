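"""Per-group agreement reports.

``run_report`` applies :func:`retest.agreement.evaluate` to every
(dataset, method, region) group and assembles the results in the
conventional column order WSCV, PTRT, ICC, RC, grand mean.  Machine
output keeps full precision; human rendering rounds to two decimals
and shows PTRT and WSCV additionally as percentages.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import agreement
from .model import TestRetestTable

__all__ = ["REPORT_COLUMNS", "run_report", "render_report"]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["WSCV", "PTRT", "ICC", "RC", "grand_mean"]
_KEY_COLUMNS = ["dataset_id", "method_id", "region"]


def run_report(
    groups: dict[tuple, TestRetestTable], alpha: float = 0.05
) -> pd.DataFrame:
    """Evaluate every group; failures become NaN rows with an ``error``
    note and the run continues."""
    rows = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        row = dict(zip(_KEY_COLUMNS, key))
        try:
            idx = agreement.evaluate(groups[key], alpha=alpha)
        except Exception as exc:  # per-group failure must not kill the run
            logger.warning("group %s failed: %s", key, exc)
            row.update({c: float("nan") for c in REPORT_COLUMNS})
            row.update({"n_subjects": len(groups[key]), "error": str(exc)})
        else:
            row.update(
                {
                    "WSCV": idx.wscv,
                    "PTRT": idx.ptrt_abs,
                    "ICC": idx.icc,
                    "RC": idx.rc,
                    "grand_mean": idx.grand_mean,
                    "n_subjects": idx.n_subjects,
                    "WSCV_ci_low": idx.ci["wscv"][0],
                    "WSCV_ci_high": idx.ci["wscv"][1],
                    "ICC_ci_low": idx.ci["icc"][0],
                    "ICC_ci_high": idx.ci["icc"][1],
                    "RC_ci_low": idx.ci["rc"][0],
                    "RC_ci_high": idx.ci["rc"][1],
                    "error": "",
                }
            )
        rows.append(row)
    cols = _KEY_COLUMNS + REPORT_COLUMNS + [
        "n_subjects",
        "WSCV_ci_low",
        "WSCV_ci_high",
        "ICC_ci_low",
        "ICC_ci_high",
        "RC_ci_low",
        "RC_ci_high",
        "error",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def render_report(report: pd.DataFrame) -> str:
    """Human-readable rendering: two decimals, PTRT and WSCV as percent.

    The percent columns are exactly 100x the machine values; no
    rounding happens in the machine output.
    """
    shown = report[_KEY_COLUMNS].copy()
    shown["WSCV (%)"] = (report["WSCV"] * 100).round(2)
    shown["PTRT (%)"] = (report["PTRT"] * 100).round(2)
    for c in ("WSCV", "PTRT", "ICC", "RC", "grand_mean"):
        shown[c] = report[c].round(2)
    shown["n"] = report["n_subjects"]
    order = _KEY_COLUMNS + REPORT_COLUMNS + ["WSCV (%)", "PTRT (%)", "n"]
    return shown[order].to_string(index=False)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the machine-readable report at full precision."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    report.to_csv(path, sep=sep, index=False)
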