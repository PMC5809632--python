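"""Readers and writers for tabular test-retest data.

Two delimited-text dialects are supported, chosen explicitly (no
auto-detection — silently misparsing repeatability data is worse than
an error):

* **long**: one row per scan, columns
  ``dataset_id, method_id, region, subject_id, scan_index, value``
  (scan_index is 1 for test, 2 for retest);
* **wide**: one row per subject, columns
  ``subject, test_value, retest_value`` — a single unlabelled group.

Strict mode raises descriptive errors with line numbers on malformed
rows, duplicate keys and subjects missing a scan; lenient mode drops
the offending rows/subjects and logs counts, because repeatability
conclusions are sensitive to silent exclusions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GroupLabels, TestRetestTable, ValidationError

__all__ = [
    "LONG_COLUMNS",
    "WIDE_COLUMNS",
    "read_table",
    "read_long",
    "read_wide",
    "write_long",
    "write_wide",
    "groups_to_long_frame",
]

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["dataset_id", "method_id", "region", "subject_id", "scan_index", "value"]
WIDE_COLUMNS = ["subject", "test_value", "retest_value"]
_GROUP_COLS = ["dataset_id", "method_id", "region"]


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(
    path: str | Path, format: str = "long", strict: bool = True
) -> dict[tuple, TestRetestTable]:
    """Read a delimited file into validated per-group tables.

    Returns a mapping from ``(dataset_id, method_id, region)`` tuples to
    :class:`TestRetestTable`; wide files yield a single group keyed
    ``(None, None, None)``.
    """
    if format == "long":
        return read_long(path, strict=strict)
    if format == "wide":
        table = read_wide(path, strict=strict)
        return {(None, None, None): table}
    raise ValidationError(f"unknown format {format!r}; use 'long' or 'wide'")


def _read_frame(path: Path, expected: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {unknown}")
    return df


def _to_numeric(df: pd.DataFrame, col: str, path: Path, strict: bool) -> pd.DataFrame:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | ~np.isfinite(vals.fillna(np.nan))
    if bad.any():
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad]]
        if strict:
            raise ValidationError(
                f"{path}: non-numeric or non-finite {col!r} at line(s) {lines}"
            )
        logger.warning("%s: dropped %d row(s) with bad %s", path, len(lines), col)
        df = df[~bad].copy()
        vals = vals[~bad]
    df[col] = vals.astype(float)
    return df


def read_long(path: str | Path, strict: bool = True) -> dict[tuple, TestRetestTable]:
    """Read a long-format file into per-(dataset, method, region) tables."""
    path = Path(path)
    df = _read_frame(path, LONG_COLUMNS)
    df = _to_numeric(df, "value", path, strict)

    scan = pd.to_numeric(df["scan_index"], errors="coerce")
    bad_scan = ~scan.isin([1, 2])
    if bad_scan.any():
        lines = [int(i) + 2 for i in df.index[bad_scan]]
        if strict:
            raise ValidationError(
                f"{path}: scan_index must be 1 or 2; bad line(s) {lines}"
            )
        logger.warning("%s: dropped %d row(s) with bad scan_index", path, len(lines))
        df = df[~bad_scan].copy()
        scan = scan[~bad_scan]
    df["scan_index"] = scan.astype(int)

    keys = _GROUP_COLS + ["subject_id", "scan_index"]
    dupes = df.duplicated(subset=keys, keep=False)
    if dupes.any():
        lines = [int(i) + 2 for i in df.index[dupes]]
        raise ValidationError(
            f"{path}: duplicate (dataset, method, region, subject, scan) "
            f"key at line(s) {lines}"
        )

    groups: dict[tuple, TestRetestTable] = {}
    n_dropped_subjects = 0
    for key, g in df.groupby(_GROUP_COLS, sort=True):
        pivot = g.pivot(index="subject_id", columns="scan_index", values="value")
        incomplete = [
            str(s)
            for s in pivot.index
            if 1 not in pivot.columns
            or 2 not in pivot.columns
            or pivot.loc[s].isna().any()
        ]
        if incomplete:
            if strict:
                raise ValidationError(
                    f"{path}: group {key}: subject(s) {incomplete} do not "
                    "have exactly 2 scans"
                )
            n_dropped_subjects += len(incomplete)
            pivot = pivot.drop(index=incomplete)
        if len(pivot) < 2:
            msg = f"{path}: group {key}: fewer than 2 complete subjects"
            if strict:
                raise ValidationError(msg)
            logger.warning("%s — group skipped", msg)
            continue
        groups[key] = TestRetestTable.from_arrays(
            pivot[1].to_numpy(),
            pivot[2].to_numpy(),
            subject_ids=[str(s) for s in pivot.index],
            labels=GroupLabels(*key),
        )
    if n_dropped_subjects:
        logger.warning(
            "%s: dropped %d subject(s) without exactly 2 scans", path, n_dropped_subjects
        )
    return groups


def read_wide(path: str | Path, strict: bool = True) -> TestRetestTable:
    """Read a wide-format file (one row per subject) into a single table."""
    path = Path(path)
    df = _read_frame(path, WIDE_COLUMNS)
    df = _to_numeric(df, "test_value", path, strict)
    df = _to_numeric(df, "retest_value", path, strict)
    dupes = df.duplicated(subset=["subject"], keep=False)
    if dupes.any():
        lines = [int(i) + 2 for i in df.index[dupes]]
        raise ValidationError(f"{path}: duplicate subject at line(s) {lines}")
    return TestRetestTable.from_arrays(
        df["test_value"].to_numpy(),
        df["retest_value"].to_numpy(),
        subject_ids=[str(s) for s in df["subject"]],
    )


def groups_to_long_frame(groups: dict[tuple, TestRetestTable]) -> pd.DataFrame:
    """Flatten per-group tables back into a long-format DataFrame."""
    rows = []
    for key, table in groups.items():
        ds, method, region = key
        for p in table.pairs:
            for j, v in ((1, p.y1), (2, p.y2)):
                rows.append(
                    {
                        "dataset_id": ds,
                        "method_id": method,
                        "region": region,
                        "subject_id": p.subject_id,
                        "scan_index": j,
                        "value": v,
                    }
                )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def write_long(
    data: pd.DataFrame | dict[tuple, TestRetestTable], path: str | Path
) -> None:
    """Write long-format data (a DataFrame or grouped tables) to CSV/TSV."""
    path = Path(path)
    if isinstance(data, dict):
        data = groups_to_long_frame(data)
    missing = [c for c in LONG_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"long frame missing column(s) {missing}")
    data[LONG_COLUMNS].to_csv(path, sep=_delimiter_for(path), index=False)


def write_wide(table: TestRetestTable, path: str | Path) -> None:
    """Write one table as a wide-format file, full float precision."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject": table.subject_ids,
            "test_value": table.values[:, 0],
            "retest_value": table.values[:, 1],
        }
    )
    df.to_csv(path, sep=_delimiter_for(path), index=False)
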