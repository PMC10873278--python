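"""Readers and writers for GBD-results-style tables and result files.

The canonical input dialect is the long-format CSV the GBD results tool
exports: one row per (location, sex, year, cause, metric) with ``val`` and
optional ``lower``/``upper`` columns.  Column names are matched flexibly
(``location`` or ``location_name``, ``metric`` or ``metric_name``, ...);
unknown extra columns are ignored with a logged notice.
"""

from __future__ import annotations

import io as _io
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CodhetError, HierarchyError, ProfileError, TableSchemaError
from .metrics import CauseProfile
from .taxonomy import CauseTree
from .trends import PANEL_COLUMNS, PanelResult

logger = logging.getLogger("codhet")

__all__ = [
    "GbdRecord",
    "read_gbd_table",
    "records_to_profiles",
    "write_results",
    "read_results",
]

_COLUMN_ALIASES = {
    "location": ("location", "location_name"),
    "sex": ("sex", "sex_name"),
    "year": ("year",),
    "cause_id": ("cause_id", "cause"),
    "cause_name": ("cause_name",),
    "metric": ("metric", "metric_name"),
    "val": ("val", "value"),
    "lower": ("lower",),
    "upper": ("upper",),
}
_REQUIRED = ("location", "sex", "year", "cause_id", "metric", "val")

_METRIC_ALIASES = {
    "deaths": "deaths",
    "deaths-count": "deaths",
    "number": "deaths",
    "percent": "percent",
    "rate": "rate",
}
_SEX_ALIASES = {"female": "female", "male": "male", "both": "both", "f": "female", "m": "male"}


@dataclass(frozen=True)
class GbdRecord:
    """One (location, sex, year, cause) observation of a mortality metric."""

    location: str
    sex: str
    year: int
    cause_id: str
    cause_name: str
    metric: str  # deaths | percent | rate
    val: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.val < 0:
            raise TableSchemaError(f"negative value {self.val} for cause {self.cause_id!r}")
        if not 1900 <= self.year <= 2100:
            raise TableSchemaError(f"implausible year {self.year}")
        if self.lower is not None and self.upper is not None:
            if not self.lower <= self.val <= self.upper:
                raise TableSchemaError(
                    f"cause {self.cause_id!r}: bounds ({self.lower}, {self.upper}) "
                    f"do not bracket value {self.val}"
                )


def _resolve_columns(frame: pd.DataFrame) -> dict[str, str]:
    lower_map = {c.lower(): c for c in frame.columns}
    resolved = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower_map:
                resolved[canon] = lower_map[alias]
                break
    missing = [c for c in _REQUIRED if c not in resolved]
    if missing:
        raise TableSchemaError(f"input table is missing required column(s) {missing!r}")
    used = set(resolved.values())
    extra = [c for c in frame.columns if c not in used]
    if extra:
        logger.info("ignoring extra columns: %s", extra)
    return resolved


def read_gbd_table(source) -> list[GbdRecord]:
    """Parse a GBD-results-style CSV into typed records.

    ``source`` may be a path, CSV text, or a file-like object.  Rows with
    non-numeric values or inverted bounds raise :class:`TableSchemaError`
    naming the offending line (header = line 1).
    """
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        frame = pd.read_csv(source, dtype=str, keep_default_na=False, encoding="utf-8")
    elif isinstance(source, str):
        frame = pd.read_csv(_io.StringIO(source), dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    cols = _resolve_columns(frame)
    records = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        get = lambda canon: getattr(row, cols[canon]) if canon in cols else ""
        try:
            year = int(float(get("year")))
            val = float(get("val"))
            lower = float(get("lower")) if get("lower") not in ("", None) else None
            upper = float(get("upper")) if get("upper") not in ("", None) else None
        except (TypeError, ValueError) as exc:
            raise TableSchemaError(f"line {pos}: non-numeric field ({exc})") from None
        metric_raw = str(get("metric")).strip().lower()
        metric = _METRIC_ALIASES.get(metric_raw)
        if metric is None:
            raise TableSchemaError(
                f"line {pos}: unknown metric {metric_raw!r} "
                f"(expected one of {sorted(set(_METRIC_ALIASES))})"
            )
        sex = _SEX_ALIASES.get(str(get("sex")).strip().lower())
        if sex is None:
            raise TableSchemaError(f"line {pos}: unknown sex {get('sex')!r}")
        try:
            records.append(
                GbdRecord(
                    location=str(get("location")),
                    sex=sex,
                    year=year,
                    cause_id=str(get("cause_id")),
                    cause_name=str(get("cause_name") or get("cause_id")),
                    metric=metric,
                    val=val,
                    lower=lower,
                    upper=upper,
                )
            )
        except TableSchemaError as exc:
            raise TableSchemaError(f"line {pos}: {exc}") from None
    return records


def records_to_profiles(
    records: Iterable[GbdRecord],
    tree: CauseTree,
    policy: str = "error",
) -> list[CauseProfile]:
    """Group records by (location, sex, year) and align them to the tree.

    ``policy`` governs analysis causes of the tree absent from a group:
    ``error`` rejects the group, ``zero-fill`` assigns share 0 with
    degenerate bounds, ``renormalize`` restricts the cause universe to the
    causes present (the usual treatment of categories with no deaths).
    Deaths/rate metrics are normalised by the group total; percent metrics
    are divided by 100 (group sums must be within 0.01 of 100).
    """
    if policy not in ("error", "zero-fill", "renormalize"):
        raise CodhetError(f"unknown policy {policy!r}")
    universe = tree.analysis_causes
    known = set(universe)
    groups: dict[tuple, dict[str, GbdRecord]] = {}
    for rec in records:
        if rec.cause_id not in known:
            raise HierarchyError(
                f"cause {rec.cause_id!r} is not an analysis cause of the hierarchy"
            )
        key = (rec.location, rec.sex, rec.year)
        bucket = groups.setdefault(key, {})
        if rec.cause_id in bucket:
            raise TableSchemaError(
                f"duplicate rows for cause {rec.cause_id!r} in group {key!r}"
            )
        bucket[rec.cause_id] = rec

    profiles = []
    for key in sorted(groups):
        bucket = groups[key]
        metrics = {rec.metric for rec in bucket.values()}
        if len(metrics) > 1:
            raise TableSchemaError(f"mixed metrics {sorted(metrics)!r} in group {key!r}")
        metric = metrics.pop()
        missing = [c for c in universe if c not in bucket]
        if missing and policy == "error":
            raise ProfileError(
                f"group {key!r} lacks {len(missing)} tree cause(s), e.g. "
                f"{missing[:5]!r}; use policy='zero-fill' or 'renormalize'"
            )
        causes = tuple(c for c in universe if c in bucket) if policy == "renormalize" else universe
        val = np.array([bucket[c].val if c in bucket else 0.0 for c in causes])
        has_bounds = all(
            bucket[c].lower is not None and bucket[c].upper is not None
            for c in causes if c in bucket
        )
        lo = np.array(
            [bucket[c].lower if c in bucket and has_bounds else (bucket[c].val if c in bucket else 0.0) for c in causes]
        )
        hi = np.array(
            [bucket[c].upper if c in bucket and has_bounds else (bucket[c].val if c in bucket else 0.0) for c in causes]
        )
        if metric == "percent":
            total = val.sum()
            if abs(total - 100.0) > 0.01 and abs(total - 1.0) > 1e-4:
                raise ProfileError(
                    f"group {key!r}: percent shares sum to {total:.4f}, "
                    "expected 100 (within 0.01)"
                )
            scale = total
        else:  # deaths or rate: normalise by the group total
            scale = val.sum()
            if scale <= 0:
                raise ProfileError(f"group {key!r}: all values are zero")
        shares, lo, hi = val / scale, lo / scale, hi / scale
        meta = {"location": key[0], "sex": key[1], "year": key[2], "metric": metric}
        profiles.append(
            CauseProfile(causes, shares, meta, bounds=np.column_stack([lo, hi]))
        )
    return profiles


def write_results(
    panel: PanelResult,
    destination,
    decompositions: dict[str, pd.DataFrame] | None = None,
) -> list[Path]:
    """Write a panel (and optional decomposition tables) as CSV files.

    ``destination`` is a directory (created if needed) or a ``.csv`` path
    when only the panel is written.  Rows are ordered by (location, sex,
    year); numeric values round-trip to better than 1e-9.
    """
    if panel.table.empty:
        raise CodhetError("refusing to write an empty panel")
    destination = Path(destination)
    written = []
    if destination.suffix == ".csv":
        panel_path = destination
        destination.parent.mkdir(parents=True, exist_ok=True)
    else:
        destination.mkdir(parents=True, exist_ok=True)
        panel_path = destination / "panel.csv"
    table = panel.table.sort_values(
        ["location", "sex", "year"], kind="mergesort"
    ).reset_index(drop=True)
    table.to_csv(panel_path, index=False, float_format="%.12g", encoding="utf-8")
    written.append(panel_path)
    if panel.significance is not None and not panel.significance.empty:
        sig_path = panel_path.with_name(panel_path.stem + "_significance.csv")
        panel.significance.to_csv(sig_path, index=False, float_format="%.12g", encoding="utf-8")
        written.append(sig_path)
    for name, frame in (decompositions or {}).items():
        path = (destination if destination.suffix != ".csv" else destination.parent) / f"decomposition_{name}.csv"
        frame.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
        written.append(path)
    logger.info("wrote %d file(s): %s", len(written), [str(p) for p in written])
    return written


def read_results(path) -> PanelResult:
    """Read back a panel CSV written by :func:`write_results`."""
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise TableSchemaError(f"panel file is missing column(s) {missing!r}")
    return PanelResult(table=table)
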