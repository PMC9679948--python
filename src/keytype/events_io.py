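"""Reading, validating, classifying and sessionizing raw keystroke event logs.

Event logs carry one record per press or release with a subject id, a
millisecond timestamp, the action, and either a pre-classified ``key_class``
or a raw ``key_label`` from which the class is derived.  No text content
beyond the key class is ever stored.

The canonical in-memory representation is a :class:`pandas.DataFrame` with
columns ``subject_id, timestamp_ms, action, key_class, key_token`` sorted by
``(subject_id, timestamp_ms)``; :func:`segment_sessions` adds a
``session_id`` column partitioning each subject's stream at typing pauses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIONS = ("press", "release")
KEY_CLASSES = ("alphanumeric", "backspace", "punctuation", "other")

#: punctuation marks mapped to the ``punctuation`` class by default
DEFAULT_PUNCTUATION = frozenset({".", ",", ";", ":", "!", "?"})

#: labels recognised as the deletion key
BACKSPACE_LABELS = frozenset({"backspace", "delete", "del", "\b", "\x7f"})

EVENT_COLUMNS = ["subject_id", "timestamp_ms", "action", "key_class", "key_token"]


class SchemaError(ValueError):
    """Input file does not conform to the documented event schema."""


@dataclass
class IngestReport:
    """Row-level accounting for one ingest."""

    n_rows: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    rejection_reasons: dict = field(default_factory=dict)

    def reject(self, reason: str, n: int = 1) -> None:
        self.n_rejected += n
        self.rejection_reasons[reason] = self.rejection_reasons.get(reason, 0) + n


def classify_key(key_label: str, punctuation: frozenset | set = DEFAULT_PUNCTUATION) -> str:
    """Map a raw key label to one of the four key classes.

    Single letter or digit characters are ``alphanumeric``, the deletion
    key is ``backspace``, a configurable set of marks is ``punctuation``,
    and everything else — space, return, shift and other multi-character
    special-key labels, emoji — is ``other``.  Total function: never
    raises on a non-empty label.
    """
    if not key_label:
        raise ValueError("key_label must be non-empty")
    if key_label.lower() in BACKSPACE_LABELS:
        return "backspace"
    if len(key_label) == 1 and key_label.isalnum():
        return "alphanumeric"
    if key_label in punctuation:
        return "punctuation"
    return "other"


def _finalize(df: pd.DataFrame, report: IngestReport) -> pd.DataFrame:
    """Validate, coerce and sort a raw event frame; drop bad rows with a tally."""
    required = {"subject_id", "timestamp_ms", "action"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    if "key_class" not in df.columns and "key_label" not in df.columns:
        raise SchemaError("missing required column(s): key_class or key_label")

    report.n_rows = len(df)
    ts = pd.to_numeric(df["timestamp_ms"], errors="coerce")
    bad_ts = ts.isna() | (ts < 0)
    if bad_ts.any():
        report.reject("unparseable or negative timestamp", int(bad_ts.sum()))
    bad_action = ~df["action"].isin(ACTIONS)
    if bad_action.any():
        report.reject("unknown action", int(bad_action.sum()))

    if "key_class" in df.columns:
        key_class = df["key_class"].astype(str)
        bad_class = ~key_class.isin(KEY_CLASSES)
        if bad_class.any():
            report.reject("unknown key_class", int(bad_class.sum()))
    else:
        labels = df["key_label"].astype(str)
        key_class = labels.map(lambda s: classify_key(s) if s else "other")
        bad_class = pd.Series(False, index=df.index)

    keep = ~(bad_ts | bad_action | bad_class)
    out = pd.DataFrame(
        {
            "subject_id": df.loc[keep, "subject_id"].astype(str),
            # sub-ms input truncated to integer milliseconds
            "timestamp_ms": ts[keep].astype(np.int64),
            "action": df.loc[keep, "action"].astype(str),
            "key_class": key_class[keep],
            "key_token": (
                df.loc[keep, "key_token"].astype(str)
                if "key_token" in df.columns
                else pd.Series("", index=df.index[keep])
            ),
        }
    )
    out = out.sort_values(["subject_id", "timestamp_ms"], kind="stable").reset_index(drop=True)
    report.n_valid = len(out)
    if report.n_rejected:
        logger.warning(
            "rejected %d of %d event rows: %s",
            report.n_rejected,
            report.n_rows,
            report.rejection_reasons,
        )
    return out


def read_events(path: str | Path, format: str = "csv") -> tuple[pd.DataFrame, IngestReport]:
    """Read a keystroke event log into the canonical sorted event frame.

    Parameters
    ----------
    path
        CSV or JSONL file with columns/keys ``subject_id, timestamp_ms,
        action`` plus ``key_class`` or ``key_label`` (and optionally
        ``key_token`` for press/release pairing under rollover).
    format
        ``"csv"`` or ``"jsonl"``.

    Returns
    -------
    (events, report)
        Events sorted by ``(subject_id, timestamp_ms)``; malformed rows are
        dropped and tallied in the report.
    """
    path = Path(path)
    report = IngestReport()
    if format == "csv":
        df = pd.read_csv(path, dtype=str)
    elif format == "jsonl":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError:
                    report.reject("unparseable JSON line")
        df = pd.DataFrame(rows)
        if df.empty:
            df = pd.DataFrame(columns=["subject_id", "timestamp_ms", "action", "key_class"])
    else:
        raise ValueError(f"unknown format: {format!r}")
    return _finalize(df, report), report


def write_events(events: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write events in the canonical schema (round-trips with read_events)."""
    out = events.reindex(columns=EVENT_COLUMNS)
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w") as fh:
            for rec in out.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def segment_sessions(events: pd.DataFrame, max_gap_s: float = 5.0) -> pd.DataFrame:
    """Partition each subject's event stream into typing sessions.

    A new session starts whenever the gap between consecutive events of the
    same subject exceeds ``max_gap_s``.  Sessions keep latency features from
    spanning long pauses (a latency is only meaningful inside one bout of
    typing).  Returns a copy with ``session_id`` (globally unique integer)
    and ``session_date`` (UTC calendar date of the session's first event)
    columns; total event count is conserved.
    """
    if max_gap_s < 0:
        raise ValueError("max_gap_s must be nonnegative")
    if events.empty:
        ev = events.copy()
        ev["session_id"] = pd.Series(dtype=np.int64)
        ev["session_date"] = pd.Series(dtype="object")
        return ev
    subj = events["subject_id"]
    codes = subj.cat.codes.to_numpy() if isinstance(subj.dtype, pd.CategoricalDtype) \
        else pd.factorize(subj)[0]
    ts = events["timestamp_ms"].to_numpy()
    same = np.r_[False, codes[1:] == codes[:-1]]
    run_start = np.r_[True, codes[1:] != codes[:-1]]
    already_grouped = bool(
        np.all(run_start | (np.r_[0, np.diff(ts)] >= 0))
        and int(run_start.sum()) == len(np.unique(codes))
    )
    if already_grouped:
        ev = events.reset_index(drop=True).copy()
    else:
        ev = events.sort_values(["subject_id", "timestamp_ms"], kind="stable").reset_index(
            drop=True
        )
        subj2 = ev["subject_id"]
        codes = subj2.cat.codes.to_numpy() if isinstance(subj2.dtype, pd.CategoricalDtype) \
            else pd.factorize(subj2)[0]
        ts = ev["timestamp_ms"].to_numpy()
        same = np.r_[False, codes[1:] == codes[:-1]]
    gap = np.r_[0, np.diff(ts)] > max_gap_s * 1000.0
    new_session = ~same | gap
    ev["session_id"] = np.cumsum(new_session) - 1
    starts = np.flatnonzero(new_session)
    counts = np.diff(np.r_[starts, len(ev)])
    start_dates = pd.to_datetime(ts[starts], unit="ms", utc=True).date
    ev["session_date"] = np.repeat(start_dates, counts)
    return ev
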