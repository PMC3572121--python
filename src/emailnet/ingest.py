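"""Reading, validating and aggregating the three input tables.

The pipeline consumes three plain CSV tables (UTF-8, header row mandatory):

* **email log** — one row per delivered email with columns
  ``sender_id,recipient_id,timestamp,n_recipients,file_size``. An empty
  sender or recipient field marks mail to/from an external address; such
  records carry no usable pair information and are dropped by
  :func:`filter_internal`. A message sent to k recipients appears as k
  rows, each with the same ``n_recipients`` (per-delivery records).
* **survey** — ``respondent_id,named_id``, one named contact per row.
* **traits** — ``person_id,bmi``.

IDs are opaque strings compared by equality; nothing assumes integer IDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EMAIL_COLUMNS",
    "SurveyTable",
    "read_email_log",
    "read_survey",
    "read_traits",
    "write_email_log",
    "write_survey",
    "write_traits",
    "filter_internal",
    "aggregate_pairs",
]

EMAIL_COLUMNS = ("sender_id", "recipient_id", "timestamp", "n_recipients", "file_size")
PAIR_COLUMNS = ("sender_id", "recipient_id", "n_single", "n_multi", "size_sum")


@dataclass(frozen=True)
class SurveyTable:
    """Name-generator survey responses as (respondent, named contact) rows.

    Every named individual shares an undirected tie with the respondent;
    named non-respondents still belong to the surveyed population.
    """

    ties: pd.DataFrame  # columns respondent_id, named_id; deduplicated

    def __post_init__(self) -> None:
        df = self.ties
        if list(df.columns) != ["respondent_id", "named_id"]:
            raise ValueError("survey table needs columns respondent_id, named_id")
        if (df["respondent_id"] == df["named_id"]).any():
            bad = df[df["respondent_id"] == df["named_id"]].index[0]
            raise ValueError(f"respondent names themself at row {bad}")

    @property
    def respondents(self) -> frozenset:
        return frozenset(self.ties["respondent_id"])

    @property
    def named(self) -> frozenset:
        return frozenset(self.ties["named_id"])

    @property
    def people(self) -> frozenset:
        """Everyone who responded to or was named in the survey."""
        return self.respondents | self.named


def read_email_log(path: str | Path) -> pd.DataFrame:
    """Read and validate an email-log CSV.

    Returns a DataFrame with the canonical columns; null sender/recipient
    (empty CSV fields) are preserved as missing values so external mail can
    be excluded downstream. Malformed rows raise ``ValueError`` naming the
    offending (0-based data) row.
    """
    df = pd.read_csv(path, dtype={"sender_id": "string", "recipient_id": "string"})
    missing = set(EMAIL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"email log {path} missing columns: {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad_ts = ts.isna() & df["timestamp"].notna()
    if bad_ts.any():
        row = int(np.flatnonzero(bad_ts)[0])
        raise ValueError(f"unparseable timestamp at row {row}: {df['timestamp'].iloc[row]!r}")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"missing timestamp at row {row}")

    nrec = pd.to_numeric(df["n_recipients"], errors="coerce")
    bad = nrec.isna() | (nrec < 1) | (nrec % 1 != 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid n_recipients at row {row}: {df['n_recipients'].iloc[row]!r}")

    size = pd.to_numeric(df["file_size"], errors="coerce")
    bad = size.isna() | (size < 0)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid file_size at row {row}: {df['file_size'].iloc[row]!r}")

    out = pd.DataFrame(
        {
            "sender_id": df["sender_id"],
            "recipient_id": df["recipient_id"],
            "timestamp": ts,
            "n_recipients": nrec.astype(int),
            "file_size": size.astype(int),
        }
    )
    return out


def read_survey(path: str | Path, max_names: int = 20) -> SurveyTable:
    """Read a survey CSV; duplicate namings collapse to one row."""
    df = pd.read_csv(path, dtype="string")
    missing = {"respondent_id", "named_id"} - set(df.columns)
    if missing:
        raise ValueError(f"survey {path} missing columns: {sorted(missing)}")
    if df[["respondent_id", "named_id"]].isna().any().any():
        row = int(np.flatnonzero(df[["respondent_id", "named_id"]].isna().any(axis=1))[0])
        raise ValueError(f"missing ID in survey at row {row}")
    df = df[["respondent_id", "named_id"]].drop_duplicates(ignore_index=True)
    counts = df.groupby("respondent_id").size()
    over = counts[counts > max_names]
    if len(over):
        raise ValueError(
            f"respondent {over.index[0]} names {int(over.iloc[0])} distinct people "
            f"(cap is {max_names})"
        )
    return SurveyTable(df)


def read_traits(path: str | Path) -> pd.Series:
    """Read a trait CSV (person_id,bmi) into a float Series indexed by person."""
    df = pd.read_csv(path, dtype={"person_id": "string"})
    missing = {"person_id", "bmi"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table {path} missing columns: {sorted(missing)}")
    if df["person_id"].duplicated().any():
        dup = df["person_id"][df["person_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate person_id in trait table: {dup}")
    s = pd.Series(
        pd.to_numeric(df["bmi"], errors="coerce").to_numpy(float),
        index=pd.Index(df["person_id"].astype(str), name="person_id"),
        name="bmi",
    )
    return s


def write_email_log(records: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, columns=list(EMAIL_COLUMNS))
    return path


def write_survey(survey: SurveyTable, path: str | Path) -> Path:
    path = Path(path)
    survey.ties.to_csv(path, index=False)
    return path


def write_traits(trait: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    trait.rename("bmi").rename_axis("person_id").to_csv(path)
    return path


def filter_internal(records: pd.DataFrame, survey_people: set | frozenset) -> pd.DataFrame:
    """Apply the two exclusion filters, preserving record order.

    1. Drop external mail: any record with a null sender or recipient.
    2. Drop records where *neither* endpoint responded to or was named in
       the survey (one surveyed endpoint is enough to keep a record).
    """
    internal = records["sender_id"].notna() & records["recipient_id"].notna()
    sp = pd.Index(sorted(survey_people))
    in_survey = records["sender_id"].isin(sp) | records["recipient_id"].isin(sp)
    return records[internal & in_survey].reset_index(drop=True)


def aggregate_pairs(
    records: pd.DataFrame,
    window: tuple | None = None,
) -> pd.DataFrame:
    """Aggregate email records to ordered-pair summaries over a time window.

    Parameters
    ----------
    records :
        Filtered email records (no nulls expected; null-endpoint and
        self-pair rows are dropped defensively).
    window :
        ``(start, end)`` datetimes; records with ``start <= t < end`` are
        counted. Defaults to the closed span of the log (both endpoints in).

    Returns
    -------
    DataFrame with one row per ordered (sender, recipient) pair that has any
    in-window email: columns ``n_single`` (emails with exactly one
    recipient), ``n_multi`` (recipient count >= 2) and ``size_sum``.
    """
    df = records[records["sender_id"].notna() & records["recipient_id"].notna()]
    df = df[df["sender_id"] != df["recipient_id"]]
    if window is not None:
        start, end = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
        if end <= start:
            raise ValueError(f"window end {end} must be after start {start}")
    elif len(df):
        start = df["timestamp"].min()
        end = df["timestamp"].max() + pd.Timedelta(1, "ns")
    else:
        start = end = None
    if start is not None:
        df = df[(df["timestamp"] >= start) & (df["timestamp"] < end)]
    if not len(df):
        return pd.DataFrame({c: pd.Series(dtype="object" if c.endswith("_id") else int)
                             for c in PAIR_COLUMNS})
    tmp = pd.DataFrame(
        {
            "sender_id": df["sender_id"].astype(str),
            "recipient_id": df["recipient_id"].astype(str),
            "n_single": (df["n_recipients"] == 1).astype(int),
            "n_multi": (df["n_recipients"] >= 2).astype(int),
            "size_sum": df["file_size"].astype(int),
        }
    )
    out = (
        tmp.groupby(["sender_id", "recipient_id"], as_index=False, sort=True)
        .sum()
    )
    return out
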