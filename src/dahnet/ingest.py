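"""Reading, validating and aggregating DAH disbursement flow tables.

A flow table is a flat pandas DataFrame with one row per disbursement
record: calendar year, source actor, channel actor, recipient country,
health area and amount in constant USD.  The CSV dialect is
``year,source_id,channel_id,recipient_id,health_area,amount_usd`` (UTF-8),
with the literal sentinel ``UNSPECIFIED`` marking endpoints the reporting
agency did not identify.  Records with any unspecified endpoint are excluded
from analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an endpoint the reporting agency did not identify.
UNSPECIFIED = "UNSPECIFIED"

#: Canonical column order of the flow-table CSV dialect.
FLOW_COLUMNS = ["year", "source_id", "channel_id", "recipient_id",
                "health_area", "amount_usd"]

_ENDPOINT_COLUMNS = ["source_id", "channel_id", "recipient_id"]


class FlowTableError(ValueError):
    """Raised for malformed flow tables; carries offending line numbers."""

    def __init__(self, message: str, lines: Sequence[int] = ()):
        super().__init__(message)
        self.lines = list(lines)


def _validate(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in FLOW_COLUMNS if c not in df.columns]
    if missing:
        raise FlowTableError(f"{origin}: missing columns {missing}")

    # data line numbers: header is line 1, first record line 2
    lineno = pd.RangeIndex(2, len(df) + 2)

    amounts = pd.to_numeric(df["amount_usd"], errors="coerce")
    bad_numeric = lineno[amounts.isna().to_numpy()]
    if len(bad_numeric):
        raise FlowTableError(
            f"{origin}: non-numeric amount_usd at lines {list(bad_numeric)}",
            lines=list(bad_numeric),
        )
    negative = lineno[(amounts < 0).to_numpy()]
    if len(negative):
        raise FlowTableError(
            f"{origin}: negative amount_usd at lines {list(negative)} "
            "(disbursements cannot be negative)",
            lines=list(negative),
        )

    years = pd.to_numeric(df["year"], errors="coerce")
    bad_year = lineno[years.isna().to_numpy()]
    if len(bad_year):
        raise FlowTableError(
            f"{origin}: non-integer year at lines {list(bad_year)}",
            lines=list(bad_year),
        )

    empty = pd.Series(False, index=df.index)
    for col in _ENDPOINT_COLUMNS + ["health_area"]:
        empty |= df[col].astype(str).str.strip().eq("")
    bad_empty = lineno[empty.to_numpy()]
    if len(bad_empty):
        raise FlowTableError(
            f"{origin}: empty identifier fields at lines {list(bad_empty)}",
            lines=list(bad_empty),
        )

    out = df.loc[:, FLOW_COLUMNS].copy()
    out["year"] = years.astype(int)
    out["amount_usd"] = amounts.astype(float)
    for col in _ENDPOINT_COLUMNS + ["health_area"]:
        out[col] = out[col].astype(str).str.strip()
    return out.reset_index(drop=True)


def read_flow_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a flow-table CSV; row order is preserved.

    Raises :class:`FlowTableError` naming the offending lines for missing
    columns, non-numeric or negative amounts, or blank identifiers.  A
    header-only file yields an empty table.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return _validate(df, origin=str(path))


def write_flow_table(flows: pd.DataFrame, path: str | Path) -> None:
    """Write a flow table in the canonical CSV dialect (deterministic bytes)."""
    out = flows.loc[:, FLOW_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.2f")


def validate_flows(flows: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory flow table against the schema contract."""
    return _validate(flows, origin="<in-memory>")


def drop_unspecified(flows: pd.DataFrame) -> pd.DataFrame:
    """Remove records with an UNSPECIFIED source, channel or recipient.

    Flows with unidentified endpoints cannot be attributed to actors and are
    excluded from all network construction and metrics.  The number of
    dropped records is logged; applying the filter twice is a no-op.
    """
    mask = pd.Series(False, index=flows.index)
    for col in _ENDPOINT_COLUMNS:
        mask |= flows[col].eq(UNSPECIFIED)
    dropped = int(mask.sum())
    if dropped == len(flows) and len(flows) > 0:
        logger.warning("all %d records have unspecified endpoints", dropped)
    elif dropped:
        logger.info("dropped %d/%d records with unspecified endpoints",
                    dropped, len(flows))
    return flows.loc[~mask].reset_index(drop=True)


def aggregate_flows(flows: pd.DataFrame, keys: Iterable[str]) -> pd.DataFrame:
    """Sum amounts over records sharing the grouping ``keys``.

    Zero-amount records are discarded here (they carry no flow), so the
    grand total is conserved exactly.  ``keys`` may be any flow columns or
    columns previously merged onto the table (e.g. an actor category).
    """
    keys = list(keys)
    unknown = [k for k in keys if k not in flows.columns]
    if unknown:
        raise KeyError(f"unknown grouping keys {unknown}; "
                       f"available: {list(flows.columns)}")
    nonzero = flows.loc[flows["amount_usd"] > 0]
    if nonzero.empty:
        return pd.DataFrame(columns=keys + ["amount_usd"])
    grouped = (
        nonzero.groupby(keys, as_index=False, sort=True)["amount_usd"].sum()
    )
    return grouped
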