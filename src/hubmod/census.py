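"""Annotation of significant hubs against a Cancer Gene Census table.

The Cancer Gene Census is a curated catalogue of genes causally
implicated in cancer, distributed as a CSV with one gene-symbol row and
columns for mutation types, tumour types, syndromes etc.  The census
file is user-supplied (it is licensed and not bundled); matching is by
exact gene symbol after whitespace trimming, case-sensitive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .data_model import HubTestResult, ParseError

logger = logging.getLogger(__name__)

DEFAULT_SYMBOL_COLUMN = "Symbol"


@dataclass
class CensusRecord:
    symbol: str
    attributes: dict[str, object]


def read_census(path, symbol_column: str = DEFAULT_SYMBOL_COLUMN,
                delimiter: str | None = None) -> list[CensusRecord]:
    """Read a census CSV/TSV keyed by a gene-symbol column.

    The delimiter is inferred from the extension when not given (.tsv ->
    tab, otherwise comma).  All non-symbol columns are carried through
    verbatim as attributes, with "NA"/empty preserved as missing.
    Duplicate symbols keep the first row (warned).
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        table = pd.read_csv(path, sep=delimiter, dtype=str,
                            keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty census file (no header)") from None
    if symbol_column not in table.columns:
        raise ParseError(
            f"{path}: symbol column {symbol_column!r} not found; "
            f"available: {list(table.columns)}")
    records: list[CensusRecord] = []
    seen: set[str] = set()
    other_cols = [c for c in table.columns if c != symbol_column]
    for _, row in table.iterrows():
        symbol = str(row[symbol_column]).strip()
        if not symbol:
            continue
        if symbol in seen:
            logger.warning("duplicate census symbol %r: keeping first row",
                           symbol)
            continue
        seen.add(symbol)
        attrs = {}
        for c in other_cols:
            value = str(row[c]).strip()
            attrs[c] = None if value in ("", "NA") else value
        records.append(CensusRecord(symbol=symbol, attributes=attrs))
    return records


def obtain_cancer_info(results: list[HubTestResult],
                       census: list[CensusRecord],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Census annotation for significant hubs (strictly p < alpha).

    Returns one row per significant hub whose ID matches a census
    symbol: hub, p_value, then every census attribute column; sorted by
    p then hub.  Empty results are legitimate (no significant hub is in
    the census).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    by_symbol = {rec.symbol: rec for rec in census}
    attr_cols: list[str] = []
    for rec in census:
        for c in rec.attributes:
            if c not in attr_cols:
                attr_cols.append(c)
    rows = []
    for r in sorted(results, key=lambda r: (r.p_value, r.hub)):
        if r.p_value >= alpha:
            continue
        rec = by_symbol.get(r.hub.strip())
        if rec is None:
            continue
        row = {"hub": r.hub, "p_value": r.p_value}
        for c in attr_cols:
            row[c] = rec.attributes.get(c)
        rows.append(row)
    return pd.DataFrame(rows, columns=["hub", "p_value"] + attr_cols)
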