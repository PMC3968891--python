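"""Rounding-tolerant comparison of a decoded IDAT against a text export.

Vendor text exports round their numbers; a decoded IDAT carries full
precision.  The comparator therefore classifies each matched (probe,
column) value pair as *exact* (bit-equal after casting the text value to
the IDAT column's storage dtype), *within rounding* (equal once both sides
are rounded half-to-even at a configurable number of decimals) or
*discordant*.  The three counts always partition the compared pairs.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, MalformedInputError
from .model import BinaryIdat, ExpressionIdat, as_table

__all__ = ["ComparisonReport", "compare_to_text_export", "DEFAULT_DECIMALS"]

#: default rounding precision; the vendor's own rule is undocumented
DEFAULT_DECIMALS = 1

_ID_ALIASES = ("probe_id", "id", "probeid", "illumicode", "illumicodeaddress",
               "address_id")


@dataclass
class ComparisonReport:
    """Aggregate outcome of one IDAT-vs-text-export comparison."""

    n_rows_compared: int
    n_exact: int
    n_within_rounding: int
    n_discordant: int
    max_abs_diff: float
    decimals: int
    per_column: dict[str, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_rows_compared": self.n_rows_compared,
            "n_exact": self.n_exact,
            "n_within_rounding": self.n_within_rounding,
            "n_discordant": self.n_discordant,
            "max_abs_diff": self.max_abs_diff,
            "decimals": self.decimals,
            "per_column": self.per_column,
        }


def _load_table(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    if isinstance(table, (str, os.PathLike)):
        return pd.read_csv(Path(table), sep=None, engine="python")
    if isinstance(table, io.IOBase):
        return pd.read_csv(table, sep=None, engine="python")
    raise MalformedInputError(
        f"cannot interpret comparison table of type {type(table).__name__}"
    )


def compare_to_text_export(
    idat: BinaryIdat | ExpressionIdat,
    table,
    decimals: int = DEFAULT_DECIMALS,
) -> ComparisonReport:
    """Compare shared columns of ``idat`` against a delimited text export.

    ``table`` may be a DataFrame, a path or an open text handle; its ID
    column is found by name (``probe_id``, ``id``, ...).  Rows are matched
    by probe ID; only IDs present on both sides are compared.

    Raises
    ------
    EmptyOverlapError
        No probe ID occurs on both sides.
    MalformedInputError
        The table has no recognizable ID column.
    """
    left = as_table(idat)
    right = _load_table(table)
    id_col = None
    for col in right.columns:
        if str(col).strip().lower() in _ID_ALIASES:
            id_col = col
            break
    if id_col is None:
        raise MalformedInputError(
            f"no probe-id column among {list(right.columns)}; "
            f"accepted names: {_ID_ALIASES}"
        )
    right = right.rename(columns={id_col: "probe_id"})
    right.columns = [str(c).strip().lower() for c in right.columns]
    left.columns = [str(c).strip().lower() for c in left.columns]

    shared = [c for c in left.columns if c != "probe_id" and c in right.columns]
    merged = left.merge(
        right[["probe_id"] + shared],
        on="probe_id",
        how="inner",
        suffixes=("_idat", "_txt"),
    )
    if merged.empty or not shared:
        raise EmptyOverlapError(
            "no overlapping probe IDs (or no shared value columns) between "
            "the IDAT and the text export"
        )

    n_exact = n_within = n_discordant = 0
    max_abs_diff = 0.0
    per_column: dict[str, dict[str, int]] = {}
    for col in shared:
        a = merged[f"{col}_idat"] if f"{col}_idat" in merged else merged[col]
        b = merged[f"{col}_txt"] if f"{col}_txt" in merged else merged[col]
        storage_dtype = left[col].dtype
        a = np.asarray(a, dtype=storage_dtype)
        af = a.astype(np.float64)
        bf = np.asarray(b, dtype=np.float64)
        if storage_dtype.kind == "f":
            # the text is a decimal rendering of the stored float: reading
            # it back at storage precision makes a faithful export bit-equal
            exact = a == np.asarray(b, dtype=storage_dtype)
        else:
            exact = af == bf
        within = ~exact & (np.round(af, decimals) == np.round(bf, decimals))
        discordant = ~exact & ~within
        if len(af):
            max_abs_diff = max(max_abs_diff, float(np.max(np.abs(af - bf))))
        counts = {
            "exact": int(exact.sum()),
            "within_rounding": int(within.sum()),
            "discordant": int(discordant.sum()),
        }
        per_column[col] = counts
        n_exact += counts["exact"]
        n_within += counts["within_rounding"]
        n_discordant += counts["discordant"]

    return ComparisonReport(
        n_rows_compared=n_exact + n_within + n_discordant,
        n_exact=n_exact,
        n_within_rounding=n_within,
        n_discordant=n_discordant,
        max_abs_diff=max_abs_diff,
        decimals=decimals,
        per_column=per_column,
    )
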