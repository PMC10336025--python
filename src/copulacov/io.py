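"""Reading, preprocessing, and writing abundance tables.

Tables are samples x taxa with a sample-id column; raw count tables
(integer entries, row sums above 1) are detected automatically and converted
to relative abundances by row normalization. Preprocessing mirrors the usual
microbiome filters: a prevalence threshold on taxa (fraction of samples with
nonzero abundance), removal of unassigned taxa, removal of all-zero samples,
and complete-case deletion on requested covariates. Every drop is logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .margins import _ONE_MINUS

__all__ = ["AbundanceTable", "read_table", "preprocess", "write_table"]


@dataclass
class AbundanceTable:
    """A samples x taxa relative-abundance matrix plus provenance log."""

    data: pd.DataFrame
    log: list = field(default_factory=list)

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def taxa(self) -> list:
        return list(self.data.columns)

    def record(self, message: str) -> None:
        self.log.append(message)


def _looks_like_counts(df: pd.DataFrame) -> bool:
    vals = df.to_numpy(dtype=float)
    integral = np.allclose(vals, np.round(vals))
    return integral and bool((vals.sum(axis=1) > 1.0 + 1e-9).any())


def read_table(path, fmt: Optional[str] = None, orientation: str = "auto") -> AbundanceTable:
    """Read a TSV/CSV abundance table.

    ``orientation``: 'samples-rows', 'taxa-rows', or 'auto' (keeps the file's
    orientation unless rows exceed columns by 5x with numeric-looking row
    ids, a heuristic for transposed exports; override explicitly when in
    doubt). Count tables are row-normalized to relative abundances; values at
    or above 1 - 1e-12 are clamped into [0, 1).
    """
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "tsv"
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    log: list = [f"read {df.shape[0]} x {df.shape[1]} table from {path}"]
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s): {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon label(s): {dupes}")
    if df.isna().any().any():
        raise ValueError("table contains missing values")
    if orientation == "taxa-rows":
        df = df.T
        log.append("transposed to samples-in-rows")
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if _looks_like_counts(df):
        sums = vals.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(sums[:, None] > 0, vals / sums[:, None], 0.0)
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
        log.append("detected integer counts; converted to relative abundances")
    high = df.to_numpy() >= _ONE_MINUS
    if high.any():
        df = df.mask(pd.DataFrame(high, index=df.index, columns=df.columns), _ONE_MINUS)
        log.append(f"clamped {int(high.sum())} value(s) at/above 1 - 1e-12 into [0, 1)")
    return AbundanceTable(data=df, log=log)


def preprocess(table: AbundanceTable, metadata: Optional[pd.DataFrame] = None,
               min_prevalence: float = 0.20, drop_unassigned: bool = False,
               unassigned_labels: Sequence[str] = ("unassigned", "unclassified"),
               complete_case: Optional[Sequence[str]] = None):
    """Standard filtering: unassigned taxa, prevalence, all-zero samples, complete case.

    Prevalence is the fraction of samples with nonzero abundance; taxa
    strictly below ``min_prevalence`` are removed. Returns the filtered
    ``AbundanceTable`` (log extended in place) and the row-aligned metadata
    (or None).
    """
    df = table.data.copy()
    log = table.log

    if drop_unassigned:
        lowered = {lab.lower() for lab in unassigned_labels}
        drop = [t for t in df.columns
                if any(key in str(t).lower() for key in lowered)]
        df = df.drop(columns=drop)
        log.append(f"dropped {len(drop)} unassigned taxa")

    prevalence = (df > 0).mean(axis=0)
    low = prevalence[prevalence < min_prevalence].index.tolist()
    df = df.drop(columns=low)
    log.append(f"dropped {len(low)} taxa below prevalence {min_prevalence:g}")

    zero_rows = df.index[(df.sum(axis=1) == 0)].tolist()
    df = df.drop(index=zero_rows)
    log.append(f"dropped {len(zero_rows)} all-zero samples")

    meta = None
    if metadata is not None:
        meta = pd.DataFrame(metadata).loc[df.index]
        if complete_case:
            before = len(meta)
            meta = meta.dropna(subset=list(complete_case))
            df = df.loc[meta.index]
            log.append(
                f"complete-case deletion on {list(complete_case)}: "
                f"dropped {before - len(meta)} samples"
            )

    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError("preprocessing removed everything; relax the filters")
    out = AbundanceTable(data=df, log=log)
    return out, meta


def write_table(df: pd.DataFrame, path, fmt: Optional[str] = None) -> None:
    """Write a DataFrame as TSV (default) or CSV with full float precision."""
    path = str(path)
    if fmt is None:
        fmt = "csv" if path.endswith(".csv") else "tsv"
    df.to_csv(path, sep="," if fmt == "csv" else "\t", float_format="%.17g")
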