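"""Reading, validating and writing OTU count tables and sample metadata.

The canonical in-memory orientation is OTUs as rows and samples as columns.
Files may be laid out either way; a dialect flag on :func:`read_otu_table`
selects the orientation.  Counts are never rarefied or subsampled anywhere
in the pipeline — normalization is per-sample relative abundance, so deep
and shallow samples keep all of their observed taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METADATA_REQUIRED = ("sample_id", "site")
METADATA_OPTIONAL = ("depth_cm", "mcrA_copies", "rate_ac", "rate_h2co2")

__all__ = [
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "to_relative_abundance",
    "read_metadata",
    "write_metadata",
]


def _first_duplicate(values) -> str | None:
    seen = set()
    for v in values:
        if v in seen:
            return str(v)
        seen.add(v)
    return None


@dataclass
class OtuTable:
    """Validated integer count matrix, OTUs (rows) x samples (columns).

    Invariants enforced at construction:

    * OTU and sample identifiers are unique;
    * all counts are non-negative integers;
    * every sample column has total count >= 1 (a zero-total sample is a
      hard error — relative abundances would be undefined);
    * every OTU row has total count >= 1; all-zero rows are dropped with a
      logged warning rather than rejected, since they are a common artifact
      of subsetting an exported table.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        dup = _first_duplicate(df.index)
        if dup is not None:
            raise ValueError(f"duplicate OTU identifier: {dup!r}")
        dup = _first_duplicate(df.columns)
        if dup is not None:
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        if not np.all(values == np.floor(values)):
            i, j = np.argwhere(values != np.floor(values))[0]
            raise ValueError(
                f"non-integer count at OTU {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        df = df.astype(np.int64)
        empty = df.sum(axis=1) == 0
        if empty.any():
            logger.warning("dropping %d all-zero OTU row(s)", int(empty.sum()))
            df = df.loc[~empty]
        if df.shape[0] == 0:
            raise ValueError("OTU table has no non-empty OTU rows")
        zero_samples = df.sum(axis=0) == 0
        if zero_samples.any():
            bad = df.columns[zero_samples][0]
            raise ValueError(f"sample {bad!r} has zero total count")
        self.counts = df

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _split_header_and_body(text: str) -> tuple[str, list[str]]:
    """Separate the header line from data lines, tolerating leading '#'
    comment lines.  A BIOM-style '#OTU ID...' line is accepted as header."""
    header: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        if header is None:
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").lstrip()
                if "\t" in line and stripped.lower().startswith("otu"):
                    header = stripped
                continue
            header = line
            continue
        if line.strip():
            body.append(line)
    if header is None:
        raise ValueError("no header line found in OTU table")
    return header, body


def read_otu_table(path: str | Path, dialect: str = "otus-as-rows") -> OtuTable:
    """Read a tab-separated OTU count table.

    Parameters
    ----------
    path
        TSV file with one identifier header row and one identifier column.
    dialect
        ``"otus-as-rows"`` (rows are OTUs, columns are samples) or
        ``"samples-as-rows"`` (the transpose).  Both are common amplicon
        exports; in memory the table is always OTUs x samples.
    """
    if dialect not in ("otus-as-rows", "samples-as-rows"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    text = Path(path).read_text(encoding="utf-8")
    header, body = _split_header_and_body(text)
    col_ids = header.split("\t")[1:]
    dup = _first_duplicate(col_ids)
    if dup is not None:
        kind = "sample" if dialect == "otus-as-rows" else "OTU"
        raise ValueError(f"duplicate {kind} identifier in header: {dup!r}")
    df = pd.read_csv(StringIO("\n".join([header] + body)), sep="\t", index_col=0)
    df.columns = col_ids  # undo any pandas dedup-mangling
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if dialect == "samples-as-rows":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    return OtuTable(numeric)


def write_otu_table(
    table: OtuTable, path: str | Path, dialect: str = "otus-as-rows"
) -> None:
    """Write a table as TSV; round-trips exactly through :func:`read_otu_table`."""
    if dialect == "otus-as-rows":
        table.counts.to_csv(path, sep="\t", index_label="otu_id")
    elif dialect == "samples-as-rows":
        table.counts.T.to_csv(path, sep="\t", index_label="sample_id")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def to_relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances X_ij = counts_ij / sample depth.

    Each column of the result sums to 1.  This is the only normalization in
    the pipeline; counts are never subsampled to a common depth.
    """
    depths = table.counts.sum(axis=0)
    if (depths == 0).any():
        bad = depths.index[depths == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return table.counts / depths


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV.

    Required columns: ``sample_id``, ``site``.  Optional columns
    (``depth_cm``, ``mcrA_copies``, ``rate_ac``, ``rate_h2co2``) are parsed
    as floats with missing cells kept as NaN — absent, never zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str})
    for col in METADATA_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    dup = _first_duplicate(df["sample_id"])
    if dup is not None:
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    if df["site"].isna().any() or (df["site"].astype(str).str.strip() == "").any():
        raise ValueError("metadata contains empty site labels")
    for col in METADATA_OPTIONAL:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)
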