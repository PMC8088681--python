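"""Tabular I/O for the mapping pipeline.

Expression tables are tab-separated files of ``identifier<TAB>value`` pairs on
an FPKM-like scale; zero and non-finite values are dropped on ingest because a
zero in these files means "not detected", not "expressed at zero".  Gene
catalogues carry 1-based, fully closed genomic coordinates (NCBI convention);
the BED export dialect converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["symbol", "chromosome", "start", "end"]

#: Natural chromosome sort order: autosomes, sex chromosomes, mitochondrial.
_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing autosomes numerically, then X, Y, MT, then others."""
    c = str(chrom)
    if c in _CHROM_ORDER:
        return (_CHROM_ORDER[c], "")
    if c.isdigit():
        return (int(c), "")
    return (1000, c)


@dataclass
class ExpressionSample:
    """One sample's gene -> expression table with its condition label.

    ``values`` is a float Series indexed by gene identifier (ENSG accession or
    official symbol); all values are strictly positive after ingest.
    Condition "A" is the trisomic pool, "B" the euploid control pool.
    """

    sample_id: str
    condition: Literal["A", "B"]
    values: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.condition not in ("A", "B"):
            raise ValueError(f"condition must be 'A' or 'B', got {self.condition!r}")
        self.values = pd.Series(self.values, dtype=float)
        self.values.index = self.values.index.astype(str)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: pd.Series) -> "ExpressionSample":
        return ExpressionSample(self.sample_id, self.condition, values)


def read_expression_table(
    path: str | Path,
    id_col: str | int | None = None,
    value_col: str | int | None = None,
    *,
    sample_id: str | None = None,
    condition: Literal["A", "B"] = "A",
    duplicate_policy: Literal["mean", "error"] = "mean",
) -> ExpressionSample:
    """Read a tab-separated ``identifier<TAB>FPKM`` table into a sample.

    Zero and non-finite values are excluded; the number of dropped rows is
    logged.  Duplicate identifiers are averaged by default (``duplicate_policy
    = "mean"``) or rejected (``"error"``).  When ``id_col``/``value_col`` are
    None the first two columns are used, with or without a header line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")

    # Sniff for a header: if the second field of the first line parses as a
    # number, the file is headerless.
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"no expression values in {path}")
    fields = first.rstrip("\n").split("\t")
    headerless = False
    if len(fields) >= 2:
        try:
            float(fields[1])
            headerless = True
        except ValueError:
            pass
    df = pd.read_csv(path, sep="\t", header=None if headerless else 0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"expected at least two tab-separated columns in {path}")

    def _col(spec, default_pos):
        if spec is None:
            return df.columns[default_pos]
        if isinstance(spec, int):
            return df.columns[spec]
        if spec not in df.columns:
            raise KeyError(f"column {spec!r} not in {path}: {list(df.columns)}")
        return spec

    ids = df[_col(id_col, 0)].astype(str)
    raw = df[_col(value_col, 1)]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        line = int(bad.idxmax()) + (1 if headerless else 2)
        raise ValueError(f"unparseable expression value at line {line} of {path}: {raw[bad.idxmax()]!r}")

    series = pd.Series(vals.to_numpy(float), index=ids.to_numpy())
    n_before = len(series)
    series = series[np.isfinite(series) & (series > 0)]
    dropped = n_before - len(series)
    if dropped:
        logger.info("%s: dropped %d zero/non-finite rows of %d", path.name, dropped, n_before)
    if series.empty:
        raise ValueError(f"no expression values in {path}")

    if series.index.has_duplicates:
        if duplicate_policy == "error":
            dups = series.index[series.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate identifiers in {path}: {dups[:5]}")
        warnings.warn(f"{path.name}: duplicate identifiers averaged", stacklevel=2)
        series = series.groupby(level=0, sort=False).mean()

    return ExpressionSample(sample_id or path.stem, condition, series)


def read_multi_sample_table(
    path: str | Path,
    conditions: dict[str, Literal["A", "B"]],
    id_col: str | int = 0,
) -> list[ExpressionSample]:
    """Read a wide supplementary-style FPKM table (one column per sample).

    ``conditions`` maps sample column names to their condition labels;
    columns not listed are ignored.  Zero and non-finite values are dropped
    per sample, as in :func:`read_expression_table`.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[id_col] if isinstance(id_col, int) else id_col
    df = df.set_index(df[id_col].astype(str))
    samples = []
    for col, cond in conditions.items():
        if col not in df.columns:
            raise KeyError(f"sample column {col!r} not in {path}")
        vals = pd.to_numeric(df[col], errors="coerce")
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.empty:
            raise ValueError(f"no expression values for sample {col} in {path}")
        samples.append(ExpressionSample(col, cond, vals))
    return samples


def read_idmap(path: str | Path) -> pd.Series:
    """Read a two-column source-identifier -> gene-symbol conversion table.

    Returns a string Series mapping each source identifier to one symbol.
    A source identifier appearing with more than one symbol is an error;
    rows with an empty target symbol are dropped.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"idmap {path} needs two tab-separated columns")
    # Tolerate a header line.
    if df.iloc[0, 0].lower() in {"source", "ensg", "id", "identifier", "gene_id"}:
        df = df.iloc[1:]
    df = df.iloc[:, :2].dropna()
    df = df[df.iloc[:, 1].str.strip() != ""]
    mapping = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())
    dup = mapping.index.duplicated(keep=False)
    if dup.any():
        conflicting = mapping[dup].groupby(level=0).nunique()
        conflicting = conflicting[conflicting > 1]
        if len(conflicting):
            raise ValueError(f"identifiers mapped to multiple symbols: {conflicting.index.tolist()[:5]}")
        mapping = mapping[~mapping.index.duplicated()]
    if mapping.empty:
        raise ValueError(f"empty idmap: {path}")
    return mapping


def collapse_to_symbols(
    sample: ExpressionSample,
    idmap: pd.Series,
    unmapped: Literal["keep", "drop"] = "keep",
) -> ExpressionSample:
    """Re-key a sample from source identifiers to official gene symbols.

    Several source identifiers mapping to one symbol are averaged.  Unmapped
    identifiers are retained under their source identifier by default (so the
    map's locus count is not silently reduced) or dropped.  Pseudogenes are
    deliberately not removed: RNA-seq distinguishes genes from their
    pseudogenes, so pseudogene loci are kept as ordinary loci.
    """
    if idmap is None or len(idmap) == 0:
        raise ValueError("empty identifier map")
    mapped = sample.values.index.to_series().map(idmap)
    if unmapped == "drop":
        keep = mapped.notna()
        values = sample.values[keep.to_numpy()]
        keys = mapped[keep].to_numpy()
    else:
        keys = mapped.fillna(pd.Series(sample.values.index, index=sample.values.index)).to_numpy()
        values = sample.values
    if len(values) == 0:
        raise ValueError("no loci left after identifier collapse")
    collapsed = pd.Series(values.to_numpy(), index=keys).groupby(level=0, sort=False).mean()
    return sample.with_values(collapsed)


def read_gene_catalog(path: str | Path) -> pd.DataFrame:
    """Read a TSV gene catalogue (symbol, chromosome, start, end).

    Coordinates are 1-based fully closed.  Records are sorted by
    (chromosome, start); duplicate symbols and inverted intervals are
    rejected.  "MT" is an ordinary chromosome.
    """
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chromosome": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene catalogue {path} lacks columns {missing}")
    df = df[CATALOG_COLUMNS].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return validate_catalog(df)


def validate_catalog(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a catalogue DataFrame."""
    if (df["start"] < 1).any():
        bad = df.loc[df["start"] < 1, "symbol"].iloc[0]
        raise ValueError(f"start < 1 for gene {bad}")
    inverted = df["end"] < df["start"]
    if inverted.any():
        bad = df.loc[inverted, "symbol"].iloc[0]
        raise ValueError(f"end < start for gene {bad}")
    if df["symbol"].duplicated().any():
        bad = df.loc[df["symbol"].duplicated(), "symbol"].iloc[0]
        raise ValueError(f"duplicate symbol in catalogue: {bad}")
    key = df["chromosome"].map(chromosome_sort_key)
    df = df.assign(_key=key).sort_values(["_key", "start"]).drop(columns="_key")
    return df.reset_index(drop=True)


_PRECISION = {
    "ratio": 2,
    "mean_value": 4,
    "value_A": 4,
    "value_B": 4,
    "score": 4,
    "sd": 4,
    "sd_A": 4,
    "sd_B": 4,
    "percentile": 2,
}


def write_map_table(
    table: pd.DataFrame,
    path: str | Path,
    dialect: Literal["tsv", "bed"] = "tsv",
) -> Path:
    """Write a pooled map, differential map or segment list as TSV.

    Columns keep a stable order; ratios are written with 2 decimals (the
    reporting convention of the maps), other values with 4.  The ``bed``
    dialect emits 0-based half-open ``chrom  start-1  end`` coordinates plus
    a name/score column where available.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty map")
    path = Path(path)
    out = table.copy()

    if dialect == "bed":
        if not {"chromosome", "start", "end"}.issubset(out.columns):
            raise ValueError("BED export needs chromosome/start/end columns")
        bed = pd.DataFrame(
            {
                "chrom": out["chromosome"],
                "start": out["start"].astype(np.int64) - 1,
                "end": out["end"].astype(np.int64),
                "name": out.get("symbol", out.get("call", pd.Series(["."] * len(out)))),
                "score": out.get("score", out.get("ratio", pd.Series([0.0] * len(out)))),
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False, float_format="%.4f")
        return path

    lead = [c for c in ("symbol", "chromosome", "start", "end") if c in out.columns]
    rest = [c for c in out.columns if c not in lead]
    out = out[lead + rest]
    for col, prec in _PRECISION.items():
        if col in out.columns:
            out[col] = out[col].map(lambda v, p=prec: "" if pd.isna(v) else f"{v:.{p}f}")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_map_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV map written by :func:`write_map_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chromosome": str})
    if df.empty:
        raise ValueError(f"empty map table: {path}")
    return df
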