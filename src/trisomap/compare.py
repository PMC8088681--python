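"""Map-vs-map and sample-vs-sample comparison statistics.

Two transcriptome maps are compared on their shared genes after an optional
log10 transform, by Spearman rank correlation by default -- absolute FPKM
scales from different platforms rarely agree linearly, while the rank
structure of expression is well conserved.  Sample-level quality control is
a symmetric matrix of pairwise Spearman correlations on log10 values over
pairwise-complete identifiers.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io_ingest import ExpressionSample


def correlate_maps(
    map1: pd.DataFrame,
    map2: pd.DataFrame,
    method: Literal["spearman", "pearson"] = "spearman",
    transform: Literal["log10", "none"] = "log10",
    value_col: str | None = None,
) -> dict:
    """Correlate two maps on the genes they share.

    ``value_col`` defaults to ``ratio`` if present in both maps, else
    ``mean_value``.  Returns gene counts (total, unique, common) and the
    correlation with a two-sided p.
    """
    if value_col is None:
        value_col = "ratio" if "ratio" in map1.columns and "ratio" in map2.columns else "mean_value"
    s1 = map1.set_index("symbol")[value_col]
    s2 = map2.set_index("symbol")[value_col]
    common = s1.index.intersection(s2.index)
    if len(common) == 0:
        raise ValueError("no genes in common between the maps")
    x, y = s1.loc[common].to_numpy(float), s2.loc[common].to_numpy(float)
    if transform == "log10":
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log10 transform requires strictly positive values")
        x, y = np.log10(x), np.log10(y)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "n_first": int(len(s1)),
        "n_second": int(len(s2)),
        "unique_first": int(len(s1) - len(common)),
        "unique_second": int(len(s2) - len(common)),
        "common": int(len(common)),
        "r": float(r),
        "p": float(p),
        "method": method,
        "transform": transform,
    }


def sample_correlation_matrix(
    samples: list[ExpressionSample],
    method: Literal["spearman", "pearson"] = "spearman",
    transform: Literal["log10", "none"] = "log10",
) -> pd.DataFrame:
    """Pairwise correlation matrix of samples on log10 values.

    Each pair is correlated over its pairwise-complete identifiers (loci
    detected in both samples); the matrix is symmetric with unit diagonal.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    ids = [s.sample_id for s in samples]
    wide = pd.concat([s.values.rename(s.sample_id) for s in samples], axis=1)
    if transform == "log10":
        wide = np.log10(wide)
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            sub = wide.iloc[:, [i, j]].dropna()
            if method == "spearman":
                r, _ = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            else:
                r, _ = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat
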