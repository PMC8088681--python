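"""Differential (trisomic / control) transcriptome map and its summaries.

The differential map carries, for every gene present in both pooled
condition maps, the ratio of pooled means A/B, together with per-pool SDs
and sample counts and a ``supported`` flag marking genes detected in at
least two samples of each pool (half of a 4-sample pool).  Genome-wide
dosage structure is summarised by ratio bins, per-chromosome means, a
Kruskal-Wallis omnibus test across chromosomes and Games-Howell post hoc
contrasts (Welch-corrected pairwise comparisons referred to the studentized
range distribution, appropriate for unequal group sizes and variances).
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_ingest import chromosome_sort_key

logger = logging.getLogger(__name__)

#: Default ratio-bin thresholds, strictly decreasing.  The bins are
#: (1.70, inf), [1.30, 1.70], [0.77, 1.30), [0.58, 0.77), (0, 0.58),
#: applied to unrounded ratios; 1.30 and 0.76 are the over-/under-expression
#: calling thresholds used throughout.
DEFAULT_BIN_BOUNDARIES = (1.70, 1.30, 0.77, 0.58)

OVER_THRESHOLD = 1.30
UNDER_THRESHOLD = 0.76


def build_differential_map(map_a: pd.DataFrame, map_b: pd.DataFrame) -> pd.DataFrame:
    """Join two pooled condition maps into a per-gene ratio map.

    Only the intersection of the two gene sets is kept (a ratio needs a
    value in both pools); the count of genes private to either map is
    logged.  Coordinates are taken from map A, falling back to map B.
    """
    a = map_a.set_index("symbol")
    b = map_b.set_index("symbol")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("the two maps share no genes")
    only_a, only_b = len(a.index.difference(b.index)), len(b.index.difference(a.index))
    if only_a or only_b:
        logger.info("differential map: %d genes only in A, %d only in B excluded", only_a, only_b)

    a, b = a.loc[common], b.loc[common]
    coords = a[["chromosome", "start", "end"]].copy()
    for col in coords:
        coords[col] = coords[col].where(coords[col].notna(), b[col])
    dm = pd.DataFrame(
        {
            "symbol": common.astype(str),
            "chromosome": coords["chromosome"].to_numpy(),
            "start": coords["start"].to_numpy(),
            "end": coords["end"].to_numpy(),
            "value_A": a["mean_value"].to_numpy(),
            "value_B": b["mean_value"].to_numpy(),
            "ratio": (a["mean_value"] / b["mean_value"]).to_numpy(),
            "sd_A": a["sd"].to_numpy(),
            "sd_B": b["sd"].to_numpy(),
            "n_A": a["n_samples"].to_numpy(),
            "n_B": b["n_samples"].to_numpy(),
        }
    )
    dm["supported"] = (dm["n_A"] >= 2) & (dm["n_B"] >= 2)
    key = dm["chromosome"].map(lambda c: chromosome_sort_key(c) if pd.notna(c) else (9999, ""))
    dm = dm.assign(_key=key).sort_values(["_key", "start"]).drop(columns="_key")
    return dm.reset_index(drop=True)


def bin_ratios(
    dm: pd.DataFrame,
    boundaries: tuple[float, ...] = DEFAULT_BIN_BOUNDARIES,
) -> pd.DataFrame:
    """Count genes per ratio bin, in total and per chromosome.

    With the default boundaries (t1, t2, t3, t4) = (1.70, 1.30, 0.77, 0.58)
    the bins are ``> t1``, ``[t2, t1]``, ``[t3, t2)``, ``[t4, t3)`` and
    ``< t4``, evaluated on unrounded ratios.  Returns a DataFrame indexed by
    bin label with one column per chromosome plus ``total``; counts sum to
    the map size.
    """
    t = tuple(boundaries)
    if list(t) != sorted(t, reverse=True) or len(set(t)) != len(t):
        raise ValueError(f"boundaries must be strictly decreasing: {t}")
    t1, t2, t3, t4 = t
    r = dm["ratio"].to_numpy()
    labels = [f">{t1:.2f}", f"{t2:.2f}-{t1:.2f}", f"{t3:.2f}-{t2:.2f}", f"{t4:.2f}-{t3:.2f}", f"<{t4:.2f}"]
    conds = [r > t1, (r >= t2) & (r <= t1), (r >= t3) & (r < t2), (r >= t4) & (r < t3), r < t4]
    binned = pd.Series(np.select(conds, labels, default=""), index=dm.index, name="bin")
    chrom = dm["chromosome"].fillna("unplaced")
    table = pd.crosstab(binned, chrom)
    table = table.reindex(index=labels, fill_value=0)
    table = table[sorted(table.columns, key=chromosome_sort_key)]
    table["total"] = table.sum(axis=1)
    assert int(table["total"].sum()) == len(dm)
    return table


def chromosome_summary(dm: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean and sample SD (n-1) of ratios per chromosome."""
    if dm.empty:
        raise ValueError("empty differential map")
    g = dm.dropna(subset=["chromosome"]).groupby("chromosome")["ratio"]
    out = pd.DataFrame({"mean_ratio": g.mean(), "sd": g.std(ddof=1), "n_genes": g.size()})
    out = out.loc[sorted(out.index, key=chromosome_sort_key)]
    out.index.name = "chromosome"
    return out


def games_howell(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Games-Howell pairwise contrasts between groups of values.

    For each pair, the Welch-corrected mean difference is referred to the
    studentized range distribution with ``k`` (the total number of groups)
    and Welch-Satterthwaite degrees of freedom:

        q = |m_i - m_j| / sqrt((s_i^2/n_i + s_j^2/n_j) / 2),
        p = P(Q_{k, df} >= q).

    Groups with fewer than two values are skipped with a warning.  Returns a
    tidy DataFrame (group1, group2, mean_diff, se, df, q, p); the implied
    matrix is symmetric.
    """
    usable = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has <2 values; its pairs are skipped", stacklevel=2)
            continue
        usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least two groups with >=2 values")
    k = len(usable)
    rows = []
    for (n1, v1), (n2, v2) in itertools.combinations(usable.items(), 2):
        m1, m2 = v1.mean(), v2.mean()
        var1, var2 = v1.var(ddof=1), v2.var(ddof=1)
        a, b = var1 / len(v1), var2 / len(v2)
        se2 = a + b
        if se2 == 0:
            rows.append({"group1": n1, "group2": n2, "mean_diff": m1 - m2, "se": 0.0,
                         "df": np.inf, "q": 0.0 if m1 == m2 else np.inf,
                         "p": 1.0 if m1 == m2 else 0.0})
            continue
        df = se2**2 / (a**2 / (len(v1) - 1) + b**2 / (len(v2) - 1))
        q = abs(m1 - m2) / np.sqrt(se2 / 2.0)
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group1": n1, "group2": n2, "mean_diff": m1 - m2,
                     "se": np.sqrt(se2 / 2.0), "df": df, "q": q, "p": min(1.0, p)})
    return pd.DataFrame(rows)


def compare_chromosome_ratios(dm: pd.DataFrame) -> dict:
    """Omnibus and post hoc comparison of ratio distributions across chromosomes.

    Kruskal-Wallis (tie-corrected, as implemented in scipy) on the ratio
    values grouped by chromosome, followed by Games-Howell pairwise
    contrasts.  Returns ``{"H", "p", "pairwise"}``.
    """
    grouped = {
        str(c): sub["ratio"].to_numpy()
        for c, sub in dm.dropna(subset=["chromosome"]).groupby("chromosome")
    }
    big = [v for v in grouped.values() if len(v) >= 2]
    if len(big) < 2:
        raise ValueError("need at least two chromosomes with >=2 genes")
    h_stat, p = stats.kruskal(*big)
    pairwise = games_howell(grouped)
    return {"H": float(h_stat), "p": float(p), "pairwise": pairwise}


def gene_set_summary(
    dm: pd.DataFrame,
    symbols: list[str],
    over_threshold: float = OVER_THRESHOLD,
    under_threshold: float = UNDER_THRESHOLD,
) -> dict:
    """Summarise a named gene set's ratios (supported records only).

    Returns n_found, mean/sd of ratios, the over- and under-expressed counts
    at the calling thresholds, the symbols absent from the map, and those
    present but excluded for lacking support.
    """
    if not symbols:
        raise ValueError("empty symbol list")
    sub = dm[dm["symbol"].isin(symbols) & dm["supported"]]
    missing = sorted(set(symbols) - set(dm["symbol"]))
    unsupported = sorted(set(symbols) - set(sub["symbol"]) - set(missing))
    if sub.empty:
        raise ValueError("no requested symbol found among supported map records")
    r = sub["ratio"]
    return {
        "n_found": int(len(sub)),
        "mean_ratio": float(r.mean()),
        "sd": float(r.std(ddof=1)) if len(sub) > 1 else 0.0,
        "n_over": int((r >= over_threshold).sum()),
        "n_under": int((r <= under_threshold).sum()),
        "missing": missing,
        "unsupported": unsupported,
    }
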