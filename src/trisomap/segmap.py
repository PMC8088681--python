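"""Sliding-window segment analysis of a transcriptome map.

The genome is tiled per chromosome with fixed windows (default 500 kb,
shifted by 250 kb, anchored at base 1, so starts are 1, 250,001,
500,001, ...).  Each window is scored by the mean value (expression or
ratio) of its member loci -- a locus belongs to every window containing its
midpoint and contributes only if its pooled value rests on enough biological
samples.  Over-/under-expression of a window is then tested by the
hypergeometric tail: with N contributing loci genome-wide of which K are
flagged (ratio beyond the calling threshold, or in the extreme quantile for
single-condition maps), a window holding n loci with k flagged has

    p_over = P(X >= k),  X ~ Hypergeom(N, K, n)

and analogously for the under direction against the under-flagged set.
Per direction, p values are Benjamini-Hochberg adjusted over all tested
windows (configurable to raw p); windows with q < alpha are called.
Overlapping same-direction calls are pruned to the extreme-scoring window.
A 12.5 kb window mode attributes window calls to single genes when the
called gene's value prevails over every other gene in the window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .diffmap import OVER_THRESHOLD, UNDER_THRESHOLD
from .io_ingest import chromosome_sort_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentConfig:
    """Parameters of the segment analysis.

    flag_mode "ratio" flags loci beyond fixed ratio thresholds (differential
    maps); "quantile" flags the top/bottom ``quantile_fraction`` of values
    (single-condition maps, where no natural threshold exists); "auto" picks
    by map type.  ``adjust`` selects BH-adjusted q values (default) or raw
    hypergeometric p.
    """

    window: int = 500_000
    shift: int = 250_000
    min_samples: int = 2
    flag_mode: Literal["auto", "ratio", "quantile"] = "auto"
    over_threshold: float = OVER_THRESHOLD
    under_threshold: float = UNDER_THRESHOLD
    quantile_fraction: float = 0.025
    alpha: float = 0.05
    adjust: Literal["bh", "none"] = "bh"

    def __post_init__(self) -> None:
        if self.shift > self.window or self.shift <= 0:
            raise ValueError("require 0 < shift <= window")
        if not (0 < self.quantile_fraction < 0.5):
            raise ValueError("quantile_fraction must be in (0, 0.5)")


def hypergeometric_tail(k: int, n_total: int, n_flagged: int, n_drawn: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N=n_total, K=n_flagged, n=n_drawn)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, n_total, n_flagged, n_drawn))


def _is_differential(gene_map: pd.DataFrame) -> bool:
    return "ratio" in gene_map.columns


def _value_column(gene_map: pd.DataFrame) -> str:
    return "ratio" if _is_differential(gene_map) else "mean_value"


def contributing_loci(gene_map: pd.DataFrame, config: SegmentConfig) -> pd.DataFrame:
    """Loci with coordinates whose value rests on >= min_samples samples.

    For a differential map the support requirement applies to both pools.
    """
    m = gene_map.dropna(subset=["chromosome", "start", "end"])
    if _is_differential(m):
        ok = (m["n_A"] >= config.min_samples) & (m["n_B"] >= config.min_samples)
    else:
        ok = m["n_samples"] >= config.min_samples
    return m[ok]


def tile_genome(catalog: pd.DataFrame, config: SegmentConfig) -> pd.DataFrame:
    """Tile each chromosome with windows anchored at base 1.

    Window starts are 1 + i*shift while start <= chromosome extent (the
    largest gene end); the terminal window may extend past the last gene.
    """
    rows = []
    for chrom, sub in catalog.groupby("chromosome"):
        extent = int(sub["end"].max())
        n_windows = max(1, math.ceil(extent / config.shift))
        for i in range(n_windows):
            start = 1 + i * config.shift
            if start > extent:
                break
            rows.append((str(chrom), start, start + config.window - 1))
    seg = pd.DataFrame(rows, columns=["chromosome", "start", "end"])
    key = seg["chromosome"].map(chromosome_sort_key)
    seg = seg.assign(_key=key).sort_values(["_key", "start"]).drop(columns="_key")
    return seg.reset_index(drop=True)


def assign_genes(segments: pd.DataFrame, gene_map: pd.DataFrame, config: SegmentConfig) -> pd.DataFrame:
    """Attach member loci and scores to tiled windows.

    A gene belongs to every window containing its midpoint
    ``(start + end) // 2``; the window score is the arithmetic mean of the
    contributing loci's values, or null for windows with none.
    """
    value_col = _value_column(gene_map)
    loci = contributing_loci(gene_map, config)
    seg = segments.copy().reset_index(drop=True)
    members: list[list[str]] = [[] for _ in range(len(seg))]
    values: list[list[float]] = [[] for _ in range(len(seg))]

    # Windows are on a regular grid per chromosome; locate each gene's
    # covering windows arithmetically instead of interval-joining.
    seg_index: dict[tuple[str, int], int] = {
        (row.chromosome, row.start): i for i, row in enumerate(seg.itertuples(index=False))
    }
    n_offsets = math.ceil(config.window / config.shift)
    for row in loci.itertuples(index=False):
        chrom = str(row.chromosome)
        mid = (int(row.start) + int(row.end)) // 2
        i_hi = (mid - 1) // config.shift
        for off in range(n_offsets):
            i = i_hi - off
            if i < 0:
                break
            w_start = 1 + i * config.shift
            if w_start <= mid <= w_start + config.window - 1:
                j = seg_index.get((chrom, w_start))
                if j is not None:
                    members[j].append(row.symbol)
                    values[j].append(float(getattr(row, value_col)))

    seg["genes"] = members
    seg["n_genes"] = [len(m) for m in members]
    seg["score"] = [float(np.mean(v)) if v else np.nan for v in values]
    seg["values"] = values
    return seg


def _flagged_sets(loci: pd.DataFrame, config: SegmentConfig) -> tuple[set[str], set[str]]:
    value_col = _value_column(loci)
    mode = config.flag_mode
    if mode == "auto":
        mode = "ratio" if _is_differential(loci) else "quantile"
    v = loci[value_col]
    if mode == "ratio":
        over = set(loci.loc[v >= config.over_threshold, "symbol"])
        under = set(loci.loc[v <= config.under_threshold, "symbol"])
    else:
        hi = v.quantile(1 - config.quantile_fraction)
        lo = v.quantile(config.quantile_fraction)
        over = set(loci.loc[v >= hi, "symbol"])
        under = set(loci.loc[v <= lo, "symbol"])
    return over, under


def test_segments(segments: pd.DataFrame, gene_map: pd.DataFrame, config: SegmentConfig) -> pd.DataFrame:
    """Hypergeometric enrichment test of scored windows, both directions.

    Adds k_over/k_under, p_over/p_under, q_over/q_under and ``call``
    (over/under/none).  Windows with no contributing loci are untested.
    """
    loci = contributing_loci(gene_map, config)
    n_total = len(loci)
    if n_total == 0:
        raise ValueError("no contributing loci for segment testing")
    over_set, under_set = _flagged_sets(loci, config)
    seg = segments.copy()
    tested = seg["score"].notna()

    for direction, flagged in (("over", over_set), ("under", under_set)):
        k = seg["genes"].map(lambda g: sum(s in flagged for s in g))
        p = np.full(len(seg), np.nan)
        for i in np.flatnonzero(tested.to_numpy()):
            p[i] = hypergeometric_tail(int(k.iloc[i]), n_total, len(flagged), int(seg["n_genes"].iloc[i]))
        q = np.full(len(seg), np.nan)
        if tested.any():
            if config.adjust == "bh":
                q[tested.to_numpy()] = multipletests(p[tested.to_numpy()], method="fdr_bh")[1]
            else:
                q[tested.to_numpy()] = p[tested.to_numpy()]
        seg[f"k_{direction}"] = k
        seg[f"p_{direction}"] = p
        seg[f"q_{direction}"] = q

    call = np.where(
        tested & (seg["q_over"] < config.alpha) & ~(seg["q_under"] < seg["q_over"]), "over",
        np.where(tested & (seg["q_under"] < config.alpha), "under", "none"),
    )
    seg["call"] = call
    return seg


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 <= e2 and s2 <= e1


def prune_overlapping(segments: pd.DataFrame) -> pd.DataFrame:
    """Reduce called windows to a non-redundant list.

    Mutually overlapping windows with the same call collapse to the one with
    the extreme score (highest for over, lowest for under); output is sorted
    by decreasing score.
    """
    called = segments[segments["call"].isin(["over", "under"])].copy()
    if called.empty:
        return called
    keep_rows = []
    for (chrom, call), sub in called.groupby(["chromosome", "call"]):
        sub = sub.sort_values("start")
        # Chain transitively overlapping windows.
        chains: list[list[int]] = []
        chain_end = -1
        for idx, row in sub.iterrows():
            if chains and row["start"] <= chain_end:
                chains[-1].append(idx)
                chain_end = max(chain_end, int(row["end"]))
            else:
                chains.append([idx])
                chain_end = int(row["end"])
        for chain in chains:
            block = sub.loc[chain]
            winner = block["score"].idxmax() if call == "over" else block["score"].idxmin()
            keep_rows.append(winner)
    out = called.loc[keep_rows].sort_values("score", ascending=False)
    return out.reset_index(drop=True)


def analyze_segments(gene_map: pd.DataFrame, catalog: pd.DataFrame | None = None,
                     config: SegmentConfig = SegmentConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tile, score, test and prune in one call.

    ``catalog`` defaults to the map's own coordinates.  Returns
    ``(all windows with statistics, pruned significant windows)``.
    """
    if catalog is None:
        catalog = gene_map.dropna(subset=["chromosome", "start", "end"])
    seg = tile_genome(catalog, config)
    seg = assign_genes(seg, gene_map, config)
    seg = test_segments(seg, gene_map, config)
    return seg, prune_overlapping(seg)


def single_gene_mode(
    gene_map: pd.DataFrame,
    config: SegmentConfig | None = None,
    adjust: Literal["bh", "none"] = "none",
) -> pd.DataFrame:
    """Attribute significance to single genes via 12.5 kb windows.

    Windows are tiled with window = shift = 12,500 bp (about a quarter of a
    typical gene length, so most windows hold one gene).  A called window
    attributes its call to a member gene only if that gene's value strictly
    prevails -- exceeds every other member value for over calls, or is below
    every other for under calls; ties attribute nothing (logged).
    Returns a DataFrame of per-gene calls (symbol, call, q, window start/end).

    Significance defaults to the raw hypergeometric tail: singleton windows
    all share the identical p = K/N, so a rank-based step-up adjustment
    degenerates (every flagged singleton gets q ~ m/N) and would never call
    anything in this mode.
    """
    base = config or SegmentConfig()
    cfg = replace(base, window=12_500, shift=12_500, adjust=adjust)
    seg, _ = analyze_segments(gene_map, config=cfg)
    rows = []
    for row in seg[seg["call"] != "none"].itertuples(index=False):
        vals = np.asarray(row.values, float)
        if len(vals) == 0:
            continue
        if row.call == "over":
            j = int(np.argmax(vals))
            prevails = (vals[j] > np.delete(vals, j)).all() if len(vals) > 1 else True
        else:
            j = int(np.argmin(vals))
            prevails = (vals[j] < np.delete(vals, j)).all() if len(vals) > 1 else True
        if not prevails:
            logger.info("window %s:%d-%d: tied extreme values, no gene attribution",
                        row.chromosome, row.start, row.end)
            continue
        q = row.q_over if row.call == "over" else row.q_under
        rows.append({"symbol": row.genes[j], "chromosome": row.chromosome,
                     "call": row.call, "q": q, "window_start": row.start, "window_end": row.end})
    out = pd.DataFrame(rows, columns=["symbol", "chromosome", "call", "q", "window_start", "window_end"])
    # A gene can sit in one 12.5 kb window only (window == shift).
    return out.reset_index(drop=True)
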