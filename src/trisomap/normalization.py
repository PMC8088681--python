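"""Intra- and inter-sample normalisation and condition-level pooling.

Two normalisations are applied, in this order:

1. *Global* (intra-sample): each sample is rescaled by one multiplicative
   factor so that its mean equals the grand mean of the per-sample means.
   Within-sample ratios are untouched.  Applied jointly across both
   condition pools to put all samples on one scale.
2. *Scaled quantile* (inter-sample): a reference distribution is the mean of
   the samples' empirical quantile functions, evaluated on a common grid of
   quantile fractions; each value is replaced by the reference value at its
   within-sample quantile fraction.  Samples with unequal locus counts are
   handled by linear interpolation of the quantile functions (the "scaled"
   part); tied values share the averaged reference value.  Applied within
   each condition pool (see :func:`normalize_samples`).

Pooling then summarises each condition per gene as the mean over the samples
in which the gene is *present* (absence is missingness, not zero), together
with the across-sample SD, the sample count, and the percentile of the pooled
mean within the whole map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_ingest import CATALOG_COLUMNS, ExpressionSample


def _quantile_fractions(n: int) -> np.ndarray:
    """Plotting positions (rank - 0.5)/n for a sample of size n."""
    return (np.arange(1, n + 1) - 0.5) / n


def global_normalize(samples: list[ExpressionSample]) -> list[ExpressionSample]:
    """Rescale every sample so its mean equals the grand mean of sample means.

    One multiplicative factor per sample; idempotent.
    """
    if not samples:
        raise ValueError("no samples")
    for s in samples:
        if len(s) == 0:
            raise ValueError(f"sample {s.sample_id} has no values")
    means = np.array([s.values.mean() for s in samples])
    grand = means.mean()
    return [s.with_values(s.values * (grand / m)) for s, m in zip(samples, means)]


def scaled_quantile_normalize(samples: list[ExpressionSample]) -> list[ExpressionSample]:
    """Quantile-normalise samples against their averaged quantile function.

    With equal locus counts this reduces to ordinary quantile normalisation
    (identical sorted vectors afterwards).  With unequal counts each sample's
    quantile function is linearly interpolated onto a grid of
    ``max(n_i)`` fractions before averaging.
    """
    if len(samples) < 2:
        raise ValueError("scaled quantile normalisation needs at least 2 samples")
    sizes = [len(s) for s in samples]
    if min(sizes) == 0:
        raise ValueError("sample with no values")
    grid = _quantile_fractions(max(sizes))
    # Reference: mean across samples of the interpolated quantile functions.
    ref = np.zeros_like(grid)
    for s in samples:
        v = np.sort(s.values.to_numpy())
        ref += np.interp(grid, _quantile_fractions(len(v)), v)
    ref /= len(samples)

    out = []
    for s in samples:
        v = s.values.to_numpy()
        frac = (rankdata(v, method="average") - 0.5) / len(v)
        new = np.interp(frac, grid, ref)
        out.append(s.with_values(pd.Series(new, index=s.values.index)))
    return out


def normalize_samples(samples: list[ExpressionSample]) -> list[ExpressionSample]:
    """Global normalisation over all samples, then per-condition quantile normalisation.

    The global step runs jointly across both conditions, putting every sample
    on one scale so that A/B ratios are meaningful.  The quantile step runs
    within each condition pool: normalising the two conditions against a
    shared reference would force identical marginal distributions on A and B
    and thereby bias the between-condition dosage ratios the differential
    map measures.
    """
    samples = global_normalize(samples)
    out = []
    for cond in sorted({s.condition for s in samples}):
        group = [s for s in samples if s.condition == cond]
        if len(group) >= 2:
            group = scaled_quantile_normalize(group)
        out.extend(group)
    return out


def build_pool_map(
    samples: list[ExpressionSample],
    catalog: pd.DataFrame | None = None,
    min_samples: int = 1,
) -> pd.DataFrame:
    """Pool one condition's samples into a quantitative transcriptome map.

    Returns a DataFrame with columns ``symbol, chromosome, start, end,
    mean_value, sd, n_samples, percentile``.  A gene's mean/SD/count run over
    the samples where the gene is present; genes seen in fewer than
    ``min_samples`` samples are dropped.  The percentile is the percentile
    rank (0-100] of the pooled mean within the map.  Genes absent from the
    catalogue keep null coordinates (they are excluded from segment analysis
    downstream but remain in the map).
    """
    if not samples:
        raise ValueError("no samples to pool")
    conditions = {s.condition for s in samples}
    if len(conditions) != 1:
        raise ValueError(f"samples from mixed conditions: {sorted(conditions)}")
    wide = pd.concat([s.values.rename(s.sample_id) for s in samples], axis=1)
    n = wide.notna().sum(axis=1)
    keep = n >= min_samples
    if not keep.any():
        raise ValueError(f"no gene present in at least min_samples={min_samples} samples")
    wide = wide[keep]
    n = n[keep]
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)  # NaN where n == 1

    pool = pd.DataFrame(
        {
            "symbol": wide.index.astype(str),
            "mean_value": mean.to_numpy(),
            "sd": sd.to_numpy(),
            "n_samples": n.to_numpy(),
        }
    )
    pool["percentile"] = rankdata(pool["mean_value"], method="average") / len(pool) * 100.0

    if catalog is not None:
        pool = pool.merge(catalog[CATALOG_COLUMNS], on="symbol", how="left")
    else:
        pool["chromosome"] = pd.NA
        pool["start"] = np.nan
        pool["end"] = np.nan
    pool = pool[["symbol", "chromosome", "start", "end", "mean_value", "sd", "n_samples", "percentile"]]
    pool.attrs["condition"] = samples[0].condition
    return pool.reset_index(drop=True)
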