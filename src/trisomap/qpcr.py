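"""RT-qPCR relative quantification and validation of map ratios.

Relative expression of a target gene against a reference gene uses the
quantification-cycle (Cq) difference: 2^-(Cq_target - Cq_reference), the
2^-dCt method.  Between two conditions the Livak 2^-ddCt fold change is the
ratio of the two relative expressions.  Group means are computed after
removing *strong* outliers -- values beyond 3 x IQR from the Tukey hinges,
the extreme-value (asterisk) rule of SPSS Explore boxplots.  Validation of
the transcriptome map is the bivariate correlation between map-derived
ratios and qPCR-derived ratios over a gene panel.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

#: Columns of a qPCR plate table.
PLATE_COLUMNS = ["subject_id", "group", "gene", "cq_mean", "reference_gene", "reference_cq_mean"]


def relative_expression(cq_target: float, cq_reference: float) -> float:
    """2^-dCt relative expression of a target vs a reference gene."""
    return float(2.0 ** -(np.asarray(cq_target, float) - np.asarray(cq_reference, float)))


def livak_ratio(cq_target_a: float, cq_ref_a: float, cq_target_b: float, cq_ref_b: float) -> float:
    """Livak 2^-ddCt fold change of condition A over condition B."""
    ddct = (cq_target_a - cq_ref_a) - (cq_target_b - cq_ref_b)
    return float(2.0 ** -ddct)


def tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Lower and upper hinges (Tukey's method, as in SPSS Explore).

    The hinges are the medians of the lower and upper halves of the sorted
    data, each half including the overall median when n is odd.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)
    half = (n + 1) // 2
    return float(np.median(v[:half])), float(np.median(v[n - half:]))


def detect_strong_outliers(values, factor: float = 3.0) -> dict:
    """Flag extreme values beyond ``factor`` x IQR from the Tukey hinges.

    With the default factor 3 this is the "strong" (asterisk) outlier rule.
    Values strictly outside [Q1 - 3*IQR, Q3 + 3*IQR] are flagged.  Returns
    ``{"indices", "lower_fence", "upper_fence", "q1", "q3"}``; requires at
    least 4 values for stable quartiles.
    """
    v = np.asarray(values, float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for outlier detection")
    q1, q3 = tukey_hinges(v)
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    idx = np.flatnonzero((v < lo) | (v > hi))
    return {"indices": idx.tolist(), "lower_fence": lo, "upper_fence": hi, "q1": q1, "q3": q3}


def group_expression_ratio(measurements: pd.DataFrame, remove_outliers: bool = True) -> dict:
    """DS/N expression ratio for one gene from per-subject qPCR measurements.

    ``measurements`` holds one row per subject with columns subject_id,
    group ("DS"/"N"), cq_mean and reference_cq_mean.  Per subject the
    2^-dCt relative expression is computed; per group, strong outliers are
    removed (when requested and the group has >= 4 values) and the ratio of
    the surviving group means is returned along with the removed subjects.
    """
    required = {"subject_id", "group", "cq_mean", "reference_cq_mean"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    out: dict = {"removed": []}
    means: dict[str, float] = {}
    for grp in ("DS", "N"):
        sub = measurements[measurements["group"] == grp]
        if len(sub) < 2:
            raise ValueError(f"group {grp} has fewer than 2 subjects")
        expr = 2.0 ** -(sub["cq_mean"].to_numpy(float) - sub["reference_cq_mean"].to_numpy(float))
        subjects = sub["subject_id"].to_numpy()
        if remove_outliers:
            if len(expr) >= 4:
                flagged = detect_strong_outliers(expr)["indices"]
            else:
                warnings.warn(f"group {grp}: <4 values, outlier removal skipped", stacklevel=2)
                flagged = []
            if flagged:
                out["removed"].extend(subjects[flagged].tolist())
                keep = np.setdiff1d(np.arange(len(expr)), flagged)
                expr = expr[keep]
                if len(expr) == 0:
                    raise ValueError(f"group {grp} emptied by outlier removal")
        means[grp] = float(expr.mean())
        out[f"mean_{grp}"] = means[grp]
        out[f"sd_{grp}"] = float(np.std(expr, ddof=1)) if len(expr) > 1 else 0.0
        out[f"n_{grp}"] = int(len(expr))
    out["ratio"] = means["DS"] / means["N"]
    return out


def validation_correlation(
    pairs: pd.DataFrame,
    method: Literal["pearson", "spearman"] = "pearson",
) -> dict:
    """Correlate map-derived and qPCR-derived ratios over a gene panel.

    ``pairs`` needs columns ``ratio_map`` and ``ratio_qpcr`` (one row per
    gene, both ratios > 0).  Returns ``{"r", "p", "n"}`` with a two-sided p.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 gene pairs")
    x = pairs["ratio_map"].to_numpy(float)
    y = pairs["ratio_qpcr"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a ratio vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "n": int(len(pairs))}


def read_plate(path) -> pd.DataFrame:
    """Read a TSV qPCR plate table (subject_id, group, gene, cq_mean, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str, "gene": str})
    missing = [c for c in ("subject_id", "group", "gene", "cq_mean") if c not in df.columns]
    if missing:
        raise ValueError(f"plate table lacks columns {missing}")
    bad_cq = ~df["cq_mean"].between(0, 45, inclusive="neither")
    if bad_cq.any():
        raise ValueError(f"Cq values outside (0, 45) for subjects {df.loc[bad_cq, 'subject_id'].tolist()}")
    return df
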