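"""End-to-end convenience drivers for the mapping pipeline."""

from __future__ import annotations

import pandas as pd

from .diffmap import build_differential_map
from .io_ingest import ExpressionSample
from .normalization import build_pool_map, normalize_samples


def differential_pipeline(
    samples: list[ExpressionSample],
    catalog: pd.DataFrame | None = None,
    min_samples: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Normalise jointly, pool each condition, and build the A/B ratio map.

    Both normalisations run across the samples of both conditions together
    so that the resulting pooled means are on one common scale and the A/B
    ratios are meaningful.  Returns ``(map_A, map_B, differential_map)``.
    """
    normalized = normalize_samples(samples)
    group_a = [s for s in normalized if s.condition == "A"]
    group_b = [s for s in normalized if s.condition == "B"]
    if not group_a or not group_b:
        raise ValueError("need samples from both conditions")
    map_a = build_pool_map(group_a, catalog, min_samples=min_samples)
    map_b = build_pool_map(group_b, catalog, min_samples=min_samples)
    return map_a, map_b, build_differential_map(map_a, map_b)
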