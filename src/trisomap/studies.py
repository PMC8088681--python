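"""Canonical simulation studies exercising the full pipeline.

Two parameter-recovery studies, with fixed designs, used by the test suite
and the reproduction script:

* **Dosage recovery** -- a 4-vs-4 experiment on a 10-chromosome genome
  (500 genes each) with chromosome "21" trisomic at 1.5x dosage, log10
  measurement noise sd 0.1 and 5% dropout.  Recovers the trisomic
  chromosome's mean expression ratio and checks it is the genome-wide
  maximum.  Because normalisation equalises sample scales, the recovered
  ratio is shrunk by the trisomic chromosome's share of total expression
  (~10% here), so the expectation is ~1.44, not 1.50.

* **Window recovery** -- a 4-chromosome x 12.5 Mb genome carrying 5,000
  null background genes and four implanted 500 kb over-expressed windows of
  3 genes each at folds 4.16 / 4.11 / 3.65 / 2.78 (mirroring the magnitude
  profile of real trisomy-21 segment calls).  The genome tiles into ~200
  windows per direction, sized so that a fully flagged 3-gene window
  reaches genome-wide BH significance at the ~5% background flag rate the
  noise level implies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffmap import chromosome_summary
from .pipeline import differential_pipeline
from .segmap import SegmentConfig, analyze_segments
from .simulate import SimulationConfig, SpikedSegment, simulate_study

WINDOW_STUDY_SPIKES = (
    SpikedSegment("1", 8_250_001, 8_750_000, 4.16),
    SpikedSegment("2", 6_000_001, 6_500_000, 4.11),
    SpikedSegment("3", 5_500_001, 6_000_000, 3.65),
    SpikedSegment("4", 10_250_001, 10_750_000, 2.78),
)


def dosage_recovery_config(seed: int) -> SimulationConfig:
    """Default study design: 10 chromosomes, "21" trisomic at 1.5x."""
    return SimulationConfig(seed=seed)


def window_recovery_config(seed: int) -> SimulationConfig:
    """Four implanted over-expressed windows on a dense null background."""
    return SimulationConfig(
        chromosomes=("1", "2", "3", "4"),
        genes_per_chromosome=1250,
        chromosome_extent=12_500_000,
        gene_length=2_000,
        trisomic_chromosome=None,
        dropout_rate=0.0,
        spiked_segments=WINDOW_STUDY_SPIKES,
        seed=seed,
    )


def run_dosage_recovery(seeds: range) -> pd.DataFrame:
    """Trisomic-chromosome mean ratio and rank across simulation seeds.

    Returns one row per seed: the recovered mean expression ratio of the
    trisomic chromosome and whether it is the genome-wide maximum.
    """
    rows = []
    for seed in seeds:
        cfg = dosage_recovery_config(seed)
        catalog, samples = simulate_study(cfg)
        _, _, dm = differential_pipeline(samples, catalog)
        summ = chromosome_summary(dm)
        tri = cfg.trisomic_chromosome
        rows.append(
            {
                "seed": seed,
                "mean_ratio": summ.loc[tri, "mean_ratio"],
                "is_genome_max": summ["mean_ratio"].idxmax() == tri,
            }
        )
    return pd.DataFrame(rows)


def run_window_recovery(seeds: range, config: SegmentConfig = SegmentConfig()) -> pd.DataFrame:
    """Implanted-window detection and false-call counts across seeds.

    A window counts as detected when a pruned over-call overlaps it; calls
    overlapping no implanted window (either direction) count as false.
    """
    rows = []
    for seed in seeds:
        cfg = window_recovery_config(seed)
        catalog, samples = simulate_study(cfg)
        _, _, dm = differential_pipeline(samples, catalog)
        _, pruned = analyze_segments(dm, config=config)
        implanted = [(s.chromosome, s.start, s.end) for s in cfg.spiked_segments]
        over = pruned[pruned["call"] == "over"]

        def hits_implant(row) -> bool:
            return any(
                row.chromosome == c and row.start <= e and row.end >= s
                for (c, s, e) in implanted
            )

        detected = sum(
            any(r.chromosome == c and r.start <= e and r.end >= s for r in over.itertuples())
            for (c, s, e) in implanted
        )
        false_over = sum(1 for r in over.itertuples() if not hits_implant(r))
        false_under = int((pruned["call"] == "under").sum())
        rows.append(
            {
                "seed": seed,
                "n_detected": detected,
                "all_detected": detected == len(implanted),
                "false_calls": false_over + false_under,
            }
        )
    return pd.DataFrame(rows)
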