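"""Synthetic genomes, FPKM sample sets and qPCR plates.

The generator emulates the statistical structure the analysis assumes: a
gene catalogue with non-overlapping loci; per-sample FPKM-scale values with
a log-normal baseline (expression spans orders of magnitude and is strongly
right-skewed); a designated trisomic chromosome whose genes carry a 3:2
(1.5x) dosage in condition A; optional implanted over-expressed windows and
single spiked genes; multiplicative log-normal measurement noise; and
per-sample dropout (a gene absent from a sample, distinct from zero).

All randomness flows from a single seed for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_ingest import ExpressionSample, validate_catalog
from .qpcr import PLATE_COLUMNS


@dataclass(frozen=True)
class SpikedSegment:
    """An implanted over-expressed window: n_genes at the given fold."""

    chromosome: str
    start: int
    end: int
    fold: float
    n_genes: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a simulated 4-vs-4 dosage experiment.

    Defaults mirror the target study: four trisomic (A) and four control
    (B) samples, a trisomic chromosome labelled "21" at 1.5x dosage, a
    log10-normal baseline (mu 1.0, sigma 0.8 in log10 FPKM), multiplicative
    log10 measurement noise of sd 0.1, and 5% per-sample dropout.
    """

    chromosomes: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7", "8", "9", "21")
    genes_per_chromosome: int = 500
    chromosome_extent: int = 50_000_000
    gene_length: int = 10_000
    baseline_log10_mu: float = 1.0
    baseline_log10_sigma: float = 0.8
    trisomic_chromosome: str | None = "21"
    dosage: float = 1.5
    dosage_noise_sd: float = 0.0
    noise_sd: float = 0.1
    spiked_segments: tuple[SpikedSegment, ...] = ()
    spiked_genes: dict[str, float] = field(default_factory=dict)
    n_samples_a: int = 4
    n_samples_b: int = 4
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dosage <= 0 or any(s.fold <= 0 for s in self.spiked_segments):
            raise ValueError("folds must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")


def _place_nonoverlapping(rng: np.random.Generator, lo: int, hi: int, n: int, length: int) -> np.ndarray:
    """n non-overlapping gene starts uniformly at random within [lo, hi].

    Stick-breaking construction: draw starts in the slack space left after
    reserving n gene lengths, sort, and shift each by its rank's offset.
    """
    if n == 0:
        return np.array([], dtype=np.int64)
    slack = (hi - lo + 1) - n * length
    if slack < 0:
        raise ValueError(f"cannot place {n} genes of {length} bp in [{lo}, {hi}]")
    starts = np.sort(rng.integers(0, slack + 1, size=n))
    return lo + starts + np.arange(n) * length


def simulate_gene_catalog(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a gene catalogue matching the configured genome.

    Background genes are placed uniformly without overlap along each
    chromosome, excluding the spiked intervals, which receive exactly their
    requested number of genes (symbols prefixed ``SPK``).
    """
    rng = rng or np.random.default_rng(config.seed)
    L = config.gene_length
    rows = []
    for chrom in config.chromosomes:
        spikes = sorted(
            (s for s in config.spiked_segments if s.chromosome == chrom), key=lambda s: s.start
        )
        # Background placement in the gaps between spiked intervals.
        gaps, cursor = [], 1
        for s in spikes:
            if s.start - 1 >= cursor:
                gaps.append((cursor, s.start - 1))
            cursor = s.end + 1
        if cursor <= config.chromosome_extent:
            gaps.append((cursor, config.chromosome_extent))
        capacity = np.array([max(0, (hi - lo + 1) // L) for lo, hi in gaps])
        if capacity.sum() < config.genes_per_chromosome:
            raise ValueError(f"chromosome {chrom} overcrowded")
        weights = capacity / capacity.sum()
        counts = rng.multinomial(config.genes_per_chromosome, weights)
        # Redistribute any excess over a gap's capacity.
        while (counts > capacity).any():
            over = counts > capacity
            excess = int((counts - capacity)[over].sum())
            counts = np.minimum(counts, capacity)
            room = capacity - counts
            for _ in range(excess):
                j = int(np.argmax(room))
                counts[j] += 1
                room[j] -= 1
        i = 0
        for (lo, hi), cnt in zip(gaps, counts):
            for start in _place_nonoverlapping(rng, lo, hi - L + 1, int(cnt), L):
                rows.append((f"G{chrom}_{i:04d}", chrom, int(start), int(start) + L - 1))
                i += 1
        for k, s in enumerate(spikes):
            for j, start in enumerate(
                _place_nonoverlapping(rng, s.start, s.end - L + 1, s.n_genes, L)
            ):
                rows.append((f"SPK{chrom}_{k}_{j}", chrom, int(start), int(start) + L - 1))
    cat = pd.DataFrame(rows, columns=["symbol", "chromosome", "start", "end"])
    return validate_catalog(cat)


def _fold_map(catalog: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Per-gene condition-A fold: dosage x segment fold x gene fold."""
    fold = pd.Series(1.0, index=catalog["symbol"].to_numpy())
    chrom = pd.Series(catalog["chromosome"].to_numpy(), index=fold.index)
    mid = pd.Series(((catalog["start"] + catalog["end"]) // 2).to_numpy(), index=fold.index)
    if config.trisomic_chromosome is not None:
        on_tri = chrom == config.trisomic_chromosome
        dosage = np.full(int(on_tri.sum()), config.dosage)
        if config.dosage_noise_sd > 0:
            dosage = dosage * 10 ** rng.normal(0.0, config.dosage_noise_sd, size=len(dosage))
        fold[on_tri] = fold[on_tri] * dosage
    for s in config.spiked_segments:
        inside = (chrom == s.chromosome) & (mid >= s.start) & (mid <= s.end)
        fold[inside] = fold[inside] * s.fold
    for sym, f in config.spiked_genes.items():
        if sym not in fold.index:
            raise KeyError(f"spiked gene {sym} not in catalogue")
        fold[sym] = fold[sym] * f
    return fold


def simulate_fpkm_samples(
    catalog: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[ExpressionSample]:
    """Simulate the A and B FPKM sample sets for a catalogue.

    Per gene g: baseline b_g ~ 10^Normal(mu, sigma); a condition-B value is
    b_g x 10^Normal(0, noise_sd); a condition-A value additionally carries
    the gene's fold (dosage x segment x gene).  Dropout removes a gene from
    a sample independently with probability dropout_rate.
    """
    rng = rng or np.random.default_rng(config.seed)
    symbols = catalog["symbol"].to_numpy()
    n_genes = len(symbols)
    baseline = 10 ** rng.normal(config.baseline_log10_mu, config.baseline_log10_sigma, n_genes)
    fold = _fold_map(catalog, config, rng).to_numpy()

    samples = []
    for cond, n_samp, mult in (("A", config.n_samples_a, fold), ("B", config.n_samples_b, 1.0)):
        for i in range(n_samp):
            noise = 10 ** rng.normal(0.0, config.noise_sd, n_genes) if config.noise_sd > 0 else 1.0
            values = baseline * mult * noise
            present = rng.random(n_genes) >= config.dropout_rate
            series = pd.Series(values[present], index=symbols[present])
            samples.append(ExpressionSample(f"{cond}{i + 1}", cond, series))
    return samples


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, list[ExpressionSample]]:
    """Catalogue plus samples from one generator seeded by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    catalog = simulate_gene_catalog(config, rng)
    return catalog, simulate_fpkm_samples(catalog, config, rng)


def simulate_qpcr_plate(
    true_ratios: dict[str, float],
    reference_cq: float = 20.0,
    base_delta_ct: float = 5.0,
    noise_sd: float = 0.15,
    n_per_group: int = 6,
    outlier_spec: list[dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-subject qPCR plate for a panel of genes.

    Control (N) subjects draw dCt around ``base_delta_ct``; DS subjects are
    shifted by -log2(fold) so the Livak ratio recovers the true fold.
    ``outlier_spec`` entries ``{"group", "gene", "subject_index",
    "shift_cycles"}`` inject extreme values by shifting a target Cq.
    """
    if any(f <= 0 for f in true_ratios.values()):
        raise ValueError("folds must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in true_ratios.items():
        for grp, prefix, shift in (("DS", "A", -np.log2(fold)), ("N", "B", 0.0)):
            for i in range(n_per_group):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                cq = reference_cq + base_delta_ct + shift + noise
                rows.append(
                    {
                        "subject_id": f"{prefix}{i + 1}",
                        "group": grp,
                        "gene": gene,
                        "cq_mean": cq,
                        "reference_gene": "GAPDH",
                        "reference_cq_mean": reference_cq,
                    }
                )
    plate = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    for spec in outlier_spec or []:
        mask = (
            (plate["group"] == spec["group"])
            & (plate["gene"] == spec["gene"])
            & (plate["subject_id"].str.endswith(str(spec["subject_index"] + 1)))
        )
        plate.loc[mask, "cq_mean"] += spec["shift_cycles"]
    return plate
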