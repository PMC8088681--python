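import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trisomap import (
    SegmentConfig,
    analyze_segments,
    assign_genes,
    differential_pipeline,
    hypergeometric_tail,
    prune_overlapping,
    simulate_study,
    single_gene_mode,
    tile_genome,
)
from trisomap import test_segments as score_segments

from test_diffmap import make_dm


def enumeration_tail(k, N, K, n):
    """Exhaustive oracle: fraction of all C(N, n) draws with >= k flagged."""
    hits = 0
    for draw in itertools.combinations(range(N), n):
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / math.comb(N, n)


def comb_sum_tail(k, N, K, n):
    """Closed-form oracle: sum_i>=k C(K,i) C(N-K,n-i) / C(N,n)."""
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(max(k, 0), min(K, n) + 1)
    ) / math.comb(N, n)


class TestHypergeometricTail:
    def test_worked_example(self):
        # N=20, K=5, n=4, k=4: C(5,4)*C(15,0)/C(20,4) = 5/4845
        assert hypergeometric_tail(4, 20, 5, 4) == pytest.approx(5 / 4845)
        assert enumeration_tail(4, 20, 5, 4) == pytest.approx(5 / 4845)

    def test_k_zero_is_certain(self):
        assert hypergeometric_tail(0, 20, 5, 4) == 1.0

    def test_all_flagged_degenerate(self):
        assert hypergeometric_tail(4, 20, 20, 4) == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [5, 8, 11])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(N + 1):
            for n in range(1, N + 1):
                for k in range(n + 1):
                    assert hypergeometric_tail(k, N, K, n) == pytest.approx(
                        enumeration_tail(k, N, K, n), abs=1e-12
                    )


def grid_config(**kw):
    return SegmentConfig(**{"window": 500_000, "shift": 250_000, **kw})


class TestTileGenome:
    def test_window_starts_anchor_at_one(self, rng):
        cat = pd.DataFrame(
            {"symbol": ["a", "b"], "chromosome": ["1", "1"], "start": [10, 999_000], "end": [20, 1_000_000]}
        )
        seg = tile_genome(cat, grid_config())
        assert seg["start"].tolist() == [1, 250_001, 500_001, 750_001]
        assert (seg["end"] - seg["start"] + 1 == 500_000).all()

    def test_window_equals_shift_is_partition(self):
        cat = pd.DataFrame({"symbol": ["a"], "chromosome": ["1"], "start": [1], "end": [1_000_000]})
        seg = tile_genome(cat, grid_config(shift=500_000))
        starts, ends = seg["start"].to_numpy(), seg["end"].to_numpy()
        assert (starts[1:] == ends[:-1] + 1).all()

    def test_grid_alignment_of_late_window(self):
        # a window on the 250 kb grid: start 41,250,001 spans to 41,750,000
        cat = pd.DataFrame({"symbol": ["a"], "chromosome": ["21"], "start": [41_500_000], "end": [41_600_000]})
        seg = tile_genome(cat, grid_config())
        row = seg[seg["start"] == 41_250_001]
        assert not row.empty and row["end"].iloc[0] == 41_750_000

    def test_shift_larger_than_window_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            grid_config(shift=600_000)


class TestAssignGenes:
    def test_membership_by_midpoint(self):
        dm = make_dm({"in": 2.0, "out": 3.0})
        dm.loc[:, ["start", "end"]] = [[50, 150], [499_990, 500_012]]  # midpoints 100, 500001
        seg = pd.DataFrame({"chromosome": ["1"], "start": [1], "end": [500_000]})
        out = assign_genes(seg, dm, grid_config())
        assert out["genes"].iloc[0] == ["in"]

    def test_score_is_mean_of_member_ratios(self):
        dm = make_dm({"a": 4.32, "b": 6.76, "c": 1.4})
        dm.loc[:, "start"] = [1000, 2000, 3000]
        dm.loc[:, "end"] = [1500, 2500, 3500]
        seg = pd.DataFrame({"chromosome": ["1"], "start": [1], "end": [500_000]})
        out = assign_genes(seg, dm, grid_config())
        assert out["score"].iloc[0] == pytest.approx(np.mean([4.32, 6.76, 1.4]))

    def test_undersupported_locus_excluded(self):
        dm = make_dm({"good": 2.0, "thin": 9.0})
        dm.loc[dm["symbol"] == "thin", "n_A"] = 1
        seg = pd.DataFrame({"chromosome": ["1"], "start": [1], "end": [500_000]})
        out = assign_genes(seg, dm, grid_config(min_samples=2))
        assert out["genes"].iloc[0] == ["good"]

    def test_overlapping_windows_share_gene(self):
        dm = make_dm({"mid": 2.0})
        dm.loc[:, ["start", "end"]] = [[300_000, 300_100]]
        cat = dm[["symbol", "chromosome", "start", "end"]]
        seg = assign_genes(tile_genome(cat, grid_config()), dm, grid_config())
        holders = seg[seg["n_genes"] > 0]
        assert set(holders["start"]) == {1, 250_001}


class TestTestSegments:
    def _run(self, ratios, adjust="bh"):
        dm = make_dm(ratios)
        n = len(dm)
        dm["start"] = np.arange(n) * 12_500 + 1
        dm["end"] = dm["start"] + 100
        cfg = grid_config(window=12_500, shift=12_500, adjust=adjust)
        seg = tile_genome(dm[["symbol", "chromosome", "start", "end"]], cfg)
        seg = assign_genes(seg, dm, cfg)
        return score_segments(seg, dm, cfg), cfg

    def test_bh_q_dominates_p_and_is_step_monotone(self, rng):
        ratios = {f"g{i}": v for i, v in enumerate(rng.lognormal(0, 0.3, 60))}
        seg, _ = self._run(ratios)
        tested = seg[seg["score"].notna()]
        assert (tested["q_over"] >= tested["p_over"] - 1e-12).all()
        ordered = tested.sort_values("p_over")
        assert ordered["q_over"].is_monotonic_increasing

    def test_raw_adjustment_option(self, rng):
        ratios = {f"g{i}": v for i, v in enumerate(rng.lognormal(0, 0.3, 30))}
        seg, _ = self._run(ratios, adjust="none")
        tested = seg[seg["score"].notna()]
        assert np.allclose(tested["q_over"], tested["p_over"], equal_nan=True)

    def test_empty_window_untested(self):
        dm = make_dm({"far": 2.0})
        dm.loc[:, ["start", "end"]] = [[400_000, 400_100]]
        cfg = grid_config(window=100_000, shift=100_000)
        seg = tile_genome(dm[["symbol", "chromosome", "start", "end"]], cfg)
        seg = score_segments(assign_genes(seg, dm, cfg), dm, cfg)
        empty = seg[seg["n_genes"] == 0]
        assert (empty["call"] == "none").all() and empty["p_over"].isna().all()


class TestPruneOverlapping:
    def _segments(self, rows):
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "score", "call"])

    def test_overlapping_over_calls_keep_highest_score(self):
        seg = self._segments(
            [("1", 1, 500_000, 3.9, "over"), ("1", 250_001, 750_000, 4.16, "over")]
        )
        out = prune_overlapping(seg)
        assert len(out) == 1 and out["score"].iloc[0] == 4.16

    def test_overlapping_under_calls_keep_lowest_score(self):
        seg = self._segments(
            [("1", 1, 500_000, 0.4, "under"), ("1", 250_001, 750_000, 0.6, "under")]
        )
        out = prune_overlapping(seg)
        assert out["score"].iloc[0] == 0.4

    def test_disjoint_windows_all_kept_sorted_by_score(self):
        seg = self._segments(
            [("1", 1, 500_000, 2.0, "over"), ("2", 1, 500_000, 5.0, "over"), ("1", 750_001, 1_250_000, 3.0, "over")]
        )
        out = prune_overlapping(seg)
        assert out["score"].tolist() == [5.0, 3.0, 2.0]

    def test_output_pairwise_nonoverlapping(self, rng):
        rows = []
        for i in range(40):
            start = 1 + int(rng.integers(0, 40)) * 250_000
            rows.append(("1", start, start + 499_999, float(rng.uniform(1.5, 5)), "over"))
        out = prune_overlapping(self._segments(rows))
        out = out.sort_values("start")
        assert (out["start"].to_numpy()[1:] > out["end"].to_numpy()[:-1]).all()


def test_implanted_windows_recovered_exactly():
    """The four implanted over-expressed windows are the called segments."""
    from trisomap.studies import window_recovery_config

    cfg = window_recovery_config(seed=11)
    catalog, samples = simulate_study(cfg)
    _, _, dm = differential_pipeline(samples, catalog)
    _, pruned = analyze_segments(dm)
    called = {(r.chromosome, r.start, r.end) for r in pruned.itertuples() if r.call == "over"}
    implanted = {(s.chromosome, s.start, s.end) for s in cfg.spiked_segments}
    assert called == implanted
    assert (pruned["q_over"] < 0.05).all()


class TestSingleGeneMode:
    def test_lone_extreme_gene_called(self, rng):
        ratios = {f"g{i}": v for i, v in enumerate(rng.lognormal(0, 0.03, 400))}
        ratios["hot"] = 8.0
        dm = make_dm(ratios)
        n = len(dm)
        dm["start"] = np.arange(n) * 12_500 + 1
        dm["end"] = dm["start"] + 100
        calls = single_gene_mode(dm)
        assert "hot" in set(calls["symbol"])
        assert calls.set_index("symbol").loc["hot", "call"] == "over"

    def test_prevailing_gene_attributed_and_tie_suppressed(self, rng):
        ratios = {f"g{i}": v for i, v in enumerate(rng.lognormal(0, 0.03, 400))}
        ratios |= {"top": 9.0, "second": 8.0}  # same window, top prevails
        ratios |= {"tie1": 7.0, "tie2": 7.0}  # same window, tied
        dm = make_dm(ratios)
        n = len(dm)
        dm["start"] = np.arange(n) * 12_500 + 1
        dm["end"] = dm["start"] + 100
        # co-locate the pairs
        dm.loc[dm["symbol"] == "second", ["start", "end"]] = dm.loc[
            dm["symbol"] == "top", ["start", "end"]
        ].to_numpy() + 50
        dm.loc[dm["symbol"] == "tie2", ["start", "end"]] = dm.loc[
            dm["symbol"] == "tie1", ["start", "end"]
        ].to_numpy() + 50
        calls = set(single_gene_mode(dm)["symbol"])
        assert "top" in calls
        assert "second" not in calls
        assert not {"tie1", "tie2"} & calls
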