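"""Peak calling, shuffle-null enrichment, profiles, closest-gene assignment
and the resampling statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nicksim._rng import rng_for
from nicksim.enrichment import (
    assign_closest_gene,
    call_peaks,
    chrom_correlation,
    enrichment_test,
    expression_resample_test,
    loess_smooth,
    metagene_profile,
    overlap_nucleotides,
    profile_comparison_tests,
    shuffle_intervals,
    two_proportion_test,
)
from nicksim.synthetic_data import Genome


def _signal(values, spacing=100, chrom="chr01"):
    pos = np.arange(spacing // 2, spacing // 2 + spacing * len(values), spacing)
    return pd.DataFrame({"chrom": chrom, "position": pos, "value": values})


class TestCallPeaks:
    def test_planted_cluster_called_once(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 0.2, 400)
        v[200:205] += 3.0
        peaks = call_peaks(_signal(v), z_threshold=4, min_probes=3, merge_gap=300)
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert p["start"] <= 200 * 100 + 50 and p["end"] >= 204 * 100 + 50

    def test_flat_noise_rarely_calls(self):
        """Gaussian tail x 20k probes: well under one false call per genome
        on average."""
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            peaks = call_peaks(_signal(rng.normal(0, 0.3, 20_000)), z_threshold=4)
            total += len(peaks)
        assert total / 20 < 1.5

    def test_degenerate_threshold_merges_whole_chromosome(self):
        rng = np.random.default_rng(1)
        peaks = call_peaks(
            _signal(rng.normal(0, 1, 500)), z_threshold=0.0, min_probes=1,
            merge_gap=100 * 30,
        )
        assert len(peaks) == 1

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            call_peaks(_signal(np.ones(100)))


class TestShuffleIntervals:
    GENOME = Genome((("chr01", 10_000),))

    def test_forced_placement_full_length_peak(self):
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [0], "end": [10_000]})
        for shuf in shuffle_intervals(peaks, self.GENOME, 5, 0):
            assert shuf.iloc[0]["start"] == 0 and shuf.iloc[0]["end"] == 10_000

    def test_length_multiset_preserved_every_draw(self):
        genome = Genome((("chr01", 10_000), ("chr02", 5_000)))
        peaks = pd.DataFrame(
            {"chrom": ["chr01", "chr01", "chr02"], "start": [0, 500, 10],
             "end": [100, 700, 40]}
        )
        for shuf in shuffle_intervals(peaks, genome, 50, 1):
            for chrom, want in (("chr01", [100, 200]), ("chr02", [30])):
                sub = shuf[shuf["chrom"] == chrom]
                assert sorted(sub["end"] - sub["start"]) == want
                assert (sub["start"] >= 0).all()
                assert (sub["end"] <= genome.lengths[chrom]).all()

    def test_placements_uniform(self):
        """Start positions of a shuffled 100-bp peak are uniform on the
        chromosome (chi-square over 10 bins, 5000 draws)."""
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [4000], "end": [4100]})
        starts = np.array(
            [s.iloc[0]["start"] for s in shuffle_intervals(peaks, self.GENOME, 5000, 3)]
        )
        counts, _ = np.histogram(starts, bins=10, range=(0, 9901))
        chi2 = ((counts - 500) ** 2 / 500).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.001

    def test_oversized_peak_rejected(self):
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [0], "end": [20_000]})
        with pytest.raises(ValueError, match="exceeds"):
            list(shuffle_intervals(peaks, self.GENOME, 1, 0))


class TestEnrichmentTest:
    GENOME = Genome((("chr01", 10_000),))

    def test_whole_genome_category_fold_one(self):
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [1000], "end": [1100]})
        cat = pd.DataFrame({"chrom": ["chr01"], "start": [0], "end": [10_000]})
        res = enrichment_test(peaks, cat, self.GENOME, n_perm=20, rng_or_seed=0)
        assert res.fold_change == 1.0
        assert res.p_two_tailed == 1.0

    def test_null_mean_matches_exhaustive_placement_oracle(self):
        """Null overlap of a 100-bp peak with a 1-kb category equals the
        average over all 9901 placements; fold lands in the 9-10 range."""
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [4950], "end": [5050]})
        cat = pd.DataFrame({"chrom": ["chr01"], "start": [4500], "end": [5500]})
        s = np.arange(0, 9901)
        oracle = np.clip(np.minimum(s + 100, 5500) - np.maximum(s, 4500), 0, None).mean()
        res = enrichment_test(peaks, cat, self.GENOME, n_perm=4000, rng_or_seed=5)
        mc_se = res.null_sd / np.sqrt(res.n_perm)
        assert abs(res.null_mean - oracle) < 4 * mc_se
        assert 9.0 <= res.fold_change <= 10.5
        assert res.observed == 100

    def test_zero_peak_nucleotides_rejected(self):
        peaks = pd.DataFrame(columns=["chrom", "start", "end"])
        cat = pd.DataFrame({"chrom": ["chr01"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            enrichment_test(peaks, cat, self.GENOME, 5, 0)


class TestTwoProportion:
    def test_equal_proportions(self):
        assert two_proportion_test(50, 100, 50, 100) == (0.0, 1.0)

    def test_arithmetic_example(self):
        z, p = two_proportion_test(90, 100, 10, 100)
        assert z == pytest.approx(11.3137, abs=1e-3)
        assert p < 1e-28

    def test_antisymmetry(self):
        z1, p1 = two_proportion_test(30, 100, 60, 120)
        z2, p2 = two_proportion_test(60, 120, 30, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == p2

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_test(0, 50, 0, 70) == (0.0, 1.0)


class TestMetagene:
    @staticmethod
    def _uniform_signal(length=30_000, spacing=100, value=1.0):
        pos = np.arange(spacing // 2, length, spacing)
        return pd.DataFrame({"chrom": "chr01", "position": pos,
                             "value": np.full(len(pos), value)})

    def test_bin_count_30_for_1500_over_100(self):
        anchors = pd.DataFrame({"chrom": ["chr01"], "position": [15_000],
                                "strand": ["+"]})
        prof = metagene_profile(self._uniform_signal(), anchors, 1500, 100)
        assert len(prof.mean) == 30

    def test_constant_signal_flat_profile(self):
        anchors = pd.DataFrame({"chrom": ["chr01"] * 3,
                                "position": [5_000, 15_000, 25_000],
                                "strand": ["+", "-", "+"]})
        prof = metagene_profile(self._uniform_signal(), anchors, 1500, 100)
        assert np.allclose(prof.mean, 1.0)

    def test_delta_spike_peaks_centrally(self):
        sig = self._uniform_signal(value=0.0)
        anchors = pd.DataFrame({"chrom": ["chr01"] * 2, "position": [10_050, 20_050],
                                "strand": ["+", "+"]})
        sig.loc[sig["position"].isin(anchors["position"]), "value"] = 5.0
        prof = metagene_profile(sig, anchors, 1500, 100)
        central = 2 * 1500 // 100 // 2
        assert prof.mean[central] > 0
        others = np.delete(prof.mean, central)
        assert np.allclose(others, 0.0)

    def test_strand_aware_flip(self):
        sig = self._uniform_signal(value=0.0)
        sig.loc[sig["position"] == 10_250, "value"] = 3.0  # +200 of anchor
        plus = pd.DataFrame({"chrom": ["chr01"], "position": [10_050], "strand": ["+"]})
        minus = plus.assign(strand="-")
        p_plus = metagene_profile(sig, plus, 1500, 100).mean
        p_minus = metagene_profile(sig, minus, 1500, 100).mean
        # +200 bp falls in bin [200,300) = 17; flipped it reads -200 bp,
        # landing in bin [-200,-100) = 13
        assert p_plus.argmax() == 17
        assert p_minus.argmax() == 13

    def test_window_not_divisible_rejected(self):
        anchors = pd.DataFrame({"chrom": ["chr01"], "position": [500], "strand": ["+"]})
        with pytest.raises(ValueError):
            metagene_profile(self._uniform_signal(), anchors, 1500, 400)

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile(self._uniform_signal(), pd.DataFrame(columns=["chrom", "position"]), 1500, 100)


class TestLoess:
    def test_reproduces_linear_input_exactly(self):
        x = np.linspace(0, 10, 50)
        y = 3.0 * x - 2.0
        for span in (0.2, 0.5, 1.0):
            assert np.allclose(loess_smooth(x, y, span), y, atol=1e-9)

    def test_constant_input(self):
        x = np.arange(20.0)
        out = loess_smooth(x, np.full(20, 7.0), 0.4)
        assert np.allclose(out, 7.0, atol=1e-9)

    def test_noise_variance_reduction(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 4 * np.pi, 300)
        truth = np.sin(x)
        y = truth + rng.normal(0, 0.5, len(x))
        smoothed = loess_smooth(x, y, 0.3)
        assert np.sqrt(np.mean((smoothed - truth) ** 2)) < np.sqrt(
            np.mean((y - truth) ** 2)
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth([1, 2, 3], [1, 2, 3], 0.5)


class TestClosestGene:
    GENES = pd.DataFrame(
        {
            "chrom": ["chr01"] * 3,
            "start": [1000, 5000, 9000],
            "end": [2000, 6000, 9500],
            "strand": ["+", "-", "+"],
            "gene_id": ["g1", "g2", "g3"],
            "rpkm": [1.0, 2.0, 3.0],
        }
    )

    def test_overlapping_peak_distance_zero(self):
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [1500], "end": [1600]})
        out = assign_closest_gene(peaks, self.GENES)
        assert out.iloc[0]["gene_id"] == "g1" and out.iloc[0]["distance"] == 0

    def test_equidistant_tie_breaks_to_5prime_most_start(self):
        peaks = pd.DataFrame({"chrom": ["chr01"], "start": [3400], "end": [3600]})
        # gaps: g1 end 2000 -> 1400; g2 start 5000 -> 1400
        out = assign_closest_gene(peaks, self.GENES)
        assert out.iloc[0]["gene_id"] == "g1"

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(10)
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["chr01", "chr02"], 100),
                "start": rng.integers(0, 90_000, 100),
                "strand": rng.choice(["+", "-"], 100),
                "rpkm": rng.random(100),
            }
        )
        genes["end"] = genes["start"] + rng.integers(200, 2000, 100)
        genes["gene_id"] = [f"g{i}" for i in range(100)]
        peaks = pd.DataFrame(
            {"chrom": rng.choice(["chr01", "chr02"], 40),
             "start": rng.integers(0, 95_000, 40)}
        )
        peaks["end"] = peaks["start"] + 100
        out = assign_closest_gene(peaks, genes)
        for _, row in out.iterrows():
            sub = genes[genes["chrom"] == row["chrom"]]
            gaps = np.maximum(
                np.maximum(sub["start"] - row["peak_end"],
                           row["peak_start"] - sub["end"]), 0
            )
            best = gaps.min()
            winners = sub[gaps == best].sort_values("start")
            assert row["gene_id"] == winners.iloc[0]["gene_id"]
            assert abs(row["distance"]) == best


class TestExpressionResample:
    @staticmethod
    def _pool(n=400, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)],
             "rpkm": rng.lognormal(np.log(10), 1.2, n)}
        )

    def test_self_comparison_all_p_one(self):
        pool = self._pool(30)
        out = expression_resample_test(pool, pool, n_resample=20, rng_or_seed=0)
        assert np.allclose(out["p_values"], 1.0)
        assert out["rejection_fraction_raw"] == 0.0

    def test_null_rejection_near_alpha(self):
        """Random nick-gene draws at realistic pool proportions (215 of
        6664, so resample overlap is negligible) reject at ~alpha."""
        pool = self._pool(6664, 1)
        rng = rng_for(1, "resample")
        fracs = []
        for _ in range(12):
            nick = pool.sample(215, random_state=int(rng.integers(2**31)))
            out = expression_resample_test(nick, pool, n_resample=100, rng_or_seed=rng)
            fracs.append(out["rejection_fraction_raw"])
        assert 0.02 < np.mean(fracs) < 0.09

    def test_top_decile_rejected_with_elevated_median(self):
        pool = self._pool(600, 2)
        nick = pool.nlargest(60, "rpkm")
        out = expression_resample_test(nick, pool, n_resample=100, rng_or_seed=3)
        assert out["median_nick"] > out["median_genome"]
        assert out["rejection_fraction_adjusted"] > 0.95

    def test_tiny_nick_set_rejected(self):
        pool = self._pool(10)
        with pytest.raises(ValueError):
            expression_resample_test(pool.head(1), pool, 10, 0)


class TestChromCorrelation:
    def test_proportional_counts_r_one(self):
        lengths = np.array([100, 200, 400, 800])
        assert chrom_correlation(lengths * 3, lengths) == pytest.approx(1.0)

    def test_sign_flip_negates(self):
        lengths = np.array([100.0, 200, 400, 800])
        counts = np.array([12.0, 18, 35, 90])
        assert chrom_correlation(-counts, lengths) == pytest.approx(
            -chrom_correlation(counts, lengths)
        )

    def test_independent_counts_small_r(self):
        rng = np.random.default_rng(3)
        rs = [
            chrom_correlation(rng.poisson(50, 16), np.geomspace(230, 1530, 16))
            for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            chrom_correlation([1, 1, 1], [100, 200, 300])
        with pytest.raises(ValueError):
            chrom_correlation([1, 2], [100, 200])


def test_profile_comparison_distinguishes_shifted_profiles():
    rng = np.random.default_rng(6)
    null = profile_comparison_tests(rng.normal(0, 1, 200), rng.normal(0, 1, 200))
    shifted = profile_comparison_tests(rng.normal(1, 1, 200), rng.normal(0, 1, 200))
    assert shifted["ks_p"] < 1e-6 and shifted["t_p"] < 1e-6
    assert null["ks_p"] > 0.01
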