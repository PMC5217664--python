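import statistics

import numpy as np
import pandas as pd
import pytest

from mutspot import (
    Cohort,
    FlankStats,
    GenomeIndex,
    GenomicInterval,
    ScoreParams,
    ScoreTrack,
    candidate_filter,
    combined_score,
    compute_window_stats,
    normalize,
    raw_conservation,
    raw_recurrence,
    score_pipeline,
    simulate_cohort,
    SimulationConfig,
)
from mutspot.synthetic_fixtures import PlantedRegion


def flank(L, R, L0, R0):
    return FlankStats(L, R, L0, R0)


class TestRawRecurrence:
    def test_equal_rates_identity(self):
        assert raw_recurrence(1, 50, flank(10_000, 10_000, 500_000, 500_000)) == 1.0

    def test_direct_evaluation(self):
        # (10/50) / (500/1e6) = 0.2 / 5e-4 = 400
        assert raw_recurrence(10, 50, flank(250, 250, 500_000, 500_000)) == 400.0

    def test_zero_flank_mutations_undefined(self):
        assert np.isnan(raw_recurrence(5, 50, flank(0, 0, 1000, 1000)))

    def test_zero_valid_flank_undefined(self):
        assert np.isnan(raw_recurrence(5, 50, flank(0, 0, 0, 0)))

    def test_monotone_in_T_with_flanks_fixed(self):
        f = flank(100, 100, 10_000, 10_000)
        scores = [raw_recurrence(t, 50, f) for t in range(1, 10)]
        assert scores == sorted(scores)
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestRawConservation:
    def _track(self, values):
        return ScoreTrack({"c1": np.asarray(values, dtype=float)})

    def test_arithmetic_mean(self):
        track = self._track([2.0, -1.0, 2.0])
        assert raw_conservation([0, 1, 2], track, chrom="c1") == 1.0

    def test_per_mutation_not_per_position(self):
        """A base mutated in two samples contributes two terms."""
        track = self._track([3.0, 0.0])
        assert raw_conservation([0, 0, 1], track, chrom="c1") == 2.0

    def test_single_mutation_identity(self):
        track = self._track([0.7])
        assert raw_conservation([0], track, chrom="c1") == 0.7

    def test_missing_positions_excluded(self):
        track = self._track([np.nan, 4.0])
        assert raw_conservation([0, 1], track, chrom="c1") == 4.0

    def test_all_missing_undefined(self):
        track = self._track([np.nan])
        assert np.isnan(raw_conservation([0], track, chrom="c1"))


class TestNormalize:
    def test_median_maps_to_zero(self):
        out = normalize([1.0, 2.0, 3.0])
        assert out[1] == 0.0

    def test_matches_brute_force_median_mad(self):
        values = [1.0, 2.0, 3.0]
        med = statistics.median(values)
        mad = statistics.median(abs(v - med) for v in values) * 1.4826
        expected = [(v - med) / mad for v in values]
        assert np.allclose(normalize(values), expected)
        assert np.allclose(normalize(values)[0], -1 / 1.4826)

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize([5.0, 5.0, 5.0])

    def test_nan_propagates(self):
        out = normalize([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_unscaled_mad_constant(self):
        out = normalize([1.0, 2.0, 3.0], mad_constant=1.0)
        assert np.allclose(out, [-1.0, 0.0, 1.0])


class TestCombinedScore:
    def test_mean(self):
        assert combined_score(4.0, 2.0) == 3.0

    def test_idempotent_on_equal(self):
        assert combined_score(1.7, 1.7) == 1.7

    def test_nan_propagates(self):
        assert np.isnan(combined_score(np.nan, 1.0))


class TestCandidateFilter:
    def _stats(self, n_samples, mean_map, mean_cons=0.5):
        return pd.DataFrame(
            {
                "chrom": ["c1"],
                "start": [0],
                "end": [50],
                "T": [max(n_samples, 3)],
                "n_samples": [n_samples],
                "mean_mappability": [mean_map],
                "mean_conservation": [mean_cons],
            }
        )

    def test_min_samples_boundary(self):
        assert candidate_filter(self._stats(2, 1.0)).empty
        assert len(candidate_filter(self._stats(3, 1.0))) == 1

    def test_mappability_boundary_inclusive(self):
        assert candidate_filter(self._stats(5, 0.49)).empty
        assert len(candidate_filter(self._stats(5, 0.50))) == 1

    def test_undefined_means_fail(self):
        assert candidate_filter(self._stats(5, np.nan)).empty
        assert candidate_filter(
            self._stats(5, 1.0, mean_cons=np.nan), require_conservation=True
        ).empty

    def test_empty_input(self):
        empty = self._stats(3, 1.0).iloc[:0]
        assert candidate_filter(empty).empty


def _uniform_cohort(positions_by_sample):
    rows = []
    for sample, positions in positions_by_sample.items():
        for pos in positions:
            rows.append((sample, "X", "chr1", pos, "C", "T"))
    return Cohort(
        pd.DataFrame(rows, columns=["sample", "cohort", "chrom", "pos", "ref", "alt"])
    )


class TestWindowStats:
    def test_counts_and_means(self):
        genome = GenomeIndex({"chr1": 1000})
        cons = ScoreTrack({"chr1": np.arange(1000, dtype=float)})
        cohort = _uniform_cohort({"S1": [10, 20], "S2": [20], "S3": [700]})
        stats = compute_window_stats(cohort, genome, 50, conservation=cons)
        first = stats[stats["start"] == 0].iloc[0]
        assert first["T"] == 3 and first["n_samples"] == 2
        assert first["mean_conservation"] == pytest.approx((10 + 20 + 20) / 3)

    def test_per_position_mode(self):
        genome = GenomeIndex({"chr1": 100})
        cons = ScoreTrack({"chr1": np.arange(100, dtype=float)})
        cohort = _uniform_cohort({"S1": [10], "S2": [10], "S3": [20]})
        per_mut = compute_window_stats(cohort, genome, 50, conservation=cons)
        per_pos = compute_window_stats(
            cohort, genome, 50, conservation=cons, per_position_conservation=True
        )
        assert per_mut["mean_conservation"].iloc[0] == pytest.approx(40 / 3)
        assert per_pos["mean_conservation"].iloc[0] == pytest.approx(15.0)


class TestScorePipeline:
    def _planted_config(self, seed=11):
        return SimulationConfig(
            seed=seed,
            n_chromosomes=1,
            chrom_length=500_000,
            cohorts={"A": 15, "B": 15},
            background_rate=2e-4,
            planted_hotspots=[
                PlantedRegion(GenomicInterval("chr1", 250_000, 250_050), 20)
            ],
        )

    PARAMS = ScoreParams(flank_size=100_000)

    def test_planted_hotspot_ranks_first(self):
        ds = simulate_cohort(self._planted_config())
        scores = score_pipeline(ds.cohort, ds.genome, ds.mappability,
                                ds.conservation, self.PARAMS)
        top = scores.iloc[0]
        assert (top["chrom"], top["start"]) == ("chr1", 250_000)

    def test_determinism(self):
        ds = simulate_cohort(self._planted_config())
        a = score_pipeline(ds.cohort, ds.genome, ds.mappability,
                           ds.conservation, self.PARAMS)
        b = score_pipeline(ds.cohort, ds.genome, ds.mappability,
                           ds.conservation, self.PARAMS)
        pd.testing.assert_frame_equal(a, b)

    def test_subset_closure_per_cohort(self):
        """Scoring one cancer type equals scoring its subset cohort."""
        ds = simulate_cohort(self._planted_config())
        sub = ds.cohort.subset_cohort("A")
        direct = score_pipeline(sub, ds.genome, ds.mappability,
                                ds.conservation, self.PARAMS)
        again = score_pipeline(
            Cohort(ds.cohort.df[ds.cohort.df["cohort"] == "A"]),
            ds.genome, ds.mappability, ds.conservation, self.PARAMS,
        )
        pd.testing.assert_frame_equal(direct, again)

    def test_scale_invariance_of_raw_recurrence(self):
        """Replicating the whole cohort k times leaves raw scores unchanged."""
        ds = simulate_cohort(self._planted_config())
        base = score_pipeline(ds.cohort, ds.genome, ds.mappability,
                              ds.conservation, self.PARAMS)
        df = ds.cohort.df
        tripled = pd.concat(
            [df.assign(sample=df["sample"] + f"_rep{k}") for k in range(3)],
            ignore_index=True,
        )
        scored = score_pipeline(
            Cohort(tripled), ds.genome, ds.mappability, ds.conservation, self.PARAMS
        )
        merged = base.merge(
            scored, on=["chrom", "start"], suffixes=("_1", "_3")
        )
        assert len(merged) == len(base)
        assert np.allclose(
            merged["raw_recurrence_1"], merged["raw_recurrence_3"]
        )

    def test_normalized_median_is_zero(self):
        ds = simulate_cohort(self._planted_config())
        scores = score_pipeline(ds.cohort, ds.genome, ds.mappability,
                                ds.conservation, self.PARAMS)
        defined = scores["norm_recurrence"].dropna()
        assert np.median(defined) == pytest.approx(0.0, abs=1e-12)

    def test_conservation_reranks_combined(self):
        """A high-conservation, mid-recurrence window overtakes under the
        combined score."""
        config = SimulationConfig(
            seed=3,
            n_chromosomes=1,
            chrom_length=500_000,
            cohorts={"A": 40},
            background_rate=2e-5,
            planted_hotspots=[
                PlantedRegion(GenomicInterval("chr1", 100_000, 100_050), 30),
                PlantedRegion(GenomicInterval("chr1", 300_000, 300_050), 12),
            ],
            conserved_elements=[(GenomicInterval("chr1", 300_000, 300_050), 6.0)],
        )
        ds = simulate_cohort(config)
        by_rec = score_pipeline(
            ds.cohort, ds.genome, ds.mappability, ds.conservation,
            ScoreParams(rank_by="recurrence", flank_size=100_000),
        )
        by_comb = score_pipeline(
            ds.cohort, ds.genome, ds.mappability, ds.conservation,
            ScoreParams(rank_by="combined", flank_size=100_000),
        )
        assert by_rec.iloc[0]["start"] == 100_000
        assert by_comb.iloc[0]["start"] == 300_000

    def test_low_mappability_window_not_scored(self):
        config = self._planted_config()
        config.low_mappability = [GenomicInterval("chr1", 250_000, 250_050)]
        ds = simulate_cohort(config)
        scores = score_pipeline(ds.cohort, ds.genome, ds.mappability,
                                ds.conservation, self.PARAMS)
        assert not ((scores["chrom"] == "chr1") & (scores["start"] == 250_000)).any()

    def test_rank_ties_broken_by_coordinate(self):
        # mirror-symmetric placement: both windows see identical flank
        # geometry, so raw scores tie exactly and order falls to coordinates
        cohort = _uniform_cohort(
            {f"S{i}": [100 + i, 9850 + i] for i in range(4)}
        )
        genome = GenomeIndex({"chr1": 10_000})
        scores = score_pipeline(cohort, genome, params=ScoreParams(flank_size=10_000))
        assert scores["raw_recurrence"].nunique() == 1
        assert scores["start"].tolist() == [100, 9850]
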