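import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import storysync as ss
from storysync.errors import InvalidInputError, SubgroupMismatchError
from storysync.isc import _segment_windows

from conftest import assert_loo_matches_oracle, brute_force_loo_spearman


class TestShiftForHemodynamics:
    def test_five_second_shift(self):
        x = np.arange(100.0)
        out = ss.shift_for_hemodynamics(x, 5, 1)
        assert out.size == 95
        assert out[0] == 5.0  # stimulus time 0 -> BOLD sample at 5 s

    def test_zero_shift_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(ss.shift_for_hemodynamics(x, 0, 1), x)

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.shift_for_hemodynamics(np.arange(8.0), 10, 1)

    def test_non_integer_shift_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.shift_for_hemodynamics(np.arange(20.0), 2.5, 2.0)


class TestLooSpearman:
    def test_identical_monotone_vectors(self):
        X = np.tile(np.arange(10.0), (4, 1))
        assert np.allclose(ss.loo_spearman(X), 1.0)

    def test_reversed_subject_gets_minus_one(self):
        X = np.tile(np.arange(10.0), (4, 1))
        X[0] = X[0][::-1]
        out = ss.loo_spearman(X)
        assert out[0] == pytest.approx(-1.0)
        assert np.all(out[1:] > 0)

    def test_zero_variance_flagged_not_zero(self):
        X = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0)])
        out = ss.loo_spearman(X)
        assert np.isnan(out[0])
        assert np.isfinite(out[1:]).all()

    def test_matches_scipy_on_pairs(self, rng):
        X = rng.standard_normal((5, 40))
        out = ss.loo_spearman(X)
        for i in range(5):
            others = X[[j for j in range(5) if j != i]].mean(axis=0)
            rho = sps.spearmanr(X[i], others).statistic
            assert out[i] == pytest.approx(rho, abs=1e-12)

    @pytest.mark.parametrize("n_subj,n_samp", [(3, 5), (4, 12), (5, 30)])
    def test_matches_brute_force_oracle(self, rng, n_subj, n_samp):
        for _ in range(20):
            X = rng.standard_normal((n_subj, n_samp))
            if rng.random() < 0.5:
                X = np.round(X)  # force ties
            assert_loo_matches_oracle(
                ss.loo_spearman(X), brute_force_loo_spearman(X)
            )

    def test_bounds(self, rng):
        X = rng.standard_normal((6, 25))
        out = ss.loo_spearman(X)
        assert np.all(np.abs(out) <= 1.0)


def _identical_subject_parcel(schedule, n_subjects=3, n_regions=4, seed=0):
    rng = np.random.default_rng(seed)
    story = schedule.stories[0]
    n_vol = int(schedule.duration_s(story))
    base = pd.DataFrame(rng.standard_normal((n_vol, n_regions)))
    return {s: {story: base.copy()} for s in range(n_subjects)}


class TestTemporalIsc:
    def test_identical_subjects_give_isc_one(self, schedule_one_story):
        parcel = _identical_subject_parcel(schedule_one_story)
        table = ss.temporal_isc(parcel, schedule_one_story)
        assert np.allclose(table["isc"], 1.0)
        assert len(table) == 3 * 5 * 4  # subject x condition x region

    def test_segments_are_mean_centered(self, schedule_one_story):
        # adding a per-segment constant to one subject leaves ISC unchanged
        parcel = _identical_subject_parcel(schedule_one_story, seed=2)
        table0 = ss.temporal_isc(parcel, schedule_one_story)
        bumped = {s: {0: d[0].copy()} for s, d in parcel.items()}
        rng = np.random.default_rng(5)
        df = bumped[0][0]
        for _, row in schedule_one_story.segments.iterrows():
            sl = slice(int(row["onset_s"]) + 5, int(row["offset_s"]) + 5)
            df.iloc[sl] += rng.uniform(-10, 10)
        table1 = ss.temporal_isc(bumped, schedule_one_story)
        assert np.allclose(table0["isc"], table1["isc"], atol=1e-12)

    def test_mixed_version_schedule_rejected(self, schedule_one_story):
        seg = schedule_one_story.segments.copy()
        seg.loc[0, "version"] = 2
        with pytest.raises(SubgroupMismatchError):
            ss.temporal_isc(
                _identical_subject_parcel(schedule_one_story), ss.Schedule(seg)
            )

    def test_planted_lambda_orders_condition_isc(self):
        lams = {"clear": 0.9, "+14 dB": 0.7, "+9 dB": 0.5, "+4 dB": 0.3,
                "-1 dB": 0.1}
        p = ss.null_params(
            n_subjects=10, n_regions=6, n_stories=1, segments_per_condition=6,
            lambda_by_condition=lams, seed=8,
        )
        ds = ss.simulate_dataset(p, include_voxels=False)
        table = ss.temporal_isc(ds.parcel, ds.schedule)
        means = table.groupby("condition")["isc"].mean()
        ordered = [means[c] for c in ss.CONDITIONS]
        assert all(a > b for a, b in zip(ordered, ordered[1:]))

    def test_isc_independent_of_mean_activation(self):
        """A planted clarity activation at its realistic scale must not move
        temporal ISC: segment mean-centering removes activation levels, so
        only HRF transients at segment edges can leak, and at the
        generator's default coupling that leakage sits below MC error."""
        lam = {c: 0.5 for c in ss.CONDITIONS}
        base = dict(n_subjects=8, n_regions=6, n_stories=1,
                    segments_per_condition=6, lambda_by_condition=lam, seed=9)
        quiet = ss.simulate_dataset(ss.null_params(**base), include_voxels=False)
        loud = ss.simulate_dataset(
            ss.null_params(condition_slope={"auditory": 0.2}, **base),
            include_voxels=False,
        )
        t_quiet = ss.temporal_isc(quiet.parcel, quiet.schedule)
        t_loud = ss.temporal_isc(loud.parcel, loud.schedule)
        audit = [r for r in quiet.truth.condition_slope
                 if loud.truth.condition_slope[r] != 0]
        for t in (t_quiet, t_loud):
            t.set_index(["subject", "condition", "region"], inplace=True)
        sel = t_quiet.index.get_level_values("region").isin(audit)
        diff = (t_loud["isc"][sel] - t_quiet["isc"][sel]).mean()
        assert abs(diff) < 0.05


class TestSpatialIsc:
    def _shared_pattern_voxels(self, schedule, n_subjects=3, n_regions=3,
                               n_vox=5, seed=0):
        rng = np.random.default_rng(seed)
        story = schedule.stories[0]
        n_vol = int(schedule.duration_s(story))
        patterns = rng.standard_normal((n_regions, n_vox))
        blocks = {
            r: np.tile(patterns[r][:, None], (1, n_vol)) for r in range(n_regions)
        }
        return {s: {story: {r: blocks[r].copy() for r in blocks}}
                for s in range(n_subjects)}

    def test_shared_pattern_gives_isc_one(self, schedule_one_story):
        voxels = self._shared_pattern_voxels(schedule_one_story)
        table = ss.spatial_isc(voxels, schedule_one_story)
        assert np.allclose(table["isc"], 1.0)

    def test_per_region_constant_leaves_isc_unchanged(self, schedule_one_story):
        voxels = self._shared_pattern_voxels(schedule_one_story, seed=3)
        t0 = ss.spatial_isc(voxels, schedule_one_story)
        voxels[0][0][1] = voxels[0][0][1] + 42.0  # constant across voxels
        t1 = ss.spatial_isc(voxels, schedule_one_story)
        assert np.allclose(t0["isc"], t1["isc"], atol=1e-12)

    def test_voxel_count_mismatch_rejected(self, schedule_one_story):
        voxels = self._shared_pattern_voxels(schedule_one_story)
        voxels[1][0][0] = voxels[1][0][0][:-1]
        with pytest.raises(InvalidInputError):
            ss.spatial_isc(voxels, schedule_one_story)

    def test_condition_specific_spatial_lambda_recovered(self):
        slam = {c: 0.1 for c in ss.CONDITIONS}
        slam["-1 dB"] = 0.9
        p = ss.null_params(
            n_subjects=8, n_regions=6, voxels_per_region=12, n_stories=1,
            segments_per_condition=4,
            spatial_lambda_by_condition=slam, seed=10,
        )
        ds = ss.simulate_dataset(p, include_voxels=True)
        table = ss.spatial_isc(ds.voxels, ds.schedule)
        means = table.groupby("condition")["isc"].mean()
        others = [means[c] for c in ss.CONDITIONS if c != "-1 dB"]
        assert means["-1 dB"] > max(others) + 0.2


class TestPoolSubgroups:
    def _table(self, subjects, version):
        return pd.DataFrame(
            {
                "subject": subjects,
                "version": version,
                "condition": "clear",
                "region": 0,
                "mode": "temporal",
                "isc": 0.5,
            }
        )

    def test_pooling_preserves_subjects_and_versions(self):
        pooled = ss.pool_subgroups(
            [self._table(range(7), 1), self._table(range(7, 14), 2),
             self._table(range(14, 20), 3)]
        )
        assert len(pooled) == 20
        assert set(pooled["version"]) == {1, 2, 3}

    def test_single_table_is_identity(self):
        t = self._table(range(5), 1)
        assert ss.pool_subgroups([t]).equals(t)

    def test_duplicate_subject_across_versions_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.pool_subgroups([self._table(range(5), 1), self._table(range(4, 9), 2)])


class TestSegmentWindows:
    def test_windows_use_stimulus_time_midpoints(self, schedule_one_story):
        wins = _segment_windows(schedule_one_story, 0, 595, 1.0)
        # full coverage of the shifted span, no overlaps
        all_idx = np.concatenate([idx for _, idx in wins])
        assert np.array_equal(np.sort(all_idx), np.arange(595))
        # truncated final window: last segment loses the shifted-away samples
        assert len(wins[-1][1]) == 25
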