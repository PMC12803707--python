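import numpy as np
import pandas as pd
import pytest

import storysync as ss
from storysync.errors import InvalidInputError


class TestExtractEpochs:
    def test_window_indices(self):
        x = np.arange(100.0)
        rows, kept = ss.extract_epochs(x, [50.0])
        assert kept.tolist() == [True]
        assert rows.shape == (1, 21)
        assert np.array_equal(rows[0], np.arange(40.0, 61.0))

    def test_incomplete_windows_excluded(self):
        x = np.arange(100.0)
        rows, kept = ss.extract_epochs(x, [5.0, 50.0, 95.0])
        assert kept.tolist() == [False, True, False]
        assert rows.shape == (1, 21)

    def test_no_complete_window_is_an_error(self):
        with pytest.raises(InvalidInputError):
            ss.extract_epochs(np.arange(15.0), [5.0])

    def test_event_time_rounds_to_nearest_volume(self):
        x = np.arange(100.0)
        rows, _ = ss.extract_epochs(x, [49.6])
        assert rows[0][10] == 50.0


class TestPostMinusPre:
    def test_constant_epoch_is_zero(self):
        assert ss.post_minus_pre(np.ones(21)) == 0.0

    def test_step_at_zero_gives_height(self):
        e = np.concatenate([np.zeros(10), np.full(11, 2.5)])
        assert ss.post_minus_pre(e) == pytest.approx(2.5)

    def test_linear_ramp(self):
        # epoch value equals its offset: mean(1..7) - mean(-7..-1) = 8
        e = np.arange(-10.0, 11.0)
        assert ss.post_minus_pre(e) == pytest.approx(8.0)

    def test_incomplete_epoch_rejected(self):
        with pytest.raises(InvalidInputError):
            ss.post_minus_pre(np.ones(20))

    def test_linear_in_the_epoch(self, rng):
        e = rng.standard_normal(21)
        f = rng.standard_normal(21)
        assert ss.post_minus_pre(3 * e - 2 * f) == pytest.approx(
            3 * ss.post_minus_pre(e) - 2 * ss.post_minus_pre(f), abs=1e-12
        )


class TestBoundaryContrasts:
    def test_zmap_zero_for_identical_event_types(self, rng):
        rows = []
        for subj in range(6):
            for region in range(3):
                v = rng.standard_normal()
                rows.append((subj, region, "boundary", "all", v, np.nan))
                rows.append((subj, region, "center", "all", v, np.nan))
        contrasts = pd.DataFrame(rows, columns=list(ss.events.CONTRAST_COLUMNS))
        zmap = ss.boundary_vs_center_zmap(contrasts, m=3)
        assert np.allclose(zmap["z"], 0.0)

    def test_sign_flip_flips_z(self, rng):
        rows = []
        for subj in range(8):
            for region in range(3):
                rows.append((subj, region, "boundary", "all",
                             rng.standard_normal() + 0.5, np.nan))
                rows.append((subj, region, "center", "all",
                             rng.standard_normal(), np.nan))
        contrasts = pd.DataFrame(rows, columns=list(ss.events.CONTRAST_COLUMNS))
        flipped = contrasts.assign(value=-contrasts["value"])
        z0 = ss.boundary_vs_center_zmap(contrasts, m=3)["z"]
        z1 = ss.boundary_vs_center_zmap(flipped, m=3)["z"]
        assert np.allclose(z0.to_numpy(), -z1.to_numpy(), atol=1e-10)

    def test_planted_transient_found_in_its_network(self):
        p = ss.SynthParams(
            n_subjects=12, n_regions=21, n_stories=2, segments_per_condition=2,
            lambda_by_condition={c: 0.0 for c in ss.CONDITIONS},
            envelope_beta={}, condition_slope={},
            boundary_amp={"frontoparietal": 3.0}, seed=6,
        )
        ds = ss.simulate_dataset(p, include_voxels=False)
        contrasts = ss.boundary_contrasts(ds.parcel, ds.events)
        zmap = ss.boundary_vs_center_zmap(contrasts, m=p.n_regions)
        thr = ss.bonferroni_z_threshold(0.05, p.n_regions)
        planted = [r for r, a in ds.truth.boundary_amp.items() if a > 0]
        z_by_region = zmap.set_index("region")["z"]
        assert min(z_by_region[r] for r in planted) > thr

    def test_interaction_exact_zero_on_constant_signals(self):
        rows = []
        for subj in range(5):
            for et in ("boundary", "center"):
                for grp in ("high", "low"):
                    rows.append((subj, 0, et, grp, 0.0, np.nan))
        contrasts = pd.DataFrame(rows, columns=list(ss.events.CONTRAST_COLUMNS))
        zmap = ss.clarity_interaction_zmap(contrasts, m=1)
        assert zmap["z"].iloc[0] == 0.0

    def test_clarity_split_uses_segment_of_event_onset(self, tiny_dataset):
        ds = tiny_dataset
        contrasts = ss.boundary_contrasts(
            ds.parcel, ds.events, schedule=ds.schedule, clarity_split=True
        )
        assert set(contrasts["clarity_group"]) <= {"all", "high", "low"}
        # split epochs cannot outnumber the unsplit analysis
        n_all = (contrasts["clarity_group"] == "all").sum()
        n_split = (contrasts["clarity_group"] != "all").sum()
        assert n_all > 0 and n_split > 0


class TestNetworkTimecourses:
    def test_epoch_network_average_commutes(self, tiny_dataset):
        ds = tiny_dataset
        means = ss.epoch_means(ds.parcel, ds.events, "boundary")
        subj = ds.subjects[0]
        via_regions = ss.network_average(means[subj], ds.parcellation)
        courses = ss.network_epoch_timecourses(
            ds.parcel, ds.events, ds.parcellation, "boundary"
        )
        for net in via_regions.columns:
            assert np.allclose(
                courses[net].loc[subj].to_numpy(),
                via_regions[net].to_numpy(),
                atol=1e-10,
            )

    def test_identical_conditions_give_empty_mask(self, rng):
        a = {"visual": pd.DataFrame(rng.standard_normal((6, 21)),
                                    columns=np.arange(-10.0, 11.0))}
        stats = ss.network_timecourse_stats(a, {"visual": a["visual"].copy()})
        assert not stats["significant"].any()

    def test_mask_subset_of_raw_threshold(self, rng):
        a = {"visual": pd.DataFrame(rng.standard_normal((8, 21)),
                                    columns=np.arange(-10.0, 11.0))}
        b = {"visual": pd.DataFrame(rng.standard_normal((8, 21)) + 0.8,
                                    columns=np.arange(-10.0, 11.0))}
        stats = ss.network_timecourse_stats(a, b, q=0.05)
        assert stats.loc[stats["significant"], "p"].le(0.05).all()


class TestRmAnova2x2:
    @staticmethod
    def _cells(y):
        n = y.shape[0]
        rows = [
            (s, et, grp, y[s, i, j])
            for s in range(n)
            for i, et in enumerate(("boundary", "center"))
            for j, grp in enumerate(("high", "low"))
        ]
        return pd.DataFrame(
            rows, columns=["subject", "event_type", "clarity_group", "value"]
        )

    def test_all_identical_cells_give_zero_f(self):
        y = np.tile(np.arange(6.0)[:, None, None], (1, 2, 2))
        res = ss.rm_anova_2x2(self._cells(y)).set_index("effect")
        assert np.allclose(res["F"], 0.0)

    def test_interaction_f_equals_squared_paired_t(self, rng):
        for _ in range(10):
            y = rng.standard_normal((10, 2, 2))
            res = ss.rm_anova_2x2(self._cells(y)).set_index("effect")
            dd = (y[:, 0, 0] - y[:, 0, 1]) - (y[:, 1, 0] - y[:, 1, 1])
            t = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
            assert abs(res.loc["interaction", "F"] - t**2) < 1e-10
            a = y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)
            t_a = a.mean() / (a.std(ddof=1) / np.sqrt(len(a)))
            assert abs(res.loc["event_type", "F"] - t_a**2) < 1e-10

    def test_matches_generic_rm_anova_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.standard_normal((12, 2, 2))
        cells = self._cells(y)
        mine = ss.rm_anova_2x2(cells).set_index("effect")
        ref = pingouin.rm_anova(
            data=cells, dv="value", within=["event_type", "clarity_group"],
            subject="subject",
        ).set_index("Source")
        assert mine.loc["event_type", "F"] == pytest.approx(
            ref.loc["event_type", "F"], abs=1e-8
        )
        assert mine.loc["clarity", "F"] == pytest.approx(
            ref.loc["clarity_group", "F"], abs=1e-8
        )
        assert mine.loc["interaction", "F"] == pytest.approx(
            ref.loc["event_type * clarity_group", "F"], abs=1e-8
        )

    def test_incomplete_subject_excluded(self, rng):
        y = rng.standard_normal((5, 2, 2))
        cells = self._cells(y)
        cells = cells[~((cells["subject"] == 0)
                        & (cells["event_type"] == "center")
                        & (cells["clarity_group"] == "low"))]
        res = ss.rm_anova_2x2(cells)
        assert (res["df2"] == 3).all()  # one subject dropped


class TestPeakLatency:
    def test_boundary_transient_mechanism_peaks_at_five_seconds(self):
        """With the noise floor removed, the boundary-locked epoch average
        is the HRF transient itself: maximum exactly 5 s post-boundary."""
        p = ss.null_params(
            n_subjects=3, n_regions=14, n_stories=1, segments_per_condition=4,
            lambda_by_condition={c: 0.0 for c in ss.CONDITIONS},
            boundary_amp={"frontoparietal": 3.0}, noise_sd=1e-9, seed=1,
        )
        ds = ss.simulate_dataset(p, include_voxels=False)
        courses = ss.network_epoch_timecourses(
            ds.parcel, ds.events, ds.parcellation, "boundary"
        )
        grand = courses["frontoparietal"].mean(axis=0)
        assert float(grand.idxmax()) == 5.0
        # epochs in unaffected networks stay flat
        assert courses["visual"].to_numpy().std() < 1e-6
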