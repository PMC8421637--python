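"""Planted designs, synthetic scans, ground-truth rates, and cohorts."""

import numpy as np
import pytest
from scipy import stats as sps

from netswitch.connectivity import SlidingWindowConfig, sliding_windows
from netswitch.synthetic import (
    PlantedDesign,
    ScheduleError,
    default_atlas,
    generate_cohort,
    generate_scan,
    module_timeline,
    planted_switch_rate,
)

SMALL_WINDOW = SlidingWindowConfig(width=20, step=1, trim_initial=0)


def small_design(**kwargs):
    defaults = dict(n_nodes=6, n_modules=2, n_volumes=120)
    defaults.update(kwargs)
    return PlantedDesign.static(**defaults)


class TestDesignValidation:
    def test_schedule_must_tile(self):
        with pytest.raises(ScheduleError, match="tile"):
            PlantedDesign(
                n_nodes=2,
                n_volumes=10,
                partition_schedule=(((0, 4), (0, 1)), ((5, 10), (0, 1))),
            )
        with pytest.raises(ScheduleError, match="covers"):
            PlantedDesign(
                n_nodes=2, n_volumes=10, partition_schedule=(((0, 4), (0, 1)),)
            )

    def test_labels_must_cover_all_nodes(self):
        with pytest.raises(ScheduleError, match="labels"):
            PlantedDesign(
                n_nodes=3, n_volumes=5, partition_schedule=(((0, 5), (0, 1)),)
            )

    def test_event_bounds_checked(self):
        with pytest.raises(ScheduleError, match="node"):
            small_design().with_events([(99, 5, 1)])
        with pytest.raises(ScheduleError, match="volume"):
            small_design().with_events([(0, 500, 1)])

    def test_events_override_schedule_persistently(self):
        d = small_design().with_events([(2, 50, 1), (2, 90, 0)])
        tl = module_timeline(d)
        assert tl[2, 49] == 0 and tl[2, 50] == 1 and tl[2, 89] == 1 and tl[2, 90] == 0


class TestGenerateScan:
    def test_deterministic_given_seed(self):
        d = small_design()
        a = generate_scan(d, 42)
        b = generate_scan(d, 42)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.motion, b.motion)
        c = generate_scan(d, 43)
        assert not np.array_equal(a.values, c.values)

    def test_noiseless_limit_correlations_approach_one(self):
        d = small_design(within_module_corr=0.6, noise_sd=1e-6)
        scan = generate_scan(d, 1)
        for a, b in [(0, 1), (3, 4)]:  # same-module pairs
            r = np.corrcoef(scan.values[a][:20], scan.values[b][:20])[0, 1]
            assert r > 0.999

    @pytest.mark.parametrize("noise_sd", [None, 0.5, 1.5])
    def test_closed_form_within_module_correlation(self, noise_sd):
        """Same-module correlation matches c/(c + sigma^2) from the loading model."""
        c = 0.5
        d = PlantedDesign.static(
            n_nodes=2, n_modules=1, n_volumes=512,
            within_module_corr=c, noise_sd=noise_sd,
        )
        sigma2 = (noise_sd if noise_sd is not None else np.sqrt(1 - c)) ** 2
        expected = c / (c + sigma2)
        rs = [
            np.corrcoef(generate_scan(d, s).values)[0, 1] for s in range(40)
        ]
        assert np.mean(rs) == pytest.approx(expected, abs=0.05)

    def test_correlation_monotone_in_noise(self):
        means = []
        for sd in [0.3, 0.8, 1.5]:
            d = PlantedDesign.static(
                n_nodes=2, n_modules=1, n_volumes=512,
                within_module_corr=0.5, noise_sd=sd,
            )
            means.append(
                np.mean([np.corrcoef(generate_scan(d, s).values)[0, 1] for s in range(20)])
            )
        assert means[0] > means[1] > means[2]

    def test_switch_event_drops_correlation_to_old_module(self):
        """The pre-to-post correlation drop matches the loading change.

        Before the event nodes 0 and 1 share a latent (expected r =
        c/(c+sigma^2)); after, they are in different modules (expected 0).
        """
        c = 0.6
        d = PlantedDesign(
            n_nodes=4,
            n_volumes=250,
            partition_schedule=(((0, 250), (0, 0, 1, 1)),),
            within_module_corr=c,
        ).with_events([(1, 125, 1)])
        pre_r, post_r = [], []
        for s in range(60):
            v = generate_scan(d, s).values
            pre_r.append(np.corrcoef(v[0, :125], v[1, :125])[0, 1])
            post_r.append(np.corrcoef(v[0, 125:], v[1, 125:])[0, 1])
        drop = np.mean(pre_r) - np.mean(post_r)
        assert drop == pytest.approx(c / (c + (1 - c)), abs=0.07)
        assert np.mean(post_r) == pytest.approx(0.0, abs=0.07)

    def test_band_limited_spectrum(self):
        d = small_design(n_volumes=256)
        scan = generate_scan(d, 5)
        freqs = np.fft.rfftfreq(256, d=2.0)
        power = np.abs(np.fft.rfft(scan.values[0])) ** 2
        out_band = power[(freqs < 0.01 - 1e-9) | (freqs > 0.10 + 1e-9)]
        assert out_band.max() < 1e-18 * power.max()


class TestPlantedSwitchRate:
    def test_static_schedule_all_zero(self):
        assert np.all(planted_switch_rate(small_design(), SMALL_WINDOW) == 0)

    def test_single_event_direct_enumeration(self):
        """One event: that node flips majority once; oracle counts windows."""
        d = small_design().with_events([(2, 60, 1)])
        rates = planted_switch_rate(d, SMALL_WINDOW)
        intervals = sliding_windows(d.n_volumes, SMALL_WINDOW)
        # independent enumeration of window majorities for node 2
        tl = module_timeline(d)[2]
        majorities = []
        for a, b in intervals:
            seg = tl[a:b]
            vals, counts = np.unique(seg, return_counts=True)
            majorities.append(vals[np.argmax(counts)])
        expected = np.count_nonzero(np.diff(majorities)) / (len(intervals) - 1)
        assert rates[2] == pytest.approx(expected)
        assert rates[2] == pytest.approx(1 / (len(intervals) - 1))
        assert np.all(np.delete(rates, 2) == 0)

    def test_relabeled_every_volume_saturates(self):
        d = small_design(n_volumes=60).with_events(
            [(0, v, v % 2) for v in range(1, 60)]
        )
        w = SlidingWindowConfig(width=3, step=1, trim_initial=0)
        assert planted_switch_rate(d, w)[0] > 0.9

    def test_rates_within_unit_interval(self, rng):
        d = small_design().with_events(
            [(int(rng.integers(6)), int(rng.integers(1, 119)), int(rng.integers(2))) for _ in range(25)]
        )
        rates = planted_switch_rate(d, SMALL_WINDOW)
        assert np.all((rates >= 0) & (rates <= 1))


class TestGenerateCohort:
    DESIGN = {
        "dependent": PlantedDesign.static(n_nodes=10, n_modules=2, n_volumes=240),
        "control": PlantedDesign.static(n_nodes=10, n_modules=2, n_volumes=240),
    }
    WINDOW = SlidingWindowConfig(width=50, step=1, trim_initial=10)

    def cohort(self, n=(4, 4), effect=0.0, seed=0, **kw):
        kw.setdefault("events_mean", 4)
        kw.setdefault("events_sd", 2)
        return generate_cohort(
            n, self.DESIGN, effect=effect, seed=seed, window=self.WINDOW, **kw
        )

    def test_arm_sizes_and_groups(self):
        cohort = self.cohort(n=(24, 26))
        counts = cohort.subjects["group"].value_counts()
        assert counts["dependent"] == 24 and counts["control"] == 26
        assert len(cohort.outcomes) == 2 * 50

    def test_zero_effect_zero_expected_paired_difference(self):
        """With effect 0, planted post rates equal pre rates exactly."""
        cohort = self.cohort(n=(6, 6), effect=0.0)
        for sub in cohort.subjects_detail:
            assert np.array_equal(sub.planted_rate, sub.planted_rate_post)

    def test_positive_effect_raises_planted_rates(self):
        """Configured rate increment is realized up to event-placement loss."""
        cohort = self.cohort(n=(6, 6), effect=0.01, seed=1)
        diffs = [
            sub.planted_rate_post.mean() - sub.planted_rate.mean()
            for sub in cohort.subjects_detail
        ]
        assert np.mean(diffs) == pytest.approx(0.01, rel=0.35)

    def test_deterministic_and_stable_under_extension(self):
        a = self.cohort(n=(4, 4), seed=9)
        b = self.cohort(n=(4, 4), seed=9)
        assert a.subjects.equals(b.subjects)
        assert a.outcomes.equals(b.outcomes)
        bigger = self.cohort(n=(7, 4), seed=9)
        first = bigger.subjects.loc[a.subjects.index]
        assert first.equals(a.subjects)

    def test_score_rate_correlation_recovered(self):
        """Configured BQDS-rate copula rho 0.9 shows up as sample Spearman."""
        rhos = []
        for draw in range(30):
            cohort = self.cohort(
                n=(60, 2),
                seed=100 + draw,
                events_mean=10,
                events_sd=4,
                score_rate_corr={"BQDS": 0.9},
            )
            dep = [s for s in cohort.subjects_detail if s.group == "dependent"]
            scores = [s.scores["BQDS"] for s in dep]
            rates = [s.planted_rate.mean() for s in dep]
            rhos.append(sps.spearmanr(scores, rates).statistic)
        assert np.mean(rhos) == pytest.approx(0.9, abs=0.05)

    def test_scans_realized_lazily_and_deterministically(self):
        cohort = self.cohort(n=(2, 2), seed=3)
        sub = cohort.subjects_detail[0]
        scan1 = sub.scan_pre
        assert scan1.values.shape == (10, 240)
        again = self.cohort(n=(2, 2), seed=3).subjects_detail[0].scan_pre
        assert np.array_equal(scan1.values, again.values)

    def test_mean_fd_positive_and_from_motion(self):
        cohort = self.cohort(n=(2, 2), seed=4)
        from netswitch.connectivity import mean_fd

        sub = cohort.subjects_detail[0]
        assert cohort.subjects.loc[sub.subject_id, "mean_fd"] == pytest.approx(
            mean_fd(sub.scan_pre.motion)
        )

    def test_default_atlas_covers_all_six_subnetworks(self):
        atlas = default_atlas([f"n{i:03d}" for i in range(160)])
        assert len(atlas.subnetworks()) == 6
        sizes = [len(atlas.members(s)) for s in atlas.subnetworks()]
        assert sum(sizes) == 160
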