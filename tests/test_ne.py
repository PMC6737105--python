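import numpy as np
import pandas as pd
import pytest

from popgenpipe import (
    NeSettings,
    NeTrajectory,
    adjust_r2,
    contemporary_ne_ld,
    effective_segments,
    harmonic_mean_ne,
    historical_ne,
    marker_requirements,
    pairwise_r2,
    regress_contemporary,
    round_hundred,
    sved_ne,
)
from popgenpipe.ne_inference import MAPPINGS


class TestSvedEquation:
    def test_round_trip_1000_random_triples(self, rng):
        for mapping, f in MAPPINGS.items():
            n = 1000 if mapping == "identity" else 200
            ne = rng.uniform(10, 5000, n)
            c = rng.uniform(1e-4, 0.5, n)
            alpha = rng.uniform(0.5, 2.5, n)
            for Ne_i, c_i, a_i in zip(ne, c, alpha):
                r2 = 1.0 / (a_i + 4 * f(c_i) * Ne_i)
                back = sved_ne(r2, c_i, alpha=a_i, mapping=mapping)
                assert abs(back - Ne_i) / Ne_i < 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sved_ne(-0.1, 0.25)
        with pytest.raises(ValueError):
            sved_ne(0.1, 0.0)
        with pytest.raises(ValueError):
            sved_ne(0.1, 0.6)
        with pytest.raises(ValueError):
            sved_ne(0.9, 0.25, alpha=2.0)  # 1/r2 < alpha

    def test_mappings_agree_at_small_c(self):
        c = 1e-4
        for f in MAPPINGS.values():
            assert f(c) == pytest.approx(c, rel=1e-3)


class TestAdjustment:
    def test_one_over_s(self):
        assert adjust_r2(np.array([0.2]), S=55)[0] == pytest.approx(0.2 - 1 / 55)

    def test_one_over_2s(self):
        assert adjust_r2(np.array([0.2]), S=55, correction="1/(2S)")[0] == pytest.approx(
            0.2 - 1 / 110
        )

    def test_small_s_rejected(self):
        with pytest.raises(ValueError):
            adjust_r2(np.array([0.2]), S=1)


class TestHistorical:
    def test_bin_to_generation_mapping(self, small_wf):
        m, _ = small_wf
        settings = NeSettings(alpha=1.0)
        pairs = pairwise_r2(m, window_bp=settings.n_bins * settings.bin_size)
        traj = historical_ne(pairs, S=m.calls.shape[0], settings=settings)
        pts = traj.points
        # t = 1/(2c), c in Morgans at the bin midpoint
        for _, row in pts.iterrows():
            assert row["t"] == max(1, round(1.0 / (2 * row["c"])))
        # generations decrease as distance (c) grows
        assert pts.sort_values("c")["t"].is_monotonic_decreasing

    def test_recovers_order_of_magnitude(self, small_wf):
        m, _ = small_wf  # constant N = 60
        settings = NeSettings(alpha=1.0, min_pairs_per_bin=20)
        pairs = pairwise_r2(m, window_bp=settings.n_bins * settings.bin_size)
        traj = historical_ne(pairs, S=m.calls.shape[0], settings=settings)
        hm = harmonic_mean_ne(traj.points["ne"].dropna())
        assert 20 < hm < 180

    def test_all_bins_sparse_raises(self):
        from popgenpipe import make_two_locus_sample

        m = make_two_locus_sample(0.5, 0.5, 0.1, 100, seed=1)
        pairs = pairwise_r2(m)
        settings = NeSettings(min_pairs_per_bin=50)
        with pytest.raises(ValueError, match="no usable distance bins"):
            historical_ne(pairs, S=100, settings=settings)


class TestContemporary:
    def test_known_drift_inversion(self):
        # feed the inversion a synthetic mean r2 equal to the Waples
        # expectation for a chosen Ne and check the closed-form inverse
        from popgenpipe.ne_inference import _waples_expected_sample_r2, _waples_invert

        S = 55
        for mating, (a, b4) in (("random", (1 / 3, 2.76)), ("monogamy", (2 / 3, 7.2))):
            for Ne in (50.0, 159.0, 1000.0):
                # the inversion solves r2' Ne^2 - a Ne + b = 0, i.e. the
                # drift expectation r2' = a/Ne - b/Ne^2 with 4b = b4
                r2_drift = a / Ne - (b4 / 4) / Ne**2
                back = _waples_invert(r2_drift, mating=mating, S=S)
                assert back == pytest.approx(Ne, rel=1e-9)

    def test_expected_sample_r2_regimes(self):
        from popgenpipe.ne_inference import _waples_expected_sample_r2

        assert _waples_expected_sample_r2(55) == pytest.approx(1 / 55 + 3.19 / 55**2)
        assert _waples_expected_sample_r2(20) == pytest.approx(
            0.0018 + 0.907 / 20 + 4.44 / 400
        )

    def test_runs_on_simulated_data(self, wf4):
        m, _ = wf4
        ne, ci = contemporary_ne_ld(m, mating="monogamy", seed=0)
        assert ne > 0
        assert ci[0] < ne < ci[1]

    def test_two_chromosomes_cannot_jackknife(self, small_wf):
        # leave-one-chromosome-out with 2 chromosomes leaves no
        # between-chromosome pairs, so the CI is undefined
        m, _ = small_wf
        ne, ci = contemporary_ne_ld(m, mating="monogamy", seed=0)
        assert ne > 0
        assert np.isnan(ci[0]) and np.isnan(ci[1])

    def test_invalid_mating(self, small_wf):
        m, _ = small_wf
        with pytest.raises(ValueError):
            contemporary_ne_ld(m, mating="asexual")


class TestRegression:
    def _traj(self, rows):
        pts = pd.DataFrame(rows, columns=["t", "ne", "c", "mean_r2_adj", "n_pairs"])
        return NeTrajectory(points=pts, settings=NeSettings(), sample_size=55,
                            per_chromosome={})

    def test_exact_line(self):
        traj = self._traj([(5, 100, 0.1, 0.01, 100), (15, 200, 1 / 30, 0.01, 100)])
        # the line through (5,100) and (15,200) is Ne = 50 + 10 t
        assert regress_contemporary(traj) == pytest.approx(60.0)

    def test_window_keeps_most_recent_points(self):
        # t_window counts the most recent (smallest-t) trajectory points
        traj = self._traj(
            [(5, 100, 0.1, 0.01, 100), (15, 200, 1 / 30, 0.01, 100),
             (500, 9000, 0.001, 0.01, 100)]
        )
        assert regress_contemporary(traj, t_window=2) == pytest.approx(60.0)

    def test_default_uses_t_up_to_100(self):
        traj = self._traj(
            [(5, 100, 0.1, 0.01, 100), (15, 200, 1 / 30, 0.01, 100),
             (500, 9000, 0.001, 0.01, 100)]
        )
        assert regress_contemporary(traj) == pytest.approx(60.0)

    def test_needs_two_points(self):
        traj = self._traj([(5, 100, 0.1, 0.01, 100)])
        with pytest.raises(ValueError):
            regress_contemporary(traj)


class TestDeskArithmetic:
    def test_round_hundred(self):
        assert round_hundred(9412) == 9400
        assert round_hundred(9450) == 9500
        assert round_hundred(78.2 * 4 * 14.8) == 4600

    def test_harmonic_mean(self):
        assert harmonic_mean_ne([2, 2, 2]) == pytest.approx(2.0)
        assert harmonic_mean_ne([1, 4, 4]) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            harmonic_mean_ne([])

    def test_effective_segments_and_requirements(self):
        raw, rounded = effective_segments(159, 14.8)
        assert raw == pytest.approx(4 * 159 * 14.8)
        assert rounded == 9400
        req = marker_requirements(159, 14.8)
        assert req.markers_10NeL_rounded == round_hundred(10 * 159 * 14.8)
        assert req.individuals_2NeL_rounded == round_hundred(2 * 159 * 14.8)
        assert req.Me_rounded == 9400
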