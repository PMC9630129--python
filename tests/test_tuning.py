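"""Place maps, Skaggs information, spatial coherence, phase coupling and
rate matching."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1

from thetapop import (SimConfig, ValidationError, make_place_map, phase_coupling,
                      rate_match, simulate_trajectory, spatial_coherence,
                      spatial_information, spatial_information_null)
from thetapop.tuning import GAMMA_MIN_SPIKES, PlaceMap


def uniform_position(duration=600.0, rate=25.0, side=41.0, seed=0):
    """Dense pseudo-uniform coverage of the arena."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    t = np.arange(n) / rate
    return pd.DataFrame({"time_s": t,
                         "x_cm": rng.uniform(0, side, n),
                         "y_cm": rng.uniform(0, side, n)})


def manual_map(rate_map, occupancy, bin_size=1.0):
    rate = np.asarray(rate_map, dtype=float)
    occ = np.asarray(occupancy, dtype=float)
    return PlaceMap(spike_map=rate * occ, occupancy=occ, rate_map=rate,
                    raw_rate_map=rate, bin_size=bin_size, smoothing_sd=0.0,
                    arena_side=rate.shape[0] * bin_size)


class TestPlaceMap:
    def test_41cm_arena_gives_30x30_grid(self):
        pos = uniform_position(duration=120.0)
        pm = make_place_map(np.array([10.0, 20.0]), pos)
        assert pm.rate_map.shape == (30, 30)

    def test_unmodulated_unit_flat_map(self):
        """5-Hz Poisson unit on a real trajectory: rate ~5 Hz, CV < 0.2."""
        rng = np.random.default_rng(1)
        duration = 600.0
        pos = simulate_trajectory(SimConfig(duration=duration, rng_seed=14))
        spikes = np.sort(rng.uniform(0, duration, rng.poisson(5.0 * duration)))
        pm = make_place_map(spikes, pos)
        vals = pm.rate_map[pm.visited]
        assert abs(np.mean(vals) - 5.0) < 0.5
        assert np.std(vals) / np.mean(vals) < 0.2

    def test_unsmoothed_spikes_land_in_single_bin(self):
        pos = uniform_position(duration=300.0)
        # park position at a known point whenever spikes occur
        pos.loc[1000:1100, ["x_cm", "y_cm"]] = 20.5
        spikes = pos["time_s"].iloc[1005:1095].to_numpy()
        pm = make_place_map(spikes, pos, smoothing_sd=0.0)
        nz = np.argwhere(np.nan_to_num(pm.raw_rate_map) > 0)
        assert len(nz) == 1

    def test_zero_occupancy_rejected(self):
        pos = pd.DataFrame({"time_s": [0.0], "x_cm": [1.0], "y_cm": [1.0]})
        with pytest.raises(ValidationError):
            make_place_map(np.array([0.5]), pos)

    def test_field_center_recovered_from_argmax(self):
        """Simulated Gaussian fields peak within 2 bins of the true center."""
        from thetapop import (GroundTruthUnit, LaserEvents, simulate_lfp,
                              simulate_spikes)
        cfg = SimConfig(duration=600.0, common_gain_sd=0.0, rng_seed=8)
        pos = simulate_trajectory(cfg)
        _, phase = simulate_lfp(cfg)
        laser = LaserEvents(np.empty(0), np.empty(0), 0.0, "none")
        units = [GroundTruthUnit(f"u{i}", "CA1", "principal", base_rate=8.0,
                                 place_center=c, place_width=6.0)
                 for i, c in enumerate([(12.0, 12.0), (28.0, 15.0), (20.0, 30.0)])]
        table = simulate_spikes(units, pos, phase, laser, cfg)
        for u in units:
            pm = make_place_map(table.times(u.unit_id), pos)
            idx = np.unravel_index(np.nanargmax(np.nan_to_num(pm.rate_map)),
                                   pm.rate_map.shape)
            center_bin = ((idx[0] + 0.5) * pm.bin_size, (idx[1] + 0.5) * pm.bin_size)
            assert np.hypot(center_bin[0] - u.place_center[0],
                            center_bin[1] - u.place_center[1]) <= 2 * pm.bin_size * np.sqrt(2)


class TestSpatialInformation:
    def test_constant_map_carries_zero_information(self):
        pm = manual_map(np.full((5, 5), 3.0), np.ones((5, 5)))
        assert spatial_information(pm) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_example(self):
        pm = manual_map(np.array([[2.0, 0.0]]), np.array([[1.0, 1.0]]))
        assert spatial_information(pm) == pytest.approx(1.0)

    def test_four_bin_one_hot_two_bits(self):
        pm = manual_map(np.array([[4.0, 0.0], [0.0, 0.0]]), np.ones((2, 2)))
        assert spatial_information(pm) == pytest.approx(2.0)

    def test_nonnegative_and_scale_invariant(self):
        rng = np.random.default_rng(2)
        rates = rng.uniform(0, 10, (8, 8))
        occ = rng.uniform(0.2, 1.0, (8, 8))
        info = spatial_information(manual_map(rates, occ))
        info_scaled = spatial_information(manual_map(7.5 * rates, occ))
        assert info >= 0
        assert info_scaled == pytest.approx(info, rel=1e-9)

    def test_null_distribution_seeded_and_discriminating(self):
        from thetapop import (GroundTruthUnit, LaserEvents, simulate_lfp,
                              simulate_spikes)
        cfg = SimConfig(duration=300.0, common_gain_sd=0.0, rng_seed=9)
        pos = simulate_trajectory(cfg)
        _, phase = simulate_lfp(cfg)
        laser = LaserEvents(np.empty(0), np.empty(0), 0.0, "none")
        unit = GroundTruthUnit("u0", "CA1", "principal", base_rate=8.0,
                               place_center=(15.0, 25.0), place_width=5.0)
        table = simulate_spikes([unit], pos, phase, laser, cfg)
        spikes = table.times("u0")
        obs = spatial_information(make_place_map(spikes, pos))
        null_a = spatial_information_null(spikes, pos, n_shuffles=30,
                                          rng=np.random.default_rng(5))
        null_b = spatial_information_null(spikes, pos, n_shuffles=30,
                                          rng=np.random.default_rng(5))
        assert np.array_equal(null_a, null_b)
        assert obs > np.quantile(null_a, 0.95)

    def test_short_session_rejected_for_null(self):
        pos = uniform_position(duration=30.0)
        with pytest.raises(ValidationError):
            spatial_information_null(np.array([1.0, 2.0]), pos, n_shuffles=2)


class TestCoherence:
    def test_linear_ramp_perfectly_coherent(self):
        ramp = np.add.outer(np.arange(10.0), np.arange(10.0))
        pm = manual_map(ramp, np.ones((10, 10)))
        assert spatial_coherence(pm) == pytest.approx(1.0, abs=1e-9)

    def test_iid_noise_map_incoherent(self):
        rng = np.random.default_rng(3)
        pm = manual_map(rng.uniform(0, 5, (30, 30)), np.ones((30, 30)))
        assert abs(spatial_coherence(pm)) < 0.2

    def test_constant_map_undefined(self):
        pm = manual_map(np.full((6, 6), 2.0), np.ones((6, 6)))
        with pytest.warns(UserWarning):
            assert np.isnan(spatial_coherence(pm))

    def test_too_few_visited_bins_rejected(self):
        pm = manual_map(np.ones((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValidationError):
            spatial_coherence(pm)


class TestPhaseCoupling:
    def test_single_phase_gives_unit_mrl(self):
        pc = phase_coupling(np.full(40, 90.0))
        assert pc.mrl == pytest.approx(1.0)
        assert pc.preferred_phase == pytest.approx(90.0)

    def test_symmetric_phases_cancel(self):
        pc = phase_coupling(np.array([0.0, 90.0, 180.0, 270.0]))
        assert pc.mrl == pytest.approx(0.0, abs=1e-12)

    def test_hand_vector_sum(self):
        pc = phase_coupling(np.array([0.0, 0.0, 90.0]))
        assert pc.mrl == pytest.approx(np.sqrt(5) / 3)
        assert pc.preferred_phase == pytest.approx(np.degrees(np.arctan2(1, 2)))

    def test_mrl_matches_von_mises_theory_and_pingouin(self):
        """MRL -> I1(k)/I0(k) within 0.02 at 10,000 spikes (k = 1)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        phases = np.degrees(rng.vonmises(0.5, 1.0, 10_000))
        pc = phase_coupling(phases)
        assert pc.mrl == pytest.approx(i1(1.0) / i0(1.0), abs=0.02)
        assert pc.mrl == pytest.approx(float(pingouin.circ_r(np.radians(phases))),
                                       abs=1e-9)

    def test_nan_phases_dropped_and_empty_rejected(self):
        pc = phase_coupling(np.array([np.nan, 30.0, np.nan]))
        assert pc.n_spikes == 1
        with pytest.raises(ValidationError):
            phase_coupling(np.array([np.nan]))

    def test_gamma_variant_requires_200_spikes(self):
        with pytest.raises(ValidationError):
            phase_coupling(np.zeros(150), min_spikes=GAMMA_MIN_SPIKES)


class TestRateMatch:
    def test_exact_duplicates_matched_perfectly(self):
        refs = {"a": 2.0, "b": 0.7}
        cands = {"x": 2.0, "y": 0.7, "z": 5.0}
        m = rate_match(refs, cands)
        assert m["a"] == ("x", pytest.approx(0.0))
        assert m["b"] == ("y", pytest.approx(0.0))

    def test_log_metric_prefers_multiplicative_closeness(self):
        m = rate_match({"r": 2.0}, {"half": 1.0, "ninety": 1.8})
        assert m["r"][0] == "ninety"

    def test_insufficient_candidates_flagged(self):
        with pytest.warns(UserWarning):
            m = rate_match({"a": 1.0, "b": 2.0}, {"x": 1.5})
        assert sum(v is None for v in m.values()) == 1

    def test_empty_candidates(self):
        with pytest.warns(UserWarning):
            m = rate_match({"a": 1.0}, {})
        assert m["a"] is None
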