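"""Population matrices, Gini/Hoyer sparsity, silencing responses,
co-firing and dimensionality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetapop import (LaserEvents, SimConfig, ValidationError,
                      build_population_matrix, cofiring_matrix,
                      compare_dimensionality, dimensionality, epoch_pair_windows,
                      gini_sparsity, hoyer_sparsity, make_session,
                      paired_sparsity_comparison, pulse_pair_windows,
                      silencing_response, smooth3)
from thetapop.core import SpikeTable
from thetapop.popdyn import PopulationMatrix
from thetapop.tagging import LaserEvents as _LE


def table_from(trains: dict, region="CA1", cls="principal"):
    rows_u, rows_t = [], []
    for uid, t in trains.items():
        rows_u += [uid] * len(t)
        rows_t.append(np.asarray(t, dtype=float))
    spikes = pd.DataFrame({"unit_id": rows_u,
                           "time_s": np.concatenate(rows_t) if rows_t else []})
    spikes = spikes.sort_values("time_s", ignore_index=True)
    units = pd.DataFrame({"unit_id": list(trains), "region": region,
                          "cell_class": cls, "tag": "none"}).set_index("unit_id")
    return SpikeTable(spikes=spikes, units=units)


def matrix_from_counts(counts, regions=None, labels=None):
    counts = np.asarray(counts)
    n_u, n_w = counts.shape
    spans = np.column_stack([np.arange(n_w) * 0.1, np.arange(n_w) * 0.1 + 0.1])
    return PopulationMatrix(counts=counts, window_spans=spans,
                            window_kind="custom",
                            unit_ids=[f"u{k}" for k in range(n_u)],
                            labels=np.array(labels if labels is not None
                                            else ["off"] * n_w),
                            regions=regions)


class TestBuildMatrix:
    def test_counts_and_half_open_windows(self):
        table = table_from({"a": [0.01, 0.05, 0.1]})
        mat = build_population_matrix(table, [[0.0, 0.1]], unit_ids=["a"])
        assert mat.counts[0, 0] == 2  # spike at exactly 0.1 excluded

    def test_pulse_windows_flank_onset(self):
        ev = LaserEvents(np.array([3.0]), np.array([0.005]), 473.0, "activation")
        spans, labels = pulse_pair_windows(ev)
        assert np.allclose(spans, [[2.9, 3.0], [3.0, 3.1]])
        assert list(labels) == ["pre", "post"]

    def test_epoch_windows_tile_5s_in_100ms_bins(self):
        ev = LaserEvents(np.array([100.0]), np.array([30.0]), 561.0, "silencing")
        spans, labels = epoch_pair_windows(ev)
        assert spans.shape == (100, 2)
        assert np.sum(labels == "off") == 50
        assert spans[0][0] == pytest.approx(95.0)
        assert spans[-1][1] == pytest.approx(105.0)

    def test_empty_selection_rejected(self):
        table = table_from({"a": [0.5]})
        with pytest.raises(ValidationError):
            build_population_matrix(table, [[0, 1]], unit_ids=[])


class TestSparsityFormulas:
    @pytest.mark.parametrize("x,expected", [
        ((1, 1, 1, 1), 0.0),
        ((0, 0, 0, 4), 0.75),
        ((0, 1, 2, 3), 10 / 24),
    ])
    def test_gini_oracles(self, x, expected):
        assert gini_sparsity(np.array(x)) == pytest.approx(expected)

    @pytest.mark.parametrize("x,expected", [
        ((3, 3, 3, 3), 0.0),
        ((0, 0, 0, 7), 1.0),
        ((0, 1, 2, 3), (2 - 6 / np.sqrt(14)) / 1.0),
    ])
    def test_hoyer_oracles(self, x, expected):
        assert hoyer_sparsity(np.array(x)) == pytest.approx(expected)

    def test_all_zero_vector_undefined(self):
        assert np.isnan(gini_sparsity(np.zeros(5)))
        assert np.isnan(hoyer_sparsity(np.zeros(5)))
        assert np.isnan(hoyer_sparsity(np.array([4.0])))  # N = 1

    def test_gini_matches_mean_absolute_difference_identity(self):
        """Gini == sum_ij |xi-xj| / (2 N^2 mean) on 1,000 random vectors."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            x = rng.integers(0, 20, n).astype(float)
            if x.sum() == 0:
                continue
            mad = np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())
            assert gini_sparsity(x) == pytest.approx(mad, abs=1e-12)

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=25).filter(
        lambda x: sum(x) > 0),
        st.floats(0.1, 40.0))
    @settings(max_examples=200, deadline=None)
    def test_scale_and_permutation_invariance(self, x, c):
        x = np.array(x, dtype=float)
        rng = np.random.default_rng(1)
        perm = rng.permutation(x.size)
        for fn in (gini_sparsity, hoyer_sparsity):
            base = fn(x)
            assert fn(c * x) == pytest.approx(base, abs=1e-9)
            assert fn(x[perm]) == pytest.approx(base, abs=1e-9)

    @given(st.lists(st.integers(1, 30), min_size=3, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_transfer_to_richest_increases_both(self, x):
        """Pigou-Dalton direction: moving a count from a poorer unit to the
        richest unit never decreases sparsity."""
        x = np.array(x, dtype=float)
        rich = int(np.argmax(x))
        poor = int(np.argmin(x))
        if x[poor] == x[rich]:
            return
        y = x.copy()
        y[poor] -= 1
        y[rich] += 1
        assert gini_sparsity(y) >= gini_sparsity(x) - 1e-12
        assert hoyer_sparsity(y) >= hoyer_sparsity(x) - 1e-12

    def test_gini_upper_bound(self):
        x = np.zeros(8)
        x[3] = 11
        assert gini_sparsity(x) == pytest.approx(7 / 8)


class TestPairedComparison:
    def test_identical_pre_post_difference_zero(self):
        counts = np.tile([[1], [2], [0]], 4)
        mat = matrix_from_counts(counts, labels=["pre", "post", "pre", "post"])
        res = paired_sparsity_comparison(mat, mode="pulse_100ms")
        assert res.mean_gini["pre"] == pytest.approx(res.mean_gini["post"])
        assert res.excluded_fraction == 0.0

    def test_all_zero_windows_excluded_and_counted(self):
        counts = np.array([[1, 2, 0, 0], [0, 1, 0, 0]])
        mat = matrix_from_counts(counts, labels=["pre", "post", "pre", "post"])
        res = paired_sparsity_comparison(mat, mode="pulse_100ms")
        assert res.n_pairs == 1
        assert res.excluded_fraction == pytest.approx(0.5)

    def test_no_pairs_rejected(self):
        mat = matrix_from_counts(np.ones((2, 2)), labels=["off", "off"])
        with pytest.raises(ValidationError):
            paired_sparsity_comparison(mat, mode="pulse_100ms")


class TestSilencingResponse:
    def events(self, n=20):
        on = 10.0 + np.arange(n) * 45.0
        return LaserEvents(on, np.full(n, 30.0), 561.0, "silencing")

    def test_rate_doubling_gives_positive_summed_z(self):
        ev = self.events()
        rng = np.random.default_rng(0)
        duration = ev.offsets[-1] + 10
        base = np.sort(rng.uniform(0, duration, rng.poisson(5.0 * duration)))
        extra = []
        for on, off in zip(ev.onsets, ev.offsets):
            extra.append(rng.uniform(on, off, rng.poisson(5.0 * 30.0)))
        spikes = np.sort(np.r_[base, np.concatenate(extra)])
        assert silencing_response(spikes, ev) > 0

    def test_unmodulated_unit_near_zero(self):
        ev = self.events()
        rng = np.random.default_rng(1)
        duration = ev.offsets[-1] + 10
        zs = []
        for k in range(30):
            rng = np.random.default_rng(100 + k)
            spikes = np.sort(rng.uniform(0, duration, rng.poisson(5.0 * duration)))
            zs.append(silencing_response(spikes, ev))
        assert abs(np.mean(zs)) < 2.0  # ~34 bins, mean |sum z| ~ sqrt(34)

    def test_full_silencing_attains_minimum(self):
        """Zero laser-on spikes: summed Z equals the minimum possible."""
        ev = self.events()
        rng = np.random.default_rng(2)
        duration = ev.offsets[-1] + 10
        spikes = np.sort(rng.uniform(0, duration, rng.poisson(5.0 * duration)))
        keep = np.ones(spikes.size, bool)
        for on, off in zip(ev.onsets, ev.offsets):
            keep &= ~((spikes >= on) & (spikes < off))
        z = silencing_response(spikes[keep], ev)
        # each laser-on bin sits at -mu/sd, the lowest achievable value
        from thetapop import build_psth
        psth = build_psth(spikes[keep], ev, (0.0, 34 * 0.875), 0.875, (-4.375, 0.0))
        assert z == pytest.approx(np.sum(psth.z))
        assert np.all(psth.z <= 0)

    def test_smooth3_is_local_average(self):
        x = np.array([0.0, 3.0, 6.0, 3.0, 0.0])
        assert np.allclose(smooth3(x), [0, 3, 4, 3, 0])


class TestCofiring:
    def test_duplicated_unit_gives_r_of_1(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(2.0, 200)
        counts = np.vstack([rng.poisson(2.0, 200) for _ in range(10)]
                           + [base, base])
        regions = ["CA3"] * 6 + ["CA1"] * 5 + ["CA3"]
        # duplicated pair: row 10 (CA1) and row 11 (CA3)
        mat = matrix_from_counts(counts, regions=regions)
        res = cofiring_matrix(mat)
        d = dict(zip(res.pair_index, res.pair_r))
        assert d[("u11", "u10")] == pytest.approx(1.0)

    def test_independent_poisson_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.0, size=(12, 5000))
        regions = ["CA3"] * 6 + ["CA1"] * 6
        res = cofiring_matrix(matrix_from_counts(counts, regions=regions))
        assert abs(res.mean_r) < 0.05

    def test_shared_gain_raises_mean_r(self):
        rng = np.random.default_rng(5)
        n_w = 3000
        lo = np.exp(rng.normal(0, 0.3, n_w))
        hi = np.exp(rng.normal(0, 1.0, n_w))
        regions = ["CA3"] * 6 + ["CA1"] * 6
        r = {}
        for name, g in (("lo", lo), ("hi", hi)):
            counts = rng.poisson(2.0 * g, size=(12, n_w))
            r[name] = cofiring_matrix(matrix_from_counts(counts,
                                                         regions=regions)).mean_r
        assert r["hi"] > r["lo"] > 0

    def test_zero_variance_unit_pairs_excluded(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(1.0, size=(12, 100))
        counts[0] = 0
        regions = ["CA3"] * 6 + ["CA1"] * 6
        res = cofiring_matrix(matrix_from_counts(counts, regions=regions))
        assert res.n_excluded_pairs == 6
        assert res.pair_r.size == 30

    def test_too_few_units_rejected(self):
        counts = np.ones((5, 50))
        with pytest.raises(ValidationError):
            cofiring_matrix(matrix_from_counts(counts, regions=["CA3"] * 5))


class TestDimensionality:
    def test_rank_one_matrix_needs_one_component(self):
        t = np.arange(500)
        loadings = np.linspace(1, 2, 12)[:, None]
        counts = (loadings * np.sin(t / 10.0)[None, :] * 10).round()
        mat = matrix_from_counts(counts)
        n, score = dimensionality(mat, 0.8)
        assert n == 1
        assert score == pytest.approx(1 / 12)

    def test_isotropic_units_need_about_80pct_of_units(self):
        rng = np.random.default_rng(7)
        n_u, n_w = 20, 20000
        counts = rng.normal(0, 1, size=(n_u, n_w))
        mat = matrix_from_counts(counts)
        n, score = dimensionality(mat, 0.8)
        assert abs(n - 16) <= 1  # ceil(0.8 * 20)

    def test_variance_target_sweep_monotone(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(2.0, size=(15, 2000))
        from thetapop import dimensionality_sweep
        sweep = dimensionality_sweep(matrix_from_counts(counts))
        ns = [sweep[t][0] for t in sorted(sweep)]
        assert ns == sorted(ns)

    def test_mismatched_unit_sets_rejected(self):
        rng = np.random.default_rng(9)
        a = matrix_from_counts(rng.poisson(1.0, (12, 100)))
        b = matrix_from_counts(rng.poisson(1.0, (12, 100)))
        b.unit_ids = [f"v{k}" for k in range(12)]
        with pytest.raises(ValidationError):
            compare_dimensionality(a, b)

    def test_degenerate_matrix_flagged(self):
        mat = matrix_from_counts(np.ones((12, 50)))
        with pytest.warns(UserWarning):
            n, score = dimensionality(mat)
        assert np.isnan(n) and np.isnan(score)
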