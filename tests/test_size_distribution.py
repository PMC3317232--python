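"""Spectrum summaries, surface partitions, GM/GSD, correlations, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rnaero.nuclide_chain import InvalidInputError
from rnaero.size_distribution import (
    SizeDistribution,
    SizeGrid,
    UndefinedSummaryError,
    correlate,
    diurnal_profile,
    gm_gsd,
    make_grid,
    read_smps_csv,
    summarize,
    surface_partition,
    total_surface,
    write_smps_csv,
)

TS = pd.Timestamp("2021-01-01")


def dist_on(grid, n):
    return SizeDistribution(timestamp=TS, grid=grid, n=np.asarray(n, dtype=float))


@pytest.fixture()
def medium_grid():
    return make_grid("medium")


class TestGrid:
    @pytest.mark.parametrize("descriptor, lo, hi", [("medium", 5, 350), ("long", 10, 1100)])
    def test_ranges(self, descriptor, lo, hi):
        g = make_grid(descriptor)
        assert len(g) == 44
        assert g.diameters[0] == pytest.approx(lo)
        assert g.diameters[-1] == pytest.approx(hi)
        assert np.all(np.diff(g.diameters) > 0)

    def test_log_uniform_edges(self):
        g = make_grid("medium")
        assert np.allclose(g.dlnd, g.dlnd[0])  # log-uniform grid, equal Δln d

    def test_bad_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            SizeGrid(diameters=np.array([10.0, 5.0]))


class TestSummarize:
    def test_monodisperse(self, medium_grid):
        n = np.zeros(44)
        idx = int(np.argmin(np.abs(medium_grid.diameters - 100.0)))
        n[idx] = 500.0
        s = summarize(dist_on(medium_grid, n), cuts=(20.0,))
        assert s.d_gm == pytest.approx(medium_grid.diameters[idx])
        assert s.x_below[20.0] == 0.0
        assert s.c_tot == 500.0

    def test_geometric_symmetry(self):
        grid = SizeGrid(diameters=np.array([10.0, 100.0, 1000.0]))
        s = summarize(dist_on(grid, [300.0, 0.0, 300.0]), cuts=())
        assert s.d_gm == pytest.approx(100.0, rel=1e-12)

    def test_cut_nesting(self, medium_grid, rng):
        n = rng.uniform(0, 100, size=44)
        s = summarize(dist_on(medium_grid, n), cuts=(10.0, 20.0))
        assert s.x_below[10.0] <= s.x_below[20.0]

    def test_dgm_within_grid(self, medium_grid, rng):
        for _ in range(20):
            n = rng.uniform(0, 100, size=44)
            s = summarize(dist_on(medium_grid, n), cuts=())
            assert medium_grid.diameters[0] <= s.d_gm <= medium_grid.diameters[-1]

    def test_cut_partition_conserves_total(self, medium_grid, rng):
        n = rng.uniform(0, 100, size=44)
        d = medium_grid.diameters
        s = summarize(dist_on(medium_grid, n), cuts=(20.0,))
        below = n[d < 20.0].sum()
        above = n[d >= 20.0].sum()
        assert below + above == pytest.approx(s.c_tot, rel=1e-12)

    def test_dndlnd_density(self, medium_grid):
        n = np.ones(44)
        s = summarize(dist_on(medium_grid, n), cuts=())
        assert np.allclose(s.dndlnd * medium_grid.dlnd, n)

    def test_all_zero_rejected(self, medium_grid):
        with pytest.raises(UndefinedSummaryError):
            summarize(dist_on(medium_grid, np.zeros(44)), cuts=())

    def test_brute_force_agreement(self, medium_grid, rng):
        # oracle: per-particle summation over an expanded population
        n = rng.integers(0, 20, size=44).astype(float)
        n[0] += 1  # nonzero
        particles = np.repeat(medium_grid.diameters, n.astype(int))
        s = summarize(dist_on(medium_grid, n), cuts=(20.0,))
        assert s.c_tot == pytest.approx(len(particles))
        assert s.d_gm == pytest.approx(np.exp(np.mean(np.log(particles))), rel=1e-12)
        assert s.x_below[20.0] == pytest.approx(np.mean(particles < 20.0), rel=1e-12)


class TestSurfacePartition:
    def test_two_channel_example(self):
        grid = SizeGrid(diameters=np.array([5.0, 50.0]))
        n_ratio, s_ratio = surface_partition(dist_on(grid, [100.0, 100.0]), cut=10.0)
        assert n_ratio == pytest.approx(1.0)
        assert s_ratio == pytest.approx(0.01)  # (5/50)²

    def test_linearity_in_small_side(self):
        grid = SizeGrid(diameters=np.array([5.0, 50.0]))
        n1, s1 = surface_partition(dist_on(grid, [100.0, 100.0]), cut=10.0)
        n2, s2 = surface_partition(dist_on(grid, [200.0, 100.0]), cut=10.0)
        assert n2 == pytest.approx(2 * n1) and s2 == pytest.approx(2 * s1)

    def test_candle_like_number_surface_inversion(self, medium_grid):
        # a nucleation burst can double the sub-10-nm number count while
        # still carrying far less surface than the larger particles
        d = medium_grid.diameters
        n = np.where(d < 10.0, 100.0, 0.0)
        n[d >= 10.0] = (n[d < 10.0].sum() / 2.0) / (d >= 10.0).sum()
        dist = dist_on(medium_grid, n)
        n_ratio, s_ratio = surface_partition(dist, cut=10.0)
        assert n_ratio == pytest.approx(2.0, rel=1e-9)
        assert s_ratio < 1.0
        # brute-force surface oracle
        s_below = sum(ni * np.pi * di**2 for ni, di in zip(n[d < 10], d[d < 10]))
        s_above = sum(ni * np.pi * di**2 for ni, di in zip(n[d >= 10], d[d >= 10]))
        assert s_ratio == pytest.approx(s_below / s_above, rel=1e-12)

    def test_empty_side_rejected(self, medium_grid):
        n = np.zeros(44)
        n[-1] = 10.0
        with pytest.raises(UndefinedSummaryError):
            surface_partition(dist_on(medium_grid, n), cut=10.0)

    def test_total_surface(self):
        grid = SizeGrid(diameters=np.array([10.0, 100.0]))
        s = total_surface(dist_on(grid, [2.0, 1.0]))
        assert s == pytest.approx(2 * np.pi * 100 + np.pi * 1e4, rel=1e-12)


class TestGmGsd:
    def test_constant_series(self):
        st_ = gm_gsd([7.0] * 10)
        assert st_.gm == pytest.approx(7.0) and st_.gsd == pytest.approx(1.0)

    def test_two_values(self):
        st_ = gm_gsd([4.0, 9.0])
        assert st_.gm == pytest.approx(6.0, rel=1e-12)

    def test_lognormal_recovery(self, rng):
        draws = np.exp(rng.normal(np.log(5120.0), np.log(1.50), size=10_000))
        st_ = gm_gsd(draws)
        assert st_.gm == pytest.approx(5120.0, rel=0.02)
        assert st_.gsd == pytest.approx(1.50, rel=0.02)

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    def test_scaling(self, k):
        vals = [1.0, 2.0, 5.0, 9.0]
        base = gm_gsd(vals)
        scaled = gm_gsd([k * v for v in vals])
        assert scaled.gm == pytest.approx(k * base.gm, rel=1e-9)
        assert scaled.gsd == pytest.approx(base.gsd, rel=1e-9)

    def test_zeros_dropped_and_counted(self):
        st_ = gm_gsd([0.0, 1.0, 4.0, -2.0])
        assert st_.n_used == 2 and st_.n_dropped == 2
        assert st_.gm == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            gm_gsd([])


class TestCorrelate:
    def _series(self, values, freq="30min"):
        idx = pd.date_range("2021-01-01", periods=len(values), freq=freq)
        return pd.Series(values, index=idx)

    def test_identity(self):
        s = self._series(np.arange(10.0) + 1)
        assert correlate(s, s) == pytest.approx(1.0)

    def test_negation(self):
        s = self._series(np.arange(10.0) + 1)
        assert correlate(s, -s) == pytest.approx(-1.0)

    def test_independent_noise_is_small(self, rng):
        a = self._series(rng.normal(size=1000))
        b = self._series(rng.normal(size=1000))
        assert abs(correlate(a, b)) < 0.1

    def test_too_few_pairs(self):
        s = self._series([1.0, 2.0])
        with pytest.raises(UndefinedSummaryError):
            correlate(s, s)

    def test_zero_variance(self):
        s = self._series([1.0] * 10)
        t = self._series(np.arange(10.0))
        with pytest.raises(UndefinedSummaryError):
            correlate(s, t)


class TestDiurnalProfile:
    def _hourly(self, values):
        idx = pd.date_range("2021-01-01", periods=len(values), freq="1h")
        return pd.Series(values, index=idx)

    def test_constant_is_flat(self):
        prof = diurnal_profile(self._hourly([5.0] * 49))
        assert np.allclose(prof, 5.0)

    def test_sinusoid_peak_at_noon(self):
        hours = np.arange(72)
        vals = 10 + np.cos((hours % 24 - 12) / 24 * 2 * np.pi)
        prof = diurnal_profile(self._hourly(vals))
        assert prof.idxmax() == 12

    def test_two_peak_series(self):
        hours = np.arange(96)
        vals = 10 + np.cos((hours % 24) / 12 * 2 * np.pi)  # maxima at 0 and 12
        prof = diurnal_profile(self._hourly(vals)).to_numpy()
        local_max = [h for h in range(24)
                     if prof[h] >= prof[(h - 1) % 24] and prof[h] >= prof[(h + 1) % 24]]
        assert 0 in local_max and 12 in local_max

    def test_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            diurnal_profile(self._hourly([1.0] * 10))


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path, medium_grid, rng):
        idx = pd.date_range("2021-01-01", periods=5, freq="4min")
        records = pd.DataFrame(rng.uniform(0, 100, size=(5, 44)), index=idx,
                               columns=medium_grid.diameters)
        path = tmp_path / "smps.csv"
        write_smps_csv(path, medium_grid, records)
        grid2, back = read_smps_csv(path)
        assert np.allclose(grid2.diameters, medium_grid.diameters, rtol=1e-4)
        assert np.allclose(back.to_numpy(), records.to_numpy(), rtol=1e-5)
        assert (back.index == idx).all()
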