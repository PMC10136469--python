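"""Wavelet coherence and the cohort IBS machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import hyperdyad as hd
from hyperdyad.ibs import (band_average, compute_cohort_ibs,
                           dyad_permutation_test, fisher_z, interaction_scan,
                           segment_average, select_band, timelag_scan)
from hyperdyad.preprocess import preprocess_cohort
from hyperdyad.wtc import MorletGrid, SmoothingKernel, cwt_morlet, wtc
from conftest import NULL_AMPS, make_cohort
from oracles import brute_wtc


class TestCwt:
    def test_sinusoid_power_peaks_at_its_frequency(self):
        fs, f0 = 1.0, 0.125
        t = np.arange(600)
        grid = MorletGrid(fs, (0.02, 0.4))
        w, _ = cwt_morlet(np.sin(2 * np.pi * f0 * t), grid)
        power = (np.abs(w) ** 2)[:, 150:450].mean(axis=1)
        peak = grid.freqs_hz[int(np.argmax(power))]
        step = 2 ** (1 / 12)
        assert f0 / step <= peak <= f0 * step

    def test_amplitude_scaling_quadratic_in_power(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        grid = MorletGrid(1.0, (0.05, 0.4))
        w1, _ = cwt_morlet(x, grid)
        w3, _ = cwt_morlet(3 * x, grid)
        assert np.allclose(np.abs(w3) ** 2, 9 * np.abs(w1) ** 2, rtol=1e-10)

    def test_shift_equivariance_in_interior(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        shift = 16
        # stay below ~0.22 Hz: near Nyquist the analytic wavelet's sharp
        # spectral cutoff induces long kernel tails that reach the edges
        grid = MorletGrid(1.0, (0.08, 0.2))
        w0, _ = cwt_morlet(x, grid)
        w1, _ = cwt_morlet(np.roll(x, shift), grid)
        # compare well inside the COI of both transforms
        assert np.allclose(w1[:, 150 + shift:250 + shift], w0[:, 150:250],
                           atol=1e-6 * np.abs(w0).max())

    def test_bad_inputs_rejected(self):
        grid = MorletGrid(1.0, (0.1, 0.6))
        with pytest.raises(ValueError):
            cwt_morlet(np.ones(100), grid)  # range beyond Nyquist
        with pytest.raises(ValueError):
            cwt_morlet(np.ones(8), MorletGrid(1.0, (0.1, 0.4)))


class TestWtc:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(0).standard_normal(400)
        cm = wtc(x, x, 1.0)
        assert np.abs(cm.coherence - 1.0).max() < 1e-6

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(64)
        y = 0.5 * x + rng.standard_normal(64)
        fr = (0.12, 0.22)  # away from Nyquist, where the analytic
        grid = MorletGrid(1.0, fr)  # wavelet is padding-independent
        cm = wtc(x, y, 1.0, fr)
        kern = SmoothingKernel(grid, 64)
        oracle = brute_wtc(x, y, 1.0, grid.scales_s,
                           scale_halfwidth=kern.scale_halfwidth)
        assert np.abs(cm.coherence - oracle).max() < 1e-8

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 300))
        a = wtc(x, y, 1.0).coherence
        b = wtc(y, x, 1.0).coherence
        assert np.allclose(a, b, atol=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        cm = wtc(rng.standard_normal(300), rng.standard_normal(300), 1.0)
        assert cm.coherence.min() >= 0.0 and cm.coherence.max() <= 1.0

    def test_white_noise_null_level(self):
        # mean in-band coherence of independent noise, over the COI-valid
        # region the segment averages actually use
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cm = wtc(rng.standard_normal(300), rng.standard_normal(300), 1.0)
            band = (cm.freqs_hz >= 0.11) & (cm.freqs_hz <= 0.14)
            valid = cm.valid_mask()[band]
            vals.append(cm.coherence[band][valid].mean())
        assert np.mean(vals) < 0.35

    def test_one_sample_delay_coherent_at_low_frequencies(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(400)
        y = np.roll(x, 1)
        cm = wtc(x, y, 1.0)
        low = cm.freqs_hz < 0.05
        high = cm.freqs_hz > 0.4
        inside = cm.valid_mask()
        lo_mean = cm.coherence[low][inside[low]].mean()
        hi_mean = cm.coherence[high][inside[high]].mean()
        assert lo_mean > 0.9 and lo_mean > hi_mean

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            wtc(np.ones(100), np.random.default_rng(0).standard_normal(100), 1.0)


class TestFisherZ:
    def test_known_values_and_cap(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.25) == pytest.approx(np.arctanh(0.5))
        assert np.isfinite(fisher_z(1.0))

    @given(st.floats(min_value=0.0, max_value=0.999),
           st.floats(min_value=0.0, max_value=0.999))
    def test_monotone(self, a, b):
        za, zb = fisher_z(a), fisher_z(b)
        if a < b:
            assert za < zb
        elif a == b:
            assert za == zb


class TestSegmentAverage:
    def test_stationary_map_segment_means_agree(self, timeline):
        rng = np.random.default_rng(5)
        n_t = int(timeline.duration_s)
        x = rng.standard_normal(n_t)
        y = rng.standard_normal(n_t)
        cm = wtc(x, y, 1.0)
        task = segment_average(cm, timeline, "task")
        rest = segment_average(cm, timeline, "rest")
        inside = np.isfinite(task) & np.isfinite(rest)
        # same stationary process: segment means differ only by noise
        assert np.nanmean(np.abs(task[inside] - rest[inside])) < 0.25

    def test_fully_coi_contaminated_frequency_is_nan(self, timeline):
        rng = np.random.default_rng(6)
        n_t = int(timeline.duration_s)
        cm = wtc(rng.standard_normal(n_t), rng.standard_normal(n_t), 1.0,
                 (0.002, 0.4))
        rest = segment_average(cm, timeline, "rest")
        assert np.isnan(rest[-1])  # slowest scale: all rests inside the COI


class TestCohortScans:
    def test_task_coupling_raises_task_over_rest(self, coupled_cohort):
        ibs = coupled_cohort["ibs"]
        bz = band_average(ibs, (0.11, 0.14))
        it, ir = ibs.seg_index("task"), ibs.seg_index("rest")
        diff = bz[:, 0, 1, it] - bz[:, 0, 1, ir]
        assert diff.mean() > 0

    def test_scan_enumerates_all_channel_pairs(self, coupled_cohort, config):
        sel = select_band(coupled_cohort["ibs"], config=config)
        n_ch = coupled_cohort["ibs"].z.shape[1]
        assert sel.n_pairs == n_ch * n_ch
        assert sel.t.shape[:2] == (n_ch, n_ch)

    def test_null_generator_yields_empty_band(self, config):
        empty = 0
        for seed in range(8):
            sessions = make_cohort(8, 8, seed=900 + seed,
                                   amplitudes=NULL_AMPS, hrf=0.0)
            kept, pairs, _ = preprocess_cohort(sessions, config)
            ibs = compute_cohort_ibs(kept, pairs, config)
            empty += select_band(ibs, config=config).is_empty
        assert empty >= 7

    def test_band_average_refuses_empty_band(self, coupled_cohort):
        from hyperdyad.ibs import BandSelection
        empty = BandSelection(coupled_cohort["ibs"].freqs_hz, None, None,
                              None, None, np.array([], dtype=int), 9)
        with pytest.raises(ValueError, match="empty"):
            band_average(coupled_cohort["ibs"], empty)

    def test_interaction_scan_shape_and_symmetry_under_relabel(self, config):
        # flipping the group labels with a sign-flipped schedule leaves the
        # interaction F at the coupled pair unchanged in distribution;
        # here we check the direct algebraic symmetry: relabelling groups
        # does not change F (the contrast is squared)
        amps = {"couple": (0.02, 0.06), "control": (0.06, 0.02)}
        sessions = make_cohort(5, 5, seed=77, amplitudes=amps)
        kept, pairs, _ = preprocess_cohort(sessions, config)
        ibs = compute_cohort_ibs(kept, pairs, config)
        scan = interaction_scan(ibs, (0.11, 0.14), (), config)
        flipped = dataclass_replace_groups(ibs)
        scan2 = interaction_scan(flipped, (0.11, 0.14), (), config)
        assert scan.F.shape == (3, 3)
        assert np.allclose(scan.F, scan2.F, equal_nan=True)


def dataclass_replace_groups(ibs):
    import copy
    out = copy.copy(ibs)
    out.groups = ["control" if g == "couple" else "couple" for g in ibs.groups]
    return out


@pytest.fixture(scope="module")
def null_cohort(config):
    sessions = make_cohort(5, 5, seed=88, amplitudes=NULL_AMPS, hrf=0.0)
    kept, pairs, _ = preprocess_cohort(sessions, config)
    return kept, pairs


class TestPermutation:
    def test_repairing_preserves_group_composition(self, null_cohort, config):
        kept, pairs = null_cohort
        res = dyad_permutation_test(kept, pairs, (1, 2), (0.11, 0.14),
                                    config, seed=1, n_iter=120)
        assert res.n_iter == 120
        assert len(res.null_F) == 120
        assert 0 < res.p <= 1

    def test_extreme_observed_gives_add_one_p(self):
        # the add-one convention directly: observed above all nulls
        null = np.zeros(1000)
        p = (1 + int(np.sum(null >= 5.0))) / (1000 + 1)
        assert p == pytest.approx(1 / 1001)

    def test_small_iteration_count_warns(self, null_cohort, config):
        kept, pairs = null_cohort
        with pytest.warns(UserWarning):
            dyad_permutation_test(kept, pairs, (1, 2), (0.11, 0.14),
                                  config, seed=2, n_iter=99)

    def test_seeded_reproducibility(self, null_cohort, config):
        kept, pairs = null_cohort
        a = dyad_permutation_test(kept, pairs, (1, 2), (0.11, 0.14),
                                  config, seed=3, n_iter=120)
        b = dyad_permutation_test(kept, pairs, (1, 2), (0.11, 0.14),
                                  config, seed=3, n_iter=120)
        assert np.array_equal(a.null_F, b.null_F) and a.p == b.p


class TestTimelag:
    def test_scan_covers_configured_lags(self, coupled_cohort, config):
        df = timelag_scan(coupled_cohort["sessions"], coupled_cohort["pairs"],
                          (1, 2), (0.11, 0.14), config)
        assert list(df["lag_s"]) == list(config.lags_s)
        assert len(df) == 10
        assert np.all(df["F"] >= 0)

    def test_zero_lag_coupling_coherence_decays_with_lag(self, config):
        # narrow-band coupling makes coherence (not the interaction F, which
        # contrasts groups) the informative lag statistic: band z at the
        # coupled pair must fall off by the time the shift reaches 10 s
        amps = {"couple": (0.08, 0.08), "control": (0.08, 0.08)}
        wins = 0
        for seed in range(6):
            sessions = make_cohort(4, 4, seed=700 + seed, amplitudes=amps,
                                   hrf=0.0)
            kept, pairs, _ = preprocess_cohort(sessions, config)
            df = timelag_scan(kept, pairs, (1, 2), (0.11, 0.14), config,
                              lags_s=(0, -10, 10))
            z = ((df["mean_z_block1"] + df["mean_z_block2"]) / 2).to_numpy()
            wins += z[0] > max(z[1], z[2])
        assert wins >= 5

    def test_asymmetric_lag_recovered_in_scan_direction(self, config):
        # generator lag_s = +4 delays the female component, i.e. the male
        # leads; compensating requires delaying the male series, which is
        # a negative scan lag under the documented sign convention
        amps = {"couple": (0.08, 0.08), "control": (0.08, 0.08)}
        wins = 0
        for seed in range(6):
            sessions = make_cohort(4, 4, seed=700 + seed, amplitudes=amps,
                                   hrf=0.0, lag=4.0)
            kept, pairs, _ = preprocess_cohort(sessions, config)
            df = timelag_scan(kept, pairs, (1, 2), (0.11, 0.14), config,
                              lags_s=(-4, 4))
            z = ((df["mean_z_block1"] + df["mean_z_block2"]) / 2).to_numpy()
            wins += z[0] > z[1]
        assert wins >= 5

    def test_excessive_lag_rejected(self, coupled_cohort, config):
        with pytest.raises(ValueError, match="lag"):
            timelag_scan(coupled_cohort["sessions"], coupled_cohort["pairs"],
                         (1, 2), (0.11, 0.14), config, lags_s=(200,))
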