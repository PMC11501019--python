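"""Multitaper TFR, coherence, power contrast, and cross-spectra."""

import numpy as np
import pytest

from obpc.containers import EpochSet
from obpc.spectral import (
    TFGrid,
    coherence,
    coherence_null_threshold,
    csd_multitaper,
    hemisphere_average,
    log_power_map,
    multitaper_tfr,
    power_contrast,
    window_length,
)

FS = 512.0


def two_channel_epochs(data, fs=FS, t0=-0.5):
    return EpochSet(data=data, roi_labels=("X", "Y"), fs=fs, t0=t0)


class TestWindowLength:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (60.0, 0.0625),   # bandwidth-limited: 3 / (0.8 * 60)
            (4.0, 0.9375),    # 3 / (0.8 * 4)
            (100.0, 0.0375),
        ],
    )
    def test_adaptive_window_formula(self, f, expected):
        assert window_length(f) == pytest.approx(expected)

    def test_bandwidth_term_always_binds_over_two_cycles(self):
        for f in np.arange(4.0, 101.0):
            assert window_length(f) > 2.0 / f - 1e-12


class TestMultitaperTfr:
    def test_stationary_sinusoid_has_constant_amplitude(self, rng):
        t = np.arange(1024) / FS
        x = np.cos(2 * np.pi * 40.0 * t)
        data = np.tile(x, (3, 2, 1))
        ep = two_channel_epochs(data)
        tfr = multitaper_tfr(ep, TFGrid(freqs=np.array([40.0]),
                                        times=np.arange(-0.2, 1.2, 0.05)))
        amp = np.abs(tfr.coeff[0, 0, 0, 0])
        amp = amp[np.isfinite(amp)]
        assert amp.std() / amp.mean() < 0.01

    def test_linearity_in_amplitude(self, rng):
        data = rng.standard_normal((2, 2, 1024))
        grid = TFGrid(freqs=np.array([10.0, 60.0]),
                      times=np.array([0.2, 0.5]))
        a = multitaper_tfr(two_channel_epochs(data), grid)
        b = multitaper_tfr(two_channel_epochs(3.0 * data), grid)
        np.testing.assert_allclose(b.coeff, 3.0 * a.coeff, rtol=1e-10)

    def test_low_frequency_edges_marked_missing(self):
        data = np.zeros((1, 2, 1024))
        grid = TFGrid(freqs=np.array([4.0]),
                      times=np.arange(-0.4, 1.4001, 0.025))
        tfr = multitaper_tfr(two_channel_epochs(data), grid)
        # 937.5 ms window: centers closer than ~469 ms to an edge invalid
        times = grid.times
        valid = tfr.valid[0]
        assert not valid[times < -0.04].any()
        assert valid[(times > -0.02) & (times < 1.02)].all()

    def test_frequency_at_nyquist_rejected(self):
        data = np.zeros((1, 2, 1024))
        with pytest.raises(ValueError, match="Nyquist"):
            multitaper_tfr(
                two_channel_epochs(data),
                TFGrid(freqs=np.array([256.0]), times=np.array([0.5])),
            )


@pytest.fixture(scope="module")
def grid():
    return TFGrid(freqs=np.arange(8.0, 101.0, 8.0),
                  times=np.arange(0.0, 1.0, 0.1))


class TestCoherence:
    def test_identical_signals_give_unity(self, rng, grid):
        x = rng.standard_normal((10, 1, 1024))
        data = np.concatenate([x, x], axis=1)
        tfr = multitaper_tfr(two_channel_epochs(data), grid)
        C = coherence(tfr, ("X", "Y")).C
        np.testing.assert_allclose(C[np.isfinite(C)], 1.0, atol=1e-12)

    def test_bounded_and_scale_invariant(self, rng, grid):
        data = rng.standard_normal((12, 2, 1024))
        ep = two_channel_epochs(data)
        C1 = coherence(multitaper_tfr(ep, grid), ("X", "Y")).C
        assert np.nanmin(C1) >= 0 and np.nanmax(C1) <= 1
        scaled = data.copy()
        scaled[:, 1] *= 17.0
        C2 = coherence(multitaper_tfr(two_channel_epochs(scaled), grid),
                       ("X", "Y")).C
        np.testing.assert_allclose(C2, C1, rtol=1e-9)

    def test_common_phase_rotation_invariant(self, rng, grid):
        data = rng.standard_normal((8, 2, 1024))
        ep = two_channel_epochs(data)
        tfr = multitaper_tfr(ep, grid)
        C1 = coherence(tfr, ("X", "Y")).C
        rot = tfr
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, size=tfr.coeff.shape[0]))
        rot.coeff = tfr.coeff * phases[:, None, None, None, None]
        C2 = coherence(rot, ("X", "Y")).C
        np.testing.assert_allclose(C2, C1, rtol=1e-9)

    def test_independent_noise_stays_below_null_threshold(self, rng, grid):
        """m = 80 trial x taper estimates: the analytic 5% null quantile
        sqrt(1 - 0.05^(1/(m-1))) bounds ~95% of cells."""
        data = rng.standard_normal((40, 2, 1024))
        tfr = multitaper_tfr(two_channel_epochs(data), grid)
        cm = coherence(tfr, ("X", "Y"))
        thr = coherence_null_threshold(80, 0.05)
        C = cm.C[np.isfinite(cm.C)]
        assert (C < thr).mean() >= 0.90  # small grid, some slack

    def test_delayed_noisy_copy_peaks_at_carrier(self, rng):
        t = np.arange(1024) / FS
        grid = TFGrid(freqs=np.arange(10.0, 91.0, 10.0),
                      times=np.array([0.3, 0.5]))
        carrier = rng.standard_normal((30, 1024))
        from scipy.signal import lfilter

        w = 2 * np.pi * 30.0 / FS
        nb = lfilter([1.0], [1.0, -2 * 0.95 * np.cos(w), 0.95**2],
                     carrier, axis=-1)
        nb /= nb.std()
        lag = 5
        x = nb + 0.5 * rng.standard_normal(nb.shape)
        y = np.roll(nb, lag, axis=-1) + 0.5 * rng.standard_normal(nb.shape)
        data = np.stack([x, y], axis=1)
        C = coherence(multitaper_tfr(two_channel_epochs(data), grid),
                      ("X", "Y")).C
        prof = np.nanmean(C, axis=1)
        assert grid.freqs[np.argmax(prof)] == 30.0

    def test_empty_subset_rejected(self, rng, grid):
        tfr = multitaper_tfr(
            two_channel_epochs(rng.standard_normal((4, 2, 1024))), grid
        )
        with pytest.raises(ValueError, match="empty"):
            coherence(tfr, ("X", "Y"), trial_subset=np.array([], dtype=int))


class TestHemisphereAverage:
    def test_mean_and_m_sum(self, rng):
        grid = TFGrid(freqs=np.array([20.0]), times=np.array([0.5]))
        ep = two_channel_epochs(rng.standard_normal((6, 2, 1024)))
        tfr = multitaper_tfr(ep, grid)
        a = coherence(tfr, ("X", "Y"))
        b = coherence(tfr, ("Y", "X"))
        avg = hemisphere_average(a, b)
        np.testing.assert_allclose(avg.C, 0.5 * (a.C + b.C))
        np.testing.assert_array_equal(avg.m, a.m + b.m)

    def test_grid_mismatch_rejected(self, rng):
        ep = two_channel_epochs(rng.standard_normal((6, 2, 1024)))
        g1 = TFGrid(freqs=np.array([20.0]), times=np.array([0.5]))
        g2 = TFGrid(freqs=np.array([30.0]), times=np.array([0.5]))
        a = coherence(multitaper_tfr(ep, g1), ("X", "Y"))
        b = coherence(multitaper_tfr(ep, g2), ("X", "Y"))
        with pytest.raises(ValueError, match="[Gg]rid"):
            hemisphere_average(a, b)


class TestPowerContrast:
    def test_identical_conditions_give_zero_t(self, rng):
        maps = rng.standard_normal((5, 6, 7))
        t, p, mask = power_contrast(maps, maps.copy())
        np.testing.assert_allclose(t, 0.0)
        assert not mask.any()

    def test_sign_flip_negates_t(self, rng):
        a = rng.standard_normal((6, 4, 5))
        b = rng.standard_normal((6, 4, 5))
        t1, _, _ = power_contrast(a, b)
        t2, _, _ = power_contrast(b, a)
        np.testing.assert_allclose(t2, -t1, atol=1e-12)

    def test_injected_power_increase_detected(self, rng):
        a = rng.standard_normal((12, 8, 8))
        b = rng.standard_normal((12, 8, 8))
        a[:, 3:5, 4:6] += 3.0
        _, _, mask = power_contrast(a, b, alpha=0.01)
        assert mask[3:5, 4:6].all()

    def test_single_participant_rejected(self, rng):
        with pytest.raises(ValueError, match="participants"):
            power_contrast(rng.standard_normal((1, 3, 3)),
                           rng.standard_normal((1, 3, 3)))


class TestCsdMultitaper:
    def test_white_noise_flat_spectrum_with_unit_integral(self, rng):
        data = rng.standard_normal((300, 2, 1024))
        csd = csd_multitaper(two_channel_epochs(data), ("X", "Y"))
        Sxx = csd.S[:, 0, 0].real
        # two-sided PSD of unit-variance noise = 1/fs; one-sided integral
        # over [0, Nyquist] recovers half the variance
        assert 2 * np.trapezoid(Sxx, csd.freqs) == pytest.approx(1.0, rel=0.05)
        assert Sxx.std() / Sxx.mean() < 0.2

    def test_grid_is_one_hertz_from_one_second_window(self, rng):
        data = rng.standard_normal((5, 2, 1024))
        csd = csd_multitaper(two_channel_epochs(data), ("X", "Y"))
        assert csd.freqs[1] - csd.freqs[0] == pytest.approx(1.0)
        assert csd.freqs[0] == 0.0 and csd.freqs[-1] == FS / 2

    def test_hermitian_positive_semidefinite(self, rng):
        data = rng.standard_normal((20, 2, 1024))
        S = csd_multitaper(two_channel_epochs(data), ("X", "Y")).S
        np.testing.assert_allclose(S, S.conj().transpose(0, 2, 1), atol=1e-15)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_independent_channels_have_low_cross_spectrum(self, rng):
        data = rng.standard_normal((100, 2, 1024))
        S = csd_multitaper(two_channel_epochs(data), ("X", "Y")).S
        coh = np.abs(S[:, 0, 1]) / np.sqrt(S[:, 0, 0].real * S[:, 1, 1].real)
        thr = coherence_null_threshold(100 * 7, 0.05)
        assert (coh < thr).mean() > 0.9

    def test_matches_analytic_var_spectrum(self):
        from obpc.varmodels import VarSpec, analytic_var_spectra, generate_var_epochs

        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.4, 0.5]]
        spec = VarSpec(A, np.eye(2), fs=FS)
        ep = generate_var_epochs(spec, 200, 512, np.random.default_rng(3))
        csd = csd_multitaper(ep, ("X", "Y"))
        S_true, *_ = analytic_var_spectra(spec, csd.freqs)
        peak = np.argmax(S_true[:, 0, 0].real)
        est = csd.S[peak, 0, 0].real
        assert est == pytest.approx(S_true[peak, 0, 0].real, rel=0.10)

    def test_window_outside_epoch_rejected(self, rng):
        data = rng.standard_normal((4, 2, 256))
        with pytest.raises(ValueError, match="window"):
            csd_multitaper(two_channel_epochs(data, t0=0.0), ("X", "Y"),
                           window=(2.0, 3.0))

    def test_too_many_tapers_rejected(self, rng):
        data = rng.standard_normal((4, 2, 1024))
        with pytest.raises(ValueError, match="tapers"):
            csd_multitaper(two_channel_epochs(data), ("X", "Y"),
                           bandwidth=2.0, n_tapers=7)


def test_log_power_map_tracks_injected_power(rng):
    grid = TFGrid(freqs=np.array([20.0, 60.0]), times=np.array([0.5]))
    weak = rng.standard_normal((10, 2, 1024))
    t = np.arange(1024) / FS
    strong = weak + 5 * np.cos(2 * np.pi * 60.0 * t)
    ep_w = two_channel_epochs(weak)
    ep_s = two_channel_epochs(strong)
    pw = log_power_map(multitaper_tfr(ep_w, grid), "X")
    ps = log_power_map(multitaper_tfr(ep_s, grid), "X")
    assert ps[1, 0] - pw[1, 0] > 1.0  # 60 Hz row grew
    assert abs(ps[0, 0] - pw[0, 0]) < 0.5  # 20 Hz row unchanged


def test_coherence_map_hdf5_roundtrip(rng, grid, tmp_path):
    from obpc.spectral import load_coherence_map, save_coherence_map

    ep = two_channel_epochs(rng.standard_normal((6, 2, 1024)))
    cm = coherence(multitaper_tfr(ep, grid), ("X", "Y"),
                   participant_id="P007", condition="unpleasant")
    path = tmp_path / "cm.h5"
    save_coherence_map(cm, path)
    back = load_coherence_map(path)
    np.testing.assert_array_equal(back.C, cm.C)
    np.testing.assert_array_equal(back.m, cm.m)
    assert back.grid.matches(cm.grid)
    assert back.pair == cm.pair
    assert back.participant_id == "P007" and back.condition == "unpleasant"
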