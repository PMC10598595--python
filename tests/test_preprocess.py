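"""Preprocessing chain: filters, line noise, baseline, rejection,
interpolation, referencing and the surface Laplacian."""

import numpy as np
import pytest
from scipy.special import eval_legendre

from rrbscope.epochs import InsufficientDataError
from rrbscope.montage import Montage, MontageError, standard_1020
from rrbscope.preprocess import (average_reference, bandpass_filter,
                                 baseline_correct, g_series, h_series,
                                 interpolate_bad_channels, preprocess,
                                 reject_artifacts, remove_line_noise,
                                 surface_laplacian)

from conftest import make_epochs, sine_epochs


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        ep = sine_epochs(freq=10.0, amp=1.0)
        out = bandpass_filter(ep)
        # compare RMS over the epoch interior to dodge filtfilt edge transients
        sl = slice(100, -100)
        ratio = _rms(out.data[0, 0, sl]) / _rms(ep.data[0, 0, sl])
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuated_20db(self):
        ep = sine_epochs(freq=45.0, amp=1.0)
        out = bandpass_filter(ep)
        sl = slice(100, -100)
        atten = 20 * np.log10(_rms(ep.data[0, 0, sl]) / _rms(out.data[0, 0, sl]))
        assert atten >= 20.0

    def test_dc_rejected(self):
        ep = make_epochs(np.full((1, 2, 750), 5.0))
        out = bandpass_filter(ep)
        assert np.abs(out.data).max() <= 0.05  # <= 1% of the 5 uV input

    def test_bad_cutoffs_raise(self):
        ep = sine_epochs()
        with pytest.raises(ValueError):
            bandpass_filter(ep, lp=130.0)
        with pytest.raises(ValueError):
            bandpass_filter(ep, hp=40.0, lp=30.0)


class TestLineNoise:
    def test_line_removed_signal_kept(self):
        ep = sine_epochs(freq=10.0, amp=1.0)
        t = ep.times_ms / 1000.0
        noisy = ep.with_data(ep.data + 2.0 * np.sin(2 * np.pi * 50.0 * t))
        out = remove_line_noise(noisy)
        residual = out.data - ep.data
        assert _rms(residual) <= 0.1 * _rms(2.0 * np.sin(2 * np.pi * 50.0 * t))

    def test_noop_on_clean_input(self):
        ep = sine_epochs(freq=10.0)
        out = remove_line_noise(ep)
        assert _rms(out.data - ep.data) <= 0.02 * _rms(ep.data)

    def test_harmonic_also_removed(self):
        ep = sine_epochs(freq=10.0, amp=1.0)
        t = ep.times_ms / 1000.0
        line = 1.0 * np.sin(2 * np.pi * 50.0 * t) + 1.0 * np.cos(2 * np.pi * 100.0 * t)
        out = remove_line_noise(ep.with_data(ep.data + line), n_harmonics=2)
        # both lines attenuated >= 20 dB
        resid = out.data[0, 0] - ep.data[0, 0]
        assert 20 * np.log10(_rms(line) / max(_rms(resid), 1e-12)) >= 20.0

    def test_line_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            remove_line_noise(sine_epochs(), base=200.0)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        ep = make_epochs(np.full((2, 3, 750), 5.0))
        out = baseline_correct(ep)
        assert np.abs(out.data).max() < 1e-9

    def test_shift_is_exact(self):
        data = np.zeros((1, 1, 750))
        data[..., :250] = 2.0  # baseline samples cover [-1000, 0)
        ep = make_epochs(data)
        out = baseline_correct(ep)
        assert np.allclose(out.data[..., :250], 2.0 - 2.0)

    def test_random_trace_window_mean_zero(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.normal(size=(4, 3, 750)))
        out = baseline_correct(ep, window=(-1000.0, 0.0))
        mask = out.time_mask(-1000.0, 0.0)
        assert np.abs(out.data[:, :, mask].mean(axis=-1)).max() < 1e-9

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            baseline_correct(sine_epochs(), window=(-5000.0, -4000.0))


class TestRejection:
    def test_excursion_rejected_boundary_retained(self):
        data = np.zeros((3, 2, 750))
        data[0, 0, 10] = 101.0  # rejected
        data[1, 1, 20] = 100.0  # exactly at the closed bound: retained
        ep = make_epochs(data, conditions=np.array(["HRIS", "HRIS", "LRIS"], dtype=object))
        out = reject_artifacts(ep)
        assert out.rejected.tolist() == [True, False, False]

    def test_planted_excursion_count(self):
        rng = np.random.default_rng(0)
        data = rng.normal(scale=10.0, size=(10, 3, 750))
        for trial in (1, 4, 7):
            data[trial, 0, 5] = 150.0
        ep = make_epochs(data, conditions=np.array(["HRIS"] * 5 + ["LRIS"] * 5, dtype=object))
        out = reject_artifacts(ep)
        assert out.rejected.sum() == 3
        assert set(np.flatnonzero(out.rejected)) == {1, 4, 7}

    def test_all_trials_of_condition_rejected_raises(self):
        data = np.full((2, 2, 750), 200.0)
        ep = make_epochs(data, conditions=np.array(["HRIS", "LRIS"], dtype=object))
        with pytest.raises(InsufficientDataError):
            reject_artifacts(ep)

    def test_bad_channels_ignored(self):
        data = np.zeros((2, 2, 750))
        data[:, 1, :] = 500.0  # huge but on a bad channel
        ep = make_epochs(data, bad_channels=("ch1",))
        out = reject_artifacts(ep)
        assert not out.rejected.any()


class TestInterpolation:
    def test_constant_field(self, montage20):
        data = np.full((2, 20, 100), 7.0)
        ep = make_epochs(data, channels=montage20.channels, bad_channels=("Cz",))
        out = interpolate_bad_channels(ep, montage20)
        cz = montage20.channels.index("Cz")
        assert np.allclose(out.data[:, cz, :], 7.0, atol=1e-6)
        # good channels untouched
        others = [i for i in range(20) if i != cz]
        assert np.array_equal(out.data[:, others, :], data[:, others, :])

    def test_smooth_dipolar_field_recovered(self, montage20):
        # potential linear in position: the smoothest nonconstant field on the sphere
        d = np.array([0.3, 0.5, 0.8])
        truth = montage20.positions @ d  # (20,)
        rng = np.random.default_rng(1)
        series = np.outer(truth, np.sin(np.linspace(0, 6, 100)))
        ep = make_epochs(series[None, :, :], channels=montage20.channels,
                         bad_channels=("Pz",))
        out = interpolate_bad_channels(ep, montage20)
        pz = montage20.channels.index("Pz")
        r = np.corrcoef(out.data[0, pz], series[pz])[0, 1]
        assert r >= 0.95

    def test_no_bad_channels_identity(self, montage20):
        ep = make_epochs(np.random.default_rng(0).normal(size=(1, 20, 50)),
                         channels=montage20.channels)
        out = interpolate_bad_channels(ep, montage20)
        assert out is ep


class TestAverageReference:
    def test_simple_example(self):
        data = np.empty((1, 3, 10))
        for ch, v in enumerate((1.0, 2.0, 3.0)):
            data[0, ch, :] = v
        ep = make_epochs(data)
        out = average_reference(ep)
        assert np.allclose(out.data[0, :, 0], [-1.0, 0.0, 1.0])

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.normal(size=(3, 8, 100)))
        once = average_reference(ep)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data)
        assert np.abs(once.data.mean(axis=1)).max() < 1e-9


class TestSurfaceLaplacian:
    def test_uniform_potential_zero_csd(self, montage20):
        ep = make_epochs(np.full((1, 20, 50), 4.0), channels=montage20.channels)
        out = surface_laplacian(ep, montage20)
        assert np.abs(out.data).max() < 1e-6 * 4.0

    def test_reference_invariance(self, montage20):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(2, 20, 60))
        ep = make_epochs(data, channels=montage20.channels)
        a = surface_laplacian(ep, montage20)
        b = surface_laplacian(ep.with_data(data + 7.0), montage20)
        assert np.abs(a.data - b.data).max() < 1e-6

    @pytest.mark.parametrize("kernel,order_offset", [(g_series, 0), (h_series, 1)])
    def test_legendre_series_matches_bruteforce(self, kernel, order_offset):
        m, n_terms = 4, 50
        xs = np.array([1.0, 0.5, 0.0, -0.7, -1.0])
        order = m - order_offset
        expected = np.zeros_like(xs)
        for n in range(1, n_terms + 1):
            expected += (2 * n + 1) / (n * (n + 1)) ** order * eval_legendre(n, xs)
        expected /= 4 * np.pi
        assert np.abs(kernel(xs, m=m, n_terms=n_terms) - expected).max() < 1e-10

    def test_duplicate_positions_raise(self):
        pos = np.eye(3)
        pos = np.vstack([pos, pos[0], [0, 0, -1], [0, -1, 0], [-1, 0, 0], pos[1]])
        mont = Montage(tuple(f"e{i}" for i in range(8)), pos)
        ep = make_epochs(np.zeros((1, 8, 10)), channels=mont.channels)
        with pytest.raises(ValueError, match="duplicate"):
            surface_laplacian(ep, mont)


def test_full_chain_shape_and_order(montage20):
    """The composed chain conserves channel/time dims and only drops trials."""
    rng = np.random.default_rng(11)
    data = rng.normal(scale=10.0, size=(6, 20, 750))
    # passband (5 Hz) artifact burst that survives the 0.1-30 Hz filter
    data[2, 3, 100:350] += 250.0 * np.sin(2 * np.pi * 5.0 * np.arange(250) / 250.0)
    ep = make_epochs(data, channels=montage20.channels,
                     conditions=np.array(["HRIS"] * 3 + ["LRIS"] * 3, dtype=object))
    out = preprocess(ep, montage20)
    assert out.data.shape == (6, 20, 750)
    assert out.rejected.sum() == 1 and out.rejected[2]
    # CSD output is still reference-free
    out2 = preprocess(ep.with_data(ep.data + 3.0), montage20)
    assert np.abs(out.data - out2.data).max() < 1e-6


def test_montage_invariants(montage20):
    assert len(set(montage20.channels)) == 20
    assert np.allclose(np.linalg.norm(montage20.positions, axis=1), 1.0, atol=1e-9)
    for name in ("C3", "P4", "Pz", "Cz", "P3", "F7", "T7", "T8", "P7", "F8",
                 "P8", "O1", "O2", "Oz"):
        assert name in montage20.channels
    with pytest.raises(MontageError):
        Montage(("a", "a"), np.array([[0, 0, 1.0], [0, 1.0, 0]]))
    with pytest.raises(MontageError):
        Montage(("a", "b"), np.array([[0, 0, 2.0], [0, 1.0, 0]]))


def test_montage_json_roundtrip(tmp_path, montage20):
    path = tmp_path / "m.json"
    montage20.to_json(path)
    back = Montage.from_json(path)
    assert back.channels == montage20.channels
    assert np.allclose(back.positions, montage20.positions, atol=1e-12)
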