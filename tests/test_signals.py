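import numpy as np
import pytest
from scipy.signal import find_peaks

import ecgmcm as e


@pytest.fixture()
def tone():
    def make(freq, fs=500.0, duration=10.0, amp=1.0):
        t = np.arange(int(duration * fs)) / fs
        return e.ECGSignal(fs, amp * np.sin(2 * np.pi * freq * t))

    return make


# -- generator ----------------------------------------------------------------


def test_generator_beat_count_and_amplitude(clean_ecg):
    """60 bpm over 10 s at 500 Hz: exactly 10 R peaks at the set amplitude."""
    peaks, _ = find_peaks(clean_ecg.samples, height=0.2)
    assert len(peaks) == 10
    # adjacent Q/S deflections shave ~1.2% off the nominal 0.30 mV R peak
    assert clean_ecg.samples[peaks] == pytest.approx(0.30, rel=0.02)
    assert clean_ecg.fs == 500 and clean_ecg.n == 5000


def test_generator_determinism_and_overrides(clean_ecg):
    again = e.generate_ecg(60, 10, 500, seed=99)  # seed is inert
    assert np.array_equal(again.samples, clean_ecg.samples)
    flat = e.generate_ecg(60, 10, 500,
                          wave_amplitudes=dict.fromkeys("PQRST", 0.0))
    assert np.all(flat.samples == 0.0)
    tall = e.generate_ecg(60, 10, 500, wave_amplitudes={"R": 1.0})
    assert tall.samples.max() == pytest.approx(1.0, rel=0.01)


def test_generator_argument_validation():
    with pytest.raises(ValueError):
        e.generate_ecg(heart_rate_bpm=20)
    with pytest.raises(ValueError):
        e.generate_ecg(fs=50)
    with pytest.raises(ValueError):
        e.generate_ecg(wave_amplitudes={"X": 1.0})


def test_baseline_and_noise_moments(clean_ecg):
    shifted = e.add_baseline_and_noise(clean_ecg, 3.00, 0.0, 0.2, 0.0)
    assert np.allclose(shifted.samples - clean_ecg.samples, 3.00)
    zero = e.ECGSignal(500, np.zeros(10_000))
    noisy = e.add_baseline_and_noise(zero, 0.0, 0.0, 0.2, 0.01, seed=5)
    assert noisy.samples.std(ddof=1) == pytest.approx(0.01, rel=0.05)
    same = e.add_baseline_and_noise(zero, 0.0, 0.0, 0.2, 0.01, seed=5)
    assert np.array_equal(same.samples, noisy.samples)


# -- detrending ---------------------------------------------------------------


def test_detrend_removes_ramp():
    t = np.arange(5000) / 500.0
    ramp = e.ECGSignal(500, 2.0 * t + 1.0)
    out = e.detrend(ramp)
    assert np.abs(out.samples).max() < 1e-9
    assert abs(out.samples.mean()) < 1e-6


def test_detrend_preserves_band_content(tone):
    t = np.arange(5000) / 500.0
    mixed = e.ECGSignal(500, 2.0 * t + np.sin(2 * np.pi * 10 * t))
    out = e.detrend(mixed)
    inner = out.samples[250:-250]  # away from edge effects
    assert inner.max() == pytest.approx(1.0, rel=0.02)
    assert abs(out.samples.mean()) < 1e-6
    # idempotence on an already trendless zero-mean signal
    sine = tone(10.0)
    once = e.detrend(sine)
    rms = np.sqrt(np.mean(sine.samples ** 2))
    assert np.sqrt(np.mean((once.samples - sine.samples) ** 2)) < 0.02 * rms


def test_detrend_too_short():
    with pytest.raises(ValueError):
        e.detrend(e.ECGSignal(500, np.array([1.0])))


# -- low-pass filter ----------------------------------------------------------


def test_lowpass_stopband_and_passband(tone):
    power = lambda s: float(np.sum(s.samples ** 2))
    s40 = tone(40.0)
    assert power(e.lowpass(s40, 30.0)) < 0.05 * power(s40)
    s5 = tone(5.0)
    assert power(e.lowpass(s5, 30.0)) == pytest.approx(power(s5), rel=0.02)
    const = e.ECGSignal(500, np.full(5000, 2.5))
    assert np.allclose(e.lowpass(const, 30.0).samples, 2.5)


def test_lowpass_preserves_length_and_rejects_bad_cutoff(clean_ecg):
    out = e.lowpass(clean_ecg, 30.0)
    assert out.n == clean_ecg.n and out.fs == clean_ecg.fs
    for bad in (0.0, 250.0, 300.0):
        with pytest.raises(ValueError):
            e.lowpass(clean_ecg, bad)


def test_detrend_and_lowpass_nearly_commute(clean_ecg):
    noisy = e.add_baseline_and_noise(clean_ecg, 3.0, 0.05, 0.2, 0.01, seed=2)
    a = e.lowpass(e.detrend(noisy)).samples
    b = e.detrend(e.lowpass(noisy)).samples
    rms = np.sqrt(np.mean(a ** 2))
    assert np.sqrt(np.mean((a - b) ** 2)) < 0.05 * rms


# -- spectra ------------------------------------------------------------------


def test_power_spectrum_constant_signal():
    n, c = 1000, 2.0
    spec = e.power_spectrum(e.ECGSignal(500, np.full(n, c)))
    peak = np.argmax(spec.power)
    assert spec.frequencies[peak] == 0.0
    assert spec.power[peak] == pytest.approx(n * c * c, rel=1e-12)
    assert np.all(spec.power >= 0)


def test_power_spectrum_sine_is_symmetric(tone):
    spec = e.power_spectrum(tone(25.0))
    top = np.argsort(spec.power)[-2:]
    assert sorted(spec.frequencies[top]) == pytest.approx([-25.0, 25.0], abs=0.06)
    # grid symmetric about zero
    assert spec.frequencies[0] == pytest.approx(-spec.frequencies[-1], abs=0.1)


def test_power_spectrum_parseval():
    x = np.random.default_rng(0).normal(size=4096)
    spec = e.power_spectrum(e.ECGSignal(500, x))
    assert spec.power.sum() == pytest.approx(np.sum(x ** 2), rel=1e-6)


def test_lowpass_removes_power_above_cutoff():
    x = np.random.default_rng(1).normal(size=20_000)
    filtered = e.lowpass(e.ECGSignal(500, x), 30.0)
    spec = e.power_spectrum(filtered)
    above = np.abs(spec.frequencies) > 30.0
    assert spec.power[above].sum() < 0.05 * spec.power.sum()


# -- spectrogram --------------------------------------------------------------


def test_spectrogram_white_noise_is_stationary():
    x = np.random.default_rng(4).normal(size=10_000)
    sg = e.spectrogram(e.ECGSignal(500, x), window_s=1.0, overlap_fraction=0.5)
    row_power = sg.power.sum(axis=1)
    assert np.ptp(row_power) < 0.5 * row_power.mean()


def test_spectrogram_tracks_frequency_step():
    t = np.arange(5000) / 500.0
    x = np.where(t < 5.0, np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 40 * t))
    sg = e.spectrogram(e.ECGSignal(500, x), window_s=0.25, overlap_fraction=0.5)
    half = len(sg.times) // 2
    lo = sg.frequencies[np.argmax(sg.power[:half].sum(axis=0))]
    hi = sg.frequencies[np.argmax(sg.power[half:].sum(axis=0))]
    assert lo == pytest.approx(10.0, abs=4.1)
    assert hi == pytest.approx(40.0, abs=4.1)


def test_spectrogram_zero_signal_and_validation(clean_ecg):
    sg = e.spectrogram(e.ECGSignal(500, np.zeros(2500)), 0.25, 0.5)
    assert np.all(sg.power == 0.0)
    with pytest.raises(ValueError):
        e.spectrogram(clean_ecg, window_s=20.0)
    with pytest.raises(ValueError):
        e.spectrogram(clean_ecg, window_s=0.25, overlap_fraction=1.0)


# -- parameter recovery -------------------------------------------------------


def test_recovers_baseline_and_noise(clean_ecg):
    """Round trip through the generator: baseline within 1%, noise within 10%."""
    noisy = e.add_baseline_and_noise(clean_ecg, 3.00, 0.05, 0.2, 0.01, seed=7)
    base_mean, base_sd, noise_sd = e.estimate_noise_params(noisy)
    assert base_mean == pytest.approx(3.00, rel=0.01)
    assert noise_sd == pytest.approx(0.01, rel=0.10)
    # baseline spread is dominated by the 0.05 mV drift (rms 0.035)
    assert base_sd == pytest.approx(0.05 / np.sqrt(2), rel=0.25)


def test_noiseless_signal_has_no_noise_floor(clean_ecg):
    _, _, noise_sd = e.estimate_noise_params(clean_ecg)
    assert noise_sd < 1e-6


def test_pure_noise_has_zero_baseline():
    x = np.random.default_rng(3).normal(0.0, 0.01, 5000)
    base_mean, _, noise_sd = e.estimate_noise_params(e.ECGSignal(500, x))
    se = 0.01 / np.sqrt(5000)
    assert abs(base_mean) < 3 * se
    assert noise_sd == pytest.approx(0.01, rel=0.10)


def test_estimate_requires_five_seconds():
    with pytest.raises(ValueError):
        e.estimate_noise_params(e.ECGSignal(500, np.zeros(1000)))


# -- I/O ----------------------------------------------------------------------


def test_csv_round_trip(tmp_path, clean_ecg):
    path = tmp_path / "sig.csv"
    clean_ecg.to_csv(path)
    again = e.ECGSignal.from_csv(path)
    assert again.fs == pytest.approx(clean_ecg.fs, rel=1e-9)
    assert np.allclose(again.samples, clean_ecg.samples)
    assert path.read_text().splitlines()[0] == "time_s,amplitude_mV"


def test_csv_rejects_irregular_sampling(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("time_s,amplitude_mV\n0.0,1.0\n0.1,1.0\n0.3,1.0\n")
    with pytest.raises(ValueError):
        e.ECGSignal.from_csv(path)
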