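"""Synthetic ECG generation and the signal analyses around the amplifier model.

The generator sums Gaussian-shaped P, Q, R, S and T deflections per beat —
a deliberately clean morphological stand-in for recorded ECG traces.  On top
of it, :func:`add_baseline_and_noise` superimposes the disturbances the
uncertainty model parameterises: a constant offset plus slow sinusoidal
drift (baseline wander, sub-0.5 Hz) and white Gaussian noise.

The analyses mirror a standard conditioning chain:

* :func:`detrend` — best-fit line plus the sub-0.5 Hz moving-average
  baseline removed, zero-mean output;
* :func:`lowpass` — zero-phase Butterworth (order 4, default corner 30 Hz);
* :func:`power_spectrum` — two-sided squared-magnitude spectrum centred at
  zero frequency, normalised by the number of frequency samples;
* :func:`spectrogram` — short-time power spectra on a sliding window;
* :func:`estimate_noise_params` — recovers the (baseline mean/sd, noise sd)
  triple the amplifier uncertainty model takes as input.

All operations preserve the sampling rate and sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ECGSignal",
    "SpectrumResult",
    "Spectrogram",
    "generate_ecg",
    "add_baseline_and_noise",
    "detrend",
    "lowpass",
    "power_spectrum",
    "spectrogram",
    "estimate_noise_params",
]

#: Default per-beat deflections: amplitude (mV), centre offset from the R
#: peak (s, at 60 bpm; offsets and widths scale with the beat interval) and
#: Gaussian width sigma (s).  Amplitudes follow the usual lead-II morphology
#: ratios scaled so the R peak matches the 0.30 mV input level of the
#: amplifier uncertainty model.
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.045, -0.200, 0.040),
    "Q": (-0.030, -0.026, 0.010),
    "R": (0.300, 0.000, 0.014),
    "S": (-0.075, 0.026, 0.010),
    "T": (0.105, 0.300, 0.060),
}


@dataclass(frozen=True)
class ECGSignal:
    """A uniformly sampled voltage trace in mV."""

    fs: float
    samples: np.ndarray = field(repr=False)
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise ValueError("signal must contain at least one sample")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "ECGSignal":
        return ECGSignal(self.fs, samples, self.t0)

    # -- I/O -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t, "amplitude_mV": self.samples})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ECGSignal":
        df = pd.read_csv(path)
        if not {"time_s", "amplitude_mV"} <= set(df.columns):
            raise ValueError(
                "signal CSV needs columns 'time_s' and 'amplitude_mV', "
                f"got {list(df.columns)}"
            )
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise ValueError("signal CSV needs at least two samples")
        dt = np.diff(t)
        if dt.min() <= 0 or np.ptp(dt) > 1e-6 * np.median(dt) + 1e-12:
            raise ValueError("signal CSV must be uniformly sampled in time")
        return cls(1.0 / float(np.median(dt)), df["amplitude_mV"].to_numpy(float),
                   t0=float(t[0]))


@dataclass(frozen=True)
class SpectrumResult:
    """Two-sided power spectrum centred at zero frequency.

    ``power[k] = |X[k]|^2 / n`` with ``X`` the DFT of the signal, so the
    total power equals the signal's summed squared samples (Parseval).
    """

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_Hz": self.frequencies,
                             "power_mV2": self.power})


@dataclass(frozen=True)
class Spectrogram:
    """Short-time power spectra: ``power[i, j]`` at ``times[i]``, ``frequencies[j]``."""

    times: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.power, index=self.times, columns=self.frequencies)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_ecg(
    heart_rate_bpm: float = 60.0,
    duration_s: float = 10.0,
    fs: float = 500.0,
    wave_amplitudes: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> ECGSignal:
    """Noiseless, drift-free synthetic ECG trace.

    Each beat is the sum of Gaussian P, Q, R, S, T deflections; beat centres
    (R peaks) sit at ``(k + 1/2) * RR``.  ``wave_amplitudes`` overrides
    individual deflection amplitudes in mV.  The generator is deterministic;
    ``seed`` is accepted for interface symmetry with the noisy stages.
    """
    del seed  # deterministic by construction
    if not 30.0 <= heart_rate_bpm <= 220.0:
        raise ValueError(
            f"heart rate must be within [30, 220] bpm, got {heart_rate_bpm}"
        )
    if fs < 100.0:
        raise ValueError(f"sampling rate must be >= 100 Hz, got {fs}")
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    amplitudes = dict()
    for w, (amp, _, _) in DEFAULT_WAVES.items():
        amplitudes[w] = amp
    if wave_amplitudes:
        unknown = set(wave_amplitudes) - set(DEFAULT_WAVES)
        if unknown:
            raise ValueError(f"unknown wave labels: {sorted(unknown)}")
        amplitudes.update(wave_amplitudes)

    rr = 60.0 / heart_rate_bpm
    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.zeros_like(t)
    n_beats = int(np.floor(duration_s / rr))
    for k in range(n_beats):
        centre = (k + 0.5) * rr
        for w, (_, offset, width) in DEFAULT_WAVES.items():
            mu = centre + offset * rr
            sig = width * rr
            x += amplitudes[w] * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return ECGSignal(fs, x)


def add_baseline_and_noise(
    sig: ECGSignal,
    baseline_mean: float = 3.00,
    drift_amplitude: float = 0.05,
    drift_freq: float = 0.20,
    noise_sd: float = 0.01,
    seed: int | None = 0,
) -> ECGSignal:
    """Superimpose constant offset, slow sinusoidal drift and white noise.

    Defaults match the disturbance levels the amplifier uncertainty model
    assigns: a 3.00 mV baseline and 0.01 mV rms noise; the drift (0.05 mV at
    0.2 Hz) emulates respiratory baseline wander below the 0.5 Hz trend
    boundary.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    out = sig.samples + baseline_mean
    if drift_amplitude != 0.0:
        out = out + drift_amplitude * np.sin(2.0 * np.pi * drift_freq * sig.t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, size=sig.n)
    return sig.with_samples(out)


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

#: Boundary between "baseline" and signal content, Hz (below cardiac
#: fundamentals, which start at 0.5 Hz for 30 bpm).
TREND_CUTOFF_HZ = 0.5


def _moving_average_baseline(x: np.ndarray, fs: float,
                             cutoff_hz: float = TREND_CUTOFF_HZ) -> np.ndarray:
    window = max(2, int(round(fs / cutoff_hz)))
    window = min(window, x.size)
    return uniform_filter1d(x, size=window, mode="reflect")


def detrend(sig: ECGSignal) -> ECGSignal:
    """Remove the best-fit line and the sub-0.5 Hz moving-average baseline.

    The output is exactly zero-mean.  A pure linear ramp maps to zero; band
    content above ~1 Hz passes essentially unchanged (the 2 s moving average
    has nulls at integer multiples of 0.5 Hz).
    """
    if sig.n < 2:
        raise ValueError("detrend needs at least 2 samples")
    x = sps.detrend(sig.samples, type="linear")
    x = x - _moving_average_baseline(x, sig.fs)
    x = x - x.mean()
    return sig.with_samples(x)


def lowpass(sig: ECGSignal, cutoff_hz: float = 30.0, order: int = 4) -> ECGSignal:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    The two-pass application squares the magnitude response, so the
    effective passband (below half the corner) is flat to well under 2% and
    the stopband roll-off is twice the single-pass order.
    """
    nyquist = sig.fs / 2.0
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {nyquist}) Hz, got {cutoff_hz}"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.fs, output="sos")
    return sig.with_samples(sps.sosfiltfilt(sos, sig.samples))


# ---------------------------------------------------------------------------
# Spectral analysis
# ---------------------------------------------------------------------------


def power_spectrum(sig: ECGSignal) -> SpectrumResult:
    """Two-sided centred power spectrum, ``|DFT|^2`` over the number of bins."""
    x = sig.samples
    X = np.fft.fftshift(np.fft.fft(x))
    freqs = np.fft.fftshift(np.fft.fftfreq(x.size, d=1.0 / sig.fs))
    power = (np.abs(X) ** 2) / x.size
    return SpectrumResult(frequencies=freqs, power=power)


def spectrogram(
    sig: ECGSignal, window_s: float = 0.25, overlap_fraction: float = 0.5
) -> Spectrogram:
    """Sliding-window power spectra (Hann window, one-sided).

    Rows are window centre times, columns frequencies; values carry the same
    mV^2 power scaling as :func:`power_spectrum` restricted to one side.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(
            f"overlap_fraction must be in [0, 1), got {overlap_fraction}"
        )
    nperseg = int(round(window_s * sig.fs))
    if nperseg < 2 or window_s >= sig.duration:
        raise ValueError(
            f"window of {window_s} s is too long for a {sig.duration} s signal"
        )
    noverlap = int(nperseg * overlap_fraction)
    freqs, times, Sxx = sps.spectrogram(
        sig.samples,
        fs=sig.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        scaling="spectrum",
        mode="psd",
    )
    return Spectrogram(times=times + sig.t0, frequencies=freqs, power=Sxx.T)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def _median_baseline(x: np.ndarray, fs: float) -> np.ndarray:
    """Baseline estimate by two-stage rolling median (0.2 s then 0.6 s).

    Medians reject the sparse P-QRS-T deflections (each occupies well under
    half of its window), so — unlike a moving average — the estimate does
    not inherit the waveform's own nonzero beat average.
    """
    s = pd.Series(x)
    w1 = max(3, int(round(0.2 * fs)) | 1)
    w2 = max(3, int(round(0.6 * fs)) | 1)
    b = s.rolling(w1, center=True, min_periods=1).median()
    b = b.rolling(w2, center=True, min_periods=1).median()
    return b.to_numpy()


def estimate_noise_params(
    sig: ECGSignal, noise_cutoff_hz: float = 30.0
) -> tuple[float, float, float]:
    """Recover ``(baseline_mean, baseline_sd, noise_sd)`` in mV.

    Baseline statistics come from the slow trend isolated by a two-stage
    rolling median; the noise sd comes from the spectral floor of the
    residual left above the ``noise_cutoff_hz`` low-pass.  The floor is a
    Welch estimate averaged over the band from max(2x cutoff, 0.6x Nyquist)
    up to Nyquist — well above both the filter transition and the spectral
    support of the cardiac deflections, where broadband noise is the only
    remaining content — with 0.5 s of each edge discarded to drop the
    zero-phase filter transients.  The band-floor route makes the estimate
    independent of the filter's roll-off shape.
    """
    if sig.duration < 5.0:
        raise ValueError(
            f"noise-parameter estimation needs >= 5 s of signal, got "
            f"{sig.duration:.2f} s"
        )
    baseline = _median_baseline(sig.samples, sig.fs)
    baseline_mean = float(baseline.mean())
    baseline_sd = float(baseline.std(ddof=1))

    residual = sig.samples - lowpass(sig, cutoff_hz=noise_cutoff_hz).samples
    trim = int(round(0.5 * sig.fs))
    residual = residual[trim: sig.n - trim] if sig.n > 2 * trim else residual
    nperseg = min(residual.size, 1024)
    freqs, psd = sps.welch(residual, fs=sig.fs, window="hann", nperseg=nperseg)
    nyquist = sig.fs / 2.0
    band_lo = min(max(2.0 * noise_cutoff_hz, 0.6 * nyquist), 0.9 * nyquist)
    band = freqs >= band_lo
    if not band.any():
        raise ValueError("no spectral band above the noise cutoff; raise fs")
    noise_var = float(psd[band].mean()) * (sig.fs / 2.0)
    return baseline_mean, baseline_sd, float(np.sqrt(max(noise_var, 0.0)))
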