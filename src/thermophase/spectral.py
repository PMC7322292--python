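"""Fourier amplitude spectra and stimulus-peak-locked segmentation.

Trend-free oscillatory stimulation (the Osci17 protocol: 15 cycles at
0.025 Hz) drives entrained calcium activity whose strength is read off
the single-sided Fourier amplitude spectrum at the stimulus frequency
omega* = 0.025 Hz.  The spectrum is scaled so a unit-amplitude sinusoid
at an on-grid frequency has amplitude ~1, which makes per-animal values
comparable across record lengths.

For epoch-based displays, records are segmented into equal windows
time-locked to the interior local maxima of the thermal stimulus, with
the time axis of each window redefined so the stimulus peak sits at
t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._peaks import local_maxima
from .errors import GridAlignmentError, LengthError, ParameterError
from .preprocess import CalciumSignal, _check_uniform_grid


@dataclass
class AmplitudeSpectrum:
    freq: np.ndarray       # Hz, ascending from 0
    amplitude: np.ndarray  # >= 0, sinusoid-amplitude scaling
    channel: str = ""

    def argmax_frequency(self) -> float:
        """Frequency of the largest spectral amplitude."""
        return float(self.freq[int(np.argmax(self.amplitude))])


@dataclass
class EpochSet:
    """Equal-length windows re-timed so the stimulus peak is at t = 0."""

    rel_time: np.ndarray      # shared relative grid, 0 at the stimulus peak
    epochs: np.ndarray        # shape (n_epochs, len(rel_time))
    peak_times: np.ndarray    # absolute times of the stimulus maxima used

    @property
    def n_epochs(self) -> int:
        return int(self.epochs.shape[0])

    def mean(self) -> np.ndarray:
        return self.epochs.mean(axis=0)


def fourier_amplitude(sig: CalciumSignal, taper: str = "rect") -> AmplitudeSpectrum:
    """Single-sided amplitude spectrum of the mean-subtracted signal.

    ``taper`` is "rect" (none; records holding an integer number of
    stimulus cycles leak negligibly) or "hann".
    """
    _check_uniform_grid(sig.time, who="spectrum input")
    y = sig.y - np.mean(sig.y)
    n = y.size
    if n < 16:
        raise LengthError(f"need at least 16 samples for a spectrum, got {n}")
    if taper == "hann":
        w = np.hanning(n)
        y = y * w / np.mean(w)
    elif taper != "rect":
        raise ParameterError(f"unknown taper {taper!r}")
    amp = np.abs(np.fft.rfft(y)) * 2.0 / n
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    freq = np.fft.rfftfreq(n, d=sig.dt)
    return AmplitudeSpectrum(freq=freq, amplitude=amp, channel=sig.channel)


def amplitude_at(spec: AmplitudeSpectrum, omega_star: float) -> float:
    """Amplitude at the grid frequency nearest ``omega_star``."""
    if omega_star > spec.freq[-1]:
        raise ParameterError(
            f"omega_star {omega_star} Hz above the spectral range {spec.freq[-1]} Hz"
        )
    return float(spec.amplitude[int(np.argmin(np.abs(spec.freq - omega_star)))])


def segment_by_stimulus_peaks(
    sig: CalciumSignal, stimulus: np.ndarray, half_width: float
) -> EpochSet:
    """One epoch per interior stimulus maximum, re-timed so the peak is t = 0.

    Peaks closer than ``half_width`` to a record edge are skipped.  A
    stimulus with no interior maxima yields an empty epoch set.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.shape != sig.time.shape:
        raise GridAlignmentError("stimulus must share the signal's time grid")
    dt = sig.dt
    half_n = int(round(half_width / dt))
    if half_n < 1:
        raise ParameterError("half_width must cover at least one sample")
    peaks = local_maxima(stimulus)
    peaks = peaks[(peaks - half_n >= 0) & (peaks + half_n < sig.y.size)]
    rel_time = np.arange(-half_n, half_n + 1) * dt
    if peaks.size == 0:
        return EpochSet(
            rel_time=rel_time,
            epochs=np.empty((0, rel_time.size)),
            peak_times=np.empty(0),
        )
    epochs = np.stack([sig.y[p - half_n: p + half_n + 1] for p in peaks])
    return EpochSet(rel_time=rel_time, epochs=epochs, peak_times=sig.time[peaks])
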