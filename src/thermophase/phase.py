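"""Instantaneous phase shift between AFD and AIY via the Hilbert transform.

The pipeline follows the standard analytic-signal route for slowly
oscillating calcium activity:

1. differentiate each calcium signal (central differences) and low-pass
   the derivative with a zero-phase Butterworth filter (passband edge
   0.12 Hz, stopband edge 1.2 Hz) -> x(t);
2. take the discrete Hilbert transform to get the imaginary part and
   form the analytic signal z = x + i*x_hat; its argument is the
   instantaneous phase theta(t);
3. phi(t) = theta_AFD(t) - theta_AIY(t), wrapped to [-pi, pi].  phi = 0
   is in-phase, phi = +/-pi anti-phase; phi > 0 means AIY lags AFD;
4. sample phi at the times where the AIY derivative peaks, and summarize
   per animal by the circular mean weighted by the AIY-derivative
   amplitude at each peak, so low-amplitude (noise-dominated) events do
   not distort the summary.

Derivatives, rather than the signals themselves, carry the phase: a
monotone rise and a plateau have very different phases as raw signals
but the derivative isolates the oscillatory component the stimulus
drives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._peaks import local_maxima
from .errors import DegenerateSignalError, GridAlignmentError, LengthError, ParameterError
from .preprocess import AnimalRecording, CalciumSignal, preprocess_recording
from .xcorr import window_mask

PASSBAND_EDGE_HZ = 0.12
STOPBAND_EDGE_HZ = 1.2


def wrap_angle(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass
class AnalyticSignal:
    """Filtered derivative x, its Hilbert transform, and the instantaneous phase."""

    time: np.ndarray
    x: np.ndarray
    x_hat: np.ndarray
    inst_phase: np.ndarray
    reliable: np.ndarray  # False within one passband period of either record edge

    @property
    def envelope(self) -> np.ndarray:
        return np.hypot(self.x, self.x_hat)


@dataclass
class PhaseShiftSeries:
    time: np.ndarray
    phi: np.ndarray  # wrapped to [-pi, pi]
    reliable: np.ndarray


@dataclass
class PhasePeakSample:
    """Phase shifts sampled where the AIY derivative peaks, with their weights."""

    event_times: np.ndarray
    event_indices: np.ndarray
    phi_k: np.ndarray
    R_k: np.ndarray  # AIY-derivative amplitude at the peak, floored at 0

    @property
    def n_events(self) -> int:
        return int(self.event_times.size)


@dataclass
class PhaseSummary:
    """Per-animal amplitude-weighted mean phase-shift direction."""

    animal_id: str
    phi_bar: float  # radians, NaN when the resultant is undefined
    resultant_length: float
    n_events: int


def filtered_derivative(
    sig: CalciumSignal,
    passband_edge: float = PASSBAND_EDGE_HZ,
    stopband_edge: float = STOPBAND_EDGE_HZ,
) -> np.ndarray:
    """Central-difference derivative, low-passed with a zero-phase Butterworth.

    The filter order/cutoff are chosen (scipy ``buttord``) to keep ripple
    <= 3 dB at the passband edge and attenuation >= 20 dB at the stopband
    edge.  When the stopband edge exceeds Nyquist it is clipped just
    below Nyquist: frequencies above Nyquist do not exist in the sampled
    record, so the attenuation requirement is vacuous there.
    """
    fs = sig.fs
    nyq = fs / 2.0
    if passband_edge >= nyq:
        raise ParameterError(f"passband edge {passband_edge} Hz >= Nyquist {nyq} Hz")
    ws = min(stopband_edge, 0.99 * nyq)
    if ws <= passband_edge:
        raise ParameterError("stopband edge must exceed the passband edge")
    dy = np.gradient(sig.y, sig.dt)
    order, wn = sps.buttord(passband_edge, ws, gpass=3.0, gstop=20.0, fs=fs)
    order = max(order, 1)
    sos = sps.butter(order, wn, btype="lowpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if dy.size <= padlen:
        raise LengthError(
            f"signal of {dy.size} samples too short for the derivative filter "
            f"(needs > {padlen})"
        )
    return sps.sosfiltfilt(sos, dy)


def analytic_signal(
    time: np.ndarray, x: np.ndarray, passband_edge: float = PASSBAND_EDGE_HZ
) -> AnalyticSignal:
    """Discrete Hilbert transform of x; flags one passband period at each edge.

    The FFT-based Hilbert transform assumes periodic extension, so the
    first and last 1/passband_edge seconds carry edge artifacts and are
    marked unreliable rather than removed.
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    if x.size < 8:
        raise LengthError("need at least 8 samples for the Hilbert transform")
    if not np.any(x):
        raise DegenerateSignalError("all-zero signal has no defined phase")
    z = sps.hilbert(x)
    dt = float(np.median(np.diff(time)))
    n_edge = int(np.ceil((1.0 / passband_edge) / dt))
    reliable = np.ones(x.size, dtype=bool)
    reliable[:n_edge] = False
    reliable[x.size - n_edge:] = False
    return AnalyticSignal(
        time=time, x=x, x_hat=z.imag, inst_phase=np.angle(z), reliable=reliable
    )


def phase_shift(afd: AnalyticSignal, aiy: AnalyticSignal) -> PhaseShiftSeries:
    """phi(t) = theta_AFD(t) - theta_AIY(t), wrapped to [-pi, pi].

    Positive phi means the AIY response lags the AFD response.
    """
    if afd.time.shape != aiy.time.shape or not np.allclose(afd.time, aiy.time):
        raise GridAlignmentError("AFD and AIY analytic signals must share one grid")
    phi = wrap_angle(afd.inst_phase - aiy.inst_phase)
    return PhaseShiftSeries(
        time=afd.time, phi=phi, reliable=afd.reliable & aiy.reliable
    )


def sample_at_aiy_peaks(
    phi: PhaseShiftSeries, aiy_x: np.ndarray, mask: np.ndarray | None = None
) -> PhasePeakSample:
    """Sample phi(t) at interior local maxima of the AIY derivative.

    Events in unreliable edge regions, or outside the optional boolean
    ``mask`` (e.g. a temperature window), are discarded.  The weight of
    each event is the AIY-derivative value there, floored at 0.
    """
    aiy_x = np.asarray(aiy_x, dtype=float)
    peaks = local_maxima(aiy_x)
    keep = phi.reliable[peaks]
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)[peaks]
    peaks = peaks[keep]
    return PhasePeakSample(
        event_times=phi.time[peaks],
        event_indices=peaks,
        phi_k=phi.phi[peaks],
        R_k=np.clip(aiy_x[peaks], 0.0, None),
    )


def weighted_mean_direction(
    sample: PhasePeakSample, animal_id: str = ""
) -> PhaseSummary:
    """phi_bar = arg(sum_k R_k exp(i phi_k)); resultant length in [0, 1].

    Returns NaN direction when the total weight is zero or the resultant
    cancels (e.g. two equal-weight antipodal events).
    """
    if sample.n_events < 1:
        raise ParameterError("need at least one event to form a mean direction")
    total_w = float(np.sum(sample.R_k))
    resultant = np.sum(sample.R_k * np.exp(1j * sample.phi_k))
    if total_w == 0.0 or np.abs(resultant) < 1e-12 * total_w:
        return PhaseSummary(animal_id, float("nan"), 0.0, sample.n_events)
    return PhaseSummary(
        animal_id=animal_id,
        phi_bar=float(np.angle(resultant)),
        resultant_length=float(np.abs(resultant) / total_w),
        n_events=sample.n_events,
    )


def pair_phase_summary(
    afd: CalciumSignal,
    aiy: CalciumSignal,
    mask: np.ndarray | None = None,
    passband_edge: float = PASSBAND_EDGE_HZ,
    stopband_edge: float = STOPBAND_EDGE_HZ,
    animal_id: str = "",
) -> PhaseSummary:
    """Full pipeline on one AFD/AIY pair of calcium signals."""
    x_afd = filtered_derivative(afd, passband_edge, stopband_edge)
    x_aiy = filtered_derivative(aiy, passband_edge, stopband_edge)
    za = analytic_signal(afd.time, x_afd, passband_edge)
    zy = analytic_signal(aiy.time, x_aiy, passband_edge)
    phi = phase_shift(za, zy)
    sample = sample_at_aiy_peaks(phi, x_aiy, mask=mask)
    if sample.n_events == 0:
        return PhaseSummary(animal_id, float("nan"), float("nan"), 0)
    return weighted_mean_direction(sample, animal_id=animal_id)


def analyze_cohort(
    recordings: list[AnimalRecording],
    temp_window: tuple[float, float] | None = None,
    time_window: tuple[float, float] | None = None,
    detrend_cutoff_hz: float = 0.01,
    passband_edge: float = PASSBAND_EDGE_HZ,
    stopband_edge: float = STOPBAND_EDGE_HZ,
) -> pd.DataFrame:
    """Preprocess and run the phase pipeline on every animal of a cohort.

    Event sampling excludes max(1/passband_edge, 1/detrend_cutoff)
    seconds at each record end: the zero-phase detrend filter leaves
    transients of ~1/cutoff seconds on ramp-bearing records whose large
    derivatives would otherwise dominate the amplitude-weighted mean.

    Returns a table with one row per animal: animal_id, condition,
    phi_bar_rad, resultant_length, n_events.
    """
    rows = []
    for rec in recordings:
        afd, aiy = preprocess_recording(rec, detrend_cutoff_hz)
        mask = window_mask(rec.time, time_window, rec.temperature, temp_window)
        edge_s = max(1.0 / passband_edge, 1.0 / detrend_cutoff_hz)
        n_edge = int(np.ceil(edge_s / afd.dt))
        mask[:n_edge] = False
        mask[mask.size - n_edge:] = False
        summary = pair_phase_summary(
            afd, aiy, mask=mask, passband_edge=passband_edge,
            stopband_edge=stopband_edge, animal_id=rec.animal_id,
        )
        rows.append(
            {
                "animal_id": rec.animal_id,
                "condition": rec.condition,
                "phi_bar_rad": summary.phi_bar,
                "resultant_length": summary.resultant_length,
                "n_events": summary.n_events,
            }
        )
    return pd.DataFrame(rows)
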