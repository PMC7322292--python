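"""Non-stationary cross-correlation between AFD and AIY calcium signals.

The correlogram C(t, tau) = y_AFD(t) * y_AIY(t + tau) is a raw product of
the [0, 1]-scaled, detrended signals -- no mean subtraction or variance
scaling -- so it retains the time axis and shows *when* during a
time-varying stimulus the two neurons co-activate, not just at what lag.
tau > 0 means the AIY signal is read later than AFD.

Cells where t + tau falls outside the record are undefined (NaN), never
zero-padded: padding would fabricate anti-correlation at the edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._peaks import local_maxima
from .errors import GridAlignmentError, ParameterError
from .preprocess import CalciumSignal


@dataclass
class CrossCorrelogram:
    """C over (t, tau); per-animal product or ensemble mean across animals."""

    t: np.ndarray
    tau: np.ndarray
    C: np.ndarray  # shape (len(t), len(tau)), NaN where undefined
    scope: str = "per_animal"
    n_animals: int = 1
    animal_id: str = ""

    def at_lag(self, tau_star: float) -> np.ndarray:
        """The time series C(t, tau*) at the grid lag nearest ``tau_star``."""
        j = int(np.argmin(np.abs(self.tau - tau_star)))
        return self.C[:, j]

    def time_averaged(self) -> np.ndarray:
        """Mean over t of C(t, tau) at each lag, ignoring undefined cells."""
        return np.nanmean(self.C, axis=0)

    def best_lag(self) -> float:
        """Lag maximizing the time-averaged correlogram."""
        return float(self.tau[int(np.nanargmax(self.time_averaged()))])


def per_animal_correlogram(
    yA: CalciumSignal, yB: CalciumSignal, tau_max: float = 30.0
) -> CrossCorrelogram:
    """C(t, tau) = yA(t) * yB(t + tau) over a symmetric lag grid.

    Lags are rounded to the nearest grid multiple; the lag grid spans
    [-tau_max, +tau_max] at the signals' sampling step.
    """
    if yA.time.shape != yB.time.shape or not np.allclose(yA.time, yB.time):
        raise GridAlignmentError("yA and yB must share one time grid")
    dt = yA.dt
    n = yA.y.size
    max_shift = int(round(tau_max / dt))
    if max_shift > n // 2:
        raise ParameterError(
            f"tau_max {tau_max}s exceeds half the record length ({n * dt / 2:.0f}s)"
        )
    shifts = np.arange(-max_shift, max_shift + 1)
    C = np.full((n, shifts.size), np.nan)
    for j, s in enumerate(shifts):
        if s >= 0:
            C[: n - s, j] = yA.y[: n - s] * yB.y[s:]
        else:
            C[-s:, j] = yA.y[-s:] * yB.y[: n + s]
    return CrossCorrelogram(
        t=yA.time.copy(),
        tau=shifts * dt,
        C=C,
        scope="per_animal",
        n_animals=1,
        animal_id=yA.animal_id,
    )


def ensemble_correlogram(correlograms: list[CrossCorrelogram]) -> CrossCorrelogram:
    """Element-wise mean over animals at each defined (t, tau) cell."""
    if not correlograms:
        raise ParameterError("need at least one correlogram")
    ref = correlograms[0]
    for cg in correlograms[1:]:
        if cg.C.shape != ref.C.shape or not (
            np.allclose(cg.t, ref.t) and np.allclose(cg.tau, ref.tau)
        ):
            raise GridAlignmentError("all correlograms must share (t, tau) grids")
    stack = np.stack([cg.C for cg in correlograms])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(stack, axis=0)
    return CrossCorrelogram(
        t=ref.t.copy(),
        tau=ref.tau.copy(),
        C=mean,
        scope="ensemble",
        n_animals=len(correlograms),
    )


def window_mask(
    t: np.ndarray,
    window: tuple[float, float] | None = None,
    temperature: np.ndarray | None = None,
    temp_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Boolean mask over ``t`` from a time interval and/or a temperature interval.

    Windows may be given in time (seconds) or, following the reporting
    convention of thermal-stimulus experiments, as a temperature band
    mapped onto the times where the stimulus lies in that band.
    """
    mask = np.ones(t.shape, dtype=bool)
    if window is not None:
        mask &= (t >= window[0]) & (t <= window[1])
    if temp_window is not None:
        if temperature is None:
            raise ParameterError("temp_window requires the temperature series")
        mask &= (temperature >= temp_window[0]) & (temperature <= temp_window[1])
    return mask


def peak_summary(
    cg: CrossCorrelogram,
    tau_star: float,
    window: tuple[float, float] | None = None,
    temperature: np.ndarray | None = None,
    temp_window: tuple[float, float] | None = None,
) -> float:
    """Mean of the interior local maxima of C(t, tau*) within a window.

    Returns NaN when the windowed series has no interior local maximum
    (monotone or constant series).
    """
    series = cg.at_lag(tau_star)
    mask = window_mask(cg.t, window, temperature, temp_window)
    mask &= np.isfinite(series)
    if not mask.any():
        raise ParameterError("window selects no defined samples")
    vals = series[mask]
    peaks = local_maxima(vals)
    if peaks.size == 0:
        return float("nan")
    return float(np.mean(vals[peaks]))
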