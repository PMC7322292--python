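"""Raw fluorescence to calcium signals.

Converts per-animal fluorescence recordings into the dimensionless
"calcium signals" consumed by the correlation, phase and spectral
analyses: the trace is rescaled as dF/F0 against the per-animal minimum,
affinely mapped onto [0, 1], and freed of slow drift (bleaching,
baseline wander) with a zero-phase high-pass Butterworth filter.

The zero-phase (forward-backward) application matters: a causal filter
would impose a frequency-dependent lag that downstream phase estimates
could not distinguish from real AFD-AIY latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    DegenerateSignalError,
    FormatError,
    GridAlignmentError,
    LengthError,
    ParameterError,
    SchemaError,
)

CONDITIONS = ("well_fed", "starved")

#: default column layout of the input CSV
DEFAULT_SCHEMA = {
    "animal_id": "animal_id",
    "condition": "condition",
    "time": "time_s",
    "temperature": "temp_C",
    "afd": "F_afd",
    "aiy": "F_aiy",
}


def _check_uniform_grid(time: np.ndarray, rtol: float = 0.01, who: str = "series") -> float:
    time = np.asarray(time, dtype=float)
    if time.size < 3:
        raise LengthError(f"{who}: need at least 3 samples, got {time.size}")
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise FormatError(f"{who}: time must be strictly increasing")
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > rtol * dt:
        raise FormatError(f"{who}: time grid not uniform within {rtol:.0%} of dt={dt}")
    return dt


@dataclass
class FluorescenceTrace:
    """Raw fluorescence F(t) of one channel of one animal."""

    time: np.ndarray
    value: np.ndarray
    channel: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise FormatError("time and value must have the same length")
        _check_uniform_grid(self.time, who=f"trace {self.animal_id}/{self.channel}")
        if not np.all(np.isfinite(self.value)):
            raise FormatError(f"trace {self.animal_id}/{self.channel}: non-finite values")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass
class AnimalRecording:
    """One imaged animal: paired temperature, AFD and AIY traces on one grid."""

    animal_id: str
    condition: str
    temperature: np.ndarray
    afd: FluorescenceTrace
    aiy: FluorescenceTrace
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        self.temperature = np.asarray(self.temperature, dtype=float)
        if not (
            self.temperature.shape == self.afd.time.shape == self.aiy.time.shape
        ) or not np.allclose(self.afd.time, self.aiy.time):
            raise GridAlignmentError(
                f"animal {self.animal_id}: temperature/AFD/AIY grids differ"
            )

    @property
    def time(self) -> np.ndarray:
        return self.afd.time


@dataclass
class CalciumSignal:
    """Dimensionless signal at one preprocessing stage (dFF/normalized/detrended)."""

    time: np.ndarray
    y: np.ndarray
    stage: str = "raw"
    channel: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.time.shape != self.y.shape:
            raise FormatError("time and y must have the same length")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


def load_recordings(path: str | Path, schema: dict | None = None) -> list[AnimalRecording]:
    """Read a traces CSV into one :class:`AnimalRecording` per animal.

    Rows may arrive unsorted; they are time-sorted per animal.  The grid
    of every animal must be uniform within 1% step jitter.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [c for c in schema.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    out: list[AnimalRecording] = []
    for animal_id, grp in df.groupby(schema["animal_id"], sort=True):
        grp = grp.sort_values(schema["time"])
        time = grp[schema["time"]].to_numpy(dtype=float)
        _check_uniform_grid(time, who=f"animal {animal_id}")
        conditions = grp[schema["condition"]].unique()
        if len(conditions) != 1:
            raise FormatError(f"animal {animal_id}: more than one condition")
        out.append(
            AnimalRecording(
                animal_id=str(animal_id),
                condition=str(conditions[0]),
                temperature=grp[schema["temperature"]].to_numpy(dtype=float),
                afd=FluorescenceTrace(time, grp[schema["afd"]].to_numpy(dtype=float),
                                      channel="AFD", animal_id=str(animal_id)),
                aiy=FluorescenceTrace(time, grp[schema["aiy"]].to_numpy(dtype=float),
                                      channel="AIY", animal_id=str(animal_id)),
            )
        )
    return out


def delta_f_over_f(raw: FluorescenceTrace) -> CalciumSignal:
    """dF/F0 = (F - F0)/F0 with F0 the per-animal minimum of the trace."""
    f0 = float(np.min(raw.value))
    if f0 <= 0:
        raise DegenerateSignalError(
            f"trace {raw.animal_id}/{raw.channel}: min(F) = {f0} <= 0, baseline undefined"
        )
    return CalciumSignal(
        time=raw.time,
        y=(raw.value - f0) / f0,
        stage="dFF",
        channel=raw.channel,
        animal_id=raw.animal_id,
    )


def normalize_unit_interval(sig: CalciumSignal) -> CalciumSignal:
    """Affine rescale onto [0, 1]; order-preserving; constant input is rejected."""
    lo, hi = float(np.min(sig.y)), float(np.max(sig.y))
    if hi <= lo:
        raise DegenerateSignalError(
            f"signal {sig.animal_id}/{sig.channel}: constant, cannot normalize"
        )
    return replace(sig, y=(sig.y - lo) / (hi - lo), stage="normalized")


def detrend(sig: CalciumSignal, cutoff_hz: float = 0.01, order: int = 4) -> CalciumSignal:
    """Zero-phase high-pass Butterworth removing drift slower than ``cutoff_hz``.

    The record must be longer than three filter transients (~3/cutoff
    seconds); shorter records cannot separate drift from signal.
    """
    fs = sig.fs
    if cutoff_hz >= fs / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz >= Nyquist {fs / 2} Hz")
    duration = sig.time[-1] - sig.time[0]
    if duration <= 3.0 / cutoff_hz:
        raise LengthError(
            f"record of {duration:.0f}s too short to detrend at {cutoff_hz} Hz "
            f"(need > {3.0 / cutoff_hz:.0f}s)"
        )
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return replace(sig, y=sps.sosfiltfilt(sos, sig.y), stage="detrended")


def preprocess_trace(raw: FluorescenceTrace, detrend_cutoff_hz: float = 0.01) -> CalciumSignal:
    """Full chain: dF/F0 -> unit-interval normalization -> high-pass detrend."""
    return detrend(normalize_unit_interval(delta_f_over_f(raw)), cutoff_hz=detrend_cutoff_hz)


def preprocess_recording(
    rec: AnimalRecording, detrend_cutoff_hz: float = 0.01
) -> tuple[CalciumSignal, CalciumSignal]:
    """Preprocess both channels of one animal; returns (AFD, AIY) calcium signals."""
    return (
        preprocess_trace(rec.afd, detrend_cutoff_hz),
        preprocess_trace(rec.aiy, detrend_cutoff_hz),
    )
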