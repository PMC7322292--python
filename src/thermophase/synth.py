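"""Synthetic stimuli, neurons, cohorts and worm tracks.

Every analysis stage in this package is testable without external data
because this module emulates the experimental conditions end to end:

- the four thermal stimulus protocols: two oscillatory ramps (Osci1721:
  17.5-21.0 C; Osci1523: 15.8-23.0 C), a trend-free 0.025-Hz oscillation
  around 16.75 C repeated 15 times (Osci17), and a low-pass-filtered
  Gaussian-noise fluctuation clipped to 17.5-19.5 C (Fluc1719);
- AFD thermosensory responses as threshold-rectified temperature
  tracking: activity proportional to max(0, T - T*), so the response
  rises with warming and falls with cooling above the threshold T*;
- AIY interneuron responses as the convolution of the AFD activity with
  a synaptic kernel K(t) = U+ exp(-t^2/2 s+^2) + U- exp(-(t-tau)^2/2 s-^2)
  of superposed excitatory and inhibitory Gaussian components, rectified
  at zero and normalized.  The well-fed default kernel (fast excitation)
  reproduces in-phase AFD-AIY coupling; the starved default (slow
  excitation plus strong sharp inhibition) inverts the oscillatory
  component, reproducing anti-phase coupling while a positive baseline
  survives rectification;
- cohorts of animals with inter-animal parameter jitter and measurement
  noise, exported as raw-fluorescence-like recordings so the full
  preprocessing chain applies, with a ground-truth table alongside;
- worm tracks at ~13.5 Hz with heading noise, a configurable curving
  bias toward the warm (+x) side, and Poisson-injected omega-turn and
  reversal episodes whose times are returned as ground truth.

All generators are reproducible from (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .behavior import FRAME_RATE_HZ, WormTrack
from .errors import LengthError, ParameterError
from .preprocess import AnimalRecording, CalciumSignal, FluorescenceTrace

OMEGA_STAR_HZ = 0.025  # stimulus oscillation frequency shared by the protocols


@dataclass(frozen=True)
class StimulusProtocol:
    """Parametric description of one thermal stimulus protocol."""

    name: str
    t_low: float
    t_high: float
    frequency_hz: float = OMEGA_STAR_HZ
    duration_s: float = 600.0
    osc_amplitude: float = 0.5
    has_ramp: bool = True
    n_cycles: int | None = None
    noise_cutoff_hz: float | None = None  # Fluc protocols only

    def __post_init__(self) -> None:
        if self.t_high <= self.t_low:
            raise ParameterError("temperature bounds must be ordered")
        if self.duration_s <= 0:
            raise ParameterError("duration must be positive")

    @staticmethod
    def osci1721() -> "StimulusProtocol":
        return StimulusProtocol("Osci1721", 17.5, 21.0)

    @staticmethod
    def osci1523(t_low: float = 15.8) -> "StimulusProtocol":
        # the protocol's lower bound is reported both as 15.0 and 15.8 C;
        # 15.8 is the default, the other bound stays selectable
        return StimulusProtocol("Osci1523", t_low, 23.0)

    @staticmethod
    def osci17() -> "StimulusProtocol":
        return StimulusProtocol(
            "Osci17", 16.5, 17.0, osc_amplitude=0.25, has_ramp=False, n_cycles=15,
        )

    @staticmethod
    def fluc1719() -> "StimulusProtocol":
        return StimulusProtocol(
            "Fluc1719", 17.5, 19.5, has_ramp=False, noise_cutoff_hz=0.1,
        )

    @staticmethod
    def by_name(name: str) -> "StimulusProtocol":
        factories = {
            "osci1721": StimulusProtocol.osci1721,
            "osci1523": StimulusProtocol.osci1523,
            "osci17": StimulusProtocol.osci17,
            "fluc1719": StimulusProtocol.fluc1719,
        }
        try:
            return factories[name.lower()]()
        except KeyError:
            raise ParameterError(
                f"unknown protocol {name!r}; choose from {sorted(factories)}"
            ) from None


def make_stimulus(
    protocol: StimulusProtocol, dt: float = 0.5, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (time, temperature) for one protocol realisation.

    Oscillatory ramps are a linear trend between the bounds (inset by the
    oscillation amplitude) plus a sinusoid; Osci17 is a pure sinusoid for
    an integer number of cycles; Fluc protocols are seeded low-pass
    Gaussian noise clipped to the bounds.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if protocol.n_cycles is not None:
        duration = protocol.n_cycles / protocol.frequency_hz
    else:
        duration = protocol.duration_s
    time = np.arange(0.0, duration, dt)

    if protocol.noise_cutoff_hz is not None:
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(time.size)
        sos = sps.butter(4, protocol.noise_cutoff_hz, fs=1.0 / dt, output="sos")
        smooth = sps.sosfiltfilt(sos, white)
        center = (protocol.t_low + protocol.t_high) / 2.0
        scale = (protocol.t_high - protocol.t_low) / 4.0  # ~2 SD inside the bounds
        temp = center + scale * smooth / np.std(smooth)
        return time, np.clip(temp, protocol.t_low, protocol.t_high)

    a = protocol.osc_amplitude
    osc = a * np.sin(2.0 * np.pi * protocol.frequency_hz * time)
    if protocol.has_ramp:
        base = (protocol.t_low + a) + (protocol.t_high - protocol.t_low - 2 * a) * (
            time / duration
        )
    else:
        base = np.full(time.size, (protocol.t_low + protocol.t_high) / 2.0)
    return time, base + osc


@dataclass(frozen=True)
class SynapticKernel:
    """Superposed excitatory/inhibitory Gaussian synaptic kernel."""

    u_plus: float
    u_minus: float
    sigma_plus: float
    sigma_minus: float
    tau_lag: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_plus <= 0 or self.sigma_minus <= 0:
            raise ParameterError("kernel widths must be positive")
        if not (self.u_plus > 0 >= self.u_minus):
            raise ParameterError("need U+ > 0 >= U-")

    def support_s(self) -> float:
        return 4.0 * max(self.sigma_plus, self.sigma_minus) + abs(self.tau_lag)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return self.u_plus * np.exp(-(t**2) / (2 * self.sigma_plus**2)) + (
            self.u_minus
            * np.exp(-((t - self.tau_lag) ** 2) / (2 * self.sigma_minus**2))
        )

    @staticmethod
    def well_fed() -> "SynapticKernel":
        # fast excitation, no inhibition: AIY tracks AFD in phase
        return SynapticKernel(u_plus=1.0, u_minus=0.0, sigma_plus=2.0, sigma_minus=3.0)

    @staticmethod
    def starved() -> "SynapticKernel":
        # slow excitation keeps a positive baseline through rectification;
        # strong sharp inhibition inverts the 0.025-Hz component -> anti-phase
        return SynapticKernel(
            u_plus=1.0, u_minus=-2.5, sigma_plus=10.0, sigma_minus=3.0
        )


def simulate_afd(
    time: np.ndarray,
    temperature: np.ndarray,
    t_star: float = 17.0,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> CalciumSignal:
    """Threshold-rectified AFD response to a thermal stimulus.

    activity = gain * max(0, T(t) - T*), min-max normalized, plus seeded
    Gaussian measurement noise.  A stimulus never crossing T* yields an
    all-zero response with a degenerate-signal warning.
    """
    if gain <= 0:
        raise ParameterError("gain must be positive")
    temperature = np.asarray(temperature, dtype=float)
    resp = gain * np.clip(temperature - t_star, 0.0, None)
    if resp.max() <= 0.0:
        warnings.warn(f"stimulus never exceeds T* = {t_star} C: all-zero AFD response")
    elif resp.max() > resp.min():
        resp = (resp - resp.min()) / (resp.max() - resp.min())
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, resp.size)
    return CalciumSignal(time=np.asarray(time, float), y=resp, stage="synthetic",
                         channel="AFD")


def simulate_aiy(
    afd: CalciumSignal,
    kernel: SynapticKernel,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> CalciumSignal:
    """AIY response: AFD activity convolved with the synaptic kernel,
    rectified at zero, min-max normalized, plus seeded noise.

    The kernel is truncated at +/- (4 max(sigma) + |tau_lag|).  An exactly
    cancelling kernel yields a flat response with a warning.
    """
    dt = afd.dt
    half = int(np.ceil(kernel.support_s() / dt))
    tk = np.arange(-half, half + 1) * dt
    if tk.size > afd.y.size:
        raise LengthError(
            f"kernel support ({tk.size} samples) exceeds the signal ({afd.y.size})"
        )
    k = kernel.evaluate(tk)
    y = np.convolve(afd.y, k, mode="same") * dt
    y = np.clip(y, 0.0, None)
    if y.max() > y.min():
        y = (y - y.min()) / (y.max() - y.min())
    else:
        warnings.warn("kernel cancels the AFD signal: flat AIY response")
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, y.size)
    return CalciumSignal(time=afd.time.copy(), y=y, stage="synthetic", channel="AIY")


@dataclass
class CohortSpec:
    """Generative configuration for one condition's cohort of animals."""

    n_animals: int = 16
    condition: str = "well_fed"
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol.osci1721)
    t_star: float = 17.0
    kernel: SynapticKernel | None = None  # None -> condition default
    t_star_jitter_sd: float = 0.1
    kernel_jitter_sd: float = 0.05
    noise_sd: float = 0.05
    dt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ParameterError("need at least one animal")
        if self.noise_sd < 0 or self.t_star_jitter_sd < 0 or self.kernel_jitter_sd < 0:
            raise ParameterError("jitter/noise SDs must be nonnegative")
        if self.kernel is None:
            self.kernel = (
                SynapticKernel.well_fed()
                if self.condition == "well_fed"
                else SynapticKernel.starved()
            )


# fluorescence scaling used to export activity as raw-fluorescence-like counts
_F_BASELINE = 100.0
_F_DYNAMIC = 1.0


def simulate_cohort(spec: CohortSpec) -> tuple[list[AnimalRecording], pd.DataFrame]:
    """Simulate one cohort; returns (recordings, ground-truth table).

    Each animal gets jittered threshold and kernel magnitudes, shared
    stimulus, independent measurement noise, and its activity is scaled
    to fluorescence counts F = F0 (1 + activity) so the full dF/F0
    preprocessing chain applies downstream.
    """
    rng = np.random.default_rng(spec.seed)
    time, temp = make_stimulus(spec.protocol, dt=spec.dt,
                               seed=int(rng.integers(2**31)))
    recordings: list[AnimalRecording] = []
    truth_rows = []
    for i in range(spec.n_animals):
        animal_id = f"{spec.condition}_{i:03d}"
        t_star_i = spec.t_star + rng.normal(0.0, spec.t_star_jitter_sd)
        k0 = spec.kernel
        scale_p = 1.0 + rng.normal(0.0, spec.kernel_jitter_sd)
        scale_m = 1.0 + rng.normal(0.0, spec.kernel_jitter_sd)
        kernel_i = replace(
            k0,
            u_plus=max(k0.u_plus * scale_p, 1e-6),
            u_minus=min(k0.u_minus * scale_m, 0.0),
        )
        afd = simulate_afd(time, temp, t_star=t_star_i, noise_sd=0.0)
        aiy = simulate_aiy(afd, kernel_i, noise_sd=0.0)
        afd_y = afd.y + rng.normal(0.0, spec.noise_sd, afd.y.size)
        aiy_y = aiy.y + rng.normal(0.0, spec.noise_sd, aiy.y.size)
        recordings.append(
            AnimalRecording(
                animal_id=animal_id,
                condition=spec.condition,
                temperature=temp,
                afd=FluorescenceTrace(time, _F_BASELINE * (1 + _F_DYNAMIC * afd_y),
                                      channel="AFD", animal_id=animal_id),
                aiy=FluorescenceTrace(time, _F_BASELINE * (1 + _F_DYNAMIC * aiy_y),
                                      channel="AIY", animal_id=animal_id),
                stimulus_id=spec.protocol.name,
            )
        )
        truth_rows.append(
            {
                "animal_id": animal_id,
                "condition": spec.condition,
                "stimulus_id": spec.protocol.name,
                "seed": spec.seed,
                "t_star_C": t_star_i,
                "u_plus": kernel_i.u_plus,
                "u_minus": kernel_i.u_minus,
                "sigma_plus_s": kernel_i.sigma_plus,
                "sigma_minus_s": kernel_i.sigma_minus,
                "tau_lag_s": kernel_i.tau_lag,
                "noise_sd": spec.noise_sd,
            }
        )
    return recordings, pd.DataFrame(truth_rows)


def recordings_to_frame(recordings: list[AnimalRecording]) -> pd.DataFrame:
    """Long-format traces table (the CSV layout `load_recordings` reads)."""
    parts = []
    for rec in recordings:
        parts.append(
            pd.DataFrame(
                {
                    "animal_id": rec.animal_id,
                    "condition": rec.condition,
                    "time_s": rec.time,
                    "temp_C": rec.temperature,
                    "F_afd": rec.afd.value,
                    "F_aiy": rec.aiy.value,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


@dataclass
class TrackPolicy:
    """Locomotion and event-injection parameters for synthetic tracks."""

    speed_um_s: float = 120.0
    curving_bias_deg_s: float = 10.0     # restoring turn toward the +x (warm) axis
    heading_noise_deg_s: float = 20.0
    omega_rate_hz: float = 0.01
    reversal_rate_hz: float = 0.01
    omega_duration_s: float = 3.0
    omega_turn_deg_s: float = 130.0
    omega_shrink: float = 0.6            # body-length factor during the turn
    body_length_um: float = 1000.0
    length_noise: float = 0.01
    plate_halfwidth_um: float = 45000.0  # 9-cm assay plate

    def __post_init__(self) -> None:
        if self.omega_rate_hz < 0 or self.reversal_rate_hz < 0:
            raise ParameterError("event rates must be nonnegative")


def _draw_event_starts(
    rng: np.random.Generator, rate_hz: float, n_frames: int, frame_rate: float,
    taken: list[tuple[int, int]], dur_frames: int, min_gap_frames: int,
) -> list[int]:
    expected = rate_hz * n_frames / frame_rate
    n_events = rng.poisson(expected)
    starts: list[int] = []
    candidates = rng.integers(min_gap_frames, max(n_frames - dur_frames - min_gap_frames, min_gap_frames + 1), size=4 * (n_events + 1))
    for c in candidates:
        if len(starts) >= n_events:
            break
        c = int(c)
        span = (c - min_gap_frames, c + dur_frames + min_gap_frames)
        clash = any(s0 <= span[1] and s1 >= span[0] for s0, s1 in taken)
        if not clash:
            starts.append(c)
            taken.append((c, c + dur_frames))
    return sorted(starts)


def simulate_tracks(
    n_worms: int = 20,
    duration_s: float = 1200.0,
    seed: int | None = None,
    policy: TrackPolicy | None = None,
    frame_rate: float = FRAME_RATE_HZ,
) -> tuple[list[WormTrack], dict]:
    """Random-walk worm tracks with injected omega turns and reversals.

    Returns (tracks, ground truth): per worm, the injected event
    intervals as inclusive frame-index pairs.  Worms reflect at the
    plate boundary; a reflection that turns the heading by more than
    150 degrees genuinely reverses the trajectory, so it is recorded in
    the reversal ground truth alongside the injected episodes.
    """
    if duration_s <= 0:
        raise ParameterError("duration must be positive")
    policy = policy or TrackPolicy()
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    n = int(round(duration_s * frame_rate))
    omega_dur = int(round(policy.omega_duration_s * frame_rate))
    rev_dur = int(round(frame_rate))  # detectable for ~one lag second
    min_gap = int(round(5.0 * frame_rate))
    hw = policy.plate_halfwidth_um

    tracks: list[WormTrack] = []
    truth: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for w in range(n_worms):
        wid = f"worm_{w:03d}"
        taken: list[tuple[int, int]] = []
        omega_starts = _draw_event_starts(
            rng, policy.omega_rate_hz, n, frame_rate, taken, omega_dur, min_gap
        )
        rev_starts = _draw_event_starts(
            rng, policy.reversal_rate_hz, n, frame_rate, taken, rev_dur, min_gap
        )
        omega_sign = {s: rng.choice([-1.0, 1.0]) for s in omega_starts}

        in_omega = np.zeros(n, dtype=bool)
        omega_turn = np.zeros(n)
        for s in omega_starts:
            in_omega[s: s + omega_dur] = True
            omega_turn[s: s + omega_dur] = omega_sign[s] * policy.omega_turn_deg_s
        flip = np.zeros(n, dtype=bool)
        for s in rev_starts:
            flip[s] = True

        noise = rng.normal(0.0, policy.heading_noise_deg_s, n)
        len_noise = 1.0 + rng.normal(0.0, policy.length_noise, n)

        pos = np.empty((n, 2))
        heading = np.empty(n)
        pos[0] = rng.uniform(-5000.0, 5000.0, 2)
        heading[0] = rng.uniform(-np.pi, np.pi)
        wall_reversals: list[tuple[int, int]] = []
        for i in range(1, n):
            h = heading[i - 1]
            if flip[i]:
                h = h + np.pi
            if in_omega[i]:
                turn = omega_turn[i]
            else:
                turn = -policy.curving_bias_deg_s * np.sin(h) + noise[i]
            h = h + np.deg2rad(turn) * dt
            h_in = h
            p = pos[i - 1] + policy.speed_um_s * dt * np.array([np.cos(h), np.sin(h)])
            if abs(p[0]) > hw:
                p[0] = np.sign(p[0]) * 2 * hw - p[0]
                h = np.pi - h
            if abs(p[1]) > hw:
                p[1] = np.sign(p[1]) * 2 * hw - p[1]
                h = -h
            if abs(np.angle(np.exp(1j * (h - h_in)))) > np.deg2rad(150.0):
                if not wall_reversals or i - wall_reversals[-1][0] > rev_dur:
                    wall_reversals.append((i, min(i + rev_dur - 1, n - 1)))
            heading[i] = np.angle(np.exp(1j * h))
            pos[i] = p

        length = policy.body_length_um * len_noise
        length = np.where(in_omega, length * policy.omega_shrink, length)
        # 11 straight body points trailing the centroid along the heading
        offsets = np.arange(11)[None, :] * (length / 10.0)[:, None]
        direction = np.stack([np.cos(heading), np.sin(heading)], axis=1)
        segments = pos[:, None, :] - offsets[:, :, None] * direction[:, None, :]

        tracks.append(
            WormTrack(
                animal_id=wid,
                frame=np.arange(n),
                time=np.arange(n) * dt,
                centroid=pos,
                segments=segments,
                frame_rate=frame_rate,
            )
        )
        truth[wid] = {
            "omega_turns": [(s, s + omega_dur - 1) for s in omega_starts],
            "reversals": sorted(
                [(s, s + rev_dur - 1) for s in rev_starts] + wall_reversals
            ),
        }
    return tracks, truth
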