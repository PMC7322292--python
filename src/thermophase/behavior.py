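"""Thermotaxis behavior from multi-worm-tracker trajectories.

Tracks live in a plate coordinate frame with the x axis parallel to the
thermal gradient (warmer = +x) and y parallel to the isotherms.  From
the centroid trajectory the module derives, at ~13.5 Hz frame rate:

- the moving vector r(t): displacement from the centroid one second
  earlier to the current centroid;
- the moving direction theta in [0 deg, 180 deg], 0 = warmer, 180 =
  colder (the sign of the isothermal component is discarded);
- the curving rate phi: unsigned angle per second between the current
  moving vector and the one a second earlier;
- omega turns: frames where the body length drops more than 1.5 SD
  below that animal's own mean AND the curving rate exceeds 90 deg/s
  (the tracker underestimates body length when the worm curls into an
  omega posture);
- reversals: frames where the 3-frame mean curving rate exceeds
  150 deg/s;

plus plate-level summaries: occupancy fractions across gradient
sections and the curving-rate profile conditioned on moving direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._peaks import bool_runs
from .errors import FormatError, LengthError, ParameterError, SchemaError

FRAME_RATE_HZ = 13.5
UM_PER_PX = 33.2

_SEG_COLS = [f"s{i}{ax}" for i in range(1, 12) for ax in ("x", "y")]
TRACK_COLUMNS = ["frame", "time_s", "animal_id", "cx_um", "cy_um", *_SEG_COLS]


@dataclass
class WormTrack:
    """One animal's trajectory: centroid plus 11 body points per frame."""

    animal_id: str
    frame: np.ndarray            # consecutive integers
    time: np.ndarray             # seconds
    centroid: np.ndarray         # (n, 2) in um
    segments: np.ndarray         # (n, 11, 2) in um
    frame_rate: float = FRAME_RATE_HZ

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.segments = np.asarray(self.segments, dtype=float)
        n = self.frame.size
        if not np.all(np.diff(self.frame) == 1):
            raise FormatError(f"track {self.animal_id}: frames not consecutive")
        if self.centroid.shape != (n, 2) or self.segments.shape != (n, 11, 2):
            raise FormatError(f"track {self.animal_id}: malformed coordinate arrays")

    @property
    def n_frames(self) -> int:
        return int(self.frame.size)

    def body_length(self) -> np.ndarray:
        """Polyline length through the 11 body points, per frame (um)."""
        d = np.diff(self.segments, axis=1)
        return np.sum(np.hypot(d[..., 0], d[..., 1]), axis=1)


@dataclass
class BehaviorEvents:
    """Detected omega-turn and reversal intervals (inclusive frame-index pairs)."""

    omega_turns: list[tuple[int, int]] = field(default_factory=list)
    reversals: list[tuple[int, int]] = field(default_factory=list)


def load_tracks(path: str | Path, frame_rate: float = FRAME_RATE_HZ) -> list[WormTrack]:
    """Read a tracks TSV (columns frame, time_s, animal_id, cx_um, cy_um,
    s1x..s11y) into one :class:`WormTrack` per animal."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    tracks = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("frame")
        seg = grp[_SEG_COLS].to_numpy(dtype=float).reshape(-1, 11, 2)
        tracks.append(
            WormTrack(
                animal_id=str(animal_id),
                frame=grp["frame"].to_numpy(),
                time=grp["time_s"].to_numpy(dtype=float),
                centroid=grp[["cx_um", "cy_um"]].to_numpy(dtype=float),
                segments=seg,
                frame_rate=frame_rate,
            )
        )
    return tracks


def tracks_to_frame(tracks: list[WormTrack]) -> pd.DataFrame:
    """Long-format table of a track list (inverse of :func:`load_tracks`)."""
    parts = []
    for tr in tracks:
        d = {
            "frame": tr.frame,
            "time_s": tr.time,
            "animal_id": tr.animal_id,
            "cx_um": tr.centroid[:, 0],
            "cy_um": tr.centroid[:, 1],
        }
        flat = tr.segments.reshape(tr.n_frames, 22)
        for j, col in enumerate(_SEG_COLS):
            d[col] = flat[:, j]
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)[TRACK_COLUMNS]


def _lag_frames(frame_rate: float, lag_s: float) -> int:
    # round-half-up: 13.5 Hz * 1 s -> 14 frames
    return int(np.floor(frame_rate * lag_s + 0.5))


def moving_vector(track: WormTrack, lag: float = 1.0) -> np.ndarray:
    """r(t) = centroid(t) - centroid(t - lag); NaN for the first lag frames."""
    k = _lag_frames(track.frame_rate, lag)
    if track.n_frames <= k:
        raise LengthError(
            f"track {track.animal_id}: {track.n_frames} frames < lag of {k}"
        )
    r = np.full_like(track.centroid, np.nan)
    r[k:] = track.centroid[k:] - track.centroid[:-k]
    return r


def moving_direction(r: np.ndarray) -> np.ndarray:
    """Angle of r from the +x (warmer) axis folded to [0, 180] degrees.

    Zero vectors and undefined rows give NaN.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    norm = np.hypot(r[:, 0], r[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(r[:, 0] / norm, -1.0, 1.0)))
    theta[norm == 0] = np.nan
    return theta if theta.size > 1 else theta


def curving_rate(track: WormTrack, lag: float = 1.0) -> np.ndarray:
    """Unsigned angle (deg/s) between the moving vector and the one ``lag``
    seconds earlier; NaN where either vector is undefined or zero."""
    r = moving_vector(track, lag)
    k = _lag_frames(track.frame_rate, lag)
    phi = np.full(track.n_frames, np.nan)
    now, prev = r[k:], r[:-k]
    dot = np.einsum("ij,ij->i", now, prev)
    cross = now[:, 0] * prev[:, 1] - now[:, 1] * prev[:, 0]
    norms = np.hypot(*now.T) * np.hypot(*prev.T)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.abs(np.arctan2(cross, dot)))
    ang[norms == 0] = np.nan
    phi[k:] = ang / lag
    return phi


def angle_between(r_prev: np.ndarray, r_now: np.ndarray, lag: float = 1.0) -> float:
    """Curving rate (deg/s) between two single moving vectors."""
    r_prev = np.asarray(r_prev, dtype=float)
    r_now = np.asarray(r_now, dtype=float)
    if np.hypot(*r_prev) == 0 or np.hypot(*r_now) == 0:
        return float("nan")
    dot = float(np.dot(r_prev, r_now))
    cross = float(r_prev[0] * r_now[1] - r_prev[1] * r_now[0])
    return float(np.degrees(abs(np.arctan2(cross, dot))) / lag)


def detect_omega_turns(track: WormTrack, lag: float = 1.0) -> list[tuple[int, int]]:
    """Frames where body length < mean - 1.5 SD (per animal) AND curving
    rate > 90 deg/s, merged into maximal consecutive-frame events."""
    if track.n_frames / track.frame_rate < 30.0:
        raise LengthError(
            f"track {track.animal_id}: need >= 30 s to estimate body-length statistics"
        )
    bl = track.body_length()
    mean, sd = float(np.mean(bl)), float(np.std(bl, ddof=1))
    if sd == 0.0:
        warnings.warn(f"track {track.animal_id}: zero body-length variance, no events")
        return []
    phi = curving_rate(track, lag)
    with np.errstate(invalid="ignore"):
        mask = (bl < mean - 1.5 * sd) & (phi > 90.0)
    return bool_runs(np.nan_to_num(mask, nan=0).astype(bool))


def detect_reversals(track: WormTrack, lag: float = 1.0) -> list[tuple[int, int]]:
    """Frames where the 3-frame mean curving rate exceeds 150 deg/s, merged."""
    phi = curving_rate(track, lag)
    if np.sum(np.isfinite(phi)) < 3:
        return []
    padded = np.concatenate([[np.nan], phi, [np.nan]])
    window = np.stack([padded[:-2], padded[1:-1], padded[2:]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        rolling = np.nanmean(window, axis=0)
    mask = np.nan_to_num(rolling, nan=0.0) > 150.0
    return bool_runs(mask)


def detect_events(track: WormTrack, lag: float = 1.0) -> BehaviorEvents:
    """Omega turns and reversals for one track (the detectors are independent:
    a frame may satisfy both)."""
    return BehaviorEvents(
        omega_turns=detect_omega_turns(track, lag),
        reversals=detect_reversals(track, lag),
    )


def section_distribution(
    tracks: list[WormTrack],
    n_sections: int = 8,
    time_bin: float = 300.0,
    x_extent: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fraction of animal-frames in each of ``n_sections`` equal x-slices of
    the plate, per time bin.  Rows (time bins) sum to 1; empty bins are NaN.
    """
    if n_sections < 2:
        raise ParameterError("need at least 2 sections")
    x = np.concatenate([tr.centroid[:, 0] for tr in tracks])
    t = np.concatenate([tr.time for tr in tracks])
    if x_extent is None:
        x_extent = (float(np.min(x)), float(np.max(x)))
    edges = np.linspace(x_extent[0], x_extent[1], n_sections + 1)
    t_edges = np.arange(0.0, np.max(t) + time_bin, time_bin)
    rows = []
    for lo, hi in zip(t_edges[:-1], t_edges[1:]):
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            rows.append(np.full(n_sections, np.nan))
            continue
        counts, _ = np.histogram(np.clip(x[sel], *x_extent), bins=edges)
        rows.append(counts / counts.sum())
    return pd.DataFrame(
        rows,
        index=pd.Index(t_edges[:-1], name="time_bin_start_s"),
        columns=[f"section_{i + 1}" for i in range(n_sections)],
    )


def curving_profile(
    tracks: list[WormTrack],
    window: tuple[float, float],
    direction_bin_deg: float = 30.0,
    lag: float = 1.0,
) -> pd.Series:
    """Mean curving rate conditioned on moving-direction bin, within a time
    window.  Bins with no frames are NaN."""
    edges = np.arange(0.0, 180.0 + direction_bin_deg, direction_bin_deg)
    centers = (edges[:-1] + edges[1:]) / 2.0
    sums = np.zeros(centers.size)
    counts = np.zeros(centers.size)
    for tr in tracks:
        phi = curving_rate(tr, lag)
        theta = moving_direction(moving_vector(tr, lag))
        sel = (tr.time >= window[0]) & (tr.time <= window[1])
        sel &= np.isfinite(phi) & np.isfinite(theta)
        idx = np.clip(np.digitize(theta[sel], edges) - 1, 0, centers.size - 1)
        np.add.at(sums, idx, phi[sel])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=pd.Index(centers, name="direction_deg"),
                     name="mean_curving_deg_per_s")


def score_event_recovery(
    detected: list[tuple[int, int]],
    truth: list[tuple[int, int]],
    tol_frames: int = 14,
) -> tuple[float, float]:
    """(precision, recall) of detected vs injected event intervals.

    A detection matches a true event when the intervals overlap after
    dilating the true interval by ``tol_frames`` on each side; each true
    event can be claimed once.
    """
    claimed = [False] * len(truth)
    tp = 0
    for ds, de in detected:
        for i, (ts, te) in enumerate(truth):
            if claimed[i]:
                continue
            if ds <= te + tol_frames and de >= ts - tol_frames:
                claimed[i] = True
                tp += 1
                break
    precision = tp / len(detected) if detected else 1.0  # no detections: vacuous
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
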