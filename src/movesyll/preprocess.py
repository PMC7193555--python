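"""Raw-signal conditioning: resampling, band-pass filtering, axis
harmonization, and sliding-window extraction.

The analysis chain brings every device recording (128 Hz in-clinic, 250 Hz
at-home, or anything else above the band) to a common 25 Hz rate, keeps the
0.2-3 Hz band where voluntary wrist movement lives (excluding both gravity/DC
and the 4-6 Hz parkinsonian tremor band), flips the right wrist's y-axis so
both wrists share a body-relative frame, and cuts the signal into overlapping
1-second windows flattened to 75-dimensional vectors (25 samples x 3 axes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from movesyll.errors import ValidationError

__all__ = [
    "RawRecording",
    "WindowSet",
    "resample_to_rate",
    "bandpass",
    "harmonize_axes",
    "extract_windows",
]


@dataclass
class RawRecording:
    """Timestamped tri-axial acceleration from one wrist.

    Parameters
    ----------
    t : (n,) array of seconds, strictly increasing.
    accel : (n, 3) array, columns x/y/z, in the declared units.
    rate_hz : nominal device sampling rate.
    wrist_side : "left" or "right" (None if unknown).
    units : "g" or "m/s2"; clustering is unit-sensitive so cohorts must agree.
    """

    participant_id: str
    session_id: str
    t: np.ndarray
    accel: np.ndarray
    rate_hz: float
    wrist_side: str | None = None
    units: str = "g"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError("accel must be an (n, 3) array")
        if self.t.shape[0] != self.accel.shape[0]:
            raise ValidationError("t and accel lengths differ")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if self.rate_hz <= 0:
            raise ValidationError("rate_hz must be positive")
        if self.wrist_side not in (None, "left", "right"):
            raise ValidationError(f"unknown wrist side {self.wrist_side!r}")

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.n_samples / self.rate_hz)


@dataclass
class WindowSet:
    """Ordered flattened window vectors with their start times.

    Each vector is the axis-block-wise flattening (all x samples, then y,
    then z) of one window of ``round(window_s * rate_hz)`` samples.
    """

    session_id: str
    window_vectors: np.ndarray  # (n_windows, 3 * L)
    start_times: np.ndarray     # (n_windows,) seconds
    rate_hz: float = 25.0
    window_s: float = 1.0
    step_s: float = 0.24
    units: str = "g"
    adl_label: str | None = None

    def __post_init__(self) -> None:
        self.window_vectors = np.asarray(self.window_vectors, dtype=float)
        self.start_times = np.asarray(self.start_times, dtype=float)
        if self.window_vectors.ndim != 2:
            raise ValidationError("window_vectors must be 2-D")
        if self.window_vectors.shape[0] != self.start_times.shape[0]:
            raise ValidationError("one start time per window required")

    @property
    def n_windows(self) -> int:
        return int(self.window_vectors.shape[0])

    @property
    def vector_length(self) -> int:
        return int(self.window_vectors.shape[1])


def resample_to_rate(rec: RawRecording, target_rate_hz: float = 25.0) -> RawRecording:
    """Down-sample a recording to the analysis rate (default 25 Hz).

    Uses polyphase rational resampling with the built-in anti-alias low-pass;
    128 -> 25 Hz is a non-integer ratio so a rational approximation of the
    rate ratio is used.  Upsampling is refused: the pipeline only reduces
    rates ahead of band-pass filtering.
    """
    if rec.n_samples == 0:
        raise ValidationError("empty input")
    if target_rate_hz > rec.rate_hz:
        raise ValidationError("upsampling not supported")
    if target_rate_hz == rec.rate_hz:
        return replace(rec)

    ratio = Fraction(target_rate_hz / rec.rate_hz).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    out = signal.resample_poly(rec.accel, up, down, axis=0)
    t0 = float(rec.t[0])
    t = t0 + np.arange(out.shape[0]) / target_rate_hz
    return replace(rec, t=t, accel=out, rate_hz=float(target_rate_hz))


def design_bandpass(
    low_hz: float, high_hz: float, rate_hz: float, order: int = 3
) -> np.ndarray:
    """Second-order sections of the order-3 Butterworth band-pass."""
    if not 0 < low_hz < high_hz < rate_hz / 2:
        raise ValidationError(
            f"invalid band ({low_hz}, {high_hz}) at rate {rate_hz} Hz"
        )
    return signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=rate_hz, output="sos"
    )


def bandpass_gain(
    freq_hz: float, low_hz: float = 0.2, high_hz: float = 3.0,
    rate_hz: float = 25.0, order: int = 3,
) -> float:
    """Single-pass magnitude response of the designed filter at ``freq_hz``.

    The pipeline applies the filter forward-backward (zero phase), so the
    effective amplitude gain is this value squared.
    """
    sos = design_bandpass(low_hz, high_hz, rate_hz, order)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=rate_hz)
    return float(np.abs(h[0]))


def bandpass(
    rec: RawRecording,
    low_hz: float = 0.2,
    high_hz: float = 3.0,
    order: int = 3,
) -> RawRecording:
    """Band-pass each axis independently (zero-phase Butterworth).

    Forward-backward application preserves the shape and timing of movement
    motifs at the cost of doubling the effective order.  DC (gravity
    projection) is removed; frequencies above 3 Hz, including parkinsonian
    tremor, are strongly attenuated.
    """
    if rec.n_samples == 0:
        raise ValidationError("empty input")
    sos = design_bandpass(low_hz, high_hz, rec.rate_hz, order)
    out = signal.sosfiltfilt(sos, rec.accel, axis=0)
    return replace(rec, accel=out)


def harmonize_axes(rec: RawRecording, force: bool = False) -> RawRecording:
    """Negate the y-axis of right-wrist recordings.

    Left and right wrists mirror each other about the body midline; flipping
    the right wrist's y-axis puts both in the same body-relative frame so a
    single syllable vocabulary serves both sides.  ``force=True`` applies the
    flip regardless of side (the transform is an involution).
    """
    if rec.wrist_side is None and not force:
        raise ValidationError("unknown wrist side")
    if force or rec.wrist_side == "right":
        accel = rec.accel.copy()
        accel[:, 1] = -accel[:, 1]
        return replace(rec, accel=accel)
    return replace(rec)


def window_count(n_samples: int, window_len: int, step: int) -> int:
    """Number of full windows: floor((N - L) / S) + 1."""
    if n_samples < window_len:
        return 0
    return (n_samples - window_len) // step + 1


def extract_windows(
    rec: RawRecording, window_s: float = 1.0, step_s: float = 0.24
) -> WindowSet:
    """Cut the recording into overlapping flattened windows.

    Windows are anchored at sample indices 0, S, 2S, ... with
    L = round(window_s * rate_hz) samples per axis and
    S = round(step_s * rate_hz) samples of step (at the 25 Hz default,
    L = 25 and S = 6 exactly).  Each window is flattened axis-block-wise:
    the 25 x samples, then the 25 y samples, then the 25 z samples -> 75
    values.  This order is fixed and must match between vocabulary fitting
    and assignment.
    """
    L = int(round(window_s * rec.rate_hz))
    S = int(round(step_s * rec.rate_hz))
    if S < 1:
        raise ValidationError("step shorter than one sample")
    if rec.n_samples < L:
        raise ValidationError("recording too short")

    n_win = window_count(rec.n_samples, L, S)
    starts = np.arange(n_win) * S
    # (n_win, L, 3) strided view -> transpose axes block-wise -> (n_win, 3*L)
    idx = starts[:, None] + np.arange(L)[None, :]
    blocks = rec.accel[idx]                       # (n_win, L, 3)
    vectors = blocks.transpose(0, 2, 1).reshape(n_win, 3 * L)
    return WindowSet(
        session_id=rec.session_id,
        window_vectors=vectors,
        start_times=rec.t[starts],
        rate_hz=rec.rate_hz,
        window_s=window_s,
        step_s=step_s,
        units=rec.units,
    )


def preprocess_recording(
    rec: RawRecording,
    rate_hz: float = 25.0,
    low_hz: float = 0.2,
    high_hz: float = 3.0,
    order: int = 3,
    window_s: float = 1.0,
    step_s: float = 0.24,
) -> WindowSet:
    """Full conditioning chain: resample -> band-pass -> harmonize -> window."""
    rec = resample_to_rate(rec, rate_hz)
    rec = bandpass(rec, low_hz, high_hz, order)
    rec = harmonize_axes(rec)
    return extract_windows(rec, window_s, step_s)
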