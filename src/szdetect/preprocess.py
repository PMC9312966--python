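"""Preprocessing chain: notch, band-pass bank, sliding windows, labels.

The chain mirrors the standard intracranial workflow: a 50 Hz notch removes
line noise, six zero-phase Butterworth band-passes split the signal into the
alpha (8-13 Hz), beta1 (13-21), beta2 (21-30), low- (30-40), medium- (40-70)
and high-gamma (70-120 Hz) rhythms, and a sliding window of length L seconds
advancing S seconds at a time turns each (electrode, band) signal into a
stream of fixed-length segments.  Every emitted window instant carries the
current segment and the previous one (shifted back by S), which bivariate
"method A" features compare against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import signal

from .recording import Recording


class BandSpec(NamedTuple):
    """A frequency band, named after its lower edge (B8 = 8-13 Hz alpha...)."""

    name: str
    lo: float
    hi: float


#: the six analysis bands, alpha through high gamma
BANDS: tuple[BandSpec, ...] = (
    BandSpec("B8", 8.0, 13.0),
    BandSpec("B13", 13.0, 21.0),
    BandSpec("B21", 21.0, 30.0),
    BandSpec("B30", 30.0, 40.0),
    BandSpec("B40", 40.0, 70.0),
    BandSpec("B70", 70.0, 120.0),
)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length L and shift S, in seconds."""

    L: float = 2.0
    S: float = 1.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.S <= 0:
            raise ValueError("window length and shift must be positive")

    def samples(self, fs: float) -> tuple[int, int]:
        """(L, S) in samples; both must be integral at rate ``fs``."""
        L_smp, S_smp = self.L * fs, self.S * fs
        if abs(L_smp - round(L_smp)) > 1e-9 or abs(S_smp - round(S_smp)) > 1e-9:
            raise ValueError(f"L*fs and S*fs must be integral (L={self.L}, S={self.S}, fs={fs})")
        return int(round(L_smp)), int(round(S_smp))


def notch_filter(rec: Recording, f0: float = 50.0, quality: float = 30.0) -> Recording:
    """Zero-phase 50 Hz notch (second-order IIR, quality factor 30)."""
    if rec.fs <= 2 * f0:
        raise ValueError(f"sampling rate {rec.fs} too low to notch at {f0} Hz")
    b, a = signal.iirnotch(f0, quality, fs=rec.fs)
    return rec.with_samples(signal.filtfilt(b, a, rec.samples, axis=1))


def bandpass_bank(
    rec: Recording, bands: Sequence[BandSpec] = BANDS, order: int = 4
) -> dict[str, Recording]:
    """Zero-phase order-4 Butterworth band-pass per analysis band."""
    nyq = rec.fs / 2.0
    for band in bands:
        if band.hi >= nyq:
            raise ValueError(f"band {band.name} upper edge {band.hi} Hz >= Nyquist {nyq} Hz")
    out = {}
    for band in bands:
        sos = signal.butter(order, [band.lo, band.hi], btype="bandpass", fs=rec.fs, output="sos")
        out[band.name] = rec.with_samples(signal.sosfiltfilt(sos, rec.samples, axis=1))
    return out


def label_window(t: float, ictal_intervals: Iterable[tuple[float, float]]) -> str:
    """Label the window ending at time ``t``.

    A window is ictal ("Y") iff its terminal sample time lies inside an
    annotated interval, intervals being half-open ``[start, end)``.
    """
    for start, end in ictal_intervals:
        if start <= t < end:
            return "Y"
    return "N"


@dataclass
class WindowedBank:
    """The (L, S) window stream over all (electrode, band) signals.

    Segments are exposed lazily as views into the band-filtered arrays, so a
    multi-hour recording never materializes its ~GB of overlapping windows.
    Instant ``t`` covers the signal interval ``(t - L, t]``; the first raw
    instant (which has no previous segment) is never emitted.
    """

    band_signals: dict[str, np.ndarray]  # band name -> (n_channels, n_samples)
    fs: float
    window: WindowSpec
    instants: np.ndarray  # terminal times, seconds
    labels: np.ndarray  # "Y"/"N" per instant
    band_names: tuple[str, ...] = field(init=False)
    n_channels: int = field(init=False)

    def __post_init__(self) -> None:
        self.band_names = tuple(self.band_signals)
        first = next(iter(self.band_signals.values()))
        self.n_channels = first.shape[0]

    def __len__(self) -> int:
        return len(self.instants)

    def segment(self, i: int, channel: int, band: str) -> tuple[np.ndarray, np.ndarray]:
        """(current, previous) L-second segments at instant ``i`` (views)."""
        L_smp, S_smp = self.window.samples(self.fs)
        end = int(round(self.instants[i] * self.fs))
        sig = self.band_signals[band]
        cur = sig[channel, end - L_smp : end]
        prev = sig[channel, end - L_smp - S_smp : end - S_smp]
        return cur, prev


def slide_windows(
    band_recs: Mapping[str, Recording],
    spec: WindowSpec = WindowSpec(),
    ictal_intervals: Sequence[tuple[float, float]] | None = None,
) -> WindowedBank:
    """Build the sliding-window stream over a dict of band-filtered recordings.

    Emits ``floor((duration - L) / S)`` instants at times ``L + S, L + 2S,
    ...``; the raw first instant ``t = L`` is dropped because it has no
    previous segment.  A recording shorter than ``L + S`` yields an empty
    stream with a warning.
    """
    recs = list(band_recs.values())
    if not recs:
        raise ValueError("no band signals given")
    fs = recs[0].fs
    n = recs[0].n_samples
    for r in recs:
        if r.fs != fs or r.n_samples != n:
            raise ValueError("band recordings must share sampling rate and length")
    if ictal_intervals is None:
        ictal_intervals = recs[0].ictal_intervals
    L_smp, S_smp = spec.samples(fs)
    duration = n / fs

    n_instants = int(np.floor((duration - spec.L) / spec.S)) if duration >= spec.L else 0
    if duration < spec.L + spec.S:
        warnings.warn(
            f"recording of {duration:.2f} s shorter than L+S={spec.L + spec.S:.2f} s; "
            "empty window stream",
            stacklevel=2,
        )
        n_instants = 0
    end_indices = L_smp + S_smp * np.arange(1, n_instants + 1)
    instants = end_indices / fs
    labels = np.array([label_window(t, ictal_intervals) for t in instants], dtype=object)
    return WindowedBank(
        band_signals={name: r.samples for name, r in band_recs.items()},
        fs=fs,
        window=spec,
        instants=instants,
        labels=labels,
    )


def window_bank(
    rec: Recording,
    bands: Sequence[BandSpec] = BANDS,
    window: WindowSpec = WindowSpec(),
    notch_hz: float | None = 50.0,
) -> WindowedBank:
    """Full preprocessing chain: notch -> band-pass bank -> sliding windows."""
    if notch_hz is not None:
        rec = notch_filter(rec, notch_hz)
    return slide_windows(bandpass_bank(rec, bands), window, rec.ictal_intervals)
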