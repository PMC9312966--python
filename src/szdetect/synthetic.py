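"""Synthetic intracranial EEG with planted seizures.

The generator emulates the statistical structure the detection pipeline
assumes of focal-epilepsy archives: six channels sampled at 256 Hz, an
interictal background of 1/f ("pink") noise plus an alpha rhythm, and ictal
episodes during which the channels near the epileptic focus additionally
carry rhythmic high-gamma (40-120 Hz) activity well above the background
RMS.  Seizure onset and offset are ramped over a couple of seconds, which
reproduces the fuzzy-onset detection delay seen in clinical traces, and
isolated broadband transients stand in for recording artifacts, the usual
source of interictal false positives.

This is not a physiological EEG model; it provides labeled signals whose
band-power contrasts are strong enough for every downstream stage to be
tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .recording import Recording, default_roles

#: background pink-noise RMS, microvolts (typical intracranial amplitude scale)
BACKGROUND_NOISE_RMS = 20.0

ALPHA_FREQ_HZ = 10.0
ICTAL_BAND_HZ = (45.0, 115.0)
RAMP_S = 2.0
ARTIFACT_DURATION_S = 0.5
ARTIFACT_AMP_FACTOR = 10.0  # relative to BACKGROUND_NOISE_RMS


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording.

    ``infokus_channels`` are 1-based electrode numbers (E1..En); by default
    the first three electrodes sit near the focus, matching the archive
    convention the pipeline targets.  Amplitudes are in microvolts:
    ``background_alpha_amp`` is the peak amplitude of the alpha sinusoid and
    ``ictal_gamma_amp`` the RMS of the high-gamma seizure component (the
    default is ~4.5x the total background RMS).
    """

    duration_s: float
    n_channels: int = 6
    fs: float = 256.0
    ictal_intervals: Sequence[tuple[float, float]] = ()
    infokus_channels: frozenset[int] = frozenset({1, 2, 3})
    background_alpha_amp: float = 10.0
    ictal_gamma_amp: float = 100.0
    artifact_rate_per_hour: float = 6.0
    phase_tag: str | None = None  # derived from intervals when None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for amp in (self.background_alpha_amp, self.ictal_gamma_amp, self.artifact_rate_per_hour):
            if amp < 0:
                raise ValueError("amplitudes and rates must be nonnegative")
        if not set(self.infokus_channels) <= set(range(1, self.n_channels + 1)):
            raise ValueError("infokus_channels must be 1-based channel numbers")
        ivals = sorted((float(a), float(b)) for a, b in self.ictal_intervals)
        for a, b in ivals:
            if b - a < 1.0:
                raise ValueError(f"ictal interval ({a}, {b}) shorter than 1 s")
            if a < 0 or b > self.duration_s:
                raise ValueError(f"ictal interval ({a}, {b}) outside [0, {self.duration_s}]")
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError("ictal intervals must be pairwise disjoint")
        self.ictal_intervals = ivals


@dataclass
class GroundTruth:
    """True seizure intervals and the recording's phase tag."""

    ictal_intervals: list[tuple[float, float]] = field(default_factory=list)
    phase_tag: str = "interictal"

    def __post_init__(self) -> None:
        if self.phase_tag == "interictal" and self.ictal_intervals:
            raise ValueError("interictal recordings cannot contain ictal intervals")


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # flatten below 1 Hz so the variance stays finite
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec * shaping, n)
    return x / max(x.std(), 1e-30)


def _ramped_envelope(t: np.ndarray, start: float, end: float, ramp_s: float) -> np.ndarray:
    """Trapezoidal 0..1 envelope over [start, end] with linear ramps."""
    ramp = min(ramp_s, (end - start) / 2.0)
    env = np.zeros_like(t)
    inside = (t >= start) & (t < end)
    env[inside] = 1.0
    if ramp > 0:
        rise = inside & (t < start + ramp)
        fall = inside & (t >= end - ramp)
        env[rise] = (t[rise] - start) / ramp
        env[fall] = (end - t[fall]) / ramp
    return env


def generate_recording(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Generate one labeled synthetic recording.

    Outside ictal intervals every channel carries pink noise plus an alpha
    sinusoid with a random phase; inside them, InFokus channels additionally
    carry amplitude-ramped band-limited high-gamma activity at RMS
    ``ictal_gamma_amp``.  Identical ``spec.seed`` gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    samples = np.empty((spec.n_channels, n))

    for ch in range(spec.n_channels):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        samples[ch] = BACKGROUND_NOISE_RMS * _pink_noise(rng, n, spec.fs)
        samples[ch] += spec.background_alpha_amp * np.sin(2 * np.pi * ALPHA_FREQ_HZ * t + phase)

    if spec.ictal_intervals and spec.ictal_gamma_amp > 0:
        lo, hi = ICTAL_BAND_HZ
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=spec.fs, output="sos")
        for start, end in spec.ictal_intervals:
            env = _ramped_envelope(t, start, end, RAMP_S)
            for ch in sorted(spec.infokus_channels):
                burst = signal.sosfiltfilt(sos, rng.standard_normal(n))
                burst /= max(burst.std(), 1e-30)
                samples[ch - 1] += spec.ictal_gamma_amp * env * burst

    if spec.artifact_rate_per_hour > 0:
        n_art = rng.poisson(spec.artifact_rate_per_hour * spec.duration_s / 3600.0)
        width = int(round(ARTIFACT_DURATION_S * spec.fs))
        window = np.hanning(width)
        amp = ARTIFACT_AMP_FACTOR * BACKGROUND_NOISE_RMS
        for _ in range(n_art):
            start_idx = int(rng.uniform(0, max(n - width, 1)))
            for ch in range(spec.n_channels):
                samples[ch, start_idx : start_idx + width] += (
                    amp * window[: n - start_idx] * rng.standard_normal(min(width, n - start_idx))
                )

    phase_tag = spec.phase_tag
    if phase_tag is None:
        phase_tag = "ictal" if spec.ictal_intervals else "interictal"
    rec = Recording(
        samples=samples,
        fs=spec.fs,
        channel_roles=default_roles(spec.n_channels, sorted(spec.infokus_channels)),
        phase_tag=phase_tag,
        ictal_intervals=list(spec.ictal_intervals),
    )
    truth = GroundTruth(ictal_intervals=list(spec.ictal_intervals), phase_tag=phase_tag)
    return rec, truth
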