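"""Multichannel EEG recordings and their on-disk formats.

Recordings are plain numeric matrices in microvolts, one row per sample and
one column per channel (the whitespace-delimited ASCII dialect used for
intracranial archives), with seizure annotations kept in a separate CSV of
``recording_id,start_s,end_s`` intervals.  EDF input is supported through
:mod:`mne` when that package is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

IN_FOKUS = "InFokus"
OUT_FOKUS = "OutFokus"
_ROLES = (IN_FOKUS, OUT_FOKUS)
PHASES = ("preictal", "ictal", "interictal")

DEFAULT_FS = 256.0


class AsciiParseError(ValueError):
    """Raised when an ASCII recording file is ragged or non-numeric."""


def default_roles(n_channels: int, infokus: Sequence[int] = (1, 2, 3)) -> list[str]:
    """Channel roles with 1-based electrodes ``infokus`` near the focus."""
    return [IN_FOKUS if (i + 1) in set(infokus) else OUT_FOKUS for i in range(n_channels)]


@dataclass
class Recording:
    """A multichannel EEG signal plus its acquisition metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in samples per second (256 for the archives this
        package targets).
    channel_roles : list of str
        ``"InFokus"`` / ``"OutFokus"`` per channel.
    phase_tag : str
        One of ``preictal``, ``ictal``, ``interictal``.
    ictal_intervals : list of (start_s, end_s)
        Annotated seizure intervals, half-open ``[start, end)`` seconds.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    channel_roles: list[str] = field(default_factory=list)
    phase_tag: str = "interictal"
    ictal_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise ValueError("samples must be a (n_channels, n_samples) matrix with >= 1 channel")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.channel_roles:
            self.channel_roles = default_roles(self.n_channels)
        if len(self.channel_roles) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_roles)} channel roles for {self.n_channels} channels"
            )
        bad = set(self.channel_roles) - set(_ROLES)
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        if self.phase_tag not in PHASES:
            raise ValueError(f"phase_tag must be one of {PHASES}")
        self.ictal_intervals = [(float(a), float(b)) for a, b in self.ictal_intervals]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "Recording":
        """Copy of the recording with the signal replaced (same metadata)."""
        return replace(self, samples=samples)


def read_ascii_recording(
    path: str | Path,
    fs: float = DEFAULT_FS,
    roles: Sequence[str] | None = None,
    phase_tag: str = "interictal",
    ictal_intervals: Sequence[tuple[float, float]] = (),
) -> Recording:
    """Read a whitespace-delimited numeric matrix (rows = samples)."""
    try:
        mat = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:  # ragged rows or non-numeric tokens
        raise AsciiParseError(f"cannot parse {path}: {exc}") from exc
    if mat.size == 0:
        raise AsciiParseError(f"{path} contains no samples")
    samples = mat.T  # file is samples x channels
    if roles is not None and len(roles) != samples.shape[0]:
        raise AsciiParseError(
            f"{path}: {samples.shape[0]} columns but {len(roles)} channel roles"
        )
    return Recording(
        samples=samples,
        fs=fs,
        channel_roles=list(roles) if roles is not None else [],
        phase_tag=phase_tag,
        ictal_intervals=list(ictal_intervals),
    )


def write_ascii(rec: Recording, path: str | Path, decimals: int = 6) -> None:
    """Write a recording as an ASCII matrix, one row per sample.

    Values are quantized to ``decimals`` decimal places; reading the file
    back recovers exactly the quantized values.
    """
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    np.savetxt(path, rec.samples.T, fmt=f"%.{decimals}f")


def read_edf_recording(
    path: str | Path,
    roles: Sequence[str] | None = None,
    phase_tag: str = "interictal",
    ictal_intervals: Sequence[tuple[float, float]] = (),
) -> Recording:
    """Read an EDF file (requires ``mne``); signal converted to microvolts."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne uses volts
    return Recording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel_roles=list(roles) if roles is not None else [],
        phase_tag=phase_tag,
        ictal_intervals=list(ictal_intervals),
    )


def read_annotations(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read a seizure-annotation CSV into ``{recording_id: [(start, end), ...]}``."""
    df = pd.read_csv(path, dtype={"recording_id": str})
    required = {"recording_id", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file {path} must have columns {sorted(required)}")
    out: dict[str, list[tuple[float, float]]] = {}
    for rec_id, sub in df.groupby("recording_id", sort=False):
        out[str(rec_id)] = list(zip(sub["start_s"].astype(float), sub["end_s"].astype(float)))
    return out


def write_annotations(
    path: str | Path, intervals_by_id: dict[str, Sequence[tuple[float, float]]]
) -> None:
    rows = [
        {"recording_id": rid, "start_s": a, "end_s": b}
        for rid, ivals in intervals_by_id.items()
        for a, b in ivals
    ]
    pd.DataFrame(rows, columns=["recording_id", "start_s", "end_s"]).to_csv(path, index=False)
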