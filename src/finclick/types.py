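"""Shared domain types for click detection and context modelling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SyntheticClick:
    """A planted ground-truth click.

    ``snr_db`` is measured in the 87-145 kHz band relative to the
    background-noise RMS in that band.
    """

    center_time: float      # s from clip start
    peak_frequency: float   # Hz
    duration: float         # s
    snr_db: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (87_000.0 <= self.peak_frequency <= 145_000.0):
            raise ValueError(
                f"peak_frequency {self.peak_frequency} Hz outside the NBHF "
                "band [87, 145] kHz"
            )


@dataclass
class AudioClip:
    """A mono waveform with its sampling rate and epoch start time."""

    samples: np.ndarray       # dimensionless amplitudes in [-1, 1]
    sample_rate: float        # Hz
    start_time: float = 0.0   # s within the study day

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate < 290_000:
            raise ValueError(
                "sample_rate must be >= 290 kHz so Nyquist covers 145 kHz"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must all be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class SpectrumSample:
    """One labelled STFT magnitude spectrum (nfft/2 + 1 bins)."""

    magnitude: np.ndarray
    label: str                # "click" or "noise"

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.label not in ("click", "noise"):
            raise ValueError(f"label must be 'click' or 'noise', got {self.label!r}")
        if np.any(self.magnitude < 0):
            raise ValueError("spectral magnitudes must be non-negative")


@dataclass(frozen=True)
class ClickEvent:
    """A detected click: centre time, extent, peak frequency and SVM score."""

    time: float             # s (event centre)
    duration: float         # s
    peak_frequency: float   # Hz
    score: float            # classifier probability in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


@dataclass
class ClickTrain:
    """>= 5 consecutive clicks with every inter-click interval <= 200 ms."""

    clicks: list[ClickEvent]
    icis: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.clicks) < 5:
            raise ValueError("a click train needs at least 5 clicks")
        if not self.icis:
            self.icis = [b.time - a.time
                         for a, b in zip(self.clicks, self.clicks[1:])]
        if len(self.icis) != len(self.clicks) - 1:
            raise ValueError("icis must have len(clicks) - 1 entries")
        if any(ici > 0.200 + 1e-12 for ici in self.icis):
            raise ValueError("every inter-click interval must be <= 200 ms")

    @property
    def start(self) -> float:
        return self.clicks[0].time

    @property
    def end(self) -> float:
        return self.clicks[-1].time
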