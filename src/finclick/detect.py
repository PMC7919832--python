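"""NBHF click detection: high-pass filter, STFT, SVM frame classifier,
click-event extraction, per-minute click density and train segmentation.

The processing chain mirrors standard passive-acoustic click logging for
porpoises: the recording is high-pass filtered (Kaiser-window FIR,
beta = 0.5, 80 kHz cut-off), transformed with a short-time Fourier
transform (window 512, noverlap 256, nfft 512), each frame's magnitude
spectrum is classified click/noise by a support vector machine trained on
labelled spectra, consecutive click frames are merged into click events,
and events are aggregated into clicks-per-minute ("click density") and
segmented into trains (>= 5 clicks, inter-click intervals <= 200 ms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .types import AudioClip, ClickEvent, ClickTrain, SpectrumSample

__all__ = [
    "DetectorConfig",
    "ClassifierModel",
    "design_highpass",
    "highpass_filter",
    "spectrogram",
    "spectra_to_arrays",
    "train_classifier",
    "kfold_accuracy",
    "classify_frames",
    "frames_to_clicks",
    "detect_clicks",
    "click_density",
    "segment_trains",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Detector front-end and decision parameters.

    Defaults follow the analysis this package re-creates: 80 kHz cut-off
    Kaiser (beta 0.5) FIR high-pass, STFT geometry 512/256/512, and a
    click acceptance band of 87-128 kHz.  ``score_threshold`` applies to
    the classifier's click probability; ``merge_gap`` is the number of
    noise frames tolerated inside one click event (0 = contiguous runs).
    """

    cutoff: float = 80_000.0
    kaiser_beta: float = 0.5
    filter_taps: int = 255
    stft_window: int = 512
    stft_noverlap: int = 256
    stft_nfft: int = 512
    click_band: tuple[float, float] = (87_000.0, 128_000.0)
    score_threshold: float = 0.5
    merge_gap: int = 0
    normalization: str = "max"   # per-frame spectrum scaling: "max" | "none"

    def __post_init__(self) -> None:
        if not (0 < self.stft_noverlap < self.stft_window <= self.stft_nfft):
            raise ValueError("require 0 < noverlap < window <= nfft")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.normalization not in ("max", "none"):
            raise ValueError("normalization must be 'max' or 'none'")

    @property
    def n_bins(self) -> int:
        return self.stft_nfft // 2 + 1

    @property
    def hop(self) -> int:
        return self.stft_window - self.stft_noverlap


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_highpass(config: DetectorConfig, sample_rate: float) -> np.ndarray:
    """Design the linear-phase Kaiser-window FIR high-pass filter.

    Raises if the cut-off is at or above Nyquist.  The returned taps are
    symmetric (type-I linear phase with the default odd tap count).
    """
    if config.cutoff >= sample_rate / 2:
        raise ValueError(
            f"cutoff {config.cutoff} Hz must be below Nyquist "
            f"{sample_rate / 2} Hz"
        )
    return signal.firwin(
        config.filter_taps,
        config.cutoff,
        window=("kaiser", config.kaiser_beta),
        pass_zero=False,
        fs=sample_rate,
    )


def highpass_filter(clip: AudioClip, coefficients: np.ndarray) -> AudioClip:
    """Apply the FIR high-pass with zero net delay (centred convolution)."""
    if len(clip.samples) == 0:
        raise ValueError("clip is empty")
    y = signal.fftconvolve(clip.samples, coefficients, mode="same")
    return AudioClip(samples=y, sample_rate=clip.sample_rate,
                     start_time=clip.start_time)


# ---------------------------------------------------------------------------
# STFT
# ---------------------------------------------------------------------------

def spectrogram(
    clip: AudioClip, config: DetectorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude STFT with the configured geometry.

    Returns ``(frame_times, frequencies, magnitude)`` where ``magnitude``
    has shape ``(nfft/2 + 1, n_frames)`` and
    ``n_frames = floor((N - noverlap) / (window - noverlap))`` (no padding).
    Frame times are window centres in seconds from clip start.
    """
    x = clip.samples
    if len(x) < config.stft_window:
        raise ValueError("clip shorter than one STFT window")
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=clip.sample_rate,
        window=signal.get_window("hamming", config.stft_window),
        nperseg=config.stft_window,
        noverlap=config.stft_noverlap,
        nfft=config.stft_nfft,
        detrend=False,
        mode="magnitude",
    )
    return times, freqs, sxx


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

def _normalize(X: np.ndarray, mode: str) -> np.ndarray:
    """Per-row spectrum normalisation (amplitude invariance)."""
    if mode == "none":
        return X
    peak = X.max(axis=1, keepdims=True)
    peak[peak == 0] = 1.0
    return X / peak


def spectra_to_arrays(
    dataset: list[SpectrumSample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a SpectrumSample list into (X, y) with y=1 for clicks."""
    X = np.vstack([s.magnitude for s in dataset])
    y = np.array([1 if s.label == "click" else 0 for s in dataset])
    return X, y


@dataclass
class ClassifierModel:
    """A trained binary spectrum classifier with its metadata.

    ``svm`` is a Platt-calibrated RBF SVM: scores are sigmoid-calibrated
    probabilities, monotone in the SVM decision value.
    """

    svm: CalibratedClassifierCV
    n_bins: int
    normalization: str
    n_samples: int
    seed: int
    cv_accuracy: float | None = None
    format_version: int = 1

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels (1 = click) and click-probability scores for spectra rows."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_bins:
            raise ValueError(
                f"expected spectra with {self.n_bins} bins, got shape {X.shape}"
            )
        Xn = _normalize(X, self.normalization)
        idx = list(self.svm.classes_).index(1)
        scores = self.svm.predict_proba(Xn)[:, idx]
        return (scores >= 0.5).astype(int), scores


def train_classifier(
    dataset: list[SpectrumSample],
    seed: int,
    config: DetectorConfig | None = None,
    C: float = 1.0,
) -> ClassifierModel:
    """Fit the RBF-kernel SVM on labelled spectra.

    Deterministic given ``seed`` (which controls the Platt probability
    calibration folds).  Requires both labels and at least 10 samples.
    """
    config = config or DetectorConfig()
    if len(dataset) < 10:
        raise ValueError("need at least 10 training samples")
    X, y = spectra_to_arrays(dataset)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both labels")
    Xn = _normalize(X, config.normalization)
    folds = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    svm = CalibratedClassifierCV(
        SVC(C=C, kernel="rbf", gamma="scale", random_state=seed),
        method="sigmoid", cv=folds, ensemble=False)
    svm.fit(Xn, y)
    return ClassifierModel(
        svm=svm,
        n_bins=X.shape[1],
        normalization=config.normalization,
        n_samples=len(dataset),
        seed=seed,
    )


def kfold_accuracy(
    dataset: list[SpectrumSample],
    k: int,
    seed: int,
    config: DetectorConfig | None = None,
    C: float = 1.0,
) -> float:
    """Mean held-out accuracy over k stratified folds.

    Raises when k < 2 or when either class has fewer than k members.
    """
    config = config or DetectorConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = spectra_to_arrays(dataset)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members, got counts {counts.tolist()}"
        )
    Xn = _normalize(X, config.normalization)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in folds.split(Xn, y):
        svm = SVC(C=C, kernel="rbf", gamma="scale", random_state=seed)
        svm.fit(Xn[train_idx], y[train_idx])
        accs.append(float(np.mean(svm.predict(Xn[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def classify_frames(
    magnitudes: np.ndarray,
    frequencies: np.ndarray,
    model: ClassifierModel,
    config: DetectorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify STFT frames; returns boolean click labels and scores.

    ``magnitudes`` has shape (n_bins, n_frames) as returned by
    :func:`spectrogram`.  Labels apply ``config.score_threshold`` to the
    click probability.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    if magnitudes.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if magnitudes.shape[0] != model.n_bins:
        raise ValueError(
            f"frame bin count {magnitudes.shape[0]} does not match model "
            f"input size {model.n_bins}"
        )
    _, scores = model.predict(magnitudes.T)
    return scores >= config.score_threshold, scores


# ---------------------------------------------------------------------------
# events, density, trains
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal index runs of True, merging runs separated by <= merge_gap."""
    idx = np.flatnonzero(labels)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev - 1 <= merge_gap:
            prev = int(i)
        else:
            runs.append((start, prev))
            start = prev = int(i)
    runs.append((start, prev))
    return runs


def frames_to_clicks(
    labels: np.ndarray,
    frame_times: np.ndarray,
    config: DetectorConfig,
    scores: np.ndarray | None = None,
    magnitudes: np.ndarray | None = None,
    frequencies: np.ndarray | None = None,
    sample_rate: float | None = None,
) -> list[ClickEvent]:
    """Merge runs of click-labelled frames into click events.

    Runs separated by at most ``merge_gap`` noise frames form one event,
    centred at the run's frame-time midpoint.  When spectra are provided
    the event peak frequency is taken from the run-averaged spectrum
    (restricted to frequencies above the high-pass cut-off) and events
    whose peak falls outside ``config.click_band`` are rejected; otherwise
    the peak frequency is reported as NaN and no band gating happens.
    """
    labels = np.asarray(labels, dtype=bool)
    frame_times = np.asarray(frame_times, dtype=float)
    if labels.shape != frame_times.shape:
        raise ValueError("labels and frame_times must have the same length")
    frame_len = (config.stft_window / sample_rate) if sample_rate else 0.0
    events: list[ClickEvent] = []
    for i0, i1 in _runs(labels, config.merge_gap):
        t = 0.5 * (frame_times[i0] + frame_times[i1])
        duration = (frame_times[i1] - frame_times[i0]) + frame_len
        peak = float("nan")
        if magnitudes is not None and frequencies is not None:
            spec = np.asarray(magnitudes)[:, i0 : i1 + 1].mean(axis=1)
            mask = np.asarray(frequencies) >= config.cutoff
            sub = np.where(mask, spec, -np.inf)
            peak = float(np.asarray(frequencies)[int(np.argmax(sub))])
            if not (config.click_band[0] <= peak <= config.click_band[1]):
                continue
        score = 1.0
        if scores is not None:
            score = float(np.max(np.asarray(scores)[i0 : i1 + 1]))
        events.append(ClickEvent(time=float(t), duration=float(duration),
                                 peak_frequency=peak, score=score))
    return events


def detect_clicks(
    clip: AudioClip,
    model: ClassifierModel,
    config: DetectorConfig | None = None,
) -> list[ClickEvent]:
    """Full detection chain: filter -> STFT -> classify -> merge to events."""
    config = config or DetectorConfig()
    coefs = design_highpass(config, clip.sample_rate)
    filtered = highpass_filter(clip, coefs)
    times, freqs, mag = spectrogram(filtered, config)
    labels, scores = classify_frames(mag, freqs, model, config)
    return frames_to_clicks(labels, times, config, scores=scores,
                            magnitudes=mag, frequencies=freqs,
                            sample_rate=clip.sample_rate)


def click_density(
    events: list[ClickEvent],
    clip_duration: float,
    clip_start: float = 0.0,
) -> pd.DataFrame:
    """Clicks per complete one-minute bin.

    Minute bins are half-open ``[60k, 60(k+1))`` seconds from clip start;
    only complete bins are reported.  Clips shorter than one minute yield
    an empty table and a warning.
    """
    n_minutes = int(clip_duration // 60)
    if n_minutes == 0:
        warnings.warn("clip shorter than one minute: no density bins",
                      stacklevel=2)
        return pd.DataFrame(columns=["minute_index", "click_count"]).astype(int)
    counts = np.zeros(n_minutes, dtype=int)
    for e in events:
        if not (0.0 <= e.time < clip_duration):
            raise ValueError(f"event at t={e.time}s outside [0, {clip_duration})")
        k = int(e.time // 60)
        if k < n_minutes:
            counts[k] += 1
    base = int(clip_start // 60)
    return pd.DataFrame({
        "minute_index": np.arange(n_minutes) + base,
        "click_count": counts,
    })


def segment_trains(
    events: list[ClickEvent],
    min_clicks: int = 5,
    max_ici: float = 0.200,
) -> list[ClickTrain]:
    """Greedy left-to-right grouping of events into click trains.

    A train extends while the next inter-click interval is <= ``max_ici``;
    completed groups with fewer than ``min_clicks`` clicks are discarded.
    Events must be time-ordered.
    """
    times = [e.time for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("events must be time-ordered")
    trains: list[ClickTrain] = []
    group: list[ClickEvent] = []
    for e in events:
        if group and (e.time - group[-1].time) > max_ici:
            if len(group) >= min_clicks:
                trains.append(ClickTrain(clicks=group))
            group = []
        group.append(e)
    if len(group) >= min_clicks:
        trains.append(ClickTrain(clicks=group))
    return trains
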